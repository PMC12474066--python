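# Reference values for the Dongping Lake heavy-metal risk pipeline.
#
# water_limit: GB 3838-2002 Class III surface-water limits (ug/L), as tabulated
#   for the twelve measured metals.
# background:  mean element contents of Yellow River sediments (mg/kg), the
#   regional geochemical baseline for the lake's fluvially derived sediments.
# toxicity:    Hakanson toxic-response coefficients (dimensionless).
# tel/pel:     freshwater sediment-quality guideline values (mg/kg).
#   RECONSTRUCTED from the SQG literature: the guideline table used by the
#   original survey is unpublished; values here are consistent with its
#   qualitative screening findings. Metals without entries are skipped by the
#   screen with a warning.
# rfd/sf:      oral reference doses (mg/kg/day) and slope factors
#   ((mg/kg/day)^-1), IRIS-style values as used in sediment health-risk
#   studies. RECONSTRUCTED: the survey's appendix parameter table is
#   unpublished.
# All values editable; downstream indices recompute from whatever is loaded.

source: "GB 3838-2002 Class III; Yellow River sediment backgrounds; Hakanson Tr; reconstructed SQG + IRIS-style toxicology"
k: 1

water_limit:
  Cr: 5
  Mn: 100
  Fe: 300
  Co: 1000
  Ni: 20
  Ti: 100
  V: 50
  Cu: 1000
  Zn: 1000
  As: 50
  Cd: 5
  Pb: 50

background:
  Cr: 60.65
  Mn: 571
  Ni: 28
  Cu: 21
  Zn: 59
  V: 75
  Cd: 0.113
  Pb: 20
  Co: 11.1

toxicity:
  Cd: 30
  Co: 5
  Pb: 5
  Cu: 5
  Ni: 5
  Cr: 2
  V: 2
  Zn: 1
  Mn: 1

tel:
  Cr: 90
  Ni: 30
  Cu: 35.7
  Zn: 80
  Cd: 1.2
  Pb: 60

pel:
  Cr: 370
  Ni: 70
  Cu: 197
  Zn: 320
  Cd: 4.2
  Pb: 160

rfd:
  Cr: 0.003
  Mn: 0.046
  V: 0.007
  Pb: 0.0035
  Ni: 0.02
  Co: 0.02
  Cu: 0.04
  Cd: 0.001
  Zn: 0.3

sf:
  Cr: 0.5
  Ni: 0.84
  Cd: 6.1
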