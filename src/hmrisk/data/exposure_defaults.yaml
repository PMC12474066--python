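# Receptor exposure parameters for sediment ingestion / dermal / inhalation
# pathways, EPA RAGS-style residential defaults as used in Chinese
# sediment/soil health-risk studies. RECONSTRUCTED: the survey's appendix
# parameter table is unpublished; all values overridable.
#
# Units: IR_ing mg/day; IR_inh m3/day; SA cm2; AF mg/(cm2*day); ABS, unitless
# fraction; PEF m3/kg; EF days/year; ED years; BW kg; AT_ca days (70-year
# lifetime); CF kg/mg. AT for non-carcinogens defaults to ED*365.

child:
  IR_ing: 200
  IR_inh: 7.6
  SA: 2800
  AF: 0.2
  ABS: 0.001
  PEF: 1.36e9
  EF: 350
  ED: 6
  BW: 15
  AT_ca: 25550
  CF: 1.0e-6

adult_female:
  IR_ing: 100
  IR_inh: 14.5
  SA: 5700
  AF: 0.07
  ABS: 0.001
  PEF: 1.36e9
  EF: 350
  ED: 24
  BW: 55
  AT_ca: 25550
  CF: 1.0e-6

adult_male:
  IR_ing: 100
  IR_inh: 16.6
  SA: 5700
  AF: 0.07
  ABS: 0.001
  PEF: 1.36e9
  EF: 350
  ED: 24
  BW: 65
  AT_ca: 25550
  CF: 1.0e-6
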