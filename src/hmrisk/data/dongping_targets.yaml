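# Generator targets transcribing the Dongping Lake survey's summary
# statistics: per-metal mean/SD/min/max for 33 water sites (ug/L) and 31
# sediment sites (mg/kg), plus mean BCR fraction profiles (percent).
#
# Corrections applied to the printed table (documented in docs/methods.md):
#   - water Cd SD: the printed 0.110 contradicts both the printed CV (0.150)
#     and the 0-0.040 range; SD here is CV*mean = 0.0033.
#   - sediment Ni min/max: printed swapped (max < mean < min); restored.
#
# BCR fraction profiles: the survey states only the dominant fraction(s) per
# metal (e.g. Cd F1 48.6, Pb F2 27.55, V F4 95.42). Full four-fraction
# vectors are RECONSTRUCTED around those stated values, preserving the
# reported RAC ordering (Cd >> Pb,Zn,Co,Ni,Cu > V,Cr) and band memberships.

water:
  n_sites: 33
  metals:
    Cr: {mean: 0.464, sd: 0.369, min: 0.170, max: 1.390}
    Mn: {mean: 1.332, sd: 1.088, min: 0.350, max: 5.860}
    Fe: {mean: 15.002, sd: 7.354, min: 7.510, max: 36.810}
    Co: {mean: 0.097, sd: 0.020, min: 0.070, max: 0.180}
    Ni: {mean: 1.145, sd: 0.106, min: 0.930, max: 1.540}
    Ti: {mean: 1.335, sd: 1.185, min: 0.070, max: 4.300}
    V: {mean: 1.505, sd: 0.195, min: 0.950, max: 1.890}
    Cu: {mean: 0.900, sd: 0.150, min: 0.630, max: 1.510}
    Zn: {mean: 3.620, sd: 2.432, min: 0.560, max: 10.260}
    As: {mean: 3.483, sd: 0.939, min: 2.050, max: 5.530}
    Cd: {mean: 0.022, sd: 0.0033, min: 0.0, max: 0.040}
    Pb: {mean: 0.050, sd: 0.038, min: 0.0, max: 0.120}

sediment:
  n_sites: 31
  metals:
    Cr: {mean: 79.44, sd: 11.46, min: 64.15, max: 121.06}
    Mn: {mean: 761.46, sd: 180.07, min: 527.41, max: 1396.08}
    Ni: {mean: 42.07, sd: 6.79, min: 29.78, max: 65.50}
    Cu: {mean: 33.19, sd: 8.94, min: 14.58, max: 52.09}
    Zn: {mean: 78.84, sd: 23.76, min: 35.83, max: 125.28}
    V: {mean: 95.65, sd: 16.30, min: 64.58, max: 143.45}
    Cd: {mean: 0.512, sd: 0.23, min: 0.15, max: 1.09}
    Pb: {mean: 32.99, sd: 9.06, min: 13.98, max: 57.20}
    Co: {mean: 18.57, sd: 4.01, min: 12.01, max: 31.19}

speciation:
  n_sites: 31
  concentration: 100          # Dirichlet precision for per-site fraction noise
  fractions:                  # [F1 weak-acid, F2 reducible, F3 oxidizable, F4 residual], percent
    V:  [0.50, 1.50, 2.58, 95.42]
    Cr: [0.80, 2.50, 4.49, 92.21]
    Co: [4.00, 5.00, 4.29, 86.71]
    Ni: [6.00, 9.00, 7.45, 77.55]
    Cu: [4.00, 3.50, 6.74, 85.76]
    Zn: [8.00, 20.00, 15.26, 56.74]
    Cd: [48.60, 25.00, 6.40, 20.00]
    Pb: [3.00, 27.55, 5.01, 64.44]
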