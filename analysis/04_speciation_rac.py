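"""BCR speciation profiles and Risk Assessment Code.

Finding: residual (F4) fractions dominate V, Cr, Co, Ni, Cu (geogenic, low
bioavailability); Cd is nearly half weak-acid-soluble (F1 ~ 48.6%, RAC high
risk), Pb notably reducible (F2 ~ 27.55%). RAC ranks Cd far above all other
metals, with V and Cr risk-free.
"""

import argparse
from pathlib import Path

from hmrisk import synth
from hmrisk.speciation import fraction_profile, rac_by_site

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out-dir", type=Path, default=Path("results"))
args = ap.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

spec = synth.load_generator_spec(seed=args.seed)
table = synth.generate_speciation(spec)

prof = fraction_profile(table)
prof.round(2).to_csv(args.out_dir / "fraction_profile.csv", index_label="metal")
res = rac_by_site(table)
res.values.round(2).to_csv(args.out_dir / "rac_by_site.csv", index_label="site")

print("mean fraction profile (percent):")
print(prof.round(2).to_string())
print("\nRAC summary:")
for metal in sorted(res.summary, key=lambda m: -res.summary[m]["mean"]):
    s = res.summary[metal]
    print(f"  {metal}: mean {s['mean']:.2f}%, max {s['max']:.2f}%, classes {s['class_counts']}")
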