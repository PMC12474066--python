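# Methods

This package re-implements, as a tested pipeline, the coupled water–sediment
heavy-metal risk assessment applied to Dongping Lake (the terminal regulating
reservoir of the South-to-North Water Diversion's Eastern Route): water-column
HPI, sediment contamination and ecological-risk indices, BCR speciation with
the Risk Assessment Code, sediment-quality-guideline screening, EPA-style
multi-pathway health risk with Monte Carlo uncertainty and sensitivity, and
Pearson common-source screening. The original survey published only summary
statistics, so a seeded synthetic-data generator stands in for the 33-site
field dataset.

## Indices

**HPI (water).** Wi = k/Si, Qi = 100·ρi/Si, HPI = Σ QiWi / Σ Wi over the ten
prioritized metals (Ti, V, Cr, Mn, Fe, Co, Ni, Cu, Zn, As), with Si the
GB 3838-2002 Class III limit (µg/L) and critical value 100. k cancels in the
quotient and defaults to 1 (it is exposed in config only for completeness).
HPI is linear in the concentration vector, so the mean of per-site HPI equals
the HPI of mean concentrations exactly; this identity is used as an oracle.
Non-detects enter as 0 — no ½-LOD imputation, since the source data used none.
The stringent Cr limit (5 µg/L) is taken verbatim from the transcribed
standard table and is editable.

**Contamination and ecological risk (sediment).** Cf = C/Bn against Yellow
River sediment backgrounds; Er = Tr·Cf with Hakanson toxic-response
coefficients (Cd 30; Co, Pb, Cu, Ni 5; Cr, V 2; Zn, Mn 1); RI = Σ Er.
Er is linear in C, so lake-level Er values are computed from the published
means and agree exactly with averaging per-site Er over a moment-calibrated
synthetic table. Published worked values are reproduced to within the
rounding of their printed three-significant-figure inputs: we obtain
Er(Cd) = 135.93 and Er(Co) = 8.36 against printed 135.95 / 8.37 (half-ulp
propagation through Cf allows ±0.73 on Er(Cd) alone), and round-then-sum
RI = 175.79 versus the printed 175.82, which is the sum of the survey's own
rounded per-metal values. Tests assert |Δ| ≤ 0.03 per metal accordingly.

**Igeo.** log2(C/(1.5·Bn)), the Müller index with K = 1.5 absorbing
lithogenic background fluctuation. It is nonlinear in C, so the index of the
mean differs from the mean of per-site indices (Jensen gap); lake-level
reproduction from means is therefore documented as approximate. A non-detect
(C = 0) yields a −∞ sentinel that is flagged and propagated, never silently
dropped (exclusion would bias means upward).

**TEL/PEL screening.** Per-metal fractions of sites above the threshold and
probable effect levels. The guideline table used by the survey is
unpublished; shipped values are reconstructions from the freshwater SQG
literature, chosen to be consistent with the survey's qualitative screening
(no metal above PEL; most Ni and roughly half of Zn sites above TEL), and
flagged "reconstructed" in the config. Metals without thresholds are skipped
with a warning.

**RAC.** 100·F1/(F1+F2+F3+F4): the weak-acid-soluble share of the four BCR
fractions, scale-invariant between absolute contents and percentages. Bands:
<1 none, 1–10 low, 10–30 medium, 30–50 high, >50 very high (the standard
literature scale; the survey's appendix scale is unpublished). Whether
published per-metal fraction percentages are means of per-site percentages or
percentages of summed contents is ambiguous in the source; both are
implemented (`fraction_profile(pooled=...)`), defaulting to
mean-of-percentages. Closure tolerance is 0.5 percentage points — analytical
BCR data rarely close exactly — and violations warn per site.

**Health risk.** ADDs for sediment ingestion, dermal contact, and particulate
inhalation in product form (see `hmrisk.health`), with CF = 1e-6 kg/mg and
AT = ED·365 d (non-carcinogenic) or a 70-year lifetime (carcinogenic). The
source text prints a "×10⁻⁶" inside its hazard-quotient formula that is
inconsistent with its own HI results; we interpret it as the misplaced mg→kg
conversion and keep HQ = ADD/RfD with CF inside ADD. TEHI = Σ HQ (threshold
1); TCRI = Σ ADD·SF with bands 1e-6/1e-4. The carcinogen set defaults to
{Cr, Ni, Cd} (the survey's results ranking; its methods sentence "(Pb, Cr,
and Pb)" is an evident typo), configurable. With AT = ED·365, non-carcinogenic
ADD is independent of ED (exact cancellation) — a tested contract.

Exposure parameters and RfD/SF values ship as reconstructions (the survey's
appendix is unpublished): EPA RAGS-style residential defaults (child
IR 200 mg/d, ED 6 y, BW 15 kg; adults IR 100 mg/d, ED 24 y, BW 55/65 kg) and
IRIS-style toxicology (e.g. RfD Cr 0.003, Mn 0.046, V 0.007 mg/kg/d; SF
Cr 0.5, Ni 0.84, Cd 6.1 (mg/kg/d)⁻¹), selected once from the variants in use
in sediment health-risk studies so that the survey's stated structure holds
on its published means: HQ ranking led by Cr > Mn > V > Pb, TEHI < 1 for all
receptors, carcinogenic ranking Cr > Ni > Cd, and receptor ordering child >
adult female > adult male. Exact reproduction of the survey's HI = 0.408 or
TCR = 6.33e-4 magnitudes is **not** claimed — those depend on the unpublished
parameter table — and is not asserted anywhere; the packaged defaults give
child TEHI ≈ 0.91 and TCRI ≈ 8.6e-5.

## Monte Carlo

`run_mc` draws n joint samples (default 10,000) from per-parameter
distributions — point, normal, lognormal (parameterised by arithmetic
mean/SD), uniform, triangular, each optionally truncated by rejection with a
capped retry count — from a single seeded NumPy Generator, in sorted-key
order so runs are reproducible at the contract level. Draws propagate through
the vectorised TEHI/TCRI computation; outputs are summarised by mean,
P5/P50/P95, a normal-theory 95% CI of the mean, and threshold-exceedance
probabilities. Convergence is checked batch-wise on the running P95 (flag at
<1% relative change). Sensitivity is signed contribution-to-variance:
squared Spearman rank correlation of each input with the output, normalised
to 100% absolute and carrying the correlation's sign — the convention of the
spreadsheet risk tools used for this kind of assessment, since the source
defines no formula; rank basis makes it invariant to monotone input
rescaling. No Latin-hypercube or Sobol schemes are used. The survey's
reported inversion (0% unacceptable-risk probability for children against
6–7% for adults despite children's higher mean) cannot be reconstructed
without its unpublished distribution table; our defaults give the
non-inverted pattern.

## Synthetic data

The generator emulates the published survey conditions: 33 water sites
(12 metals, µg/L), 31 sediment sites (9 metals, mg/kg), and 31-site BCR
profiles for 8 metals, with per-metal targets transcribed into
`data/dongping_targets.yaml`. Concentrations are lognormal — non-negative
and right-skewed, the conventional model for environmental trace data. By
default draws are *moment-calibrated*: the standardised normal deviates are
passed through exp(α + βz) with β solved by Brent's method so the sample
CV equals the target and α scaling the mean, making each table's sample
mean and SD equal the targets exactly while preserving lognormal shape.
This is a deliberate design choice: the generator's purpose is to emulate a
published summary table, and calibration makes 31-site tables do so
faithfully; plain i.i.d. sampling remains available (`calibrate=False`).
Truncation to the published [min, max] is opt-in (rejection sampling, capped
at 1000 passes) and disables calibration, since truncation distorts moments;
the shipped spec carries the printed ranges as metadata only.

Two printed-table inconsistencies are corrected in the shipped targets:
water-Cd SD (printed 0.110 µg/L, impossible against the printed CV 0.150 and
range 0–0.040; set to CV·mean = 0.0033) and the swapped sediment-Ni min/max.
Sediment-Cd keeps SD = 0.23 (consistent with its printed range and the
reported hotspots) over its inconsistent printed CV.

BCR fractions are Dirichlet with mean equal to the target profile and
precision 100 (per-site fraction SD ≈ 5 points at Cd's F1 ≈ 49%, a realistic
between-site spread); `noise=False` is the infinite-precision limit. The
survey states only the dominant fractions per metal (Cd F1 48.6%, Pb F2
27.55%, residuals V 95.42% … Zn 56.74%); the remaining entries of each
profile are reconstructed to honor every stated value exactly and preserve
the reported RAC ordering and band memberships.

Spatial structure is reduced to a labelled hotspot mechanism (multiplicative
enrichment of named sites, emulating the Cd point sources near the river
inlet); there are no coordinates, variograms, temporal dynamics, or
water–sediment partitioning, and water and sediment site sets are treated as
independent (the survey does not publish a site mapping). Passing tests on
synthetic tables therefore demonstrate correctness of the indices and their
contracts — not geochemical realism of any individual site.

## Correlation

Pairwise complete-case Pearson r with two-tailed p-values (≥3 complete cases
per pair; zero-variance variables yield flagged NaN, never a silent 1).
The common-source rule tiers pairs as strong (|r| ≥ 0.7 and p ≤ 0.01) or
moderate (0.3 ≤ |r| < 0.7, same significance). The source text writes the
threshold as "R²"; its own 0.3–0.7 moderate band indicates the coefficient r,
so |r| is the default with `use_r2=True` available. No multiple-testing
correction by default, mirroring the source; a Benjamini–Hochberg option is
provided as an extension.

## Numerical choices and problem sizes

All banding scales are lower-inclusive/upper-exclusive — one documented
convention rather than per-scale guessing — so Er = 40 is "moderate" and
HPI = 100 "exceeds acceptable". Classification is total and monotone
(property-tested). Generator calibration solves to |CV error| < 1e-14;
round-trip I/O is bit-exact (`float_precision="round_trip"` on read).
Stochastic tests state explicit seeds; Monte Carlo checks use n = 10,000
with 3-standard-error gates, and generator parameter-recovery uses 1000
sites. The analysis drivers default to the survey's site counts (33/31) and
10,000 MC iterations.

## Known limitations

- Reconstructed reference tables (TEL/PEL, RfD/SF, exposure parameters, RAC
  and Er band scales, full BCR profiles) are labelled as such in the shipped
  configs; absolute health-risk magnitudes depend on them.
- Lake-level Igeo from means understates per-site means (convexity).
- No source-apportionment modelling (PMF/PCA) and no spatial interpolation;
  the correlation stage plus external knowledge is the only source evidence,
  as in the original assessment.
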