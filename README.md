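# varusplan

Coronal lower-limb deformity analysis and rule-based osteotomy simulation
for varus knees.

The package measures the five standard coronal alignment parameters (mFTA,
mMPTA, mLDFA, JLCA, WBL ratio) from 2D landmarks on a calibrated full-leg
radiograph, locates the bony deformity with the malalignment test, and
deterministically simulates valgizing osteotomies — isolated medial
open-wedge HTO, isolated lateral closed-wedge DFO, or a double-level
combination — to a target of 2° mechanical valgus under joint-line-obliquity
limits (postoperative mMPTA ≤ 90° "anatomic" or ≤ 95° "overcorrection",
mLDFA ≥ 85°). Legs that cannot reach the target even with both sites at
their limits are flagged uncorrectable. A synthetic cohort generator
(truncated-normal marginals, mFTA ≥ 3° varus inclusion by rejection
sampling) and cohort statistics (prevalence tables, chi-square with
Bonferroni post hoc, Kruskal–Wallis with Dunn post hoc, two-way ICC) round
out the toolkit.

## CLI

All commands are available under a single entry point:

```bash
# measure one leg from a landmark file (JSON or CSV)
varusplan measure leg.json

# synthetic cohort (CSV with provenance header)
varusplan generate --out cohort.csv --n 200 --seed 1

# deformity location, severity, correction potentials
varusplan classify cohort.csv --out classified.csv

# osteotomy simulation under a scenario
varusplan plan cohort.csv --out plans.csv --summary summary.csv \
    --scenario overcorrection

# full cohort report (descriptives, prevalence, plan tables, tests)
varusplan report cohort.csv --out-dir report/
```

Scenarios: `anatomic` (mMPTA ≤ 90), `overcorrection` (mMPTA ≤ 95), or
`custom` with `--scenario-file scenario.json`:

```json
{"mmpta_upper": 92, "mldfa_lower": 85, "target_mfta_varus": -2}
```

Angles are decimal degrees; varus is positive mFTA (the -2 above is 2°
valgus). Landmark JSON maps each landmark name to `[x, y]` millimetres plus
`"side"`; see `varusplan.io` for the full name list.

## Model notes

- Wedge model is first-order additive: a 1° wedge changes mFTA by 1°; JLCA
  is frozen during simulation (static alignment only).
- The primary osteotomy site is the site of greatest deformity, or the
  greater anatomic correction potential when no bony deformity exists; site
  choice is scenario-stable, ties go to the tibia.
- The synthetic generator draws mMPTA/mLDFA/JLCA independently before
  selection; cohort-level percentages are emergent, not calibrated to any
  real cohort.
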