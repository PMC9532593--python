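# enzlim

Microbial communities in lake sediments meet their elemental budgets by
allocating extracellular enzyme activity (EEA) among carbon-, nitrogen- and
phosphorus-acquiring enzymes. **enzlim** turns a per-site survey of the five
standard hydrolases — BG, CBH (C), NAG, LAP (N), AP (P) — plus water/sediment
chemistry and microbial count tables into the standard ecoenzymatic
stoichiometry analysis:

* **Vector analysis of nutrient limitation.** With acquisition sums
  C = BG + CBH, N = NAG + LAP, P = AP and proportions x = C/(C+P),
  y = C/(C+N), each site gets a *vector length* √(x² + y²) (C-limitation
  index), a *vector angle* = ∠(x, y) in degrees (above 45° ⇒ relative P
  limitation, below ⇒ N limitation) and an *N-limitation index* 90° − angle.
  Water-column N/P status is classified by the molar Redfield threshold
  TN:TP = 16.
* **Community linkage.** Per-group richness and Bray–Curtis dissimilarity,
  element-cycle (five-enzyme, z-scored Euclidean) and limitation-difference
  matrices, and one-tailed Mantel permutation tests (999 permutations by
  default, exact enumeration for n ≤ 7) linking community turnover to
  enzyme-allocation turnover.
* **Regression layer.** Pearson screens, OLS, quadratic fits with
  hump/U-shape detection, and bidirectional AIC stepwise screening of
  chemistry predictors.
* **Synthetic surveys.** A seeded generator producing realistic ~23-site
  saline-lake surveys with known directional effects (salinity and sediment
  TP increase C limitation, water TN increases N limitation, concave pH
  responses, gradient-coupled bacterial communities), so the whole pipeline
  is testable end to end without field data.

See `docs/methods.md` for the model details and conventions.

## Worked example

Simulate a default 23-site survey, then analyze it:

```sh
$ enzlim simulate --seed 1 --out-dir data/
wrote 5 files to data/ (23 sites, seed 1)

$ enzlim analyze --chemistry data/chemistry.csv --enzymes data/enzymes.csv \
    --bacteria data/bacteria.tsv --fungi data/fungi.tsv \
    --out-dir results/ --seed 1
23 sites | mean vector length 1.156 | mean angle 42.58° | classes {'N_LIMITED': 15, 'P_LIMITED': 8, 'BALANCED': 0}
```

The mean vector length of **1.156** (well above the √0.5 ≈ 0.71 of a
perfectly balanced site) says most enzyme effort targets C acquisition —
`summary.json` puts the mean C-fraction of total EEA at **0.689**. The mean
angle of **42.58°** sits below the 45° boundary, and 15 of 23 sites are
classified N-limited: the sediment microbes of this synthetic saline lake
are C- and N-colimited while its water column (TN:TP ≫ 16 at all 23 sites)
is P-limited — exactly the generator's encoded structure.

`results/` also contains the per-site `limitation.tsv`, `water.tsv`,
`richness.tsv`, the `correlations.tsv` / `regressions.tsv` /
`quadratic.tsv` / `stepwise.tsv` screens, `mantel.tsv` (12 tests: each
microbial group against the element cycle, the three acquisition sums and
the two limitation differences) and a provenance block in `summary.json`
sufficient to re-run bit-identically.

The same workflow is available as a library:

```python
from enzlim import SurveyConfig, generate_survey, acquisition_sums, vector_limitation

survey = generate_survey(SurveyConfig(seed=1))
v = vector_limitation(acquisition_sums(survey.enzymes[0]))
print(round(v.vector_length, 3), round(v.vector_angle_deg, 2), v.limitation_class)
# 1.335 45.29 P_LIMITED
```

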