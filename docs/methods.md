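# Methods

## The vector analysis of ecoenzymatic stoichiometry

Sediment microorganisms regulate the share of extracellular enzyme activity
(EEA) they direct at carbon, nitrogen and phosphorus acquisition. The five
assayed hydrolases map onto the three elements as

| element | enzymes | acquisition sum |
|---|---|---|
| C | BG (β-1,4-glucosidase), CBH (cellobiohydrolase) | C = BG + CBH |
| N | NAG (β-1,4-N-acetylglucosaminidase), LAP (leucine aminopeptidase) | N = NAG + LAP |
| P | AP (alkaline phosphatase) | P = AP |

all in nmol g⁻¹ dry sediment h⁻¹. From the relative proportions
x = C/(C+P) and y = C/(C+N) the analysis computes

* **vector length** √(x² + y²) ∈ (0, √2] — an index of microbial C
  limitation (longer = more of the total effort is directed at C);
* **vector angle** — the angle of the point (x, y) from the x-axis in
  degrees, strictly inside (0°, 90°); angles above 45° indicate relative P
  limitation, below 45° relative N limitation;
* **N-limitation index** 90° − angle, so larger values mean stronger N
  limitation.

Two conventions deserve making explicit. First, x and y are *proportions*
(bounded in (0, 1]), not activity ratios; the proportional form bounds the
vector length by √2 and is the convention under which the 45° threshold was
defined. The N-vs-P classification itself is identical under either reading
(both boundaries reduce to N-acquisition = P-acquisition). Second, the angle
is the angle of (x, y) measured from the x-axis, i.e. `atan2(y, x)` in the C
argument convention (equal to spreadsheet `ATAN2(x, y)`); only this reading
puts equal N- and P-acquisition exactly on 45°. Implementation-independent
identities — angle(x,y) + angle(y,x) = 90°, N-limitation + angle = 90°,
scale invariance under activity rescaling — are enforced as property tests.

Classification uses a configurable BALANCED band of ±`tolerance` degrees
around 45° (default 10⁻⁹: exact ties are measure-zero in real data). All
three acquisition sums must be strictly positive; a zero sum makes the angle
undefined and raises a degenerate-profile error rather than returning a
silent NaN.

Water-column limitation uses the Redfield threshold: the molar ratio
(TN/14.007)/(TP/30.974) above 16 is classified P-limited, at or below 16
N-limited (the boundary is assigned to the N side; masses in g mol⁻¹, TN/TP
in mg L⁻¹).

## Distance structures and the Mantel linkage

The *element cycle* of a site is its vector of the five enzyme activities.
Pairwise element-cycle difference is the Euclidean distance after z-scoring
each enzyme column (sample SD, ddof = 1); standardization is the default so
that low-activity enzymes such as LAP carry the same weight as BG, and can
be disabled for raw-scale distances. Per-site scalars (vector length,
N-limitation, each acquisition sum) become difference matrices |vᵢ − vⱼ|.

Community dissimilarity is quantitative Bray–Curtis,
BC(i,j) = 1 − 2·Σ min(c_it, c_jt)/(Σ c_it + Σ c_jt), computed on counts as
given by default; a `relative` mode renormalizes rows first. The package
does not assert which of the two a given published survey used — both are
exposed.

The Mantel statistic is the Pearson correlation of the n(n−1)/2
upper-triangle pairs; the null is built by jointly permuting rows and
columns of the second matrix, with a one-tailed "greater" alternative
(the linkage hypotheses here are positive) and the add-one convention
p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm), so p can never be 0 and never
falls below 1/(n_perm+1). The default is 999 permutations. For n ≤ 7 the
implementation switches to exact enumeration of all n! relabelings
(p = #{r_perm ≥ r_obs}/n!, identity included). Permutation comparisons use
an absolute tolerance of 10⁻¹² on r to keep ties stable under floating-point
noise. A constant distance matrix has no defined correlation and is
rejected.

## Regression layer

Pearson correlations use the exact t-based two-sided p-value. OLS fits use
classical homoskedastic standard errors (via statsmodels behind the module
surface). Quadratic fits y = a + bx + cx² are labelled HUMP only when the
curvature is negative, significant at 0.05, *and* the vertex −b/(2c) lies
inside the observed x range — a concave fit whose maximum falls outside the
data is just a monotone trend and is labelled NONE (U symmetric for positive
curvature). Stepwise screening is bidirectional from the intercept-only
model with AIC as the default criterion: every one-term addition and removal
is scored, the largest AIC decrease is taken, ties break on predictor name
order, and the search stops when no move improves AIC or the fit is
numerically perfect. A p-value entry/removal mode (α_enter = 0.05,
α_remove = 0.10) is available. Significance is two-sided α = 0.05
throughout with no multiple-testing correction — the screens are
exploratory, and users combining many responses and covariates should
correct downstream.

## The synthetic survey generator

The generator emulates a ~23-site survey of an alkaline saline lake
(default pH range 9.40–10.25, salinity 9–21 ‰, water TN lognormal with
median 1 mg L⁻¹, sediment TP lognormal with median ≈ 0.62 g kg⁻¹; other
covariates from fixed plausible ranges, e.g. depth 5–27 m, water TP around
0.04 mg L⁻¹, sediment TC around 65 g kg⁻¹). Enzyme activities follow a
log-linear response model: baseline log-means α_e reproduce typical printed
survey means (BG 458.12, CBH 159.11, NAG 114.38, LAP 24.9 nmol g⁻¹ h⁻¹);
AP has no published anchor and defaults to 100, deliberately below
NAG + LAP = 139.28 so the baseline lake is N- rather than P-limited — the
direction such surveys report. The encoded directional effects are
positive salinity and sediment-TP slopes on the C-acquisition enzymes
(default 0.40 and 0.30 per SD), a positive water-TN slope on the
N-acquisition enzymes (0.50 per SD), and a concave sediment-pH term
γ(pH − pH_opt)² with γ = −0.8, pH_opt = 9.8, applied to all enzymes except
LAP.

Noise is i.i.d. Normal(0, σ = 0.25) per enzyme × site on the log scale.
A site-*shared* noise term would cancel exactly in the limitation indices
(they are scale-invariant by construction), leaving them deterministic
functions of the covariates; per-enzyme noise keeps the indices
realistically stochastic, which is what the calibration and effect-recovery
suites rely on.

Communities follow Gaussian niche curves along a gradient score (the
standardized sum of z-scored salinity and water TN — the same covariates
that drive enzyme allocation). Each site's effective position is
`coupling × gradient + Normal(0, 0.5)` noise; taxon niche centers, widths
and lognormal commonness are drawn per taxon. Counts are
Dirichlet-multinomial (concentration 50, library size 10,000). The
bacterial coupling default is 1.5 and the fungal 0.3, so bacterial turnover
tracks enzyme-allocation turnover strongly and fungal turnover only weakly.
The bacterial value was set by a design pass: couplings were increased until
the bacterial Bray–Curtis vs element-cycle Mantel test recovered a positive
significant association in ≥ 90 of 100 seeds at 50 sites, then frozen.

What the generator does *not* emulate: spatial autocorrelation among sites,
sequencing noise and compositional artifacts of amplicon pipelines, depth
structure within the sediment, and covariance among chemistry covariates
beyond the salinity/TN gradient. Passing effect-recovery tests therefore
demonstrates that the pipeline detects the encoded structure at realistic
survey sizes — not that real lake data will show it.

One RNG seed sequence is spawned into substreams per generator (chemistry,
enzymes, communities), so enlarging the taxon tables leaves chemistry and
enzyme draws untouched; surveys are byte-identical across runs for a fixed
config.

## Pipeline and numerical choices

`run_analyze` computes, in order: acquisition sums → vector analysis per
site → water Redfield classes → richness and Bray–Curtis per group →
element-cycle and scalar difference matrices → Mantel tests (each group
against the element cycle, the three acquisition sums, |Δ vector length|
and |Δ N-limitation|) → Pearson/linear/quadratic screens of every
limitation index, enzyme and acquisition sum against every chemistry
covariate (plus the C-vs-N limitation trade-off) → stepwise screens for
vector length and N-limitation over all chemistry covariates. Sites with
missing or invalid fields are rejected, never imputed — at survey sizes of
~23 sites silent imputation would be indefensible. Mantel seeds are derived
deterministically from the run seed per test, and per-test seeds are
recorded in `mantel.tsv`, so any single test can be replayed. Output floats
are written with `%.10g`; simulated inputs with `%.17g` (exact IEEE-754
round trip, which the byte-identity guarantees depend on). The summary's
mean C-fraction is the per-site mean of C/(C+N+P), recovered from the
proportions as 1/(1/x + 1/y − 1).

Problem sizes used by the verification suites: oracle-equivalence checks run
1,000 random profiles; Mantel type-I calibration uses 200 replicates at
n = 20 with 199 permutations; null p-value uniformity uses 50 seeds at 23
sites; effect recovery uses 100 seeds at 50 sites with 199-permutation
Mantel tests. These sizes give stable verdicts (binomial SEs of a few
percent) at interactive runtimes.

## Known limitations

* The Mantel permutation loop is pure Python/NumPy; at 999 permutations and
  a few hundred sites it is still subsecond, but very large site sets would
  benefit from vectorizing the permutation batch.
* Stepwise selection inherits the usual post-selection inference caveats:
  the reported p-values of the final model are conditional on selection and
  should not be read as confirmatory.
* The water Redfield classification uses total N and P, not bioavailable
  fractions.
* Random-forest importances, ordination (RDA/DCA) and structural equation
  models — common companions of this analysis in survey papers — are out of
  scope here.
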