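# Methods

This note documents the statistical model behind `cdpop`, the design
choices made where several reasonable implementations exist, what the
synthetic-data generator does and does not emulate, and the problem
sizes used by the test suite and the acceptance script.

## Model

### G-BLUP and the genomic relationship matrix

Phenotypes of the calibration set follow the standard G-BLUP mixed
model

    y = X β + Z u + e,    u ~ N(0, K σ_g²),    e ~ N(0, I σ_e²),

with an intercept-only fixed part by default, `Z` the incidence of
calibration records on the model individuals, and `K` the VanRaden
genomic relationship matrix on the 0–1 dosage scale used for inbred and
doubled-haploid (DH) material:

    K[i,j] = Σ_l (G[i,l] − p_l)(G[j,l] − p_l) / D,
    D      = Σ_l p_l (1 − p_l).

The allele-frequency source `p_l` is configurable: the genotyped set
itself (default) or an external reference panel. When the frequencies
come from the data, the centred genotype matrix has zero row sums, so
`K` is exactly singular (its rows sum to zero). Every inversion of `K`
in the package therefore adds a diagonal ridge of `1e-6` first, and the
same ridged matrix is used consistently wherever `K` appears (mixed
model equations, CD numerator and denominator). The ridge magnitude is
far below any biologically meaningful relationship difference and
leaves the hand-worked examples correct to five decimals.

Predictions solve Henderson's mixed-model equations

    [ X'X      X'Z        ] [β̂]   [X'y]
    [ Z'X  Z'Z + λ K⁻¹    ] [û] = [Z'y],     λ = σ_e²/σ_g²,

over a model set that is the union of the calibration set and the
target set, in stable (kinship) order; unphenotyped targets receive
GEBV through their relationships. λ comes from a heritability
(`λ = 1/h² − 1`), from REML, or is fixed at 1 (h² = 0.5) when no
phenotypes exist yet — the conventional setting for optimizing a
calibration set before phenotyping.

### REML

`estimate_lambda_reml` fits the intercept-plus-polygenic model by
projecting out the intercept with an orthonormal basis of the
complement of the 1-vector, rotating to the eigenbasis of the projected
(ridged) `K`, and profiling σ_g² out of the restricted likelihood. The
resulting one-dimensional criterion in λ is maximized by a bounded
scalar search on log λ over `[1e-4, 1e4]` with tolerance `1e-6`, with
an explicit comparison against the interval endpoints because boundary
optima (noiseless or pure-noise data) are legitimate outcomes. If the
projected spectrum is numerically flat (K proportional to the
identity), σ_g² and σ_e² are confounded; a warning is raised and a
boundary estimate returned.

### Generalized coefficient of determination

The reliability of predicting a contrast `c` (any weighting with
`1'c = 0`) of genetic values is

    CD(c) = c'(K − λ (Z'MZ + λK⁻¹)⁻¹) c / (c'Kc),

where `M = I − X(X'X)⁻X'` projects records orthogonally to the fixed
effects (generalized inverse = pseudoinverse; for the default intercept
`Z'MZ` is computed as `Z'Z − (Z'1)(1'Z)/n`). CD is the squared
correlation between the true and the predicted contrast — the expected
reliability — and relates to the prediction error variance by

    PEV(c) = c'(Z'MZ + λK⁻¹)⁻¹ c / (c'c) · σ_e²,
    CD(c)  = 1 − λ c'(Z'MZ + λK⁻¹)⁻¹ c / (c'Kc).

Both bounds 0 ≤ CD ≤ 1 are exact consequences of `Z'MZ ⪰ 0` and hold
with the ridge applied consistently; values outside `[−1e-9, 1+1e-9]`
indicate numerical failure and raise instead of being clamped. An empty
calibration set is handled explicitly (every CD is 0; `M` is undefined
at n = 0). A single calibration record also yields CD = 0 because the
intercept absorbs it — the formula needs no special case.

### Criteria for structured populations

For a structured target population the contrasts that matter compare
individuals to family means (Mendelian-sampling deviations):

* `cdpop(F)` — mean over family F of √CD of the individual-vs-family-
  mean contrasts; forecasts within-family prediction *accuracy* (square
  roots make the criterion commensurate with a correlation).
* `cdpop_mean` — unweighted mean of per-family cdpop values, each
  evaluated in its own model set (calibration ∪ that family).
* `cdallnam` — mean √CD of individual-vs-overall-mean contrasts over
  the pooled target set; forecasts global accuracy ignoring structure.
* `crit_kin` — mean relationship between calibration and target
  individuals; the baseline criterion. With overlapping calibration and
  target sets the plain double mean includes self-relationships.

An individual may belong to both the calibration and the target set
(joint prediction inside the target population); its contrast column
then has a nonzero weight at its own phenotyped position and the
algebra goes through unchanged.

## Calibration-set optimization

The exchange algorithm swaps one randomly chosen selected individual
with one randomly chosen excluded candidate and keeps the swap iff the
criterion strictly improves (ties rejected, which prevents cycling).
Defaults: `max(10000, 100·size)` proposals per restart, stop after
2000 consecutive rejections, 5 restarts, best restart returned,
everything reproducible from the seed. A greedy warm start by maximum
mean relatedness to the target set is available (`crit_kin_warm`); it
seeds the first restart only, so the remaining restarts still explore.
Because `crit_kin` is additive over calibration members, its greedy
maximizer is exactly the top-k candidates by mean relatedness, which is
also used as the `crit_kin` "sampler" in the scenario harness.
`brute_force_optimize` enumerates subsets (guarded at 10,000) and is
the exact oracle in tests.

The stratified baselines allocate per-family quotas (equal, or
proportional to family size) by the largest-remainder rule; ties in the
fractional parts are broken by a seeded permutation.

## Synthetic NAM designs

The generator emulates the structure of maize-style nested association
mapping material:

* **Ancestors** — a small pool (default 4) of fully inbred founders
  with independent per-locus allele frequencies drawn uniformly in
  `[maf_low, 1 − maf_low]`.
* **Parents** — the central line and the donor parents are single DH
  offspring of random ancestor pairs, so parent pairs range from
  closely related (shared ancestor) to unrelated. This heterogeneity is
  deliberate: in real elite pools some family pairs are near-duplicates
  and others are distant, and that spread is precisely what reliability
  forecasting and calibration-set optimization feed on. With unrelated
  donors all families become exchangeable and there is nothing to
  optimize.
* **Families** — each DH line is one F1 gamete doubled: a single
  meiosis under Haldane's model (recombination probability
  `(1 − e^(−2d/100))/2` between adjacent loci `d` cM apart, independent
  across intervals and chromosomes, no interference), giving fully
  homozygous offspring. Default family sizes
  (64, 99, 100, 66, 96, 104, 53, 94, 81, 84) mirror the spread of a
  real ten-family DH NAM population (about 84 lines per family, range
  53–104).
* **Panel** — optional: the NAM parents plus further ancestral-cross
  inbreds, echoing diversity panels that contain the population
  founders.
* **Trait** — additive effects `N(0, effect_sd²)` at all loci (or a
  chosen subset), TBV = Σ (dosage − 0.5)·effect with centred coding so
  allele relabelling only flips effect signs, and residual variance set
  from the realized TBV variance so the target h² holds by
  construction. Per-family "design-level" heritabilities are computed
  from the simulation ground truth
  (`h²_f = var(TBV_f)/(var(TBV_f)+σ_e²)`) and used exactly where an
  experimenter would plug in estimated family heritabilities.
* The default genome is 5 chromosomes × 60 loci × 150 cM — enough loci
  for a polygenic trait and realized-kinship variation at desk-scale
  runtime.

What the generator does **not** emulate: genotyping error and missing
calls (QC operators are exercised on constructed examples), ascertained
SNP panels, selection during DH production, crossover interference,
dominance/epistasis, genotype-by-environment structure, and traits
driven by a few major QTL. Consequently, passing tests demonstrate the
internal consistency of the machinery and its behaviour when the
G-BLUP assumptions hold; they do not certify performance on traits
with major genes or on populations whose kinship poorly reflects the
trait covariance — settings where CD-based forecasts are known to
degrade.

## Scenario harness

`run_scenario` reproduces the standard experimental layouts: S1
(cross-with-cross), S2 (leave-one-cross-out), S3 (panel predicts
families, plus the pooled target set scored by `cdallnam`), and OT1–OT4
(calibration sets of increasing size sampled by the CD criteria, by
mean relatedness, stratified, or at random). Observed accuracy is the
Pearson correlation between GEBV and phenotypes of the target
individuals divided by √h² of the predicted family; the sign is kept,
values may exceed 1 under sampling noise, and they are reported as-is.
In S scenarios λ comes from the calibration set's heritability
(per-family for single-family calibration; the pooled entry of the h²
table — or, failing that, the unweighted mean with a warning — for
multi-family calibration; REML as an alternative policy). In OT
scenarios λ defaults to 1. OT replicate count defaults to 20 per size.
For OT3/OT4 the "global" accuracy pools predictions of all targets into
one correlation, and per-family accuracies use all family members,
including any that sit in the calibration set.

Families with fewer than two members cannot form within-family
contrasts and are skipped with a logged warning. Scenario runs use a
reduced exchange budget (400 proposals, patience 120, 2 restarts) since
the search is re-run for every cell; at the pool sizes involved this
sits within about 0.01 of the long-run criterion optimum.

## Benchmarks and problem sizes

Two simulation experiments condense the method's qualitative claims
into reproducible numbers (both re-run by `scripts/acceptance.py`):

* **OT1 benchmark** — 10 independent simulated designs of 5 families ×
  150 DH; in each, every family is predicted in turn from CDpop-
  optimized (sizes 30 and 60) versus random calibration sets drawn from
  the other families, with observed accuracies averaged over predicted
  families and sizes (5 random sets per cell). Reported: the fraction
  of replicates where optimization does at least as well, and both mean
  accuracies.
* **S1 benchmark** — 20 independent simulated ten-family designs with
  the unequal default family sizes; all 90 ordered family pairs are
  predicted and the Spearman correlation between the CDpop forecast and
  observed accuracy computed per replicate. Reported: the fraction of
  replicates with positive rank correlation and the median correlation.

A third directional check mirrors the panel-calibration observation
that global accuracy (family means included) exceeds the mean
within-family accuracy: it uses a design with a wider ancestral pool
(12 ancestors), because the effect is driven by between-family
differentiation — with near-duplicate donors the family means carry too
little variance for the contrast to emerge.

These sizes (hundreds of individuals, a few hundred loci) are scaled-
down analogues of a real NAM study chosen so the full battery runs on a
laptop in minutes; the qualitative contrasts they probe (optimized ≥
random; forecast ranks accuracies) are size-stable in our experience.

## Numerical choices and limitations

* Ridge `1e-6` on `K` everywhere; pseudoinverse for `(X'X)⁻`.
* Negative CDs beyond `−1e-9` raise; smaller negatives clamp to 0.
* Exchange ties are rejected; accepted criterion values are strictly
  increasing along the trace.
* Genotype tables are strict at parse time ({0, 0.5, 1, NA}), but the
  in-memory container accepts any dosage in [0, 1] because family-mean
  imputation necessarily produces fractional dosages.
* The imputation fallback for a (family, locus) cell with no observed
  member is the global locus mean, keeping the operator total.
* CD always increases as the calibration set grows; real data often
  disagree (adding distant individuals can hurt), a known limitation of
  kinship-based reliability theory rather than of this implementation.
* λ = ∞ (h² = 0) is rejected by the solver; the CD limit CD → 0 is
  exercised in tests via large finite λ.
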