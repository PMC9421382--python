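# Methods

This note documents the statistical model behind `stratewas`, the design
choices made where the method description leaves them open, and what the
synthetic-data tests do and do not demonstrate about real data.

## The analysis model

For each probe *g* and fetal-sex stratum *s* ∈ {female, male}, the
pipeline fits ordinary least squares on the beta (methylation-fraction)
scale:

    beta_g ~ 1 + EPDS + EccPC1..5 + chip + chip position
               + extraction method + bisulfite concentration

and reports the two-sided *t*-test of the EPDS coefficient with
df = n − (number of model columns). Association runs on beta values;
batch adjustment runs on M-values (M = log₂(β/(1−β))) — both transforms
are explicit operations so the scale choice is auditable. Categorical
covariates use treatment contrasts with the first observed level as
reference; any full-rank coding gives identical EPDS inference. Samples
with missing EPDS or covariates are dropped listwise and counted in the
result's metadata. Probes with numerically constant methylation are
flagged `degenerate` and excluded from all downstream distributional
summaries. p-values below 1e-300 are stored as 1e-300 to keep logs
finite.

**Why chip appears in the regression even though ComBat already ran.**
Empirical-Bayes chip adjustment operates on the full cohort; a stratified
reanalysis then sees, within each stratum, small chip-constant residuals
(each stratum inherits minus the other stratum's share of the per-chip
noise mean, plus whatever the EB shrinkage deliberately left). Across
~20,000 correlated probes the one-sided KS statistic is sensitive enough
that these leftovers occasionally mimic a weak global signal in a null
stratum. Chip indicator covariates absorb them exactly, at the cost of
the between-chip share of EPDS variance (~1/chip size). The default
pipeline therefore includes them; callers reproducing the bare study
equation can pass a `CovariateSpec` without `chip`.

**ComBat and covariate protection.** `combat_adjust` implements the full
parametric location/scale empirical-Bayes algorithm (standardization
against the batch-design OLS fit and pooled variance; normal prior on
location, inverse-gamma on scale, moment-matched hyperparameters,
iterated conditional estimation to tolerance 1e-4). It matches
`sva::ComBat` to ~1e-14 with and without a covariate design. Two
practical findings are encoded in the defaults and tests:

- *The adjustment is not value-idempotent.* The scale step re-shrinks
  chance between-batch variance differences on every pass (the reference
  implementation behaves identically), so repeated application contracts
  toward a fixed point rather than reproducing its input. Batch-mean
  structure, which is what the adjustment exists to remove, is stable.
- *Do not protect the tested covariate by default.* Passing EPDS in the
  ComBat design re-injects the full-sample OLS EPDS fit into the adjusted
  matrix; a downstream per-stratum regression then partially re-tests its
  own training fit and the null strata become strongly anti-conservative
  (measured null D⁺ ≈ 0.05 at 20,000 probes). With EPDS essentially
  orthogonal to chip assignment, unprotected adjustment leaves the signal
  intact; the design argument remains available for genuinely confounded
  covariates.

**KS uniformity test.** D⁺ = maxᵢ(i/n − p₍ᵢ₎), floored at 0, against the
asymptotic one-sided tail exp(−2nD⁺²); `mode="exact"` uses the exact
one-sided small-sample distribution (intended for n ≤ 100). At the
pipeline's n ≈ 2·10⁴ the asymptotic form is standard and slightly
conservative (measured rejection ≈ 4.9% at nominal 5% for n = 1000).
One caveat the tests make explicit: per-CpG p-values within a cohort are
correlated (shared latent factors), so the per-cohort KS p-value is a
descriptive statistic of that cohort's p-value distribution, not a
calibrated test across independent probes.

**Variable-CpG filter.** The range rule trims per-probe outliers with
Tukey fences at 1.5·IQR (quartiles by linear interpolation) and keeps
probes whose trimmed range is ≥ 5 percentage points, boundary inclusive.
Fence multiplier, threshold and inclusivity are configuration because the
outlier definition is not standardized; at least 4 samples are required
for quartiles to be meaningful.

**Probe QC.** A probe is removed if *any* sample has detection p ≥ 0.01
(boundary inclusive) or fewer than 3 beads in either channel, or if it is
SNP-flagged or cross-hybridizing. A per-value masking policy
(`policy="mask"`) is available where per-sample treatment is preferred.

**Cell-type deconvolution.** Per sample, min ‖Rw − b‖² subject to w ≥ 0,
Σw = 1, solved by non-negative least squares with a high-weight
sum-to-one penalty row followed by exact renormalization onto the
simplex; the reference panel must have full column rank on the shared
probes. Composition PCs use centering only (no scaling — proportions
share units), signs fixed so each loading vector's largest-magnitude
entry is positive; the simplex constraint caps the useful number of PCs
at (cell types − 1).

**Enrichment.** Two-sided Fisher exact p-values use the probability-mass
rule (sum of hypergeometric probabilities of tables no more probable than
the observed one, tie tolerance 1+1e-7), so a single test yields both the
enriched and depleted calls; the direction comes from the sample odds
ratio, with 0/∞ reported for zero cells. The gene-set engine is an
over-representation test, P(X ≥ overlap) under the hypergeometric, with
Benjamini–Hochberg adjustment across the collection; gene symbols are
harmonized by uppercasing and whitespace stripping only (no alias
database).

## The synthetic cohort generator

The generator emulates the statistical structure of maternal-blood
Infinium data, not its biochemistry:

- **Baselines.** Per probe, a Beta(a,b) shape drawn from a
  low/high/intermediate mixture (45/45/10%), then one baseline per cell
  type from that shape — bimodal array-like betas with cell types that
  differ per probe (which is what makes deconvolution identifiable).
- **Mixtures.** Per-sample compositions from a Dirichlet around an uneven
  base profile (concentration 30), mixed on the beta scale.
- **Technical structure.** Chip-level, probe-specific shifts
  ~ Normal(0, 0.45) and iid noise ~ Normal(0, 0.25), both on the M-scale;
  chips of 8 samples with a row-position label. Chip effects exceeding
  residual noise is deliberate: it reflects a setting in which an explicit
  chip-adjustment step is necessary rather than cosmetic.
- **Phenotype.** EPDS ~ Normal(7, 4.2), rounded and clipped to [0, 30]
  (no zero-inflation — the emulated cohorts' summary moments are matched,
  nothing finer is claimed); fetal sex female with probability 0.477;
  extraction method, bisulfite concentration and group labels as inert
  technical covariates.
- **Planted effects.** A fraction (default 2%) of probes receives a
  linear EPDS effect on the M-scale, restricted to one stratum
  (default female). With `effect_r2` set (default 0.05), the slope
  magnitude is calibrated so the effect explains that share of the total
  stochastic M-scale variance the generator adds
  (slope² · Var(EPDS) = r²/(1−r²) · (noise² + chip-shift²)); signs are
  random. Setting `effect_r2=None` instead draws slopes from
  Normal(0, `effect_slope_sd`). `context_bias` multiplies the sampling
  odds of planting an effect on probes in designated contexts (default
  open sea / intergenic).
- **Reference panel.** The true cell-type baselines at the probes where
  cell types separate most — an idealized, noise-free panel.
- **Determinism.** All randomness flows from one seed through named
  per-stage substreams (annotation, baselines, composition, batch, noise,
  sample sheet, effects), so identical configurations give bit-identical
  bundles and editing one stage's draw never perturbs another's.

### What passing tests do and do not show

The simulator is linear-Gaussian on the M-scale given composition, has an
exactly known reference panel, independent probes apart from shared
composition and chip factors, and no genetic structure, age effects,
zero-inflated phenotypes, probe-type chemistry differences or missing
values. Recovery results (slope CIs, deconvolution RMSE, context
enrichment flags) therefore demonstrate correctness of the estimators
under the stated model — they do not certify power or calibration on real
arrays, where reference-panel mismatch and unmodeled covariate structure
dominate. One realistic pathology the simulator *does* reproduce is
cohort-level KS instability from chip-clustered residual covariance,
which is why the default model keeps chip indicators (above).

### Problem sizes used in tests

Fixed once as the package's reference scale: 20,000 probes × 200 samples
for the headline female-vs-male contrast, slope-recovery and
context-recovery suites (24 and 50 seeds respectively for the two
multi-seed properties); 250 probes × 80 samples × 100 replicates for
null-calibration; 1,000 × 1,000 uniform draws for KS calibration. With
two independent null strata tested at α = 0.05 per cohort, the expected
rate of "both strata non-significant" is ~90%, not higher — the
calibration suite therefore checks the per-stratum rejection rate (3–7%)
rather than the joint event.

## Known limitations

- Preprocessing starts from beta values: no idat parsing, no
  within-sample (Noob) or functional normalization, no genotype-based
  sample QC — those require raw intensities.
- The Fisher engine enumerates one hypergeometric support per table; it
  is exact but not meant for tables with margins in the millions (the
  pipeline's 2×2 tables are at most array-sized, which is fine).
- Gene-set content is user-supplied GMT only; no pathway ontology or
  tissue-expression resources ship with the package.
- BED export assumes each probe interrogates a CpG dinucleotide
  ([position, position+2), 0-based half-open).
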