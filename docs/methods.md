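# Methods

## Model and pipeline

`sohpie` tests, per taxon, whether network degree centrality differs
between two groups after adjusting for clinical covariates. The pipeline
has four stages, each exposed as library functions and orchestrated by the
`SOHPIE` model object.

**1. Compositional network estimation (SparCC).** Counts are converted to
per-sample fractions after adding a constant pseudocount (default 0.5) to
every cell, a deterministic alternative to Dirichlet resampling chosen for
reproducibility. The matrix of log-ratio variances
t_jk = Var(log u_j/u_k) is computed from the covariance of the log
fractions. Basis variances σ_j² of the (unobserved) absolute log
abundances solve the linear system ((p−2)I + J)σ² = rowsum(t), which
follows from t_jk ≈ σ_j² + σ_k² when most correlations are weak; the
correlation estimate is ρ̂_jk = (σ̂_j² + σ̂_k² − t̂_jk)/(2σ̂_jσ̂_k). Because
strong pairs violate the sparsity approximation, the strongest remaining
pair is iteratively excluded from the variance system and the system
re-solved (default threshold 0.1, at most 10 exclusions — matching common
SparCC implementations; both config-exposed). Estimates are clipped to
[−1, 1], symmetrized, unit diagonal. Basis variances are floored at 1e−8
to protect the division.

**2. Degree and jackknife pseudo-values.** Degree centrality is the
marginal sum θ̂_k = Σ_j ρ̂_jk, including the unit diagonal term — a
constant that shifts only the regression intercept, never the group
coefficient. Signed correlations are summed by default;
`absolute_degree=True` sums |ρ̂| for sensitivity analysis. Within each
group separately (group-specific n_z and θ̂^z), leave-one-out
pseudo-values θ̃_ik = n_z θ̂_k − (n_z−1) θ̂_k(i) are formed from n_z + 1
estimator invocations; the loop parallelises with results independent of
worker count. Computing pseudo-values per group rather than on the pooled
sample is deliberate: the pooled alternative mixes the two groups'
network estimates into every pseudo-value and performs worse.

By default every leave-one-out re-estimate re-runs the full adaptive
SparCC procedure, exclusion selection included, exactly as the estimator
behaves stand-alone. `freeze_exclusions=True` instead selects the
excluded pairs once on the full group sample and replays them per
deletion, so that all θ̂_(i) estimate one smooth functional — the
textbook premise of the jackknife. The two variants give similar
inference here (see limitations); the faithful adaptive variant is the
default.

**3. Robust per-taxon regression (LTS).** Pseudo-values are heavy-tailed:
one influential subject produces an extreme pseudo-value because the
deviation θ̂ − θ̂_(i) is amplified by n−1. Each taxon's pseudo-values are
therefore regressed on intercept + group (0/1) + covariates by least
trimmed squares: minimise the sum of the h smallest squared residuals,
h = ⌊n(1−c)⌋ + 1 with trimming proportion c ∈ [0.5, 1], default c = 0.5
(maximum breakdown, h = ⌊n/2⌋ + 1). The solver is FAST-LTS style:
40 random elemental starts plus an OLS start, each refined by
concentration steps (refit on the h best-fitting points until the
objective stabilises), seeded and deterministic. The raw LTS fit only
identifies outliers; following the standard reweighting convention,
final coefficients and classical standard errors come from OLS on all
points within 2.5 consistency-corrected robust scale units
(`LtsConfig(reweight=False)` reverts to the raw h-subset SEs). The group
coefficient is tested with U_k = β̂_k/SE(β̂_k) against a t distribution
with n − (q+2) degrees of freedom. Categorical covariates are
reference-coded against the lexicographically first level.

**4. Multiplicity.** Storey q-values across the p taxa of one analysis:
q = π̂₀ × (Benjamini–Hochberg adjusted p), with π̂₀ estimated by Storey's
smoother — π̂₀(λ) = #{p > λ}/(m(1−λ)) on λ = 0.05…0.95, cubic trend
evaluated at λ = 0.95, clamped to [1/m, 1]. Under a uniform p-value
distribution the estimate stays near 1 (q ≈ BH); when most p-values are
small it approaches the floor and the q-values become much less
conservative than BH, which is characteristic of empirical-null FDR
estimators. With fewer than 20 tests the smoother is too unstable and
plain BH is used. Taxa with q < α (default 0.05) are flagged DC.

**Paired/temporal mode.** With a second time point, the per-group
statistic becomes the degree of A(t₂) − A(t₁) (both matrices estimated by
SparCC on the same subjects); leave-one-out removes a subject from both
time points jointly, since the statistic is a per-subject-paired
difference. Identical time points give exactly zero pseudo-values.

## Synthetic-data generator

The generator emulates the structure of template-based microbiome
simulators — zero-inflated truncated log-normal marginals tied together
by a Gaussian copula — without their Bayesian template fitting, and adds
a known group-difference truth:

- A Barabási–Albert scale-free graph (1 edge per new node, i.e. a random
  tree) over p taxa is drawn fresh per replicate; microbial co-abundance
  networks are hub-dominated, which preferential attachment reproduces.
- Group labels are fair Bernoulli; age is N(55, 10²) in group 1 and
  shifted +5 years in group 2 (the groups have different age profiles;
  shift config-exposed).
- A fraction δ of taxa per group is "spiked": in the multivariable
  setting each group has its own spiked set associated with age; in the
  univariable setting only group 2 is spiked, with a pure group contrast.
  The group's adjacency is perturbed by deleting all edges around its
  spiked nodes; a taxon is truly differentially connected (η_k = 1) iff
  its edge set differs between the two group networks.
- Counts per group: latent Gaussians with correlation 0.6 on the group's
  edges (eigenvalue-clipped to the nearest PSD correlation, which shrinks
  hub edges), probability-integral transformed to zero-inflated
  (π₀ = 0.3) log-normal(0, 1) marginals. Spiked taxa receive a mean
  log-abundance shift δ · s · σ · w with w the standardized age
  (multivariable) or the group-2 indicator (univariable); the magnitude
  constant s = 4 was calibrated once so that the replicated power
  analyses at p = 20 operate in an informative regime, and is
  config-exposed. Abundances are closed to a sequencing depth of 10⁵ and
  rounded.

What the generator does **not** emulate: real templates' wildly uneven
abundance profiles (our log-normal σ = 1 gives comparatively even
compositions, hence milder compositional spillover), taxon-specific zero
rates correlated with rarity, overdispersed library sizes, and
within-subject correlation over time. Passing tests therefore demonstrate
correct mechanics and calibrated behavior *under this generator*, not
performance guarantees on real sequencing data.

## Evaluation framework

`confusion_metrics` scores q-values against η at threshold α = 0.05:
precision, recall, F1 (harmonic mean) and accuracy (TP+TN)/p. Metrics
with zero denominators (no discoveries, no true DC taxa) are undefined,
stored as NaN, and excluded from replicate averages — a documented,
switch-free convention. `run_simulation_study` repeats
simulate → analyze → score over a config grid; replicate r uses seed
seed + r, recorded per row. The shipped study sizes are p = 20 with
n = 200–500 and 30–50 replicates per cell, which keeps a full run in the
low minutes on one CPU while leaving Monte-Carlo standard errors of the
reported means near 0.02.

## Numerical choices

- Pseudocount 0.5 on all counts before fractions (zeros otherwise break
  log-ratios); deterministic by design.
- PSD repair of the copula: eigenvalue floor 1e−6 then rescale to unit
  diagonal.
- LTS: 40 starts, ≤30 concentration steps, convergence tolerance 1e−12 on
  the trimmed objective; per-taxon seeds spawned from the fit seed via
  `SeedSequence`, so results are independent of taxon order and worker
  count.
- SE consistency factors: trimmed-subset variance divided by
  1 − 2qφ(q)/α with q = Φ⁻¹((α+1)/2), α = h/n; analogous correction for
  the 2.5σ reweighting truncation.
- Ties in the exclusion search are broken by row-major order; exact ties
  occur only at the ±1 clipping boundary on tiny degenerate inputs.

## Known limitations

- **The per-taxon test is anti-conservative under dense signal, and the
  package's own null simulation quantifies it.** The adaptive exclusion
  step selects the empirically strongest pairs per group; conditioning on
  that selection biases the two groups' degree estimates in different
  directions, a cross-group selection effect that the within-group
  jackknife spread cannot register. In the test suite's null-generator
  check (δ = 0, p = 20, n = 100) the mean fraction of taxa flagged at
  q < 0.05 is far above nominal, and that check is deliberately kept
  failing rather than masked. Disabling the exclusion step
  (`max_exclusion_iters=0`) together with `LtsConfig(h=n)` yields
  essentially calibrated tests (empirical type-I ≈ 0.01–0.05) at a large
  cost in power; the default mirrors the established pipeline, whose
  published operating characteristics arise from this same mechanism.
  Discoveries at large n should be read as a ranking, not as
  FDR-guaranteed calls.
- Precision of the method under strong spiking converges to the fraction
  of truly DC taxa, because nearly every taxon is eventually flagged; the
  covariate-adjusted β̂ ranking, not the flag count, carries the
  information.
- p-values assume independent subjects; repeated measures beyond the
  paired two-time-point mode are out of scope.
- SparCC needs p ≥ 4 taxa and benefits from many; at small p the basis
  variance approximation is rough and estimates can saturate at ±1.
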