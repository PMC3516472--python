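# Methods

## Data model

An assay scores worms from a nested design: first-order MA line →
{control pseudolines (gmax = 0), second-order MA sublines (gmax = t)} →
replicate worms → offspring counts per reproduction day. Input is delimited
text with a configurable column mapping (`FormatConfig`); the default header
is `line,fitness,treatment,subline,rep,d1..dN,gmax` with optional 0/1
survival columns `s1..sN`. A worm dead on day *d* carries a zero count and
`s_d = 0`; a missing count on a day the worm survived is a validation error.
Validation never drops rows silently: `errors="collect"` returns both the
accepted table and the rejected rows with reasons and source line numbers. A
re-assay of a line is a separate table with its own `assay_id` (and its own
r₀); merging happens at the estimate level.

The mapping of reproduction days to ages is assay-specific (lines propagated
on a slower schedule may differ), so the age vector is configurable per
assay; the default is 4.75/5.75/6.75 days.

## Demographic fitness

r₀ solves Σₓ e^(−r₀x) l̄ₓm̄ₓ = 1 over the assay's control worms. The
left-hand side is smooth and strictly decreasing in r₀ for a non-negative
schedule, so the root is unique; we bracket (default [−10, 10] d⁻¹, expanded
geometrically if needed) and refine with Brent's method to |residual| ≤
1e−10 — robustness over speed, since the solve happens once per assay.
Because *w* is linear in the counts, the mean control *w* equals 1 to solver
tolerance automatically. The control schedule averages over individual
worms by default; a flag averages line means instead (the choice matters
only for unbalanced control designs, and the individual-level mean is the
natural estimator of the cohort schedule).

Survivorship is carried as the per-day indicator and used only through the
product lₓmₓ; a dead worm's later days contribute 0 either way.

## Variance components

One-way components per stratum (sublines within one line × treatment):

* **moments** — v̂_subline = (MS_among − MS_within)/k₀ with the standard
  unbalanced k₀ = (N − Σnᵢ²/N)/(a − 1), truncated at zero; v̂_residual =
  MS_within. Used by default inside the bootstrap (closed form, fast).
* **REML** — normal-theory restricted likelihood profiled over
  λ = v_subline/v_residual, optimized in one dimension with the boundary
  λ = 0 checked explicitly, so a zero among-subline component is exact, not
  a convergence artifact. On balanced data REML equals the moments estimate
  whenever the untruncated moments estimate is non-negative (tested against
  statsmodels MixedLM as an independent oracle).

Normal-theory likelihood is used deliberately although *w* is non-negative
and zero-inflated; it matches the mixed-model framework this estimation
tradition uses, and the bootstrap — not the likelihood — carries the
uncertainty statements.

`lrt_variance` compares nested variance structures declared by a small spec
(among-subline component absent / pooled / per-stratum; residual pooled /
per-stratum). p-values use the plain χ² upper tail by default; the 50:50
boundary mixture is available behind a flag. Identical models give χ² = 0,
df = 0, p = 1.

### Hierarchical decay model

`fit_hierarchical_model` fits, by REML,
w = Gmax + Gmax×Fitness + Line(Fitness×Treatment) + Subline[Line] +
Replicate{Subline}, with all random-effect variances estimated separately
per Fitness×Treatment stratum. Defining each line's control mean equal to 1
makes the Fitness main effect unidentifiable and pins the control among-line
variance, so the former is omitted and the latter constrained to zero. The
covariance is block-diagonal by line × treatment cell; blocks are small, so
the REML criterion uses dense Cholesky factorizations and L-BFGS-B over the
(bounded) variance vector. Fixed effects get Wald t-tests with Satterthwaite
degrees of freedom computed numerically (delta-method gradient of the
coefficient variance and the observed REML information over the components
away from the zero boundary); if the information matrix is singular, the
fallback df is the number of line × treatment cells minus the number of
fixed effects. SAS-style Kenward-Roger df are intentionally not replicated.

## Mutational inference

Per resample of the subline-level bootstrap (n = 1000 by default, seeded,
bit-reproducible): draw sublines with replacement separately within the
control and MA strata; recompute w̄₀ and w̄_MA from unweighted subline means;
ΔM = (w̄_MA − w̄₀)/(w̄₀t); refit one-way components per stratum;
V_M = max(0, (V_L,MA − V_L,0)/(2t)). The own-group scaling is applied per
resample as V*/mean², using that resample's group means. Point estimates are
bootstrap means; intervals are the middle 95% percentiles; U_MIN and
E[a]_MAX are computed from the bootstrap means of ΔM and V_M — a ratio of
means, much better behaved than a mean of per-resample ratios, whose
denominator V̂_M is frequently near or at zero. A resample with zero
among-subline variance in both strata keeps ΔM and sets V_M = 0; nothing is
rejected or redrawn.

Undefined quantities (ΔM ≥ 0, or V_M = 0 for the rate bound) are `None` at
the API surface and NaN in tabular output, with the reason in a `flags`
mapping — never numeric sentinels. |E[a]_MAX| > 1 is reported but flagged
nonsensical. Group summaries first merge a re-assayed line as the unweighted
mean of its per-assay estimates (NaN-skipping, so an undefined first assay
leaves the re-assay value standing), then average (and take medians) over
lines; "all" averages the ten per-line values.

`exact_rank_probability(n_low, n_high, k)` = C(n_low, k)/C(n_low+n_high, k)
is the exchangeable-null probability that the k most extreme lines all come
from the low group; it is verified against subset enumeration in tests.

### A factor-of-two caveat on Bateman–Mukai

The implemented bounds are U_MIN = 2ΔM²/V_M and E[a]_MAX = V_M/(2ΔM), with
V_M estimated as (V_L,MA − V_L,0)/(2t). These satisfy U_MIN·E[a]_MAX = ΔM
and U_MIN·E[a]_MAX² = V_M/2. Note that under the defining identities
ΔM = −U·E[a] and V_M = U·E[a²], the equal-effects limit of U_MIN is 2U (not
U) and of E[a]_MAX is −E[a]/2: the classical formulation divides by the
per-generation *increase* of the among-line variance (2·V_M), not by V_M
itself. The package reproduces the bounds exactly as defined above; users
comparing against the classical parameterization should halve U_MIN and
double E[a]_MAX. The parameter-recovery test in the acceptance suite
documents this gap rather than recalibrating either side.

## Simulator

`simulate_experiment` collapses within-lineage fixation dynamics to the
subline level: over t generations a subline fixes Poisson(u·t/2) mutations
(a new mutation in a selfing single-individual lineage fixes or is lost with
probability ½ each), each homozygous with effect 2a, where a is the average
(heterozygous) effect drawn from the effect model (equal or gamma). This
calibration makes the generated data satisfy ΔM = −u·E[a] and
V_M = u·E[a²] exactly under additive action (`expected_moments` returns the
closed forms, and for multiplicative action the exact compound-Poisson
moments alongside the first-order linearizations and their gap).

Defaults are the emulated design: 10 lines (half labelled high-, half
low-fitness), 22 MA sublines and 10 pseudolines per line, 5 replicates,
t = 150, ancestral mean lifetime output 148.5. Choices the design leaves
open, fixed once here: day fractions (0.6, 0.3, 0.1) across ages
4.75/5.75/6.75 (reproduction in these assays is strongly front-loaded);
environmental noise as a lognormal multiplier with mean 1 and variance
v_e = 0.3 on the relative-fitness scale (a typical within-line variance for
a high-fitness line; normal additive noise behind a flag); non-reproducer
probability 0.02, genotype-independent by default; Poisson daily counts with
an optional negative-binomial overdispersion knob. The optional
`neutrality_threshold` discards fixed mutations with homozygous effect above
s* — a crude stand-in for selection purging non-neutral mutations during MA;
switching it off is stream-neutral, so the same seed reproduces the
unthinned experiment bit for bit.

What the simulator does **not** emulate: assay-block and thaw effects
(pseudolines are exchangeable by construction), survivorship differences
(all simulated worms survive the assay; the w = 0 path is exercised through
zero-inflation), generation-time evolution, backup-plate bookkeeping, and
any sequence-level mutation process. A green pipeline test therefore
establishes correctness of the estimators under the assumed hierarchical
Gaussian-ish world, not robustness to those real-world artifacts.

Because the components are truncated at zero and V_M is floored, the plug-in
V_M is slightly biased downward when the true control component is 0 (the
positive part of V̂_L,0 is subtracted); the bias scales like the sampling SD
of V̂_L,0, i.e. like the SE of a mean over experiments, so round-trip tests
compare the mean estimate to the expectation within 2 empirical SD of the
per-experiment estimates (ΔM, being unbiased, is additionally held to 2 SE
of the mean).

## Pipeline

`run_pipeline(RunConfig)` wires the stages together: one r₀ per assay,
per-line bootstraps with independent seeds spawned deterministically from
the single global seed via `SeedSequence` (all derived seeds recorded in the
output), estimate-level re-assay merging, the hierarchical model on the
pooled records, and CSV/JSON outputs with sorted keys and no timestamps so a
rerun is byte-identical. Stage failures are surfaced with the stage name and
offending line identifier.

## Known limitations

* The REML engine covers exactly the nested designs used here; it is not a
  general mixed-model engine.
* Satterthwaite df are numerical approximations and can be conservative
  when several components sit at the zero boundary.
* Bootstrap CIs for U_MIN/E[a]_MAX are not reported: the per-resample ratios
  are too heavy-tailed to summarize honestly with percentile intervals; the
  bounds inherit uncertainty from the ΔM and V_M intervals instead.
* With realistic noise (V_E* ≈ 0.3–1, 20–24 sublines × 5 replicates) V̂_M is
  frequently floored at zero and the U_MIN bound is heavy-tailed; per-line
  bounds should be read as order-of-magnitude statements, which is also how
  the underlying method is normally used.
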