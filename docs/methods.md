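# Methods

This note documents the statistical model behind each stage of
`ewaskit`, the defaults and why they were chosen, what the synthetic
cohorts do and do not emulate, and the numerical conventions that make
runs reproducible.

## Synthetic cohorts

The generator (`ewaskit.simulate`) produces probe-by-sample beta
matrices with the structure the downstream analysis assumes.

**Latent model.** Every probe carries a background methylation level
drawn from a three-state mixture — unmethylated (mean 0.08),
hemi-methylated (0.50), methylated (0.92) with weights 0.25 / 0.13 /
0.62, chosen so the genome-wide mean beta sits near 0.655, the level
typical of whole-blood leukocyte methylomes. Marker probes instead take
cell-type-specific values: each of the 7 blood cell types (B, NK, CD4T,
CD8T, monocytes, neutrophils, eosinophils; leukocyte/epithelial for
saliva) owns alternating hypo-/hyper-methylated marker blocks separated
from all other types by at least 0.5 beta. A sample's latent methylome
is the convex mixture of the reference columns under its true cell
fractions, drawn from a Dirichlet whose mean mirrors blood composition
(granulocytes ~0.72, CD8T ~0.09, monocytes ~0.06, minor lymphocyte
fractions) with concentration 60. A dedicated set of purity probes is
unmethylated (beta 0.16) in all leukocyte types, so pure blood samples
score ~(1 − 0.16)/0.85 ≈ 0.988 on the LUMP scale.

**Treatment effect and decay.** A configurable fraction of promoters
(default 2%) is causal with a coherent signed shift per promoter
(alternating sign), plus isolated causal probes up to 1% of the
universe. Treated samples receive `delta * exp(-ln 2 * t / h)` at causal
probes, `t` being years from treatment start to specimen collection and
`h` the decay half-life. Defaults: `delta = 0.1` on the beta scale and
`h = 1` year. Neither magnitude is an empirical estimate — published
cohort studies report effect attenuation but not the underlying shift
distribution — so both are documented assumptions, fixed once and used
by every test.

**Nuisance structure.** Per-(probe, batch) offsets (SD 0.005),
per-subject random intercepts (SD 0.01, shared across a pre/post pair),
type-II probe compression toward 0.5 (logit-scale shrink by a factor
1.6 on the 70% of probes assigned design class II), observation noise
`Beta(mu*nu, (1-mu)*nu)` with precision `nu = 100` (per-probe SD ~0.05
at mid-range betas, a few times a typical array's technical noise, so
power checks are not trivially easy), sporadic elevated detection
p-values (0.2% of entries), missing entries (0.1%), and optional
wholesale-failing or low-purity samples. Reference marker probes and
purity probes are assigned design class I: real deconvolution
references are built from well-behaved probes, and this keeps the
reference on the same scale as the emitted betas without requiring
normalization first.

**Cohort designs.** The paired arm draws pre/post pairs (default 125)
with post-treatment draw times uniform on 0.02–0.3 years and a
post-treatment monocyte expansion (Dirichlet concentration for
monocytes inflated 1.3×), so adjusting for monocytes is meaningful. The
single-time-point arm (defaults 1,066 treated / 742 untreated blood;
207/130 for saliva) assigns treated samples to time strata with
proportions 0.20 / 0.45 / 0.30 / 0.05 for < 0.5 y, 0.5–2 y, > 2 y and
"unspecified" (time recorded as missing), drawing times uniformly
within 0.05–0.5, 0.5–2 and 2–6 years respectively. Probe counts default
to 20,000 — the generator emulates the structure of a 588,798-probe
EPIC-style array, not its cardinality; tests and the acceptance script
use 600–5,000 probes so the whole suite runs in well under an hour on
one CPU.

**What the generator does not emulate** — and therefore what passing
tests do not show about real data: raw two-channel intensities and
dye/background chemistry; genomic autocorrelation between neighbouring
probes (probes are conditionally independent given the latent mean);
probe-specific SNP artefacts beyond a binary flag; age/ethnicity
effects on methylation (covariates are drawn independently of beta, so
adjustment is exercised structurally, not against real confounding);
and non-exponential (e.g. plateauing) recovery trajectories.

## QC and normalization

**Greedycut.** The detection-p matrix is scanned iteratively: at each
step the row (probe) or column (sample) with the largest fraction of
entries failing `p > 0.01` is removed, rows winning ties. The published
descriptions of this algorithm leave the stopping rule open; here
removal stops when no row or column fails more than `stop_frac = 0.05`
of its entries. Surviving sporadic failures are masked to missing and
later imputed — running to zero failures would discard large parts of a
matrix with scattered noise.

**BMIQ.** For each sample, three-state beta mixtures are fitted to
type-I and type-II probes separately by EM. The M-step is the weighted
maximum-likelihood update (Newton on the digamma moment equations,
warm-started from weighted moment matching), which keeps the
log-likelihood monotone; convergence is a relative log-likelihood
change below 1e-6, max 200 iterations, values clipped to
[1e-6, 1 − 1e-6]. Initialization splits the *beta scale* at 1/3 and
2/3: splitting at the data quantiles instead seeds two components
inside the dominant methylated mode (~60% of probes) and traps EM in a
local optimum. Type-II U-state values are quantile-mapped onto the
type-I U component (lower tail), M-state values onto the type-I M
component (upper tail), and the hemi-methylated middle is carried
across by a linear dilation between the transformed state boundaries;
type-I values are returned unchanged. Mixtures are fitted on at most
5,000 values per class (deterministic subsample) and applied to all
probes. BMIQ is only *approximately* idempotent: a second application
refits the mixture on finite data and moves values at the
O(n^-1/2) scale of the parameter estimates, so the tests assert that a
second pass moves values far less than the first rather than a
machine-precision identity.

**Filters and imputation.** Probe filters are set intersections
(order-independent): non-CpG contexts (CC, CAG, CAH, CTG, CTH, Other),
SNP-overlapping, cross-reactive, chromosome-Y probes, and probes with
standard deviation strictly below 0.005 across samples. Missing
entries are imputed from the `k = 10` nearest probes by Euclidean
distance over jointly observed samples (no rescaling by the number of
shared samples), using only donors observed at the target sample; ties
break by probe order. Observed values are never altered.

**Paired shift test.** Wilcoxon signed-rank with Pratt zero handling;
exact null for n ≤ 25 without zeros, otherwise the normal approximation
with continuity correction. All-zero differences return p = 1 with a
warning.

## Deconvolution

RPC regresses each sample's marker-probe betas on the reference columns
with Huber loss (tuning constant 1.345, IRLS max 100 iterations,
tolerance 1e-8, intercept included then discarded), truncates negative
coefficients at zero and renormalizes to sum to one. The
renormalization is a deliberate divergence from implementations that
leave truncated coefficients unscaled: downstream use as model
covariates wants fractions on a common scale. The LUMP score is
`min(1, mean(1 - beta over purity probes) / 0.85)`; the 0.85 scaling
constant and the purity-probe set are conventions of this package (the
estimator family is published, the exact constants are not), and the
purity cutoff removes samples scoring below 0.9.

## Differential methylation

Models are fitted on beta values (an M-value toggle is deliberately
absent from the default path: the pipeline's contracts are stated on
the beta scale). The paired design is intercept-free with both
time-level columns, n − 1 subject indicators (reference = first subject
by sort order) and numeric covariates (e.g. monocyte fraction);
contrast post − pre. The single design carries both treatment-level
columns plus covariates — categorical covariates expand to indicators
against the earliest batch / majority level; cell fractions must enter
with one type dropped (they sum to one), and collinear columns are
reported by name. Per-feature OLS gives `effect = c'B`, residual
variance `s^2` on `d = n - rank(X)` df, and the shared
`stdev_unscaled = sqrt(c'(X'X)^- c)`.

Moderation estimates the prior `(d0, s0^2)` by moment matching on
`e = log s^2 - digamma(d/2) + log(d/2)`: the excess of `Var(e)` over
`trigamma(d/2)` determines `d0` through trigamma inversion (Newton),
and the mean fixes `s0^2`; when the excess is non-positive the prior is
infinite and `s0^2` is the mean variance. Posterior variances
`s2_post = (d0 s0^2 + d s^2)/(d0 + d)`, total df `d + d0` capped at the
pooled residual df. Features with `s^2 = 0` are excluded from prior
estimation and assigned `s0^2`. On fixed test fixtures this chain
reproduces the R package limma's moderated t and p to ~1e-11
(frozen-oracle tests). Ranking statistics are
`z = sign(effect) Phi^-1(1 - p/2)` with p clipped at 1e-300; ties in z
break by |effect| then feature ID. Promoter-level analysis averages
member-probe betas per sample (promoters defined by annotation or by
TSS windows, 1.5 kb upstream / 0.5 kb downstream, strand-aware) and
refits the same models; promoters losing all probes to QC are dropped.

## Enrichment and the two nulls

The enrichment score walks the gene list ranked by z (descending):
members increment the running sum by `|z|^exponent` normalized by the
total member weight (exponent 1), non-members decrement by
`1/(N - |S|)`; ES is the signed maximum deviation. Genes mapped by
multiple promoters keep the most significant one. Set sizes outside
[10, 500] after intersection with the ranked universe are dropped.

*Gene permutation* draws `n_perm` (default 10,000) random same-size
sets from the universe — simple Monte-Carlo rather than an adaptive
multilevel approximation; at these scales the plain estimator is
unbiased and fast enough. *Label permutation* (default 500 iterations)
shuffles the treated/untreated labels across individuals, keeping all
covariates attached to their samples, and re-runs model fitting,
moderation, ranking and scoring per iteration; degenerate single-label
draws are rejected and redrawn.

Both nulls report the plus-one one-sided tail
`p = (1 + #{null at least as extreme in the tested tail})/(1 + n_perm)`
with resolution floor `1/(n_perm + 1)`. By default the tested tail
follows the observed ES sign — the usual exploratory convention, which
is at most a factor two anti-conservative under the null because the
tail is chosen after seeing the sign. Passing a fixed a-priori
direction per set (or `two_sided=True`) makes the null p exactly
uniform; calibration tests and the acceptance script use the
fixed-direction mode. One further caveat: within a single cohort the
per-set label-permutation p-values share the observed ranked list and
are strongly correlated, so uniformity is a statement about independent
cohorts (and is tested that way), not about the spread of p-values
inside one run. NES divides ES by the mean |null ES| of matching sign.

## Attenuation

Treated samples are binned by time from treatment start with half-open
boundaries [0, 0.5), [0.5, 2), [2, ∞) years; treated samples without a
recorded time form an "unspecified" stratum that is modelled (it
absorbs its group mean) but excluded from decay comparisons. A single
joint intercept-free fit with the five-level stratum factor and the
single-design covariates yields each stratum-vs-untreated contrast with
shared residual variances.

The attenuation slope regresses late-comparison effects on
early-comparison effects **through the origin** (`b = Σxy/Σx²`, with
`se = sqrt(Σ(y - bx)²/(n-1)/Σx²)`): the scientific claim is
proportional attenuation of the same planted effects, for which a free
intercept has no meaning; an intercept toggle exists for sensitivity
analysis. Slopes are computed over features significant in the earlier
comparison by default (configurable to all features). Two estimator
caveats are worth knowing: (i) both contrasts share the untreated
reference group, which biases the null (complete-decay) slope upward by
roughly `n_early/(n_early + n_untreated)` — negligible when the
untreated arm is large, and dominated by real signal otherwise;
(ii) regression on *estimated* early effects attenuates slopes slightly
toward zero when early effects are noisy (classical errors-in-variables),
which is why recovery tests compare against the analytic expectation
`E[exp(-λt_late)]/E[exp(-λt_early)]` with a generous CI rather than the
raw decay factor. Persistence counts flag, among features significant
in the latest comparison, sign-concordance across all comparisons and
strictly decreasing |effect| from earliest to latest.

## Orchestration and reproducibility

All randomness flows from explicit seeds through
`numpy.random.default_rng`; no stage reads the wall clock or global RNG
state. Every output table is written with a fixed `%.10g` float format,
and the manifest records the configuration hash (analysis parameters
only, output paths excluded), seeds, per-stage counts matching the
QC-report semantics, and SHA-256 digests of every file — re-running a
config reproduces the outputs byte for byte, which the test suite and
the acceptance script both verify.

## Problem sizes

Tests and the acceptance script run scaled-down versions of the study
designs: 600–5,000 probes, 60–125 pairs or 60–1,200 single-time-point
samples, 100–500 gene permutations and 20–100 label permutations,
chosen so the full suite completes in about a minute and the acceptance
script in about half a minute on one CPU while keeping every estimator
in its calibrated regime. Statements about power and calibration are
made under these planted-truth conditions; they do not certify
behaviour on real arrays with correlated probes and unmodelled
confounding.

## Known limitations

* BMIQ assumes three distinguishable methylation states per design
  class; arrays dominated by a single state collapse the fit (an error
  is raised rather than a silent pass-through).
* The label-permutation null re-fits the full model per iteration and
  is O(n_perm × model fit); at the paper-scale 500 permutations on
  hundreds of thousands of probes this is a batch job, not interactive.
* `intersect_significant` requires sign concordance but not effect-size
  homogeneity across datasets; heterogeneous cohorts should be compared
  on effects, not just flags.
* The generator's covariates are independent of methylation by
  construction; confounding-robustness is out of scope.
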