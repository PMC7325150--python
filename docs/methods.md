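# Methods

## Model and assumptions

`rankenrich` performs functional-class-scoring enrichment analysis jointly
over *k* differential-expression contrasts. The response variable is the
genes × contrasts matrix of centred ranks; a gene set defines a two-group
split (members vs non-members) of the rows; the null hypothesis is that the
member and non-member mean rank vectors coincide. The test is a one-way
two-group MANOVA with the Pillai–Bartlett trace V = tr(H(H+E)⁻¹), which for
two groups is equivalent to Hotelling's T², with the exact transform
F = ((n−k−1)/k)·V/(1−V) on (k, n−k−1) degrees of freedom. For a single
contrast the test reduces to the one-way two-group ANOVA (the squared
pooled-variance t-test).

The F reference distribution assumes approximately normal group means with
a common covariance. Ranks are bounded and uniform, but set means at
typical sizes (m ≥ 10) are close to normal by the central limit theorem;
empirically the null p-values are uniform to beyond the 10⁻⁵ tail at the
default conditions (checked in the test suite). The test treats genes as
exchangeable under the null: like all tests of this family it does not
model inter-gene correlation, so on strongly co-expressed real sets the
p-values can be anti-conservative relative to a sample-permutation test.
Because all k responses enter one statistic, per-set computation is a pure
function of the rank matrix and the membership, and sets can be tested
independently (and in parallel) with results identical to serial execution.

### Scoring and ranking

* Direct-statistic table dialects copy the tool's signed statistic; paired
  (effect, p) dialects use D = −log₁₀(p)·sign(log₂FC). sign(0) = 0, so a
  zero effect yields D = 0; p = 0 is clamped to the smallest positive
  normal double before the log, keeping D finite (~308) while preserving
  the extreme rank.
* Ranks are ascending with **average** ties (the symmetric choice, which
  keeps the null distribution of s symmetric), centred by subtracting
  N_neg + (N_zero+1)/2 so that a score of exactly 0 maps to centred rank 0
  and sign(centred rank) = sign(score). A strictly increasing transform of
  the scores changes centred ranks by at most a per-contrast constant
  (when the zero-crossing moves), which cancels in s, S and the MANOVA:
  results depend on the scores only through their within-contrast order.

### Per-set quantities

* s = 2(R₁−R₂)/n per contrast, in [−1, 1]; positive s means members sit
  toward the up-regulated end.
* S = ‖s‖₂ (non-directional multidimensional effect size); sSD = sample
  standard deviation (ddof = 1) of s across contrasts, undefined (NaN) for
  k = 1.
* Benjamini–Hochberg adjustment is applied across exactly the sets that
  passed size filtering, not the full library.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `min_size` | 10 | minimum effective members (set ∩ profile); smaller sets give unstable rank means. Sets must also have ≥ k+2 effective members for positive error df, enforced with a separate warning. |
| join `mode` | `intersect` | genes present in all contrasts; `union` fills absent scores with 0 (centred rank ≈ 0, the least informative placement) for sparse designs such as single-cell contrasts. |
| `priority` | `significance` | row order: ascending p, or descending S (`effect`), or descending sSD (`SD`, for discordant regulation). Ties broken by set name so output is deterministic. |
| `top_n` | 50 | number of sets given detailed plots / report sections. |
| `on_duplicate` | `error` | duplicate gene ids in one DE table are a data problem; `max_abs` opts into keeping the strongest row. The same largest-|score| rule resolves many-to-one identifier-map collisions. |
| `n_jobs` | 1 | worker processes for per-set tests; results are identical at any worker count. |

There is no hard upper limit on contrast count; a warning is emitted above
20 contrasts because the plotting routines refuse more than 20 (pairwise
panels stop being readable).

## Numerical implementation

For two groups H + E equals the total SSCP matrix T about the grand mean,
which is independent of the set. With d the difference of group mean
vectors and c = m(n−m)/n, H = c·dd′ has rank one and V = c·d′T⁻¹d, so one
Cholesky factorisation of the k×k matrix T serves every set tested on a
given rank matrix; testing a library is a batch of small triangular
solves. This closed form is verified in the test suite against (i) a
textbook Hotelling T² implementation and (ii) the general
eigen-decomposition Pillai trace, both to 10⁻¹⁰ relative error.

Degenerate inputs: a constant contrast (zero rank variance) raises an
error naming the contrast; sets overlapping none or all of the profile are
rejected (empty complement); p-values are clamped into (0, 1] at the
smallest positive double. V is capped at 1 (possible only in degenerate
exact-separation cases).

## Synthetic data generators

The simulation module generates the study conditions under which the
method's accuracy is measured:

* **Null profiles** — each contrast is an independent uniform permutation
  of the centred ranks {1..n} − (n+1)/2. Defaults mirror a typical bulk
  RNA-seq contrast after expression filtering: n = 15,240 genes, five
  contrasts.
* **Random libraries** — 1000 sets of 50 members sampled uniformly without
  replacement, independently per set (sets therefore overlap by chance).
* **Rank-shift injection** — for each of 20 designated DE sets and each
  contrast, s* ~ Normal(0, SD) is drawn and δ = n·s*/2 is added to member
  centred ranks, *without re-ranking*: the additive shift moves the
  member/non-member mean difference by exactly n·s*/2, so a lone injected
  set's measured s moves by exactly s*, and E[s] = s* in general
  (re-ranking would attenuate the injected signal; shifted values may
  exceed the original rank range). Shifts are additive for genes in
  several DE sets. The SD grid 0–0.25 corresponds to mean |s*| of
  0–0.2 (= SD·√(2/π)).
* **Null randomisations** — three type-I-error probes of a fixed profile:
  shuffle gene names jointly (preserves inter-contrast correlation),
  shuffle each contrast's values independently (destroys it), or keep the
  profile and draw fresh random sets matching a prescribed size template.
  The built-in template emulates a curated pathway library (log-normal
  sizes, median ≈ 40, clipped to [10, 400]).
* **Count simulation** — a synthetic sequencing experiment for single- and
  dual-contrast harnesses: per-gene abundances from a long-tailed
  log-normal stand-in for a deeply sequenced library, multinomial
  downsampling to a target depth, per-gene noise factors
  log₂(max(ε, Normal(2, SD))) (exactly 1 at SD = 0), and multiplicative
  case fold changes resolved per gene (a gene recruited both up and down
  receives none).

What these generators deliberately do **not** emulate: inter-gene
correlation within real pathways, heavy-tailed and discrete DE-score
distributions, biologically structured set overlap, or real library size
distributions. Passing benchmarks therefore demonstrate the calibration
and power of the statistic under exchangeable nulls, not performance on
any particular real dataset.

## Benchmarks, problem sizes and the detection boundary

The power benchmark runs profile → library → injection → enrichment →
FDR-threshold → precision/recall/F1 against the injected truth, averaged
over seeded replications; the package runs 100 replications per SD grid
point (both in the test suite and in `scripts/acceptance.py`), which
bounds the Monte-Carlo standard error of mean precision and F1 below
about 0.01 while keeping a full grid run under two minutes on one CPU.

The attainable power is fixed by arithmetic, and it is worth stating
explicitly. For a set of m genes in a profile of n, the null standard
deviation of s per contrast is ≈ 1/√(3m) — independent of n — so an
injected s* contributes a standardised effect z ≈ s*·√(3m) per contrast
and a noncentrality λ = Σ_d z_d² overall. At the default m = 50, z ≈
12.2·s*. A Benjamini–Hochberg call at q < 0.05 among 1000 sets with ~20
real signals requires roughly p < 10⁻³, i.e. T² ≳ 20. With s* ~
Normal(0, 0.15), λ ~ 3.35·χ²₅ (median ≈ 15), so a substantial fraction of
injected sets sit *below* the detection boundary: measured mean recall at
SD = 0.15 is ≈ 0.39 and mean F1 ≈ 0.54, rising to ≈ 0.9 at SD = 0.25.
This is not an implementation ceiling — no test, however constructed, can
reliably separate a 50-member set whose mean rank moved by less than a
couple of null standard deviations — and the same arithmetic puts
near-perfect F1 at SD = 0.15 beyond any method under these study
conditions. Precision behaves differently: at SD = 0 essentially nothing
is called (BH under the global null rejects anything at all in ≲ 5% of
runs, so single false positives appear at a rate of a few per hundred
runs), and across the grid mean precision stays ≥ 0.92 at 5% FDR and
≥ 0.98 at 1% FDR; the worst point is SD = 0.05, where false positives are
inflated by random sets that share members with injected sets and thus
carry diluted real signal.

The null-randomisation benchmark (two contrasts, 1000 template-sized sets)
yields ≈ 0.05–0.2 false positives per run at FDR < 0.05 for all three
procedures, consistent with BH behaviour under a global null.

## Design choices

* The two-group closed form is the implementation; the general multi-group
  eigen path exists only as a test oracle. Exact, stable and orders of
  magnitude faster than a generic MANOVA solver at library scale.
* Format autodetection tries exact column signatures of known tool
  dialects, most specific first; an ambiguous match without a hint is an
  error rather than a guess. All paired dialects use the same D score.
* GMT parsing is strict (≥ 3 tab-separated fields, unique names, no empty
  libraries): a silently shrinking library is worse than a parse failure.
* The HTML report embeds static base64 PNGs rather than interactive
  JavaScript charts, keeping it a dependency-free single file; contours
  are Gaussian KDEs with Scott bandwidth on an 80-point grid padded by
  three bandwidths (density integrates to 1 within ~1%).
* All simulation operations are pure functions of (inputs, seed), with
  per-replication child seeds spawned from a root seed sequence.

## Known limitations

* No modelling of inter-gene correlation (no CAMERA-style variance
  inflation) and no set-overlap correction; strongly overlapping real
  libraries will produce correlated results rows.
* No pathway-topology information and no single-sample scoring.
* The count simulator's baseline abundance profile is synthetic; absolute
  accuracy numbers from it are not comparable to pipelines anchored on a
  specific real dataset.
* Detection of sets with S below ≈ √(20/(3m)) (e.g. ≈ 0.36 at m = 50) is
  power-limited for any method; prioritising by S or sSD does not change
  which sets reach significance, only how significant sets are ordered.
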