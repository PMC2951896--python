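# Methods

## The two models

Cross-species comparison of expression is indirect: expression values
measured on different platforms for different species are never compared
directly. Both models reduce each gene to a within-dataset summary that
is comparable across datasets.

**Corresponding-tissue EC.** Given n tissues judged biologically
corresponding between species A and B, gene i's profile in each species
is normalised to relative abundance, s_ij = E_ij / Σ_j E_ij, and
EC_i = r(s^A_i, s^B_i), the Pearson correlation over the n tissues.
Divergence is alternatively the Euclidean distance between the two RA
vectors, which lies in [0, √2] because RA vectors live on the
probability simplex. Assumptions: the tissue correspondence is
meaningful (tissues themselves evolve, so "corresponding" is an
approximation), n ≥ 3, and profiles are complete and nonnegative. RA
removes per-gene scale; Pearson additionally removes per-gene offset, so
EC is invariant to positive rescaling of either profile.

**Co-expression EC.** Each species' matrix over the k row-aligned 1-1
orthologs is converted to a k×k pairwise correlation matrix (PCM) of
Pearson correlations between gene profiles over all of that species' own
conditions. EC_i is the correlation between row i of the two PCMs over a
chosen reference set:

- whole ortholog set: all positions j ≠ i;
- ICC: all positions j ≠ i, weighted by w_j = the previous iteration's
  EC_j, iterated from uniform weights until the largest elementwise EC
  change falls below a tolerance;
- CCN restriction: only positions that are nodes of conserved
  co-expression networks — genes with at least one partner whose
  within-species correlation strictly exceeds the x-quantile of a
  random-gene-pair background distribution in both species.

Assumption shared by all three: the reference orthologs carry genuine
co-expression structure (a gene uncorrelated with everything has an
undefined or meaningless fingerprint), and reference orthology is
correct — which the permuted-reference control deliberately breaks.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `floor` | 200 (intensity units) | a gene never reaching this level in a species is dropped (pair-synchronised); limits the influence of low-intensity noise on correlations. Masking individual sub-floor values instead would create incomplete vectors and is rejected. |
| `x` (background quantile) | 0.975, also 0.95 / 0.99 | CCN edge stringency; higher x shrinks the node set (node sets are nested in x). |
| `n_pairs` (background) | 20,000 | random gene pairs per species for the background distribution; ordered pairs with replacement, degenerate (constant-profile) draws skipped and counted. |
| `tol`, `max_iter` (ICC) | 1e-3, 100 | convergence is the max-norm of the EC change — the strictest elementwise criterion; both are recorded with the result for auditability. |
| `weight_scheme` (ICC) | `clamp` | previous-iteration ECs are clamped at `weight_floor` (default 0) so negative ECs get no influence; `shifted` ((EC+1)/2) and `raw` variants are exposed since the weighting transform is a genuinely open choice. |
| `exclude_self` | true | PCM diagonals are structurally 1 in both species and carry no cross-species information; including them would inflate every EC identically. |

## Numerical and procedural choices

- **Undefined scores are missing, never zero.** An EC is undefined when a
  profile or restricted reference row is constant, or RA is undefined
  (all-zero profile). Such pairs carry `valid = False` and NaN, are given
  weight 0 inside ICC, and are excluded from summaries and agreement
  statistics (complete-case policy: agreement uses pairs valid under both
  methods). Reporting 0 instead would contaminate distribution means.
- **Constant-vector detection is exact** (max = min over the weighted
  support), not a variance-epsilon heuristic.
- **Summation order is deterministic** (ascending reference index,
  C-contiguous containers), so restricted variants reduce *exactly*:
  CCN-EC with the full node set is bitwise the whole-set EC, and ICC
  iteration 0 is bitwise the whole-set EC.
- **Quantiles** are linear-interpolation empirical quantiles; the CCN
  edge test uses strict inequality (> threshold, in both species).
- **Ties** in Spearman agreement and in the truth-recovery AUC use
  average ranks (ties count one half in the AUC).
- **Two-sample tests** are Welch's unequal-variance t-test; no
  multiple-testing correction is applied and raw p-values are reported,
  both recorded in the run manifest.
- **Nulls.** The random-pair null pairs A-gene i with B-gene π(i) for one
  uniform permutation π (fixed points permitted and logged; ≈1 expected
  at realistic k). For co-expression methods the reference orthology is
  left intact and both self positions {i, π(i)} are excluded, so the
  identity permutation reproduces the ortholog ECs exactly. The
  permuted-reference control instead shuffles the *columns* of the
  reference-side PCM, preserving each row's value distribution while
  destroying the cross-species meaning of the reference positions.
- **Seeding.** Every stochastic stage receives a seed derived by hashing
  (global seed, stage name), so adding a stage never perturbs another
  stage's stream and full runs are byte-identical under a fixed seed.
- **Filters** are pair-synchronised (dropping pair i removes row i in
  both species, keeping k equal), idempotent, and applied in a fixed
  order: expression floor, then zero-variance removal.

## The simulator

A latent-module factor model on the log scale: m module activity
profiles per tissue (standard normal), per-gene module loadings
(standard normal), expression = `intensity_scale · exp(loading·activity
+ N(0, noise_sd))`. This produces strictly positive, right-skewed
intensities with multiplicative noise and genuine co-expression
structure (genes sharing modules correlate), which the co-expression
methods require. Cross-species structure: the first `n_common` tissue
columns correspond, with species B's activities there perturbed by
N(0, `tissue_evolution_sd`) — tissues evolve; a fraction `p_cons` of
genes keeps identical loadings (conserved), the rest get
`(1−d)·loading_A + d·fresh` with d = `divergence_d`;
`divergence_scope="noncommon"` confines divergence to species B's
non-common tissues, the regime where a corresponding-tissue panel hides
divergence the full data can see.

Defaults (k = 500, 30/24 tissues with 20 corresponding, m = 8,
p_cons = 0.5, d = 1, tissue sd 0.2, noise sd 0.3, scale 1000, seed 7)
define the standard condition used throughout the tests and the
acceptance script: a panel-size ratio and common-tissue fraction in the
neighbourhood of real two-species tissue compendia, at a size where
every stage runs in seconds. The information-loss analyses use k = 300
with equal 30-tissue panels (20 corresponding for the concentrated-
divergence scenario; 28 for the no-tissue-specific-divergence limb).

What the simulator does **not** emulate: probe effects,
cross-hybridisation, platform-specific normalisation artefacts,
phylogenetic structure among more than two species, and expression
breadth/specificity evolution. Passing tests therefore demonstrate the
correctness and calibration of the machinery under a controlled
generative model, not performance on any real compendium.

## Known limitations

- On strongly right-skewed multiplicative data such as the simulator's
  (per-gene log-sd ≈ √m), the corresponding-tissue EC of *random* gene
  pairs has a small positive expectation rather than zero: Pearson
  correlation of exponentiated Gaussian profiles compresses negative
  latent correlation into a narrow band while preserving positive
  correlation, so the null mean shifts above zero (the null-calibration
  tests compute this shift; the co-expression methods, which correlate
  rows of correlation matrices, do not show it). On moderately skewed
  real intensity data the shift is correspondingly smaller.
- ICC's refinement inherits its starting point: if the uniform-weight
  iteration 0 misranks genes badly, subsequent weights propagate the
  error. The per-iteration history is returned so this can be audited.
- A very small CCN node set makes the restricted EC unstable (few
  reference positions per correlation); the implementation refuses node
  sets smaller than 4 and flags per-gene reference sets smaller than 3.
- EC and Euclidean divergence answer different questions and can
  disagree strongly; both are reported so the disagreement is visible
  rather than hidden.
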