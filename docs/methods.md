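# Methods

## The model

SWIPE-NMF fuses heterogeneous evidence of regulatory interaction into
tissue-specific scored networks by penalized non-negative matrix
tri-factorization. Six genomic segment types are modeled — enhancers,
promoters, Hi-C anchors, eQTL SNPs, DHS sites and TADs — with stable codes
1..6 so that `G_1` is always the enhancer factor and `G_2` the promoter
factor. Evidence between types *i* and *j* is a sparse binary matrix
`R_ij` (n_i x n_j); same-type prior knowledge is a signed constraint matrix
`Theta_ii` (negative entries mark interacting pairs). All present blocks are
factorized simultaneously,

    min_{G >= 0}  f(G, S) = sum_{R_ij} || R_ij - G_i S_ij G_j^T ||_F^2
                            + trace(G^T Theta G),

where `G_i` (n_i x k_i, non-negative) encodes soft cluster memberships of
type-*i* segments and `S_ij` (k_i x k_j) couples the clusters of two types.
Outputs per window are the reconstructed enhancer-promoter block
`G_1 S_12 G_2^T` plus the same-type association maps `G_1 G_1^T`
(enhancer-enhancer) and `G_2 G_2^T` (promoter-promoter).

### Input blocks

The default per-tissue schema holds 17 matrices: 4 interaction blocks
(E-P coactivity; Hi-C anchor-anchor; SNP-promoter eQTL; DHS-promoter
correlation), 11 incidence blocks (>=1 bp interval overlap between pairs of
types: anchor-E, anchor-P, SNP-E, DHS-E, TAD-{E, P, anchor, SNP, DHS},
SNP-anchor, DHS-anchor), and 2 constraint blocks `Theta_EE`, `Theta_PP`
marking pairs joined by a Hi-C contact or sharing a TAD (entries
`-lambda_Theta`, default weight 1.0, symmetric, zero diagonal). The schema
is configuration-driven; any block may be absent, and a block is recorded as
absent rather than as a zero matrix when its segment type or evidence source
is unavailable. Every block carries its evidence-source dependencies so that
leave-one-dataset-out removes everything a source contributes (e.g. holding
out Hi-C drops the anchor-anchor block, all anchor incidences, and the Hi-C
ingredient of both constraint blocks).

Load-time filters are applied exactly as the sources publish their
statistics: Hi-C pairs at q-value < 1e-3, eQTL links at P < 1e-5, DHS-
promoter correlations at score > 0.9, coactivity links unfiltered. The
inequalities are strict; boundary values are dropped.

## Solver

Each iteration runs a Gauss-Seidel sweep of multiplicative `G_i` updates
followed by the exact least-squares `S` update
`S_ij = (G_i^T G_i)^+ G_i^T R_ij G_j (G_j^T G_j)^+`. Since `S` carries
mixed signs and `Theta` is signed, every term of the `G` ratio is split into
positive and negative parts:

    G_i <- G_i o sqrt( [lin]^+ + G_i [quad]^- + Theta^- G_i
                      ---------------------------------------- )
                       [lin]^- + G_i [quad]^+ + Theta^+ G_i

with `lin = R_ij G_j S_ij^T` (and the transposed role), `quad = S_ij (G_j^T
G_j) S_ij^T`, `0/0 -> 0`, and denominators floored at 1e-12. Initialization
is random Acol: each `G_i` column is the mean of 5 randomly drawn columns of
the horizontal concatenation of all R blocks incident to type *i*; a type
with no incident block is initialized uniform in [0, 1). Iteration stops
when the relative objective change drops below `tol` (default 0.01) or
after `max_iter` (default 200) iterations.

**Boundedness.** With a purely attractive zero-diagonal `Theta` the raw
objective is unbounded below: scaling `G_i` by c while `S` scales by 1/c^2
leaves every residual unchanged and sends the trace term to -inf, and the
multiplicative iteration follows this ray to numerical overflow within tens
of iterations. The solver therefore anchors each attractive constraint with
its degree diagonal, `Theta -> Theta + D` with `D = diag(W 1)`,
`W = -Theta^-`. The penalty becomes the graph-smoothness form
`sum_pq w_pq ||g_p - g_q||^2 >= 0` standard in graph-regularized NMF: same
co-clustering reward, bounded objective, empirically monotone updates
(verified to 1e-9 relative on batteries of random constrained problems).
`objective()` evaluated with an explicit constraint matrix still returns the
plain trace form.

**Local minima.** Multiplicative updates are local; on exactly
factorizable block data a single run from Acol init reaches the global
optimum in roughly 6 of 10 seeds and stalls otherwise. The method's own
remedy is its restart ensemble (below); exact-recovery checks use the best
of the standard restarts.

### Rank selection and ensemble

Ranks are tied to one fraction k: `k_i = max(1, round(k * n_i))`. Each
window scans k over {0.05, 0.10, ..., 0.50} with a single seeded run per
grid point, records the residual reconstruction error (trace penalty
excluded), and picks the k at the maximum kink — the largest discrete
second difference `e[t-1] - 2 e[t] + e[t+1]` over interior grid points, ties
to the smaller k (parsimony). At the selected rank, 20 independently
initialized runs are averaged; averaging is over the reconstructed outputs
(`G_1 S_12 G_2^T`, `G_1 G_1^T`, `G_2 G_2^T`), never over raw factors, which
are identifiable only up to permutation and scaling. Member seeds derive
from (master seed, window key, member index) with a stable window key, so
results are bit-reproducible and independent of processing order.

## Sliding windows and stitching

Factorization runs on 5 Mb windows sliding by 2.5 Mb (TAD scale; whole
chromosomes are computationally out of reach and would swamp local
structure). Windows start at every multiple of the step below the
chromosome length, the last truncated at the chromosome end; base pairs past
the first step are covered by exactly two windows. A segment belongs to
every window it overlaps (TADs clipped to window bounds for incidence); a
pair is scored in a window only when both members are present. Stitching
averages the scores of pairs seen in two windows and passes single-window
scores through; pairs never co-resident in a window get no edge. Negative
round-off in reconstructions is clipped at zero.

## Cutoff calibration

The enhancer-promoter network is thresholded so the mean number of retained
promoter partners per edge-bearing enhancer is closest to 3, the prevailing
estimate of promoters per enhancer. The denominator counts enhancers with at
least one retained edge (configurable; the alternative of counting all
enhancers is not the default because fully pruned enhancers say nothing
about the partner count the estimate describes). The search is an exact
descending sweep: candidate cutoffs are the distinct edge scores at
tie-group boundaries, and one cumulative pass yields retained-edge and
retained-enhancer counts for every candidate, so the globally closest
achievable ratio is found deterministically (a bisection over this
non-monotone step function could miss it). E-E and P-P networks are left
unfiltered, as no analogous partner-count estimate exists for them.

## Baselines

* **Concatenation** — mean of per-source 0/1 indicators on the E-P grid
  (binary indicators are already min-max normalized).
* **Nearest promoter** — each enhancer links to the promoter with the
  closest interval midpoint on its chromosome, ties to the smaller catalog
  ordinal.
* **Coactivity only** — the coactivity links, score 1.
* **SNF** — similarity network fusion on the unified enhancer+promoter node
  set, no local neighborhood restriction. Normalization:
  `P(x,y) = p(x,y) / (2 sum_{k != x} p(x,k))` off-diagonal, diagonal fixed
  at 1/2, isolated nodes left diagonal-only with a warning. Fusion:
  `P_i <- P_i x (mean of the others) x P_i^T`, renormalizing after every
  step, for 20 iterations (the fusion literature's typical horizon; the
  method itself prescribes no stopping rule). The fused mean is symmetrized
  (row normalization breaks exact symmetry between the two orientations of a
  pair) and restricted to E-P pairs.

## Evaluation protocols

* **Link cross-validation** — coactivity links are split into 5 disjoint
  folds; per fold the held-out links are removed from the inputs (a
  structural check asserts no leakage), the pipeline re-run, and AUROC
  computed on held-out positives vs an equal number of negatives sampled
  uniformly from co-window E-P pairs absent from every evidence source
  (each source mapped to E-P pairs by interval overlap). No distance
  restriction is applied to negatives by default.
* **Leave-one-dataset-out** — an entire source and all blocks it
  contributes are dropped; its rows, mapped to E-P pairs, are the positives.
* **TAD contrast** — with TAD blocks excluded from the inputs, scored pairs
  are labeled intra-TAD (both members overlap a common TAD) or inter-TAD and
  compared with a two-sided Wilcoxon rank-sum test (the shift alternative
  fits a score-level comparison and needs no distributional assumption).
* **Distance filter** — pairs at midpoint distance strictly greater than
  5 kb, available for biological-correlate analyses.

AUROC is rank-based with mean-rank tie handling, identical to the
Mann-Whitney U statistic divided by n+ n-; the test suite cross-checks it
against a brute-force pair counter to 1e-12.

## Synthetic data

The planted-structure generator is the package's test bed and defines its
study conditions. Defaults: one 10 Mb chromosome tiled by 6 equal TADs,
3 latent clusters assigned to TADs round-robin; 200 enhancers (1 kb),
100 promoters (1.5 kb), 60 Hi-C anchors (40 kb), 120 SNPs, 120 DHS sites
(300 bp) placed uniformly. A segment adopts its TAD's cluster with
probability 0.9, tying latent structure to genomic domains; SNPs and DHS
sites co-locate with a host enhancer with probability 0.7 and inherit its
cluster (cis-variants and open chromatin sit in regulatory elements).
Evidence between two segments within 2 Mb is emitted with probability 0.3
for same-cluster pairs and 0 otherwise, then flipped with the 10% noise
rate; statistic columns are drawn strictly inside the significant range so
load-time filters keep every emitted row. Pair counts come out at roughly
7 coactivity links per enhancer.

The **null source** used for leave-noise-out calibration is drawn uniformly
from the co-window, evidence-free pair frame — the same frame evaluation
samples negatives from — at density 0.03. This makes null positives and
negatives exchangeable, which is the property a null calibration tests. A
noise source with a different distance composition, or one overlapping the
informative sources, instead measures the score-distance profile or genuine
cross-source redundancy: both were observed to push the null AUROC to
0.57-0.76 while the exchangeable construction sits at 0.47-0.51.

What the generator does **not** emulate: genomic distance decay of contact
probability, length and density heterogeneity of real annotations, unequal
cluster sizes, assay-specific error structure, and the three orders of
magnitude between desk-scale and genome-scale segment counts. Passing tests
demonstrate that the machinery recovers planted low-rank structure under
calibrated noise — not performance on real epigenomes.

## Problem sizes and numerical choices

Pipeline-level checks run the full method on the default fixture (4 windows
of up to ~100 enhancers and ~50 promoters; 17 blocks per window; 10-point
rank grid + 20-member ensemble per window), which completes in seconds per
run; solver-level properties use random block systems of 20-50 segments per
type. Stopping tolerance 0.01 (relative objective change), cap 200
iterations, update denominators floored at 1e-12, `0/0 -> 0` in the
multiplicative ratio, pseudo-inverses for singular Grams in the S update.
Ties: rank-grid kink to the smaller k; nearest-promoter to the smaller
ordinal; calibration sweep to the first closest candidate in descending
score order. Degenerate inputs: windows without enhancers, promoters or any
relation block yield empty results; empty networks refuse calibration;
single-class label sets refuse AUROC.

## Known limitations

* The Laplacian anchoring of attractive constraints means the solver's
  penalty differs from the raw trace form by the non-negative ridge
  `trace(G^T D G)`; with the raw form the optimization problem itself is
  ill-posed (unbounded), so this is a modeling commitment, not a shortcut.
* Ensemble averaging of reconstructions gives scores, not probabilities;
  scores are comparable within a run, not across tissues.
* Windowing bounds detectable interactions at the window size (5 Mb);
  pairs never sharing a window are structurally unscorable.
* The identity of the original 17-block schema is reconstructed from the
  method's description; the block list is configurable precisely because
  this reconstruction is a documented choice.
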