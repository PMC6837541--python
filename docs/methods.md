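# Methods

## The selection model

`multimark` treats marker selection as a two-filter problem on a gene × cell
log-expression matrix with N genes and L cells.

**Filter 1 — discriminativeness.** A gene whose expression separates cell
subpopulations cannot be unimodal across a mixed population: it has an "on"
mode in the populations that express it and an "off" mode (often a dropout
mass at zero) elsewhere. Each gene's density is estimated with a Gaussian
kernel,

    f̂_h(g) = (1/(L·h)) · Σ_{j=1..L} φ((g − g_j) / h),

where g_j is the gene's expression in cell j and φ the standard normal pdf.
Every cell contributes, zeros included — the dropout mass at zero is part of
the on/off signal, not an artifact to be removed. The number of peaks T is
counted with an interval rule: a point c is a peak when f̂_h(c) ≥ f̂_h(g)
for all g in the 2h-wide interval [c − h, c + h]. Genes with T ≥ 2 pass.
This deliberately avoids mixture-model fits, which would require choosing a
number of components per gene.

**Filter 2 — paired expression.** Real markers participate in cell-type
expression programs, so they co-occur with markers of the same program and
exclude markers of other programs. The multimodal submatrix is binarized at
each gene's own mean (strictly above → 1), giving X ∈ {0,1}^(N_m × L). Two
integer count matrices follow:

    S = X·Xᵀ        S[i,j] = #cells with gene i on and gene j on
    M = (1−X)·Xᵀ    M[i,j] = #cells with gene i off and gene j on

S is symmetric; M is not, and the identity M[i,j] + S[i,j] = S[j,j] holds by
construction (each count partitions the cells expressing gene j). Each
matrix induces a directed graph: A→B requires at least n supporting cells
and B must be among A's k largest counts (threshold first, then top-k). A
gene is selected iff it is bi-directionally connected to another gene in the
co-occurrence graph (KNCON) or the mutual-exclusivity graph (KNMEN) — the
union of genes in at least one such reciprocal pair (CMEGP) is the marker
set. Reciprocity in KNMEN demands both M[A,B] and M[B,A] large, i.e.
genuine two-sided exclusivity, not mere absence of one gene.

## Parameters

| parameter | default | meaning |
|---|---|---|
| h | 0.3 (plate), 0.05 (droplet) | KDE bandwidth on the log2 scale; wider kernels suit the broader per-gene spread of full-transcript plate data. `bandwidth="silverman"` instead uses the per-gene rule h = (4σ⁵/3L)^(1/5) with σ the sample standard deviation (L−1 denominator). |
| k | 300 | neighbour-list size per gene in both graphs; caps how promiscuous a gene's pairing can be. |
| n | 30 | minimum supporting cells per edge; the evidence floor. Raising n can only remove edges, so the marker set shrinks monotonically in n at fixed k (a tested invariant). |
| size_factor_target, pseudocount | 10⁴, 1 | library-size normalisation target and log2 pseudocount for raw-count input. Matrices tagged `log` pass through untouched; double transformation is refused. The fixed bandwidth defaults only make sense on a compressed log-like scale, which is why the pipeline requires `scale="log"`. |

## Numerical choices

- **Grid.** f̂_h is evaluated on a uniform grid spanning the data ± 3h. The
  grid has at least 512 points and grows until the spacing is below h/4
  (capped at 8192 points), so the discrete window test faithfully tracks the
  continuous interval rule; `count_peaks` refuses grids with spacing ≥ h.
- **Plateaus.** On a grid, tied maxima are possible. Qualifying points
  within h of each other are necessarily equal (each lies in the other's
  window) and are chain-grouped into one plateau, counted once, leftmost
  point reported.
- **Degenerate genes.** Constant genes (σ = 0, bandwidth rule undefined) and
  genes with fewer than two distinct values are classified unimodal without
  running the KDE — they cannot separate subpopulations.
- **Binarization ties.** Values exactly at the gene mean map to 0 ("strictly
  above"); the strict rule is deterministic. Non-constant rows always
  binarize to a mix of 0s and 1s; constant rows are a hard error (they
  should have been removed by filter 1).
- **Tie-breaks at the k-th neighbour** go to the lower gene index, making
  marker lists reproducible byte-for-byte. All outputs are deterministic
  given inputs, flags and seed.
- **Exact integer algebra.** S is computed as a sparse integer product where
  the input is sparse; M as a literal (1−X)·Xᵀ product in float64 and cast
  back (exact for any realistic L), keeping the conservation identity an
  independent cross-check rather than the definition. Both are formed only
  over the multimodal submatrix, never over all N genes; sparse droplet
  matrices stay sparse through binarization and are densified one gene row
  at a time during density estimation.

## Evaluation design

Marker-set quality is scored by clustering cells on the gene-restricted
matrix (k-means or Ward agglomerative clustering; no PCA by default, so the
comparison is about gene selection, not embedding) and computing the
Hubert–Arabie adjusted Rand index against known labels. Comparisons always
use equal-size gene sets: the baselines (highest mean expression; highest
variance, or mean-binned standardized dispersion with 20 equal-frequency
bins, at least ~10 genes per bin) are cut to the selected-marker count. The
binned-dispersion ranking is a from-scratch implementation of the standard
highly-variable-gene idea, not a bit-for-bit reproduction of any external
tool's ranking — the comparison design, not a specific tool, is what is
reproduced.

## The synthetic generator

`simulate` draws log-scale values directly: cells are assigned to
populations by the configured fractions; each planted marker gene gets an
"on" population (round-robin, so markers of the same population co-occur
and markers of different populations are mutually exclusive — exercising
both graphs); on-cells draw Normal(base_mean + shift, sd), everything else
Normal(base_mean, sd), clipped at zero; each entry is then zeroed
independently with the dropout probability.

Reference conditions, fixed as the package's study design: 500 cells, 1000
genes, 2 equal populations, 40 markers (20 per population), shift 4,
sd 0.5, dropout 0.1. `base_mean = 1.0` is deliberately low: for background
genes the dropout mass at zero then merges with the baseline mode into a
single density peak — as it does for ubiquitously low-expressed genes in
real data — while marker on-cells sit 4 log2-units away and stay clearly
bimodal. A high baseline mean would instead make every background gene's
dropout spike a second mode, which is a property of real high-expression
genes the multimodality filter genuinely flags; the reference design keeps
the planted truth unambiguous.

What the generator does **not** emulate: count-scale negative-binomial
noise, depth variation between cells, correlated background programs,
doublets, batch effects, or more than a handful of populations. Passing
tests on it therefore show the pipeline implements its definitions
correctly and recovers planted structure; they do not certify performance
on any real dataset or platform.

## Problem sizes

The test suite and the acceptance script run the full pipeline on
1000-gene × 500-cell simulations (10 replicates) plus many small algebraic
oracle checks; the whole acceptance computation is a ~30-second run on one
CPU. These sizes were chosen as the smallest at which every pipeline stage
(both graph kinds, dropout, baseline comparisons) is exercised with
comfortable statistical margins.

## Known limitations

- Fixed bandwidth is a per-platform convention; data on an unusual scale
  (e.g. natural-log, or un-normalised TPM) needs a user-chosen h or the
  Silverman mode.
- The peak rule counts boundary plateaus: a strictly monotone density has
  one peak at its maximum. Genes whose density is monotone with a shoulder
  are counted unimodal.
- With fewer than two multimodal genes no pairs exist; the selector returns
  an empty set (with a warning) rather than falling back to a ranking.
- k and n interact with dataset size: with very few cells, n = 30 can be
  unsatisfiable and the `sweep` command exists precisely to explore the
  (k, n) response on the user's own data.
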