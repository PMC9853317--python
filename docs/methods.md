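# Methods

This note documents the models and procedures implemented in `scegrn`, the
assumptions behind them, the defaults that matter, and what the bundled
synthetic data does and does not establish.

## Model overview

The package assumes a single dynamic process (differentiation, activation,
remodeling) sampled by single-cell RNA and ATAC profiles, and reconstructs a
directed TF → gene network in which every regulatory claim is backed by three
independent observations along that process: the TF's motif accessibility
moves with its own expression, the target's expression moves with the
accessibility of a distal peak near it, and the TF's motif occurs in that
peak. Correlation along a shared pseudotime axis is the common currency; the
enhancer constraint supplies the mechanism.

## Cross-modality integration

**Gene activity.** For unpaired data, ATAC cells are summarized as gene
activity: the sum of peak counts overlapping the gene body extended
`upstream_bp` upstream of the TSS (strand-aware; 0-based half-open
coordinates throughout, minus-strand TSS = `end − 1`). Default
`upstream_bp = 100,000`: under an enhancer-based model the
trajectory-informative ATAC signal is largely distal, so the window is chosen
in the spirit of gene score models that aggregate peaks within ~100 kb of the
TSS. A peak overlapping two genes' windows counts for both.

**Co-embedding.** CCA over the shared gene space: the `n_features = 2000`
most variable shared genes on log-normalized RNA (counts per 10k, log1p),
both matrices feature-standardized, then the SVD of the cross-product
K = X<sub>rna</sub><sup>T</sup> X<sub>atac</sub>, computed through thin QR
factorizations of each side so no cells × cells matrix is formed and the
result is deterministic. Cell coordinates are singular vectors scaled by
singular values; the sign of each component is fixed so its
largest-magnitude cell coordinate is positive; rows are L2-normalized so
Euclidean distance is monotone in cosine distance. Batch correction is not
implemented; a pre-corrected embedding can be substituted upstream of
pairing.

**Pairing.** One-to-one minimum-total-cost assignment on co-embedding
distances, restricted to the union of each cell's `k_candidates = 10`
nearest cross-modality neighbors (non-candidates receive a prohibitive
cost). The assignment is always solved exactly. Up to 6,000 cells per side
the dense Hungarian-type solver is used: we found scipy's sparse exact
matcher can be pathologically slow precisely when the k-candidate graph
admits a perfect matching (minutes at 3,000 × 3,000 versus ~2 s dense), so
the sparse solver is reserved for problems too large to hold densely, with a
dense fallback when the candidate restriction is infeasible. Rectangular
problems match min(n<sub>RNA</sub>, n<sub>ATAC</sub>) cells and report the
unmatched surplus.

Paired protocols set `modality = PAIRED` and skip all of the above; the
trajectory then uses a deterministic PCA of log-normalized RNA. An externally
supplied pairing (config `integration.pairs_file`) follows the same paired
path, which makes "true pairs fed to the unpaired path" exactly reproduce
the paired-protocol result — a property the tests exploit.

## Supervised pseudotime and binning

The user orders cluster labels from root to terminal. Cells in cluster i are
projected onto the unit vector from centroid c<sub>i</sub> to c<sub>i+1</sub>
(the last cluster uses the incoming direction), min-max scaled to [0, 1]
within the cluster, offset by i − 1, rank-transformed over all member cells
and rescaled to [0, 100]. The rank transform makes the result robust to
uneven centroid spacing; the scheme is deterministic and order- and
rotation-invariant. One inherent artifact: min-max scaling ties the last cell
of each cluster with the first of the next, so rank correlation with an
underlying 1-D coordinate is 1 only up to those m − 1 boundary ties. A
single-cluster path falls back to the cluster's principal axis, oriented
toward user-designated terminal cells when given. This centroid-projection
scheme is intentionally simpler than iterative spline-refinement trajectory
tools: supervised contract in (ordered groups), monotone pseudotime out.

Matrices are summarized along the trajectory with `n_bins = 100` equal-width
bins (matching the 0–100 scale) and per-bin means; empty bins inherit the
nearest occupied bin's value; a moving average of `window = 5` bins
(truncated at the edges) smooths the profile. Every downstream correlation
is a Pearson correlation over these bins — an aggregation choice that makes
estimates stable and runs deterministic, in place of single-cell or metacell
correlation schemes. Correlations of constant profiles are undefined and
flagged NaN, never turned into edges.

## TF activity (motif deviations)

With X the peak × cell counts, t<sub>c</sub> column totals and
a<sub>p</sub> = Σ<sub>c</sub>X<sub>pc</sub> / Σ<sub>pc</sub>X<sub>pc</sub>
read fractions (Σ<sub>p</sub> a<sub>p</sub> = 1):

    O[k,c] = Σ_p M[p,k] X[p,c]          observed reads in motif peaks
    E[k,c] = t_c Σ_p M[p,k] a_p         expected under uniform read fractions
    Y[k,c] = (O − E) / E                raw deviation

Backgrounds: each peak is matched to its `n_neighbors = 50` nearest peaks in
the standardized 2-D space of (GC fraction, log1p mean accessibility); each
of `n_iterations = 50` background sets replaces every motif peak with one
sampled pool member (with replacement, seeded, bit-reproducible). The
z-score is (Y − mean<sub>b</sub> Y<sub>b</sub>) / sd<sub>b</sub> Y<sub>b</sub>
with the sample (n − 1) standard deviation. Numerical conventions: a TF with
no matched peaks or no reads in matched peaks is dropped with a logged
reason (not NaN-propagated); a background entry with zero expectation
contributes deviation 0; entries with zero background sd are NaN, counted,
and treated as 0 when binned. Raw deviations are invariant to uniform count
scaling (read-fraction formulation) and identically zero for a motif
matching all peaks.

## Selection, linking, assembly

- TF selection: Pearson r between a TF's binned activity z-profile and its
  coding gene's binned expression; default positive-only mode with
  `tf_cor_cutoff = 0.4` (a driver is both more expressed *and* more
  accessible); an absolute mode admits repressors.
- Variable genes: variance of the smoothed binned profile;
  exactly ceil(`top_fraction` × n_genes) genes, ties broken by gene id.
  Default 0.1.
- Peak-gene links: candidates within `max_distance = 250,000` bp of the TSS
  (distance = nearest peak edge, 0 if the peak covers the TSS — this makes
  the later "at least 2 kb" enhancer test conservative); kept at r ≥
  `link_cor_cutoff = 0.5`.
- Enhancers: links with distance ≥ `min_tss_distance = 2000` (the boundary
  value is kept).
- eGRN: edge k → g iff r<sub>kg</sub> ≥ `weight_cutoff = 0.4` (positive-only
  default; absolute mode for repressive edges), gene g has ≥ 1 enhancer
  link, and TF k's motif matches ≥ 1 linked enhancer peak. Weight =
  r<sub>kg</sub>. TF self-edges are permitted and flagged.
- Ranking: PageRank (damping 0.85) on |weight| with row-normalized
  transitions and uniform teleport for dangling nodes, iterated to L1 change
  < 1e-10 (sums to 1); betweenness on unweighted directed shortest paths —
  correlation weights have no path-length interpretation. Each TF also
  carries the bin-center pseudotime of its maximal smoothed activity (ties
  to the earliest bin; flat profiles flagged).

## Synthetic data: what it emulates, and what it does not

The simulator plants a full causal chain on one linear chromosome: true
pseudotime t ~ U(0, 100); four ordered quartile clusters; per-TF smooth
latent profiles (logistic ramps or Gaussian bumps); TF-gene expression
softplus(f<sub>k</sub>) + Gaussian rate noise; target genes
softplus(Σ<sub>k</sub> w<sub>kg</sub> f<sub>k</sub>) with weights only on
planted edges (drawn Bernoulli(`edge_density = 0.15`) per TF-gene pair);
decoy genes and decoy TFs flat; one promoter peak per gene covering the TSS
(flat, hence failing the 2 kb rule by construction) and
`enhancers_per_gene = 2` enhancer peaks at 2–100 kb whose accessibility rate
tracks the gene's expression; motif matches of TF k in the enhancers of g
iff k → g is planted, plus a 1% false-match rate over all peaks; GC ~
U(0.3, 0.7); Poisson counts (negative binomial optional) at ~5,000 expected
counts per cell and modality with lognormal per-cell depth factors. Genes
are spaced 500 kb apart so one gene's enhancers never enter a neighbor's
linking window — the planted peak → gene truth is unambiguous, which is what
makes recall and precision well defined. The unpaired view relabels the
same count draws into RNA/ATAC cell copies (ATAC columns shuffled), so
paired and unpaired analyses of one simulation are directly comparable.

**Mass balance.** Dynamic genes (and dynamic enhancer peaks) are rescaled so
their summed rate is identical in every cell. Without this, depth
normalization hands every flat feature a mirror image of the dynamic mass —
a compositional trend that binning and smoothing amplify into spurious
correlations — and "trajectory-independent decoy" would be false as stated.
The balance enforces the generator's contract that decoys are flat *after*
normalization. Real data are not mass-balanced; there, compositional trends
are small because dynamic programs are a tiny fraction of the transcriptome,
a regime a 420-gene simulation cannot reach.

**Study configuration.** Analyses of the synthetic study run at module
defaults with one exception: `linking.top_fraction = 0.5`, because half the
simulated genes are dynamic by design — a 10% cutoff, sensible on a
20,000-gene transcriptome, cannot contain the planted targets of a 420-gene
simulation. The cutoff is exactly the user-facing knob the method documents
for this purpose.

**Limitations.** The simulator does not emulate: doublets, batch effects,
ambient contamination, fragment-level ATAC structure, overlapping regulatory
domains, trans-chromosomal regulation, unmodeled covariates of motif
deviation (e.g. sequence composition beyond GC), or realistic gene/peak
densities. Passing tests therefore demonstrate correctness of the
implemented computations and recoverability of a planted signal under the
model's own assumptions — not performance on real tissue atlases. The
trajectory model assumes one non-branching process; cells outside the
ordered cluster path are excluded.

## Numerical and reproducibility notes

- All randomness flows from one root seed (simulation, background sampling);
  two runs with identical config and seed produce byte-identical artifacts.
- Assignment, SVD/QR and correlation computations are deterministic; CCA and
  PCA sign indeterminacy is fixed by the largest-magnitude-coordinate
  convention.
- Problem sizes used in the test suite and acceptance script (up to 3,000
  cells, 420 genes, ~1,500 peaks) were chosen so the full study, paired plus
  unpaired, completes in about a minute on one CPU while keeping ~300
  planted edges for stable recall/precision estimates.
- Degenerate inputs: empty eGRNs are returned with a warning (and written as
  header-only tables); genes with no overlapping peaks keep zero activity
  rows; groups absent from the cluster labels, malformed files, and unknown
  config keys raise immediately with positional messages.
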