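# scegrn

Enhancer-based gene regulatory network (eGRN) inference from single-cell
multiome data — paired or unpaired scRNA-seq + scATAC-seq profiles of a
dynamic process such as differentiation or disease-driven remodeling.

Many regulatory interactions act through distal enhancers rather than
promoters. `scegrn` reconstructs a directed, weighted TF → gene network in
which every edge is required to be *mediated by an enhancer*: the target gene
must have a distal accessible peak whose accessibility tracks its expression,
and the regulating TF's motif must sit in one of those peaks. The pipeline:

1. **Integration** (unpaired protocols): gene activity scores from ATAC,
   canonical correlation analysis (CCA) co-embedding of RNA and ATAC cells,
   and exact minimum-cost one-to-one cell pairing — building a
   pseudo-multimodal dataset. Paired protocols (e.g. 10x Multiome) skip this.
2. **Trajectory**: supervised pseudotime t ∈ [0, 100] over a user-ordered
   cluster path; all matrices are binned and smoothed along t.
3. **TF activity**: per-cell motif-deviation z-scores. With peak × cell
   counts X, per-cell totals t_c and read fractions a_p, the deviation of
   TF k is (O − E)/E with O<sub>kc</sub> = Σ<sub>p</sub> M<sub>pk</sub>X<sub>pc</sub>
   and E<sub>kc</sub> = t_c Σ<sub>p</sub> M<sub>pk</sub>a<sub>p</sub>,
   standardized against GC- and accessibility-matched background peak sets.
4. **Selection and linking**: candidate TFs are those whose activity and own
   expression correlate along the trajectory (r ≥ 0.4 by default — a factor
   that is both expressed and differentially accessible); candidate genes are
   the most variable along the trajectory (top 10% by default); peaks within
   250 kb of a gene's TSS are linked when accessibility–expression
   correlation r ≥ 0.5 over trajectory bins.
5. **eGRN assembly**: the quantitative network (TF-activity × gene-expression
   correlations) is intersected with the enhancer-mediated network — links at
   least 2 kb from the TSS, motif of the TF present in a linked enhancer.
   Edges are weighted by the correlation; regulators are ranked by PageRank
   and betweenness, and each TF is annotated with the pseudotime of its peak
   activity.

A bundled synthetic multiome simulator plants a known TF → gene network with
pseudotime-driven expression, tracking enhancer accessibility and motif
placements, so every stage can be validated against ground truth.

## Worked example

```python
from scegrn import SimConfig, simulate_multiome
from scegrn.config import PipelineConfig
from scegrn.pipeline import MultiomeData, run_pipeline

sim = simulate_multiome(SimConfig(n_cells=1000, n_tfs=5, n_decoy_tfs=5,
                                  n_target_genes=50, n_decoy_genes=50,
                                  n_decoy_peaks=60, seed=1))
cfg = PipelineConfig()
cfg.linking.top_fraction = 0.5   # half the simulated genes are dynamic
data = MultiomeData(sim.rna, sim.atac, sim.peaks, sim.genes, sim.motifs, sim.cells)
res = run_pipeline(cfg, data=data)

print(f"selected TFs : {res.selected_tfs}")
print(f"candidate genes: {len(res.selected_genes)}   peak-gene links: {len(res.links)}"
      f"   enhancer links: {len(res.enhancer_links)}")
print(f"eGRN edges   : {len(res.egrn.edges)}")
```

prints

```
selected TFs : ['TF00', 'TF01', 'TF02', 'TF03', 'TF04']
candidate genes: 55   peak-gene links: 93   enhancer links: 93
eGRN edges   : 36
```

All five planted driver TFs pass activity–expression selection and none of
the five flat decoy TFs do; the 36 recovered edges cover 97% of the planted
network at precision 1.0 on this instance (compare `res.egrn.edge_set` with
`sim.truth.edge_set`). `res.node_stats` holds per-node PageRank, betweenness
and TF peak-activity pseudotime for regulator ranking.

The same run from the shell, stage by stage or end to end:

```bash
scegrn run-all -c run.yaml -o out/     # or: simulate, integrate, trajectory,
                                       #     activity, link, grn
```

with a YAML config carrying every tunable (`integration.k_candidates`,
`trajectory.groups/n_bins/window`, `activity.n_iterations/n_neighbors/seed`,
`linking.*`, `grn.*`, `simulate.*`, one root `seed`). Outputs are plain
tables: `pairing.tsv`, `trajectory.tsv`, `activity_z.tsv`, `links.tsv`,
`egrn_edges.tsv`, `egrn.graphml`, plus a `MANIFEST.json` recording per-stage
parameters, input hashes and row counts.

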