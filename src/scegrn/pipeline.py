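"""End-to-end orchestration: simulate/load -> integrate -> trajectory ->
activity -> select/link -> GRN, with per-stage artifacts and a run manifest.

The pipeline operates on an in-memory :class:`MultiomeData` bundle (loaded
from a data directory of MTX/TSV/BED files, or produced by the synthetic
simulator) and optionally writes each stage's output table to an artifact
directory. When resuming, stages whose artifacts already exist are skipped
and their outputs reloaded. A MANIFEST.json records, per stage, the
parameters used, hashes of the file inputs, output row counts and status;
on failure the manifest marks the failed stage and partial artifacts are
retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from scegrn import grn as grn_mod
from scegrn import io, linking
from scegrn._stats import lognorm_cp10k
from scegrn.config import PipelineConfig
from scegrn.integration import (
    Embedding,
    Pairing,
    gene_activity_scores,
    joint_embedding,
    pair_cells,
    pca_embedding,
)
from scegrn.tf_activity import background_peaks, deviation_zscores
from scegrn.trajectory import BinnedMatrix, Trajectory, bin_smooth, supervised_pseudotime

logger = logging.getLogger(__name__)

STAGES = ["simulate", "integrate", "trajectory", "activity", "link", "grn"]


@dataclass
class MultiomeData:
    """The input bundle every stage consumes."""

    rna: io.CountMatrix
    atac: io.CountMatrix
    peaks: list[io.Peak]
    genes: list[io.GeneAnnotation]
    motifs: io.MotifMatches
    cells: pd.DataFrame

    @property
    def paired(self) -> bool:
        return set(self.cells["modality"]) == {"PAIRED"}


@dataclass
class PipelineResult:
    """Everything a run produces, for downstream inspection."""

    trajectory: Trajectory
    pairing: Pairing | None
    activity_tf_ids: list[str]
    expression_binned: BinnedMatrix
    activity_binned: BinnedMatrix
    atac_binned: BinnedMatrix
    tf_selections: list[linking.TFSelection]
    selected_tfs: list[str]
    selected_genes: list[str]
    links: list[linking.PeakGeneLink]
    enhancer_links: list[linking.PeakGeneLink]
    qgrn: grn_mod.QuantGRN
    egrn: grn_mod.EGRN
    node_stats: pd.DataFrame
    peak_times: dict[str, float]
    manifest: dict[str, Any]


def load_data(data_dir: str | Path) -> MultiomeData:
    """Load a full input bundle from the conventional file layout."""
    d = Path(data_dir)
    rna = io.read_count_matrix(
        d / "rna.mtx", d / "rna_features.tsv", d / "rna_barcodes.tsv"
    )
    atac = io.read_count_matrix(
        d / "atac.mtx", d / "atac_features.tsv", d / "atac_barcodes.tsv"
    )
    peaks = io.read_peaks_bed(d / "peaks.bed")
    genes = io.read_gene_annotations(d / "genes.tsv")
    motifs = io.read_motif_matches(d / "motifs.mtx", d / "motif_tfs.tsv")
    cells = io.read_cell_table(d / "cells.tsv")
    if len(peaks) != atac.shape[0]:
        raise io.FormatError(
            f"{d}: peaks.bed has {len(peaks)} peaks but atac.mtx has "
            f"{atac.shape[0]} rows"
        )
    return MultiomeData(rna, atac, peaks, genes, motifs, cells)


def _file_hashes(data_dir: str | Path) -> dict[str, str]:
    hashes = {}
    d = Path(data_dir)
    if not d.is_dir():
        return hashes
    for f in sorted(d.iterdir()):
        if f.is_file():
            hashes[f.name] = hashlib.md5(f.read_bytes()).hexdigest()
    return hashes


class _Manifest:
    def __init__(self, out_dir: Path | None, config: PipelineConfig):
        self.out_dir = out_dir
        self.data: dict[str, Any] = {"config": config.to_dict(), "stages": {}}

    def record(self, stage: str, status: str, **info: Any) -> None:
        self.data["stages"][stage] = {"status": status, **info}
        self.flush()

    def flush(self) -> None:
        if self.out_dir is not None:
            (self.out_dir / "MANIFEST.json").write_text(
                json.dumps(self.data, indent=2, default=str)
            )


def _paired_views(
    data: MultiomeData, pairing: Pairing | None
) -> tuple[io.CountMatrix, io.CountMatrix, pd.Series]:
    """RNA and ATAC matrices over the same (pseudo-)cells, plus cluster labels.

    In paired mode the matrices are aligned on shared cell ids. In unpaired
    mode each matched pair becomes one pseudo-cell named after its RNA member,
    carrying the RNA cell's counts, cluster label, and the ATAC partner's
    accessibility.
    """
    meta = data.cells.set_index("cell_id")
    if data.paired:
        shared = [c for c in data.rna.cell_ids if c in set(data.atac.cell_ids)]
        if not shared:
            raise ValueError("paired data share no cell ids between modalities")
        rna_p = data.rna.subset_cells(shared)
        atac_p = data.atac.subset_cells(shared)
        labels = meta.loc[shared, "cluster"]
        return rna_p, atac_p, labels
    if pairing is None:
        raise ValueError("unpaired data require a pairing")
    rna_ids = [r for r, _ in pairing.pairs]
    atac_ids = [a for _, a in pairing.pairs]
    rna_p = data.rna.subset_cells(rna_ids)
    atac_p = data.atac.subset_cells(atac_ids)
    atac_p = io.CountMatrix(atac_p.values, list(atac_p.feature_ids), rna_ids)
    labels = meta.loc[rna_ids, "cluster"]
    return rna_p, atac_p, labels


def run_pipeline(
    config: PipelineConfig,
    data: MultiomeData | None = None,
    out_dir: str | Path | None = None,
    resume: bool = False,
    stop_after: str | None = None,
) -> PipelineResult | None:
    """Run the pipeline (optionally only up to ``stop_after``).

    ``data`` may be passed in memory; otherwise it is loaded from
    ``config.io.data_dir``, or simulated when ``config.simulate.enabled``.
    With ``resume=True``, stages whose artifact files already exist in
    ``out_dir`` are skipped and reloaded. Returns ``None`` when stopping
    before the final stage.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config)
    stage = "setup"
    try:
        # ---------------------------------------------------------- inputs
        stage = "simulate"
        if data is None:
            if config.simulate.enabled:
                from scegrn.synthetic import simulate_multiome

                sim = simulate_multiome(config.sim_config())
                if config.simulate.unpaired:
                    sim = sim.as_unpaired()
                if out is not None:
                    sim_dir = out / "data"
                    sim.write(sim_dir)
                    manifest.record(
                        "simulate",
                        "ok",
                        params=config.to_dict()["simulate"],
                        outputs={"dir": str(sim_dir)},
                    )
                data = MultiomeData(
                    sim.rna, sim.atac, sim.peaks, sim.genes, sim.motifs, sim.cells
                )
            else:
                data = load_data(config.io.data_dir)
                manifest.record(
                    "simulate",
                    "skipped",
                    inputs=_file_hashes(config.io.data_dir),
                )
        if stop_after == "simulate":
            return None

        # ------------------------------------------------------- integrate
        stage = "integrate"
        icfg = config.integration
        pairing: Pairing | None = None
        emb_for_traj: Embedding
        if data.paired:
            rna_p, atac_p, labels = _paired_views(data, None)
            emb_for_traj = pca_embedding(rna_p, icfg.n_dims)
            manifest.record("integrate", "skipped (paired protocol)")
        else:
            pairing_path = out / "pairing.tsv" if out is not None else None
            emb_path = out / "embedding_rna.tsv" if out is not None else None
            if (
                resume
                and pairing_path is not None
                and pairing_path.exists()
                and emb_path is not None
                and emb_path.exists()
            ):
                frame = pd.read_csv(pairing_path, sep="\t")
                pairing = Pairing(
                    pairs=list(zip(frame["rna_cell"], frame["atac_cell"])),
                    costs=frame["cost"].to_numpy(),
                    total_cost=float(frame["cost"].sum()),
                )
                emb_frame = pd.read_csv(emb_path, sep="\t", index_col=0)
                emb_rna = Embedding(
                    emb_frame.to_numpy(), emb_frame.index.tolist(), "RNA"
                )
                emb_for_traj = emb_rna
                manifest.record("integrate", "resumed", outputs={"pairs": len(pairing.pairs)})
            elif icfg.pairs_file:
                # externally supplied pairing (e.g. ground truth): no
                # co-embedding needed, downstream mirrors the paired protocol
                frame = pd.read_csv(icfg.pairs_file, sep="\t")
                pairing = Pairing(
                    pairs=list(zip(frame["rna_cell"], frame["atac_cell"])),
                    costs=np.zeros(len(frame)),
                    total_cost=0.0,
                )
                rna_pf = data.rna.subset_cells([r for r, _ in pairing.pairs])
                emb_for_traj = pca_embedding(rna_pf, icfg.n_dims)
                manifest.record(
                    "integrate", "ok", params={"pairs_file": icfg.pairs_file},
                    outputs={"pairs": len(pairing.pairs)},
                )
            else:
                activity = gene_activity_scores(
                    data.atac, data.peaks, data.genes, icfg.upstream_bp
                )
                emb_rna, emb_atac = joint_embedding(
                    data.rna, activity, icfg.n_dims, icfg.n_features
                )
                pairing = pair_cells(emb_rna, emb_atac, icfg.k_candidates)
                if pairing_path is not None:
                    pd.DataFrame(
                        {
                            "rna_cell": [r for r, _ in pairing.pairs],
                            "atac_cell": [a for _, a in pairing.pairs],
                            "cost": pairing.costs,
                        }
                    ).to_csv(pairing_path, sep="\t", index=False)
                if emb_path is not None:
                    pd.DataFrame(emb_rna.coords, index=emb_rna.cell_ids).to_csv(
                        emb_path, sep="\t"
                    )
                emb_index = {c: i for i, c in enumerate(emb_rna.cell_ids)}
                rows = [emb_index[r] for r, _ in pairing.pairs]
                emb_for_traj = Embedding(
                    emb_rna.coords[rows], [r for r, _ in pairing.pairs], "RNA"
                )
                manifest.record(
                    "integrate",
                    "ok",
                    params={"k_candidates": icfg.k_candidates, "n_dims": icfg.n_dims},
                    outputs={"pairs": len(pairing.pairs)},
                )
            rna_p, atac_p, labels = _paired_views(data, pairing)
            emb_index = {c: i for i, c in enumerate(emb_for_traj.cell_ids)}
            rows = [emb_index[c] for c in rna_p.cell_ids]
            emb_for_traj = Embedding(emb_for_traj.coords[rows], list(rna_p.cell_ids), "RNA")
        if stop_after == "integrate":
            return None

        # ------------------------------------------------------ trajectory
        stage = "trajectory"
        tcfg = config.trajectory
        groups = tcfg.groups or sorted(set(labels))
        traj_path = out / "trajectory.tsv" if out is not None else None
        if resume and traj_path is not None and traj_path.exists():
            traj = Trajectory.from_frame(pd.read_csv(traj_path, sep="\t"), groups)
            manifest.record("trajectory", "resumed", outputs={"cells": len(traj.cell_ids)})
        else:
            traj = supervised_pseudotime(
                emb_for_traj.coords, emb_for_traj.cell_ids, labels.to_numpy(), groups
            )
            if traj_path is not None:
                traj.to_frame().to_csv(traj_path, sep="\t", index=False)
            manifest.record(
                "trajectory",
                "ok",
                params={"groups": groups, "n_bins": tcfg.n_bins, "window": tcfg.window},
                outputs={"cells": len(traj.cell_ids)},
            )
        rna_t = rna_p.subset_cells(traj.cell_ids)
        atac_t = atac_p.subset_cells(traj.cell_ids)
        if stop_after == "trajectory":
            return None

        # -------------------------------------------------------- activity
        stage = "activity"
        acfg = config.activity
        mean_acc = np.asarray(atac_t.values.mean(axis=1)).ravel()
        bg = background_peaks(
            data.peaks, mean_acc, acfg.n_neighbors, acfg.n_iterations, acfg.seed
        )
        act = deviation_zscores(atac_t, data.motifs, bg)
        z = np.nan_to_num(act.z, nan=0.0)  # unstable entries contribute nothing
        if out is not None:
            pd.DataFrame(z, index=act.tf_ids, columns=traj.cell_ids).to_csv(
                out / "activity_z.tsv", sep="\t"
            )
        manifest.record(
            "activity",
            "ok",
            params={"n_iterations": acfg.n_iterations, "n_neighbors": acfg.n_neighbors},
            outputs={"tfs": len(act.tf_ids), "dropped": act.dropped},
        )
        if stop_after == "activity":
            return None

        # ------------------------------------------------------------ link
        stage = "link"
        lcfg = config.linking
        expr_binned = bin_smooth(
            lognorm_cp10k(rna_t.values), rna_t.feature_ids, traj, tcfg.n_bins, tcfg.window
        )
        act_binned = bin_smooth(z, act.tf_ids, traj, tcfg.n_bins, tcfg.window)
        atac_binned = bin_smooth(
            lognorm_cp10k(atac_t.values), atac_t.feature_ids, traj, tcfg.n_bins, tcfg.window
        )
        tf_selections = linking.select_tfs(
            act_binned, expr_binned, data.motifs, lcfg.tf_cor_cutoff, lcfg.tf_cor_mode
        )
        selected_tfs = [s.tf_id for s in tf_selections if s.selected]
        selected_genes = linking.select_variable_genes(expr_binned, lcfg.top_fraction)
        links = linking.peak_gene_links(
            atac_binned,
            expr_binned,
            data.peaks,
            data.genes,
            gene_ids=selected_genes,
            max_distance=lcfg.max_distance,
            cor_cutoff=lcfg.link_cor_cutoff,
        )
        if out is not None:
            pd.DataFrame(
                [(s.tf_id, s.correlation, s.selected) for s in tf_selections],
                columns=["tf_id", "correlation", "selected"],
            ).to_csv(out / "tf_selection.tsv", sep="\t", index=False)
            pd.Series(selected_genes, name="gene_id").to_csv(
                out / "variable_genes.tsv", sep="\t", index=False
            )
            linking.links_to_frame(links, data.peaks).to_csv(
                out / "links.tsv", sep="\t", index=False
            )
        manifest.record(
            "link",
            "ok",
            params={
                "tf_cor_cutoff": lcfg.tf_cor_cutoff,
                "link_cor_cutoff": lcfg.link_cor_cutoff,
                "max_distance": lcfg.max_distance,
                "top_fraction": lcfg.top_fraction,
            },
            outputs={
                "selected_tfs": len(selected_tfs),
                "selected_genes": len(selected_genes),
                "links": len(links),
            },
        )
        if stop_after == "link":
            return None

        # ------------------------------------------------------------- grn
        stage = "grn"
        gcfg = config.grn
        if not selected_tfs:
            raise ValueError("no TFs passed selection; nothing to assemble")
        qgrn = grn_mod.quantitative_grn(act_binned, expr_binned, selected_tfs, selected_genes)
        enh = grn_mod.enhancer_links(links, gcfg.min_tss_distance)
        egrn = grn_mod.assemble_egrn(qgrn, enh, data.motifs, gcfg.weight_cutoff, gcfg.weight_mode)
        stats = grn_mod.network_statistics(egrn, gcfg.damping)
        peak_times, _flat = grn_mod.tf_peak_time(act_binned)
        node_stats = grn_mod.annotate_nodes(egrn, stats, peak_times)
        if out is not None:
            io.write_grn(egrn.edges, node_stats, out / "egrn_edges.tsv", out / "egrn.graphml")
        manifest.record(
            "grn",
            "ok",
            params={
                "weight_cutoff": gcfg.weight_cutoff,
                "min_tss_distance": gcfg.min_tss_distance,
                "damping": gcfg.damping,
            },
            outputs={"edges": len(egrn.edges), "enhancer_links": len(enh)},
        )
    except Exception as exc:
        manifest.record(stage, "failed", error=str(exc))
        raise

    return PipelineResult(
        trajectory=traj,
        pairing=pairing,
        activity_tf_ids=act.tf_ids,
        expression_binned=expr_binned,
        activity_binned=act_binned,
        atac_binned=atac_binned,
        tf_selections=tf_selections,
        selected_tfs=selected_tfs,
        selected_genes=selected_genes,
        links=links,
        enhancer_links=enh,
        qgrn=qgrn,
        egrn=egrn,
        node_stats=node_stats,
        peak_times=peak_times,
        manifest=manifest.data,
    )
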