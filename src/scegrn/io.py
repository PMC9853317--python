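"""Domain types and readers/writers for the on-disk formats the pipeline touches.

All genomic coordinates are 0-based, half-open (BED-native): a peak
``[start, end)`` covers bases ``start .. end-1``. The transcription start
site of a minus-strand gene annotated by a half-open interval
``[start, end)`` is ``end - 1`` (the last covered base). Every distance
computation in the package goes through :func:`tss_distance` so the
convention is applied in exactly one place.

Sparse count matrices travel as MatrixMarket coordinate files with TSV
sidecars for feature and barcode names (10x-style triplet layout).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-"}
# unicode minus occasionally shows up in hand-edited annotation tables
_STRAND_ALIASES = {"+": "+", "-": "-", "−": "-"}


class FormatError(ValueError):
    """Malformed on-disk input (wrong dimensions, bad record, etc.)."""


class ValidationError(ValueError):
    """Input parsed but violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peak:
    """An ATAC peak on the 0-based half-open interval [start, end).

    ``gc_fraction`` is the GC content of the underlying sequence, used as a
    covariate when sampling background peaks for TF-activity bias correction;
    it may be NaN when unknown.
    """

    chrom: str
    start: int
    end: int
    gc_fraction: float = float("nan")

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"peak {self.chrom}:{self.start}-{self.end} is empty or negative"
            )
        if not np.isnan(self.gc_fraction) and not 0.0 <= self.gc_fraction <= 1.0:
            raise ValidationError(
                f"gc_fraction {self.gc_fraction} outside [0, 1] for "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its strand-resolved TSS (and, optionally, its body).

    The annotation stores the resolved TSS rather than raw gene bounds:
    ``tss = start`` on the plus strand and ``tss = end - 1`` on the minus
    strand under the half-open convention. ``start``/``end`` delimit the gene
    body when known and are used to widen the gene-activity window.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValidationError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id}: negative TSS {self.tss}")
        if (self.start is None) != (self.end is None):
            raise ValidationError(
                f"gene {self.gene_id}: start/end must be given together"
            )
        if self.start is not None and self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: empty body [{self.start}, {self.end})"
            )


@dataclass
class CountMatrix:
    """Sparse non-negative integer feature x cell matrix (genes or peaks)."""

    values: sp.csr_matrix
    feature_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        n_feat, n_cell = self.values.shape
        if n_feat != len(self.feature_ids):
            raise ValidationError(
                f"matrix has {n_feat} rows but {len(self.feature_ids)} feature ids"
            )
        if n_cell != len(self.cell_ids):
            raise ValidationError(
                f"matrix has {n_cell} columns but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("feature ids are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell ids are not unique")
        data = self.values.data
        if data.size:
            if data.min() < 0:
                raise ValidationError("count matrix contains negative entries")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("count matrix contains non-integer entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, ids: Sequence[str]) -> "CountMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[i] for i in ids]
        return CountMatrix(self.values[rows, :], list(ids), list(self.cell_ids))

    def subset_cells(self, ids: Sequence[str]) -> "CountMatrix":
        index = {c: i for i, c in enumerate(self.cell_ids)}
        cols = [index[i] for i in ids]
        return CountMatrix(self.values[:, cols], list(self.feature_ids), list(ids))


@dataclass
class MotifMatches:
    """Binary peak x TF motif-match indicator with a TF -> coding-gene map.

    ``tf_to_gene`` maps each motif/TF identifier to the gene symbol whose
    expression represents the TF; TFs whose gene is absent from the
    expression matrix are skipped downstream with a logged reason.
    """

    indicator: sp.csc_matrix
    tf_ids: list[str]
    tf_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        self.indicator = sp.csc_matrix(self.indicator)
        if self.indicator.shape[1] != len(self.tf_ids):
            raise ValidationError(
                f"motif matrix has {self.indicator.shape[1]} columns but "
                f"{len(self.tf_ids)} TF ids"
            )
        if len(set(self.tf_ids)) != len(self.tf_ids):
            raise ValidationError("TF ids are not unique")
        data = self.indicator.data
        if data.size and not np.isin(data, (0, 1)).all():
            raise ValidationError("motif matrix entries must be 0/1")
        missing = [t for t in self.tf_ids if t not in self.tf_to_gene]
        if missing:
            raise ValidationError(f"TFs without a gene mapping: {missing[:5]}")

    @property
    def n_peaks(self) -> int:
        return self.indicator.shape[0]


@dataclass(frozen=True)
class EdgeRecord:
    """One directed TF -> gene edge, weighted by activity-expression correlation."""

    tf: str
    gene: str
    weight: float
    self_edge: bool = False

    def __post_init__(self) -> None:
        if abs(self.weight) > 1 + 1e-12:
            raise ValidationError(
                f"edge {self.tf}->{self.gene}: |weight| {self.weight} > 1"
            )


# ---------------------------------------------------------------------------
# coordinate helper (single source of truth for the distance convention)
# ---------------------------------------------------------------------------


def tss_distance(peak_start: int, peak_end: int, tss: int) -> int:
    """Minimum distance in bp from any base of [peak_start, peak_end) to the TSS.

    Returns 0 when the peak covers the TSS. Both inputs follow the 0-based
    half-open convention used throughout the package.
    """
    if peak_start <= tss < peak_end:
        return 0
    if tss < peak_start:
        return peak_start - tss
    return tss - (peak_end - 1)


# ---------------------------------------------------------------------------
# count matrices (MatrixMarket + TSV sidecars)
# ---------------------------------------------------------------------------


def _read_id_column(path: str | Path) -> list[str]:
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_count_matrix(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> CountMatrix:
    """Read a features x cells sparse count matrix from MTX + TSV sidecars."""
    try:
        mat = spio.mmread(str(mtx_path))
    except Exception as exc:  # noqa: BLE001 - rewrap with the file name
        raise FormatError(f"{mtx_path}: not a readable MatrixMarket file ({exc})")
    mat = sp.csr_matrix(mat)
    features = _read_id_column(features_path)
    barcodes = _read_id_column(barcodes_path)
    if mat.shape[0] != len(features):
        raise FormatError(
            f"{features_path}: {len(features)} features but matrix "
            f"{mtx_path} declares {mat.shape[0]} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix "
            f"{mtx_path} declares {mat.shape[1]} columns"
        )
    return CountMatrix(mat, features, barcodes)


def write_count_matrix(
    matrix: CountMatrix,
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write a CountMatrix as integer MatrixMarket coordinate + TSV sidecars."""
    coo = matrix.values.tocoo()
    coo.data = np.round(coo.data).astype(np.int64)
    spio.mmwrite(str(mtx_path), coo, field="integer")
    Path(features_path).write_text("".join(f"{f}\n" for f in matrix.feature_ids))
    Path(barcodes_path).write_text("".join(f"{c}\n" for c in matrix.cell_ids))


# ---------------------------------------------------------------------------
# peaks (BED3 / BED4 with gc_fraction in column 4)
# ---------------------------------------------------------------------------


def read_peaks_bed(path: str | Path) -> list[Peak]:
    """Read peaks from a BED3+ file; optional column 4 carries gc_fraction."""
    peaks: list[Peak] = []
    seen: set[tuple[str, int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: empty interval {chrom}:{start}-{end}"
                )
            gc = float("nan")
            if len(fields) >= 4 and fields[3] not in ("", "."):
                try:
                    gc = float(fields[3])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: column 4 is not numeric")
            key = (chrom, start, end)
            if key in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate peak {chrom}:{start}-{end}"
                )
            seen.add(key)
            peaks.append(Peak(chrom, start, end, gc))
    return peaks


def write_peaks_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            gc = "." if np.isnan(p.gc_fraction) else f"{p.gc_fraction:.6g}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{gc}\n")


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene annotation TSV.

    Requires columns ``gene_id``, ``chrom``, ``strand`` and either a
    pre-resolved ``tss`` column or ``start``/``end`` from which the TSS is
    resolved strand-aware (``start`` on +, ``end - 1`` on -).
    """
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "strand"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    has_tss = "tss" in table.columns
    has_bounds = {"start", "end"} <= set(table.columns)
    if not has_tss and not has_bounds:
        raise FormatError(f"{path}: need either a tss column or start/end columns")
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for row_no, row in enumerate(table.itertuples(index=False), start=2):
        strand = _STRAND_ALIASES.get(str(row.strand))
        if strand is None:
            raise ValidationError(
                f"{path}:{row_no}: unknown strand symbol {row.strand!r}"
            )
        start = int(row.start) if has_bounds and pd.notna(row.start) else None
        end = int(row.end) if has_bounds and pd.notna(row.end) else None
        if has_tss and pd.notna(row.tss):
            tss = int(row.tss)
        elif start is not None and end is not None:
            tss = start if strand == "+" else end - 1
        else:
            raise FormatError(f"{path}:{row_no}: no TSS and no usable start/end")
        if row.gene_id in seen:
            raise ValidationError(f"{path}:{row_no}: duplicate gene_id {row.gene_id}")
        seen.add(row.gene_id)
        genes.append(GeneAnnotation(row.gene_id, row.chrom, strand, tss, start, end))
    return genes


def write_gene_annotations(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "tss": g.tss,
            "start": g.start if g.start is not None else "",
            "end": g.end if g.end is not None else "",
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# motif matches and cell metadata
# ---------------------------------------------------------------------------


def read_motif_matches(mtx_path: str | Path, tf_table_path: str | Path) -> MotifMatches:
    """Read a binary peak x TF motif-match MTX and a (tf_id, gene_id) TSV."""
    try:
        mat = sp.csc_matrix(spio.mmread(str(mtx_path)))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{mtx_path}: not a readable MatrixMarket file ({exc})")
    table = pd.read_csv(tf_table_path, sep="\t", dtype=str)
    if not {"tf_id", "gene_id"} <= set(table.columns):
        raise FormatError(f"{tf_table_path}: need columns tf_id, gene_id")
    tf_ids = table["tf_id"].tolist()
    if mat.shape[1] != len(tf_ids):
        raise FormatError(
            f"{tf_table_path}: {len(tf_ids)} TFs but matrix {mtx_path} "
            f"declares {mat.shape[1]} columns"
        )
    return MotifMatches(mat, tf_ids, dict(zip(tf_ids, table["gene_id"])))


def write_motif_matches(
    motifs: MotifMatches, mtx_path: str | Path, tf_table_path: str | Path
) -> None:
    coo = motifs.indicator.tocoo()
    coo.data = np.round(coo.data).astype(np.int64)
    spio.mmwrite(str(mtx_path), coo, field="integer")
    pd.DataFrame(
        {"tf_id": motifs.tf_ids, "gene_id": [motifs.tf_to_gene[t] for t in motifs.tf_ids]}
    ).to_csv(tf_table_path, sep="\t", index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read cell metadata: columns cell_id, modality, cluster[, batch]."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_id", "modality", "cluster"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = set(table["modality"]) - {"RNA", "ATAC", "PAIRED"}
    if bad:
        raise ValidationError(f"{path}: unknown modality values {sorted(bad)}")
    dup = table.duplicated(subset=["cell_id", "modality"])
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate cell_id within a modality "
            f"({table.loc[dup, 'cell_id'].iloc[0]})"
        )
    return table


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------


def write_grn(
    edges: Sequence[EdgeRecord],
    node_stats: pd.DataFrame | None,
    edgelist_path: str | Path | None = None,
    graphml_path: str | Path | None = None,
) -> None:
    """Export an eGRN as edge-list TSV and/or GraphML.

    ``node_stats`` is indexed by node id with columns ``pagerank``,
    ``betweenness`` and ``peak_time`` (NaN for target-gene nodes, which have
    no TF activity profile). An empty graph writes headers only.
    """
    if not edges:
        warnings.warn("writing an empty eGRN (headers only)", stacklevel=2)
    frame = pd.DataFrame(
        [(e.tf, e.gene, e.weight, e.self_edge) for e in edges],
        columns=["tf", "gene", "weight", "self_edge"],
    )
    if edgelist_path is not None:
        out = frame
        if node_stats is not None and not frame.empty:
            out = frame.merge(
                node_stats.add_prefix("tf_"), left_on="tf", right_index=True, how="left"
            )
        out.to_csv(edgelist_path, sep="\t", index=False)
    if graphml_path is not None:
        graph = nx.DiGraph()
        if node_stats is not None:
            for node, row in node_stats.iterrows():
                graph.add_node(
                    str(node),
                    pagerank=float(row.get("pagerank", np.nan)),
                    betweenness=float(row.get("betweenness", np.nan)),
                    peak_time=float(row.get("peak_time", np.nan)),
                )
        for e in edges:
            graph.add_edge(e.tf, e.gene, weight=float(e.weight))
        nx.write_graphml(graph, str(graphml_path))


def read_grn_graphml(path: str | Path) -> nx.DiGraph:
    return nx.read_graphml(str(path))
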