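"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from scegrn.config import PipelineConfig
from scegrn.pipeline import MultiomeData, run_pipeline
from scegrn.synthetic import SimConfig, simulate_multiome

# ---------------------------------------------------------------------------
# independent oracle: naive triple-loop motif-deviation z-scores
# ---------------------------------------------------------------------------


def brute_deviation_zscores(
    x: np.ndarray, m: np.ndarray, bg: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Dense, loop-based reference for the motif-deviation computation.

    ``x``: peaks x cells counts; ``m``: peaks x TFs 0/1; ``bg``: peaks x
    iterations background indices. Returns (raw deviations, z-scores) with
    NaN z where the background sd is zero. Assumes every TF has >= 1 matched
    peak with reads (no drop logic).
    """
    n_peaks, n_cells = x.shape
    n_tfs = m.shape[1]
    n_iter = bg.shape[1]
    t = x.sum(axis=0)
    a = x.sum(axis=1) / x.sum()

    def dev_for(peak_lists: list[list[int]]) -> np.ndarray:
        out = np.zeros((n_tfs, n_cells))
        for k in range(n_tfs):
            for c in range(n_cells):
                obs = sum(x[p, c] for p in peak_lists[k])
                exp = t[c] * sum(a[p] for p in peak_lists[k])
                out[k, c] = (obs - exp) / exp if exp > 0 else 0.0
        return out

    fg = [[p for p in range(n_peaks) if m[p, k]] for k in range(n_tfs)]
    raw = dev_for(fg)
    bg_devs = np.zeros((n_iter, n_tfs, n_cells))
    for b in range(n_iter):
        sets = [[int(bg[p, b]) for p in range(n_peaks) if m[p, k]] for k in range(n_tfs)]
        bg_devs[b] = dev_for(sets)
    mean = bg_devs.mean(axis=0)
    sd = bg_devs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (raw - mean) / sd
    z[sd == 0] = np.nan
    return raw, z


def brute_betweenness(edges: list[tuple[str, str]], nodes: list[str]) -> dict[str, float]:
    """Betweenness by exhaustive shortest-path counting on a directed graph."""
    adj: dict[str, list[str]] = {n: [] for n in nodes}
    for u, v in edges:
        if v not in adj[u]:
            adj[u].append(v)
    inf = float("inf")
    dist: dict[str, dict[str, float]] = {}
    sigma: dict[str, dict[str, float]] = {}
    for s in nodes:  # BFS per source: distances and path counts
        d = {n: inf for n in nodes}
        c = {n: 0.0 for n in nodes}
        d[s], c[s] = 0, 1.0
        frontier = [s]
        while frontier:
            nxt: list[str] = []
            for u in frontier:
                for v in adj[u]:
                    if d[v] == inf:
                        d[v] = d[u] + 1
                        nxt.append(v)
                    if d[v] == d[u] + 1:
                        c[v] += c[u]
            frontier = nxt
        dist[s], sigma[s] = d, c
    bt = {n: 0.0 for n in nodes}
    for s in nodes:
        for t in nodes:
            if s == t or dist[s][t] == inf:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                if dist[s][v] + dist[v][t] == dist[s][t]:
                    bt[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    return bt


def study_pipeline_config() -> PipelineConfig:
    """Analysis configuration for the bundled synthetic study.

    Module defaults throughout, except the variable-gene fraction: half the
    simulated genes are trajectory-dynamic by design, so the candidate-gene
    pool is set to the top 50% (the cutoff the method exposes to users).
    """
    cfg = PipelineConfig()
    cfg.linking.top_fraction = 0.5
    return cfg


def as_data(sim) -> MultiomeData:
    return MultiomeData(sim.rna, sim.atac, sim.peaks, sim.genes, sim.motifs, sim.cells)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_sim():
    """A 600-cell simulation small enough for per-module tests."""
    return simulate_multiome(
        SimConfig(
            n_cells=600,
            n_tfs=5,
            n_decoy_tfs=5,
            n_target_genes=50,
            n_decoy_genes=50,
            n_decoy_peaks=60,
            seed=1,
        )
    )


@pytest.fixture(scope="session")
def small_run(small_sim):
    """Paired-mode pipeline result on the small simulation."""
    return run_pipeline(study_pipeline_config(), data=as_data(small_sim))
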