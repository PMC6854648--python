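"""Tumour-vs-normal differential expression of circRNA junction counts.

The abundance measure is the junction read count (reads spanning the
back-splice), normalized to junction reads per million linearly mapped
reads (JRPM). Fold change is the ratio of group means with a pseudocount
of 1 on the normalized scale; significance comes from a paired two-sided
t-test on log2(JRPM + 1) across tumour/normal pairs. The screening filter
is |FC| ≥ 2 (inclusive) with P < 0.05 (strict), with no multiple-testing
correction by default to mirror the raw-p screening convention; a
Benjamini–Hochberg option is available. Heatmap row ordering uses
hierarchical clustering under the 1 − Pearson-r distance with average
linkage.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

PSEUDOCOUNT = 1.0


@dataclass
class CircCountMatrix:
    """Junction read counts per circRNA (rows) per library (columns)."""

    counts: pd.DataFrame                 # int counts, circ ids × lib ids
    meta: pd.DataFrame                   # per-library: condition, pair_id
    library_size: pd.Series              # linearly mapped read totals

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = [c for c in self.counts.columns if c not in self.meta.index]
        if missing:
            raise ValueError(f"libraries without metadata: {missing}")

    def paired_columns(self) -> list[tuple[str, str]]:
        """(tumour, normal) library ids per pair, ordered by pair id."""
        pairs = []
        for pid, grp in self.meta.groupby("pair_id"):
            tum = grp.index[grp.condition == "tumour"]
            nor = grp.index[grp.condition == "normal"]
            if len(tum) != 1 or len(nor) != 1:
                raise ValueError(f"pair {pid} is not a (tumour, normal) pair")
            pairs.append((tum[0], nor[0]))
        return pairs


@dataclass
class DiffExpResult:
    circ_id: str
    mean_tumour: float                   # mean normalized tumour abundance
    mean_normal: float
    log2fc: float
    p_value: float
    direction: str                       # "up" | "down" | "ns"


def build_count_matrix(
    per_library: dict[str, dict[tuple, int]],
    meta: pd.DataFrame,
    library_size: dict[str, int],
) -> CircCountMatrix:
    """Assemble the count matrix from per-library candidate counts.

    ``per_library`` maps library id → {circ key → junction read count}.
    The row set is the union of keys; a circ absent from a library is 0.
    Row and column order are deterministic (sorted keys, metadata order).
    """
    lib_ids = list(per_library)
    if len(set(lib_ids)) != len(lib_ids):
        raise ValueError("duplicate library id")
    all_keys = sorted({k for d in per_library.values() for k in d})
    ids = [f"{c}:{s}-{e}|{st}" for c, s, e, st in all_keys]
    data = {lib: [per_library[lib].get(k, 0) for k in all_keys] for lib in lib_ids}
    counts = pd.DataFrame(data, index=ids, columns=list(meta.index))
    counts = counts.fillna(0).astype(int)
    return CircCountMatrix(counts, meta, pd.Series(library_size))


def normalize_counts(matrix: CircCountMatrix) -> pd.DataFrame:
    """Junction reads per million mapped reads (JRPM)."""
    sizes = matrix.library_size.reindex(matrix.counts.columns)
    if (sizes <= 0).any():
        bad = sizes.index[sizes <= 0].tolist()
        raise ValueError(f"zero/negative library size for {bad}")
    return matrix.counts / sizes * 1e6


def _paired_t_pvalue(tum: np.ndarray, nor: np.ndarray) -> float:
    """Two-sided paired t-test on log2(x + 1); degenerate limits handled:
    all-zero differences → p = 1, constant nonzero differences → p = 0."""
    d = np.log2(tum + PSEUDOCOUNT) - np.log2(nor + PSEUDOCOUNT)
    if np.allclose(d.std(ddof=1), 0.0):
        return 1.0 if np.allclose(d.mean(), 0.0) else 0.0
    return float(stats.ttest_rel(np.log2(tum + PSEUDOCOUNT),
                                 np.log2(nor + PSEUDOCOUNT)).pvalue)


def differential_test(
    normalized: pd.DataFrame,
    matrix: CircCountMatrix,
    fc: float = 2.0,
    p: float = 0.05,
    bh_correct: bool = False,
) -> list[DiffExpResult]:
    """Per-circRNA paired test with fold-change direction calls."""
    pairs = matrix.paired_columns()
    if len(pairs) < 2:
        raise ValueError(f"paired t-test undefined for {len(pairs)} pair(s); "
                         "need at least 2")
    tum_cols = [t for t, _ in pairs]
    nor_cols = [n for _, n in pairs]
    results = []
    pvals = []
    for circ_id, row in normalized.iterrows():
        tum = row[tum_cols].to_numpy(dtype=float)
        nor = row[nor_cols].to_numpy(dtype=float)
        pvals.append(_paired_t_pvalue(tum, nor))
        results.append((circ_id, tum.mean(), nor.mean()))
    pvals = np.asarray(pvals)
    if bh_correct and len(pvals):
        from statsmodels.stats.multitest import multipletests
        pvals = multipletests(pvals, method="fdr_bh")[1]
    out = []
    for (circ_id, mt, mn), pv in zip(results, pvals):
        ratio = (mt + PSEUDOCOUNT) / (mn + PSEUDOCOUNT)
        log2fc = float(np.log2(ratio))
        if ratio >= fc and pv < p:
            direction = "up"
        elif ratio <= 1.0 / fc and pv < p:
            direction = "down"
        else:
            direction = "ns"
        out.append(DiffExpResult(circ_id, float(mt), float(mn), log2fc,
                                 float(pv), direction))
    return out


def filter_de(results: list[DiffExpResult]) -> tuple[list[DiffExpResult],
                                                     list[DiffExpResult]]:
    """Partition results into (upregulated, downregulated) lists."""
    up = [r for r in results if r.direction == "up"]
    down = [r for r in results if r.direction == "down"]
    return up, down


def _pearson_distance(normalized: pd.DataFrame) -> np.ndarray:
    """Condensed 1 − Pearson-r distance; constant rows get r = 0 against
    everything (distance 1)."""
    x = normalized.to_numpy(dtype=float)
    n = x.shape[0]
    sd = x.std(axis=1)
    centred = x - x.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.outer(sd, sd) * x.shape[1]
        corr = centred @ centred.T / np.where(denom > 0, denom, np.nan)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    return dist[np.triu_indices(n, k=1)]


def cluster_rows(normalized: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Average-linkage hierarchical clustering of rows under 1 − Pearson r.

    Returns the deterministic leaf order (row ids) and the scipy linkage
    matrix for dendrogram rendering.
    """
    if normalized.shape[0] < 2:
        return list(normalized.index), np.empty((0, 4))
    dist = _pearson_distance(normalized)
    linkage = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(linkage)
    return [normalized.index[i] for i in order], linkage


def write_results(results: list[DiffExpResult], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)
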