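"""Count-matrix assembly, JRPM normalization, the paired test with the
|FC| ≥ 2 / P < 0.05 screen, and correlation-distance row clustering."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circseek.diffexp import (PSEUDOCOUNT, CircCountMatrix, build_count_matrix,
                              cluster_rows, differential_test, filter_de,
                              normalize_counts)


def _meta(n_pairs):
    rows = []
    for i in range(1, n_pairs + 1):
        rows.append({"lib_id": f"T{i}", "condition": "tumour", "pair_id": i})
        rows.append({"lib_id": f"N{i}", "condition": "normal", "pair_id": i})
    return pd.DataFrame(rows).set_index("lib_id")


def _matrix(rows: dict[str, list[int]], n_pairs, sizes=None):
    """rows: circ id → counts in column order T1, N1, T2, N2, ..."""
    meta = _meta(n_pairs)
    counts = pd.DataFrame(rows, index=meta.index).T
    sizes = sizes if sizes is not None else {lib: 1_000_000 for lib in meta.index}
    return CircCountMatrix(counts, meta, pd.Series(sizes))


def test_disjoint_libraries_make_a_block_matrix():
    keyA, keyB = ("chr1", 10, 500, "+"), ("chr1", 900, 1400, "-")
    per_lib = {"T1": {keyA: 5}, "N1": {keyB: 7}}
    m = build_count_matrix(per_lib, _meta(1), {"T1": 100, "N1": 100})
    assert m.counts.loc["chr1:10-500|+", "T1"] == 5
    assert m.counts.loc["chr1:10-500|+", "N1"] == 0
    assert m.counts.loc["chr1:900-1400|-", "N1"] == 7
    assert m.counts.loc["chr1:900-1400|-", "T1"] == 0


def test_column_sums_equal_per_library_junction_totals():
    rng = np.random.default_rng(0)
    keys = [("chr1", i * 100, i * 100 + 50, "+") for i in range(8)]
    per_lib = {}
    for lib in ("T1", "N1", "T2", "N2"):
        picks = rng.choice(8, size=5, replace=False)
        per_lib[lib] = {keys[i]: int(rng.integers(1, 20)) for i in picks}
    m = build_count_matrix(per_lib, _meta(2), {l: 100 for l in per_lib})
    for lib, d in per_lib.items():
        assert m.counts[lib].sum() == sum(d.values())


def test_matrix_requires_metadata_and_nonnegative_counts():
    meta = _meta(1)
    counts = pd.DataFrame({"T1": [1], "N1": [2], "X9": [3]}, index=["c1"])
    with pytest.raises(ValueError, match="X9"):
        CircCountMatrix(counts, meta, pd.Series({"T1": 1, "N1": 1, "X9": 1}))
    with pytest.raises(ValueError, match="nonnegative"):
        CircCountMatrix(pd.DataFrame({"T1": [-1], "N1": [2]}, index=["c1"]),
                        meta, pd.Series({"T1": 1, "N1": 1}))


def test_normalization_is_reads_per_million():
    m = _matrix({"c1": [5, 5]}, 1)
    norm = normalize_counts(m)
    assert norm.loc["c1", "T1"] == pytest.approx(5.0)


def test_normalization_scale_invariance():
    m1 = _matrix({"c1": [10, 30], "c2": [4, 8]}, 1,
                 sizes={"T1": 2_000, "N1": 4_000})
    m2 = _matrix({"c1": [20, 60], "c2": [8, 16]}, 1,
                 sizes={"T1": 4_000, "N1": 8_000})
    pd.testing.assert_frame_equal(normalize_counts(m1), normalize_counts(m2))


def test_normalization_matches_per_cell_recomputation():
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 50, size=(6, 4))
    sizes = {lib: int(s) for lib, s in
             zip(_meta(2).index, rng.integers(500, 5_000, 4))}
    m = _matrix({f"c{i}": list(counts[i]) for i in range(6)}, 2, sizes)
    norm = normalize_counts(m)
    for i, circ in enumerate(m.counts.index):
        for j, lib in enumerate(m.counts.columns):
            assert norm.loc[circ, lib] == pytest.approx(
                counts[i, j] / sizes[lib] * 1e6)


def test_zero_library_size_rejected():
    m = _matrix({"c1": [1, 1]}, 1, sizes={"T1": 0, "N1": 10})
    with pytest.raises(ValueError, match="T1"):
        normalize_counts(m)


def test_identical_tumour_and_normal_columns_are_ns():
    m = _matrix({"c1": [7, 7, 9, 9, 3, 3], "c2": [0, 0, 5, 5, 1, 1]}, 3)
    results = differential_test(normalize_counts(m), m)
    for r in results:
        assert r.log2fc == pytest.approx(0.0)
        assert r.direction == "ns"
        assert r.p_value == pytest.approx(1.0)


def test_single_pair_is_an_error():
    m = _matrix({"c1": [1, 2]}, 1)
    with pytest.raises(ValueError, match="pair"):
        differential_test(normalize_counts(m), m)


def test_fold_change_and_t_statistic_match_hand_arithmetic():
    """3 circRNAs × 3 pairs with library size 1e6 so counts are already
    JRPM; expected numbers computed by explicit arithmetic here."""
    rows = {"c1": [40, 10, 36, 9, 44, 11],     # consistent 4× up
            "c2": [3, 12, 2, 8, 4, 16],        # consistent 4× down
            "c3": [5, 5, 8, 8, 2, 2]}          # null
    m = _matrix(rows, 3)
    results = {r.circ_id: r for r in differential_test(normalize_counts(m), m)}
    for circ_id, vals in rows.items():
        tum = np.array(vals[0::2], dtype=float)
        nor = np.array(vals[1::2], dtype=float)
        expected_fc = (tum.mean() + PSEUDOCOUNT) / (nor.mean() + PSEUDOCOUNT)
        got = results[circ_id]
        assert got.log2fc == pytest.approx(np.log2(expected_fc), abs=1e-6)
        lt, ln = np.log2(tum + 1), np.log2(nor + 1)
        d = lt - ln
        if d.std(ddof=1) > 0:
            t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            expected_p = 2 * stats.t.sf(abs(t), len(d) - 1)
            assert got.p_value == pytest.approx(expected_p, abs=1e-6)
    assert results["c1"].direction == "up"
    assert results["c2"].direction == "down"
    assert results["c3"].direction == "ns"


def test_fc_bound_is_inclusive():
    """A ratio of exactly 2 with consistent direction must be called up."""
    rows = {"c1": [19, 9, 39, 19, 59, 29, 79, 39, 99, 49]}  # (mean_t+1)=2(mean_n+1)
    m = _matrix(rows, 5)
    results = differential_test(normalize_counts(m), m)
    tum = np.array(rows["c1"][0::2], dtype=float)
    nor = np.array(rows["c1"][1::2], dtype=float)
    assert (tum.mean() + 1) / (nor.mean() + 1) == pytest.approx(2.0)
    assert results[0].p_value < 0.05
    assert results[0].direction == "up"


def test_filter_partitions_by_direction():
    rows = {"up1": [40, 10, 36, 9, 44, 11],
            "dn1": [3, 12, 2, 8, 4, 16],
            "ns1": [5, 5, 8, 8, 2, 2],
            "ns2": [9, 8, 7, 8, 8, 9]}
    m = _matrix(rows, 3)
    results = differential_test(normalize_counts(m), m)
    up, down = filter_de(results)
    assert [r.circ_id for r in up] == ["up1"]
    assert [r.circ_id for r in down] == ["dn1"]


def test_label_swap_negates_log2fc_and_swaps_directions():
    rows = {"up1": [40, 10, 36, 9, 44, 11],
            "dn1": [3, 12, 2, 8, 4, 16],
            "ns1": [5, 5, 8, 8, 2, 2]}
    m = _matrix(rows, 3)
    fwd = {r.circ_id: r for r in differential_test(normalize_counts(m), m)}

    swapped_meta = _meta(3).copy()
    swapped_meta["condition"] = swapped_meta["condition"].map(
        {"tumour": "normal", "normal": "tumour"})
    m2 = CircCountMatrix(m.counts, swapped_meta, m.library_size)
    rev = {r.circ_id: r for r in differential_test(normalize_counts(m2), m2)}
    flip = {"up": "down", "down": "up", "ns": "ns"}
    for circ_id in rows:
        assert rev[circ_id].log2fc == pytest.approx(-fwd[circ_id].log2fc)
        assert rev[circ_id].p_value == pytest.approx(fwd[circ_id].p_value)
        assert rev[circ_id].direction == flip[fwd[circ_id].direction]


# ---------------------------------------------------------------------------
# clustering


def _brute_force_average_linkage(dist):
    """O(n³) agglomeration over a dense 1−r distance matrix; returns the
    merge order as frozensets of original leaf indices."""
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a] | clusters[b], d))
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return merges


def test_identical_rows_merge_first_and_anticorrelated_last():
    base = [1.0, 2.0, 3.0, 4.0]
    m = pd.DataFrame({"a": base, "b": base,
                      "c": [-x for x in base],
                      "d": [2.0, 1.5, 3.1, 0.2]}).T
    order, linkage = cluster_rows(m)
    assert sorted([int(linkage[0, 0]), int(linkage[0, 1])]) == [0, 1]  # a with b
    assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert linkage[-1, 2] == pytest.approx(max(linkage[:, 2]))
    # c (the negation) joins at distance ~2 from its anticorrelated partners
    assert max(linkage[:, 2]) > 1.5


def test_merge_order_matches_brute_force_agglomeration():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(5, 6))
    m = pd.DataFrame(x, index=list("abcde"))
    _, linkage = cluster_rows(m)

    corr = np.corrcoef(x)
    dist = 1 - corr
    np.fill_diagonal(dist, 0.0)
    brute = _brute_force_average_linkage(dist)
    assert len(brute) == linkage.shape[0]
    for (members, d), row in zip(brute, linkage):
        assert d == pytest.approx(row[2], abs=1e-9)


def test_constant_rows_cluster_without_nans():
    m = pd.DataFrame({"flat": [3.0, 3.0, 3.0, 3.0],
                      "a": [1.0, 2.0, 3.0, 4.0],
                      "b": [1.1, 2.2, 2.9, 4.2]}).T
    order, linkage = cluster_rows(m)
    assert np.isfinite(linkage).all()
    assert set(order) == {"flat", "a", "b"}
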