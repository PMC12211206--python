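"""NB differential expression: size factors, dispersion, Wald test, BH, DEG calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitonuc.de import (
    DeThresholds,
    bh_adjust,
    call_degs,
    dispersion_mom,
    nb_wald_pairwise,
    size_factors,
    union_deg_count,
)


def _frame(arr, prefix="s"):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=pd.Index([f"g{i}" for i in range(arr.shape[0])], name="gene_id"),
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


def _meta(columns, labels, grouping="grp"):
    return pd.DataFrame({"sample_id": columns, grouping: labels})


# ---------------------------------------------------------------------------
# size factors


def test_size_factors_identical_samples():
    counts = _frame(np.tile([[10], [20], [5]], (1, 4)))
    assert np.allclose(size_factors(counts), 1.0)


def test_size_factors_hand_computed():
    # medians of ratios to geometric means: s = (1/sqrt(2), sqrt(2))
    counts = _frame([[2, 4], [8, 16], [50, 100]])
    s = size_factors(counts)
    assert s == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])


def test_size_factors_scale_equivariance():
    """Doubling one sample doubles its factor relative to every other sample."""
    rng = np.random.default_rng(1)
    base = rng.integers(1, 200, size=(50, 3))
    doubled = base.copy()
    doubled[:, 1] *= 2
    s0 = size_factors(_frame(base))
    s1 = size_factors(_frame(doubled))
    assert (s1[1] / s1[0]) / (s0[1] / s0[0]) == pytest.approx(2.0)
    assert (s1[2] / s1[0]) / (s0[2] / s0[0]) == pytest.approx(1.0)


def test_size_factors_no_all_positive_gene():
    counts = _frame([[0, 5], [3, 0]])
    with pytest.raises(ValueError, match="strictly positive"):
        size_factors(counts)


# ---------------------------------------------------------------------------
# dispersion


def test_dispersion_poisson_hits_floor():
    rng = np.random.default_rng(2)
    counts = _frame(rng.poisson(50, size=(200, 40)))
    s = size_factors(counts)
    alpha = dispersion_mom(counts, s, [np.arange(20), np.arange(20, 40)])
    assert np.median(alpha) < 0.01


def test_dispersion_constant_gene_floor():
    counts = _frame(np.full((3, 6), 7))
    alpha = dispersion_mom(counts, np.ones(6), [np.arange(3), np.arange(3, 6)])
    assert alpha == pytest.approx(1e-8)


def test_dispersion_moment_recovery():
    """Median moment estimate within 10% of alpha = 0.2 at n = 5000 samples."""
    rng = np.random.default_rng(3)
    alpha, mean = 0.2, 100.0
    r = 1 / alpha
    counts = _frame(rng.negative_binomial(r, r / (r + mean), size=(200, 5000)))
    s = np.ones(5000)
    est = dispersion_mom(counts, s, [np.arange(2500), np.arange(2500, 5000)])
    assert abs(np.median(est) - alpha) / alpha < 0.10


# ---------------------------------------------------------------------------
# Wald test


def test_identical_profiles_null_result():
    counts = _frame(np.tile([[30], [60], [90]], (1, 6)))
    meta = _meta(counts.columns, ["A"] * 3 + ["B"] * 3)
    res = nb_wald_pairwise(counts, meta, "grp", "A", "B")
    assert np.allclose(res.table["log2fc"], 0.0)
    assert np.allclose(res.table["p_raw"], 1.0)
    assert res.n_deg == 0


def test_overlapping_groups_error():
    counts = _frame(np.ones((2, 4)))
    meta = _meta(counts.columns, ["A", "A", "B", "B"])
    with pytest.raises(ValueError, match="empty or absent"):
        nb_wald_pairwise(counts, meta, "grp", "A", "C")


def test_symmetry_swap_groups():
    rng = np.random.default_rng(4)
    counts = _frame(rng.negative_binomial(5, 0.05, size=(100, 10)))
    meta = _meta(counts.columns, ["A"] * 5 + ["B"] * 5)
    ab = nb_wald_pairwise(counts, meta, "grp", "A", "B")
    ba = nb_wald_pairwise(counts, meta, "grp", "B", "A")
    assert np.allclose(ab.table["log2fc"], -ba.table["log2fc"])
    assert np.allclose(ab.table["p_raw"].fillna(-1), ba.table["p_raw"].fillna(-1))


def test_normalization_equivariance_log2fc():
    """Scaling one sample's counts leaves log2FC unchanged (all-positive genes)."""
    rng = np.random.default_rng(5)
    base = rng.integers(1, 500, size=(80, 8))
    scaled = base.copy()
    scaled[:, 0] *= 3
    meta = _meta([f"s{j}" for j in range(8)], ["A"] * 4 + ["B"] * 4)
    r0 = nb_wald_pairwise(_frame(base), meta, "grp", "A", "B")
    r1 = nb_wald_pairwise(_frame(scaled), meta, "grp", "A", "B")
    assert np.allclose(r0.table["log2fc"], r1.table["log2fc"], atol=1e-9)


def test_planted_fold_change_recovery():
    """Median estimated log2FC within 0.3 of 2 for a planted 4-fold effect.

    The effect sits in a minority of genes (50 of 500) so that
    median-of-ratios normalization anchors on the null majority.
    """
    rng = np.random.default_rng(6)
    alpha, mean, n = 0.1, 100.0, 5
    r = 1 / alpha
    mu = np.full((500, 2 * n), mean)
    mu[:50, n:] *= 4.0
    counts = _frame(rng.negative_binomial(r, r / (r + mu)))
    meta = _meta(counts.columns, ["A"] * n + ["B"] * n)
    res = nb_wald_pairwise(counts, meta, "grp", "A", "B")
    assert abs(np.median(res.table["log2fc"][:50]) - 2.0) < 0.3


def test_all_zero_genes_untested():
    counts = _frame([[0, 0, 0, 0], [5, 6, 7, 8]])
    meta = _meta(counts.columns, ["A", "A", "B", "B"])
    res = nb_wald_pairwise(counts, meta, "grp", "A", "B")
    assert not res.table.loc[0, "tested"]
    assert np.isnan(res.table.loc[0, "p_adj"])
    assert not res.table.loc[0, "is_deg"]
    assert res.table.loc[1, "tested"]


# ---------------------------------------------------------------------------
# BH and DEG calling


def bh_oracle(p):
    """Literal step-up definition: p_adj(i) = min_{k >= rank(i)} m p_(k) / k."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for pos, i in enumerate(order):
        rank = pos + 1
        out[i] = min(
            min(m * p[order[k - 1]] / k for k in range(rank, m + 1)), 1.0
        )
    return out


def test_bh_hand_example():
    p = np.array([0.01, 0.02, 0.03, 0.04])
    assert bh_adjust(p) == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_singleton_and_nan():
    assert bh_adjust(np.array([0.3])) == pytest.approx([0.3])
    with pytest.raises(ValueError, match="NaN"):
        bh_adjust(np.array([0.1, np.nan]))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_bh_matches_oracle_and_properties(seed):
    rng = np.random.default_rng(seed)
    p = rng.random(rng.integers(1, 40))
    adj = bh_adjust(p)
    assert np.allclose(adj, bh_oracle(p))
    assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()


def test_call_degs_boundaries():
    tab = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c"],
            "log2fc": [1.0, 0.9, -1.2],
            "p_adj": [0.01, 0.005, 0.02],
            "tested": [True, True, True],
        }
    )
    from mitonuc.de import DeResult

    res = DeResult(pair=("A", "B"), table=tab)
    ids, n = call_degs(res, DeThresholds())
    assert ids == ["a"] and n == 1  # boundary inclusive; b fails FC, c fails p


def test_call_degs_brute_force_scan():
    rng = np.random.default_rng(7)
    tab = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(20)],
            "log2fc": rng.normal(0, 1.5, 20),
            "p_adj": rng.random(20) * 0.05,
            "tested": rng.random(20) > 0.2,
        }
    )
    from mitonuc.de import DeResult

    _, n = call_degs(DeResult(pair=("A", "B"), table=tab), DeThresholds())
    expected = sum(
        bool(t and p <= 0.01 and abs(l) >= 1.0)
        for t, p, l in zip(tab["tested"], tab["p_adj"], tab["log2fc"])
    )
    assert n == expected


# ---------------------------------------------------------------------------
# union over pairs


def test_union_two_groups_equals_single_pair():
    rng = np.random.default_rng(8)
    counts = _frame(rng.negative_binomial(5, 0.02, size=(100, 10)))
    meta = _meta(counts.columns, ["A"] * 5 + ["B"] * 5)
    res = union_deg_count(counts, meta, "grp")
    assert len(res.per_pair_counts) == 1
    assert res.union_count == next(iter(res.per_pair_counts.values()))


def test_union_disjoint_planted_sets():
    """Three groups, 10 genes hugely up in each -> union 30, per-pair >= 10."""
    rng = np.random.default_rng(9)
    n_per = 8
    base = rng.poisson(100, size=(200, 3 * n_per)).astype(float)
    for block, rows in enumerate([range(0, 10), range(10, 20), range(20, 30)]):
        cols = slice(block * n_per, (block + 1) * n_per)
        for r in rows:
            base[r, cols] *= 64
    counts = _frame(rng.poisson(base))
    meta = _meta(counts.columns, ["A"] * n_per + ["B"] * n_per + ["C"] * n_per)
    res = union_deg_count(counts, meta, "grp")
    assert res.union_count == 30
    assert sum(res.per_pair_counts.values()) >= res.union_count


def test_union_leq_sum_of_pairs(default_counts, default_metadata):
    counts, _ = default_counts
    for grouping in ("station", "mitotype", "nuclear_type"):
        res = union_deg_count(counts, default_metadata, grouping, keep_tables=False)
        assert res.union_count <= sum(res.per_pair_counts.values())
        assert res.union_count >= max(res.per_pair_counts.values())
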