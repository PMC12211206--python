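"""Negative-binomial pairwise differential expression.

A self-contained, vectorized NB Wald test: median-of-ratios size factors,
gene-wise method-of-moments dispersion (no empirical-Bayes shrinkage), a
normal-approximation Wald test on the log ratio of group means, BH-FDR per
comparison, and DEG calling at adjusted p <= 0.01 and |log2FC| >= 1
(fold change of at least 2).

The per-gene model is Var = mu + alpha * mu^2 on the normalized scale.  For
group g with samples j, the delta-method variance of ln(mean normalized
count) is

    Var(ln mu_g) = sum_j (mu_g / s_j + alpha mu_g^2) / (n_g mu_g)^2

where s_j are size factors.  Groups with zero mean are given the continuity
substitute 0.5 / sum_j s_j so the log ratio stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm

ALPHA_MIN = 1e-8
ALPHA_MAX = 10.0


@dataclass
class DeThresholds:
    alpha_adj: float = 0.01
    min_abs_log2fc: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_adj < 1.0:
            raise ValueError("alpha_adj must be in (0, 1)")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")


@dataclass
class DeResult:
    """Per-gene statistics for one pairwise contrast (B vs A)."""

    pair: tuple[str, str]
    table: pd.DataFrame  # gene_id, base_mean_a, base_mean_b, log2fc, se, p_raw, p_adj, is_deg, tested

    @property
    def deg_ids(self) -> list[str]:
        return self.table.loc[self.table["is_deg"], "gene_id"].tolist()

    @property
    def n_deg(self) -> int:
        return int(self.table["is_deg"].sum())


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (genes x samples input).

    Each sample's factor is the median, over genes positive in every sample,
    of the ratio of its count to the gene's geometric mean across samples.
    """
    k = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, dtype=float)
    pos = (k > 0).all(axis=1)
    if not pos.any():
        raise ValueError(
            "no gene with strictly positive counts in all samples; "
            "median-of-ratios undefined (consider a pseudo-reference fallback)"
        )
    logk = np.log(k[pos])
    log_geomean = logk.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logk - log_geomean, axis=0))
    return s


def normalized_counts(counts: pd.DataFrame | np.ndarray, s: np.ndarray | None = None) -> np.ndarray:
    k = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, dtype=float)
    if s is None:
        s = size_factors(k)
    return k / s[None, :]


def dispersion_mom(
    counts: pd.DataFrame | np.ndarray,
    s: np.ndarray,
    group_idx: list[np.ndarray],
) -> np.ndarray:
    """Method-of-moments NB dispersion per gene.

    On normalized counts q = K/s: alpha = (v - mu * mean_j(1/s_j)) / mu^2,
    with v the pooled within-group variance of q and mu the grand mean,
    clipped to [1e-8, 10].  The mu*mean(1/s) term subtracts the expected
    Poisson contribution on the normalized scale.
    """
    q = normalized_counts(counts, s)
    cols = np.concatenate(group_idx)
    qs = q[:, cols]
    mu = qs.mean(axis=1)
    n_tot = sum(len(ix) for ix in group_idx)
    n_groups_ge2 = sum(1 for ix in group_idx if len(ix) >= 2)
    df = n_tot - len(group_idx)
    if df <= 0 or n_groups_ge2 == 0:
        raise ValueError("need at least one group with >= 2 samples")
    ss = np.zeros(q.shape[0])
    for ix in group_idx:
        sub = q[:, ix]
        m = sub.mean(axis=1, keepdims=True)
        ss += ((sub - m) ** 2).sum(axis=1)
    v = ss / df
    mean_inv_s = (1.0 / s[cols]).mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - mu * mean_inv_s) / np.where(mu > 0, mu**2, 1.0)
    alpha[mu == 0] = ALPHA_MIN
    return np.clip(alpha, ALPHA_MIN, ALPHA_MAX)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _wald_stats(
    q: np.ndarray,
    s: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    alpha: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Wald test core on normalized counts q.

    Returns (mu_a, mu_b, log2fc, se_ln, p_raw, tested).
    """
    qa, qb = q[:, idx_a], q[:, idx_b]
    mu_a = qa.mean(axis=1)
    mu_b = qb.mean(axis=1)
    tested = (mu_a > 0) | (mu_b > 0)
    sub_a = 0.5 / s[idx_a].sum()
    sub_b = 0.5 / s[idx_b].sum()
    mu_a_c = np.where(mu_a > 0, mu_a, sub_a)
    mu_b_c = np.where(mu_b > 0, mu_b, sub_b)
    lam = np.log(mu_b_c) - np.log(mu_a_c)
    inv_s_a = (1.0 / s[idx_a]).sum()
    inv_s_b = (1.0 / s[idx_b]).sum()
    n_a, n_b = len(idx_a), len(idx_b)
    var_a = (mu_a_c * inv_s_a + n_a * alpha * mu_a_c**2) / (n_a * mu_a_c) ** 2
    var_b = (mu_b_c * inv_s_b + n_b * alpha * mu_b_c**2) / (n_b * mu_b_c) ** 2
    se = np.sqrt(var_a + var_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lam / np.where(se > 0, se, 1.0), 0.0)
    p_raw = 2.0 * norm.sf(np.abs(z))
    return mu_a, mu_b, lam / np.log(2.0), se, p_raw, tested


def _group_columns(meta: pd.DataFrame, samples: list[str], grouping: str) -> dict[str, np.ndarray]:
    lbl = meta.set_index("sample_id").loc[samples, grouping]
    out = {}
    for g in pd.unique(lbl):
        out[g] = np.flatnonzero((lbl == g).to_numpy())
    return out


def nb_wald_pairwise(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    grouping: str,
    group_a: str,
    group_b: str,
    thresholds: DeThresholds | None = None,
    s: np.ndarray | None = None,
    alpha: np.ndarray | None = None,
) -> DeResult:
    """NB Wald test of group_b vs group_a for one metadata grouping.

    ``counts`` is genes x samples with a ``gene_id`` index or first column.
    Size factors default to the full-matrix median-of-ratios; dispersion
    defaults to the two-group method-of-moments estimate on A union B.
    """
    thresholds = thresholds or DeThresholds()
    counts = _as_count_frame(counts)
    samples = list(counts.columns)
    gidx = _group_columns(meta, samples, grouping)
    for g in (group_a, group_b):
        if g not in gidx or len(gidx[g]) == 0:
            raise ValueError(f"group {g!r} empty or absent in {grouping!r}")
    if set(gidx[group_a]) & set(gidx[group_b]):
        raise ValueError("groups overlap")
    if s is None:
        s = size_factors(counts)
    q = counts.to_numpy(dtype=float) / s[None, :]
    idx_a, idx_b = gidx[group_a], gidx[group_b]
    if alpha is None:
        alpha = dispersion_mom(counts, s, [idx_a, idx_b])
    mu_a, mu_b, log2fc, se, p_raw, tested = _wald_stats(q, s, idx_a, idx_b, alpha)
    p_adj = np.full(p_raw.shape, np.nan)
    if tested.any():
        p_adj[tested] = bh_adjust(p_raw[tested])
    is_deg = (
        tested
        & (p_adj <= thresholds.alpha_adj)
        & (np.abs(log2fc) >= thresholds.min_abs_log2fc)
    )
    table = pd.DataFrame(
        {
            "gene_id": counts.index,
            "base_mean_a": mu_a,
            "base_mean_b": mu_b,
            "log2fc": np.where(tested, log2fc, 0.0),
            "se": se,
            "p_raw": np.where(tested, p_raw, np.nan),
            "p_adj": p_adj,
            "is_deg": is_deg,
            "tested": tested,
        }
    ).reset_index(drop=True)
    return DeResult(pair=(group_a, group_b), table=table)


def call_degs(result: DeResult, thresholds: DeThresholds | None = None) -> tuple[list[str], int]:
    """Re-apply DEG thresholds to a result table; returns (ids, count)."""
    t = thresholds or DeThresholds()
    tab = result.table
    mask = (
        tab["tested"]
        & (tab["p_adj"] <= t.alpha_adj)
        & (tab["log2fc"].abs() >= t.min_abs_log2fc)
    )
    ids = tab.loc[mask, "gene_id"].tolist()
    return ids, len(ids)


def _as_count_frame(counts: pd.DataFrame) -> pd.DataFrame:
    if "gene_id" in counts.columns:
        counts = counts.set_index("gene_id")
    return counts


@dataclass
class UnionDeResult:
    grouping: str
    per_pair: dict[tuple[str, str], DeResult] = field(default_factory=dict)
    per_pair_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    union_degs: set[str] = field(default_factory=set)

    @property
    def union_count(self) -> int:
        return len(self.union_degs)


def union_deg_count(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    grouping: str,
    thresholds: DeThresholds | None = None,
    keep_tables: bool = True,
) -> UnionDeResult:
    """Run all unordered pairwise contrasts of a grouping; union their DEGs.

    The analysis-level statistic is the number of genes significant in at
    least one pairwise comparison.  Size factors are computed once on the
    full matrix; dispersion once per grouping from the pooled within-group
    variance over all its groups.
    """
    thresholds = thresholds or DeThresholds()
    counts = _as_count_frame(counts)
    samples = list(counts.columns)
    gidx = _group_columns(meta, samples, grouping)
    if len(gidx) < 2:
        raise ValueError(f"grouping {grouping!r} has fewer than two groups")
    s = size_factors(counts)
    alpha = dispersion_mom(counts, s, list(gidx.values()))
    res = UnionDeResult(grouping=grouping)
    for a, b in combinations(gidx.keys(), 2):
        r = nb_wald_pairwise(counts, meta, grouping, a, b, thresholds, s=s, alpha=alpha)
        res.per_pair_counts[(a, b)] = r.n_deg
        res.union_degs |= set(r.deg_ids)
        if keep_tables:
            res.per_pair[(a, b)] = r
    return res


# ---------------------------------------------------------------------------
# Fast path used by the randomization null (no DataFrames in the loop)


def union_deg_count_fast(
    q: np.ndarray,
    s: np.ndarray,
    group_idx: list[np.ndarray],
    thresholds: DeThresholds,
) -> int:
    """Union DEG count over all group pairs, given precomputed normalized counts.

    Same statistics as :func:`union_deg_count` but operating on raw arrays;
    used inside the randomized-grouping loop where thousands of reanalyses
    are required.
    """
    n_genes = q.shape[0]
    cols = np.concatenate(group_idx)
    qs = q[:, cols]
    mu = qs.mean(axis=1)
    df = len(cols) - len(group_idx)
    ss = np.zeros(n_genes)
    means = []
    for ix in group_idx:
        sub = q[:, ix]
        m = sub.mean(axis=1)
        means.append(m)
        ss += ((sub - m[:, None]) ** 2).sum(axis=1)
    v = ss / df
    mean_inv_s = (1.0 / s[cols]).mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - mu * mean_inv_s) / np.where(mu > 0, mu**2, 1.0)
    alpha[mu == 0] = ALPHA_MIN
    alpha = np.clip(alpha, ALPHA_MIN, ALPHA_MAX)

    union = np.zeros(n_genes, dtype=bool)
    k = len(group_idx)
    for ai in range(k):
        for bi in range(ai + 1, k):
            idx_a, idx_b = group_idx[ai], group_idx[bi]
            mu_a, mu_b = means[ai], means[bi]
            tested = (mu_a > 0) | (mu_b > 0)
            if not tested.any():
                continue
            sub_a = 0.5 / s[idx_a].sum()
            sub_b = 0.5 / s[idx_b].sum()
            mu_a_c = np.where(mu_a > 0, mu_a, sub_a)
            mu_b_c = np.where(mu_b > 0, mu_b, sub_b)
            lam = np.log(mu_b_c) - np.log(mu_a_c)
            inv_s_a = (1.0 / s[idx_a]).sum()
            inv_s_b = (1.0 / s[idx_b]).sum()
            n_a, n_b = len(idx_a), len(idx_b)
            var_a = (mu_a_c * inv_s_a + n_a * alpha * mu_a_c**2) / (n_a * mu_a_c) ** 2
            var_b = (mu_b_c * inv_s_b + n_b * alpha * mu_b_c**2) / (n_b * mu_b_c) ** 2
            se = np.sqrt(var_a + var_b)
            z = np.where(se > 0, lam / np.where(se > 0, se, 1.0), 0.0)
            p_raw = 2.0 * norm.sf(np.abs(z))
            p_adj = bh_adjust(p_raw[tested])
            deg_t = (p_adj <= thresholds.alpha_adj) & (
                np.abs(lam[tested] / np.log(2.0)) >= thresholds.min_abs_log2fc
            )
            deg = np.zeros(n_genes, dtype=bool)
            deg[np.flatnonzero(tested)[deg_t]] = True
            union |= deg
    return int(union.sum())
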