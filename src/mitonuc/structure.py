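"""Population genetic structure: distance-based AMOVA, genotype PCA, G'ST.

AMOVA follows the classical distance-based variance partition on squared
Euclidean genotype distances (two strata: among groups vs within groups,
here "between stations" vs "within individuals"), with significance from a
label-permutation test.  Differentiation between group pairs uses Hedrick's
standardized G'ST computed per locus from allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import MISSING, VariantMatrix


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float | None = None


@dataclass
class PcaResult:
    scores: np.ndarray           # samples x components
    explained_pct: np.ndarray    # per component
    loadings: np.ndarray | None = None


@dataclass
class GstResult:
    pair: tuple[str, str]
    per_locus_gst: np.ndarray
    mean_gst: float
    n_loci_used: int


def pairwise_distance_matrix(v: VariantMatrix) -> np.ndarray:
    """Squared Euclidean dosage distances with missing-data rescaling.

    For each pair the squared difference is summed over loci called in both
    individuals and rescaled by (total loci / shared loci), an unbiased
    expansion when missingness is locus-independent.

    Raises
    ------
    ValueError
        If some pair shares no called locus.
    """
    if v.n_individuals < 2:
        raise ValueError("need at least two individuals")
    gt = v.genotypes.astype(float)
    called = (v.genotypes != MISSING).astype(float)
    gt_z = np.where(v.genotypes == MISSING, 0.0, gt)
    # pairwise sums of x^2, y^2 and xy restricted to jointly called loci
    sq = gt_z**2
    shared = called.T @ called                      # loci called in both
    cross = gt_z.T @ gt_z
    a2 = sq.T @ called                              # sum_i x_i^2 over shared loci
    d2 = a2 + a2.T - 2.0 * cross
    n = v.n_individuals
    off = ~np.eye(n, dtype=bool)
    if (shared[off] == 0).any():
        i, j = np.argwhere((shared == 0) & off)[0]
        raise ValueError(
            f"individuals {v.samples[i]!r} and {v.samples[j]!r} share no called locus"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(off, d2 * (v.n_loci / np.maximum(shared, 1)), 0.0)
    np.fill_diagonal(d2, 0.0)
    return (d2 + d2.T) / 2.0


def _group_indices(groups: pd.Series | dict | list, samples: list[str]) -> dict[str, np.ndarray]:
    if isinstance(groups, pd.Series):
        if set(samples) <= set(groups.index):
            labels = groups.reindex(samples).to_numpy()
        elif len(groups) == len(samples):
            # positionally aligned label vector
            labels = groups.to_numpy()
        else:
            missing = [s for s in samples if s not in groups.index]
            raise ValueError(f"samples without group label: {missing}")
    elif isinstance(groups, dict):
        labels = np.array([groups[s] for s in samples], dtype=object)
    else:
        labels = np.asarray(groups, dtype=object)
        if len(labels) != len(samples):
            raise ValueError("group label vector length mismatch")
    out: dict[str, np.ndarray] = {}
    for g in pd.unique(labels):
        out[g] = np.flatnonzero(labels == g)
    return out


def amova_from_distances(d2: np.ndarray, group_idx: dict[str, np.ndarray]) -> AmovaResult:
    """Two-level AMOVA variance partition from a squared-distance matrix.

    SS_total = (1/N) sum_{i<j} d2; SS_within = sum_g (1/n_g) sum_{i<j in g} d2;
    sigma2_within = SS_within/(N-G); sigma2_among = (MS_among - sigma2_within)/n_bar
    with n_bar = (N - sum n_g^2 / N)/(G-1).  Phi_ST = sigma2_among / total.
    A fully degenerate input (all distances zero) yields Phi = 0, pct_among = 0.
    """
    n = d2.shape[0]
    sizes = np.array([len(ix) for ix in group_idx.values()])
    g = len(sizes)
    if g < 2:
        raise ValueError("need at least two groups")
    if sizes.sum() != n:
        raise ValueError("group sizes do not sum to matrix dimension")
    df_among = g - 1
    df_within = n - g
    if df_within == 0:
        raise ValueError("all groups of size 1: no within-group degrees of freedom")
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for ix in group_idx.values():
        if len(ix) < 2:
            continue
        sub = d2[np.ix_(ix, ix)]
        ss_within += np.triu(sub, k=1).sum() / len(ix)
    ss_among = ss_total - ss_within
    sigma2_within = ss_within / df_within
    n_bar = (n - (sizes**2).sum() / n) / df_among
    ms_among = ss_among / df_among
    sigma2_among = (ms_among - sigma2_within) / n_bar
    total = sigma2_among + sigma2_within
    if total <= 0:
        phi = 0.0
        pct_among = 0.0
    else:
        phi = sigma2_among / total
        pct_among = 100.0 * sigma2_among / total
    return AmovaResult(
        df_among=df_among,
        df_within=df_within,
        ss_among=ss_among,
        ss_within=ss_within,
        sigma2_among=sigma2_among,
        sigma2_within=sigma2_within,
        pct_among=pct_among,
        pct_within=100.0 - pct_among,
        phi_st=phi,
    )


def amova(d2: np.ndarray, groups, samples: list[str] | None = None) -> AmovaResult:
    """AMOVA on a squared-distance matrix with labelled groups.

    ``groups`` may be a pandas Series indexed by sample, a dict, or a label
    vector aligned with the matrix rows.
    """
    if samples is None:
        samples = [str(i) for i in range(d2.shape[0])]
    return amova_from_distances(d2, _group_indices(groups, samples))


def amova_permutation_test(
    d2: np.ndarray,
    groups,
    samples: list[str] | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> AmovaResult:
    """Permutation p-value for Phi_ST: p = (1 + #{Phi_perm >= Phi_obs})/(n_perm + 1)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if samples is None:
        samples = [str(i) for i in range(d2.shape[0])]
    group_idx = _group_indices(groups, samples)
    obs = amova_from_distances(d2, group_idx)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = [(g, len(ix)) for g, ix in group_idx.items()]
    n = d2.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        start = 0
        pidx = {}
        for g, sz in sizes:
            pidx[g] = perm[start : start + sz]
            start += sz
        phi = amova_from_distances(d2, pidx).phi_st
        if phi >= obs.phi_st:
            count += 1
    obs.p_value = (1 + count) / (n_perm + 1)
    return obs


def genotype_pca(v: VariantMatrix, n_components: int | None = None) -> PcaResult:
    """Covariance PCA of the dosage matrix with per-locus mean imputation.

    Missing dosages are replaced by the locus mean over called individuals,
    columns (loci) are centered, and scores come from the SVD of the
    individuals x loci matrix.  Explained percentages are eigenvalue shares
    of the total variance of the centered matrix.
    """
    if v.n_individuals < 2 or v.n_loci < 1:
        raise ValueError("need >= 2 individuals and >= 1 locus")
    x = v.genotypes.T.astype(float)          # individuals x loci
    miss = x == MISSING
    x[miss] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    x = np.where(np.isnan(x), col_mean[None, :], x)
    x = x - x.mean(axis=0, keepdims=True)
    n = x.shape[0]
    k_full = min(n, x.shape[1])
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    if total <= 0:
        k = n_components or k_full
        return PcaResult(
            scores=np.zeros((n, k)), explained_pct=np.zeros(k), loadings=None
        )
    explained = 100.0 * eig / total
    scores = u * s
    if n_components is not None:
        scores = scores[:, :n_components]
        explained = explained[:n_components]
        vt = vt[:n_components]
    return PcaResult(scores=scores, explained_pct=explained, loadings=vt.T)


def _alt_freqs(gt: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus ALT allele frequency and called-allele totals in a subset."""
    sub = gt[:, idx]
    called = sub != MISSING
    total = 2 * called.sum(axis=1)
    alt = np.where(called, sub, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    return p, total


def hedrick_gst_from_freqs(p_a: np.ndarray, p_b: np.ndarray) -> np.ndarray:
    """Hedrick's G'ST per locus for two subpopulations from allele frequencies.

    H_S = mean of within-group expected heterozygosities 2p(1-p); H_T uses
    the unweighted mean frequency.  G'ST = G_ST (k-1+H_S)/((k-1)(1-H_S)) with
    k = 2.  Loci with H_T = 0 or H_S = 1 come back as NaN.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    h_s = (2 * p_a * (1 - p_a) + 2 * p_b * (1 - p_b)) / 2.0
    p_bar = (p_a + p_b) / 2.0
    h_t = 2 * p_bar * (1 - p_bar)
    out = np.full(p_a.shape, np.nan)
    ok = np.isfinite(p_a) & np.isfinite(p_b) & (h_t > 0) & (h_s < 1)
    gst = np.where(ok, (h_t - h_s) / np.where(h_t > 0, h_t, 1.0), np.nan)
    k = 2
    out[ok] = gst[ok] * (k - 1 + h_s[ok]) / ((k - 1) * (1 - h_s[ok]))
    return out


def hedrick_gst_pairwise(
    v: VariantMatrix, groups, pair: tuple[str, str]
) -> GstResult:
    """Pairwise Hedrick's G'ST between two labelled groups, per locus + mean."""
    gidx = _group_indices(groups, v.samples)
    a, b = pair
    for g in pair:
        if g not in gidx:
            raise ValueError(f"group {g!r} not present")
    p_a, tot_a = _alt_freqs(v.genotypes, gidx[a])
    p_b, tot_b = _alt_freqs(v.genotypes, gidx[b])
    per_locus = hedrick_gst_from_freqs(p_a, p_b)
    per_locus[(tot_a == 0) | (tot_b == 0)] = np.nan
    used = np.isfinite(per_locus)
    if not used.any():
        raise ValueError(f"no usable loci for pair {pair}")
    return GstResult(
        pair=(a, b),
        per_locus_gst=per_locus[used],
        mean_gst=float(per_locus[used].mean()),
        n_loci_used=int(used.sum()),
    )


def gst_density(values: np.ndarray, n_grid: int = 256) -> pd.DataFrame:
    """Gaussian KDE of per-locus G'ST values (Silverman bandwidth) on a grid."""
    from scipy.stats import gaussian_kde

    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2 or np.allclose(values, values[0]):
        grid = np.linspace(values.min() - 0.05, values.max() + 0.05, n_grid) if values.size else np.linspace(0, 1, n_grid)
        dens = np.zeros(n_grid)
        return pd.DataFrame({"grid": grid, "density": dens})
    kde = gaussian_kde(values, bw_method="silverman")
    lo, hi = values.min(), values.max()
    pad = 0.1 * (hi - lo + 1e-9)
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    return pd.DataFrame({"grid": grid, "density": kde(grid)})
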