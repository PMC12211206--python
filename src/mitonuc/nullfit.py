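"""Randomized-grouping null for DEG counts with a gamma exceedance test.

The validation procedure: re-run the whole pairwise differential-expression
analysis many times with the sample labels randomly re-partitioned into
groups of the original sizes (the "size conformation"), collect the union
DEG count of each randomized run, fit candidate distributions (gamma,
lognormal, Weibull, normal) by maximum likelihood, select by AIC, and test
whether the observed DEG count of the real grouping exceeds the 0.95
quantile (Q0.95) of the selected fit.  A parametric-bootstrap confidence
interval accompanies Q0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .de import DeThresholds, normalized_counts, size_factors, union_deg_count_fast

_POSITIVE_SUPPORT = ("gamma", "lognormal", "weibull")
_CANDIDATES = ("gamma", "lognormal", "weibull", "normal")


class DegenerateNullError(ValueError):
    """Null DEG-count sample is constant; no distribution can be fitted."""


@dataclass
class SizeConformation:
    """Ordered group sizes a randomized grouping must preserve."""

    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        self.sizes = tuple(int(s) for s in self.sizes)
        if any(s <= 0 for s in self.sizes):
            raise ValueError("group sizes must be positive")

    @property
    def total(self) -> int:
        return sum(self.sizes)

    @classmethod
    def parse(cls, text: str) -> "SizeConformation":
        return cls(tuple(int(t) for t in text.replace(" ", "").split(",")))


@dataclass
class CandidateFit:
    name: str
    params: dict[str, float]
    log_lik: float
    aic: float


@dataclass
class NullFit:
    values: np.ndarray
    candidate_fits: list[CandidateFit]
    selected: CandidateFit
    shift: float
    q95: float | None = None
    q95_ci: tuple[float, float] | None = None
    n_iter: int = 0
    seed: int | None = None


@dataclass
class ExceedanceVerdict:
    observed: int
    q95: float
    exceeds: bool
    empirical_p: float
    method: str = "gamma"


def random_grouping(
    sample_ids: list[str], conf: SizeConformation, rng: np.random.Generator
) -> dict[str, list[str]]:
    """Uniformly random partition of the samples into groups of fixed sizes."""
    if len(sample_ids) != conf.total:
        raise ValueError(
            f"{len(sample_ids)} samples but conformation total {conf.total}"
        )
    perm = rng.permutation(len(sample_ids))
    out: dict[str, list[str]] = {}
    start = 0
    for gi, size in enumerate(conf.sizes):
        out[f"g{gi + 1}"] = [sample_ids[i] for i in perm[start : start + size]]
        start += size
    return out


def null_distribution(
    counts: pd.DataFrame,
    sample_ids: list[str],
    conf: SizeConformation,
    thresholds: DeThresholds | None = None,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Union DEG counts from ``n_iter`` randomized groupings of the samples.

    Size factors and normalized counts are computed once; each iteration
    only re-partitions the sample columns and reruns the pairwise Wald
    analysis on the new groups.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    thresholds = thresholds or DeThresholds()
    if "gene_id" in counts.columns:
        counts = counts.set_index("gene_id")
    counts = counts[sample_ids]
    s = size_factors(counts)
    q = normalized_counts(counts, s)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(sample_ids)
    out = np.empty(n_iter, dtype=np.int64)
    bounds = np.cumsum((0,) + conf.sizes)
    for it in range(n_iter):
        perm = rng.permutation(n)
        group_idx = [perm[bounds[i] : bounds[i + 1]] for i in range(len(conf.sizes))]
        out[it] = union_deg_count_fast(q, s, group_idx, thresholds)
    return out


# ---------------------------------------------------------------------------
# Distribution fitting


def _gamma_mle(x: np.ndarray, tol: float = 1e-10, max_iter: int = 100) -> tuple[float, float]:
    """Gamma(shape k, scale theta) MLE via Newton iteration on the shape.

    Uses the standard closed-form start from s = ln(mean) - mean(ln x) and
    Newton steps on  ln k - psi(k) = s.  Requires strictly positive input.
    """
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError("gamma MLE requires positive values")
    m = x.mean()
    s = np.log(m) - np.log(x).mean()
    if s <= 0:  # numerically constant sample
        raise DegenerateNullError("constant sample")
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(max_iter):
        f = np.log(k) - special.digamma(k) - s
        fp = 1.0 / k - special.polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < tol * k:
            k = k_new
            break
        k = k_new
    return float(k), float(m / k)


def _fit_candidate(name: str, x: np.ndarray) -> CandidateFit:
    if name == "gamma":
        k, theta = _gamma_mle(x)
        ll = stats.gamma.logpdf(x, k, scale=theta).sum()
        params = {"shape": k, "scale": theta}
    elif name == "lognormal":
        mu = np.log(x).mean()
        sigma = np.log(x).std(ddof=0)
        if sigma <= 0:
            raise DegenerateNullError("constant sample")
        ll = stats.lognorm.logpdf(x, sigma, scale=np.exp(mu)).sum()
        params = {"meanlog": float(mu), "sdlog": float(sigma)}
    elif name == "weibull":
        c, loc, scale = stats.weibull_min.fit(x, floc=0)
        ll = stats.weibull_min.logpdf(x, c, scale=scale).sum()
        params = {"shape": float(c), "scale": float(scale)}
    elif name == "normal":
        loc, scale = x.mean(), x.std(ddof=0)
        if scale <= 0:
            raise DegenerateNullError("constant sample")
        ll = stats.norm.logpdf(x, loc, scale).sum()
        params = {"mean": float(loc), "sd": float(scale)}
    else:
        raise ValueError(f"unknown candidate {name!r}")
    n_par = 2
    return CandidateFit(name=name, params=params, log_lik=float(ll), aic=2 * n_par - 2 * float(ll))


def _frozen(fit: CandidateFit):
    p = fit.params
    if fit.name == "gamma":
        return stats.gamma(p["shape"], scale=p["scale"])
    if fit.name == "lognormal":
        return stats.lognorm(p["sdlog"], scale=np.exp(p["meanlog"]))
    if fit.name == "weibull":
        return stats.weibull_min(p["shape"], scale=p["scale"])
    if fit.name == "normal":
        return stats.norm(p["mean"], p["sd"])
    raise ValueError(fit.name)


def fit_null(
    values: np.ndarray,
    candidates: tuple[str, ...] = _CANDIDATES,
    seed: int | None = None,
) -> NullFit:
    """Fit candidate distributions by MLE and select the minimal-AIC one.

    If any value is <= 0 the sample is shifted by +0.5 before fitting the
    positive-support candidates (gamma, lognormal, Weibull); the shift is
    recorded so quantiles can be mapped back (floored at 0).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 values")
    if not np.isfinite(values).any():
        raise ValueError("no finite values")
    if np.allclose(values, values[0]):
        raise DegenerateNullError(
            f"all {values.size} null DEG counts equal {values[0]:g}; nothing to fit"
        )
    shift = 0.5 if (values <= 0).any() else 0.0
    fits: list[CandidateFit] = []
    for name in candidates:
        x = values + shift if name in _POSITIVE_SUPPORT else values
        if name in _POSITIVE_SUPPORT and (x <= 0).any():
            # values below -shift: candidate's support cannot hold the sample
            continue
        try:
            fit = _fit_candidate(name, x)
        except (DegenerateNullError, ValueError, RuntimeError):
            continue
        if np.isfinite(fit.aic):
            fits.append(fit)
    if not fits:
        raise DegenerateNullError("no candidate distribution could be fitted")
    selected = min(fits, key=lambda f: f.aic)
    return NullFit(
        values=values,
        candidate_fits=fits,
        selected=selected,
        shift=shift,
        n_iter=values.size,
        seed=seed,
    )


def _q95_of(fit: CandidateFit, shift: float) -> float:
    q = float(_frozen(fit).ppf(0.95))
    if fit.name in _POSITIVE_SUPPORT:
        q = max(q - shift, 0.0)
    return q


def gamma_q95_ci(
    fit: NullFit,
    conf_level: float = 0.95,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, tuple[float, float]]:
    """Q0.95 of the selected fit with a parametric-bootstrap percentile CI.

    ``n_boot`` samples of the original size are drawn from the fitted
    distribution, refitted within the same family, and the percentile
    interval of their Q0.95 values at ``conf_level`` is returned.
    Bootstrap refits that fail are skipped; more than 10% skipped is an
    error.  Results are stored on ``fit`` as well.
    """
    sel = fit.selected
    q95 = _q95_of(sel, fit.shift)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frozen = _frozen(sel)
    n = fit.n_iter
    boot_q: list[float] = []
    skipped = 0
    for _ in range(n_boot):
        x = frozen.rvs(size=n, random_state=rng)
        if sel.name in _POSITIVE_SUPPORT:
            x = np.maximum(x, 1e-12)
        try:
            refit = _fit_candidate(sel.name, x)
        except (DegenerateNullError, ValueError, RuntimeError):
            skipped += 1
            continue
        boot_q.append(_q95_of(refit, fit.shift))
    if skipped > 0.1 * n_boot:
        raise RuntimeError(f"{skipped}/{n_boot} bootstrap refits failed")
    lo, hi = np.quantile(boot_q, [(1 - conf_level) / 2, 1 - (1 - conf_level) / 2])
    fit.q95 = q95
    fit.q95_ci = (float(lo), float(hi))
    return q95, (float(lo), float(hi))


def exceedance_test(observed: int, fit: NullFit) -> ExceedanceVerdict:
    """Is the observed DEG count strictly above the fitted Q0.95?

    Also reports the empirical permutation p-value
    (1 + #{null >= observed}) / (n_iter + 1).
    """
    q95 = fit.q95 if fit.q95 is not None else _q95_of(fit.selected, fit.shift)
    emp = (1 + int((fit.values >= observed).sum())) / (fit.n_iter + 1)
    return ExceedanceVerdict(
        observed=int(observed),
        q95=float(q95),
        exceeds=bool(observed > q95),
        empirical_p=float(emp),
        method=fit.selected.name,
    )


def empirical_verdict(observed: int, values: np.ndarray) -> ExceedanceVerdict:
    """Fallback verdict from the empirical 0.95 quantile of the null sample.

    Used when the null DEG-count sample is degenerate (e.g. all zero on a
    no-effect dataset) and no parametric fit exists.
    """
    values = np.asarray(values, dtype=float)
    q95 = float(np.quantile(values, 0.95))
    emp = (1 + int((values >= observed).sum())) / (values.size + 1)
    return ExceedanceVerdict(
        observed=int(observed), q95=q95, exceeds=bool(observed > q95),
        empirical_p=float(emp), method="empirical",
    )
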