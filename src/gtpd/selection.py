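"""Goodness-of-fit model comparison for positive data series.

Fits the Gemeay distribution (GD) and a panel of classical lifetime
baselines by maximum likelihood, then reports four information criteria

    Cr1 = -2L + 2p                      (Akaike)
    Cr2 = Cr1 + 2p(p+1)/(n-p-1)         (corrected Akaike)
    Cr3 = -2L + p log n                 (Bayesian)
    Cr4 = -2L + 2p log(log n)           (Hannan-Quinn)

and three distance statistics on the fitted CDF values u_i = F(x_(i)):
Anderson-Darling (G1), Cramer-von Mises (G2), and Kolmogorov-Smirnov (G3)
with its asymptotic p-value.  Lower is better throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .estimators import SortedSample, fit as _gd_fit, neg_log_likelihood

__all__ = [
    "FittedModel",
    "GofReport",
    "information_criteria",
    "gof_statistics",
    "baseline_panel",
    "compare",
    "ttt_and_pp",
]

BASELINE_ORDER = ("GD", "ED", "FD", "LD", "LoD", "HLD", "MD")


@dataclass
class FittedModel:
    """A candidate model after maximum-likelihood fitting."""

    name: str
    n_params: int
    params: dict[str, float]
    standard_errors: dict[str, Optional[float]]
    loglik: float
    cdf: Callable[[np.ndarray], np.ndarray]
    pdf: Callable[[np.ndarray], np.ndarray]


@dataclass
class GofReport:
    """Criteria table, per-criterion rankings, and the fitted models."""

    table: pd.DataFrame            # index: model, columns: neg_loglik, Cr1..Cr4, G1..G3, G3_p
    ranks: pd.DataFrame            # same shape, average-tie ranks per criterion column
    fitted: dict[str, FittedModel]

    def winner(self, criterion: str = "Cr1") -> str:
        return self.table[criterion].idxmin()


def information_criteria(loglik: float, p: int, n: int) -> dict[str, float]:
    """AIC / AICc / BIC / HQIC from a maximized log-likelihood."""
    if p < 1 or n < 1:
        raise ValueError("need p >= 1 parameters and n >= 1 observations")
    if n <= p + 1:
        raise ValueError("corrected AIC undefined for n <= p + 1")
    m2l = -2.0 * loglik
    cr1 = m2l + 2.0 * p
    return {
        "Cr1": cr1,
        "Cr2": cr1 + 2.0 * p * (p + 1.0) / (n - p - 1.0),
        "Cr3": m2l + p * math.log(n),
        "Cr4": m2l + 2.0 * p * math.log(math.log(n)),
    }


def gof_statistics(sample, cdf: Callable[[np.ndarray], np.ndarray]) -> dict[str, float]:
    """Anderson-Darling, Cramer-von Mises, and KS statistics of a fitted CDF."""
    x = sample.values if isinstance(sample, SortedSample) else np.sort(np.asarray(sample, float))
    n = x.size
    u = np.asarray(cdf(x), dtype=float)
    if np.any((u <= 0.0) | (u >= 1.0)):
        import warnings

        warnings.warn("fitted CDF values hit 0 or 1; clamping for the statistics", RuntimeWarning)
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
    i = np.arange(1, n + 1)
    g1 = -n - float(np.sum((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1])))) / n
    g2 = 1.0 / (12.0 * n) + float(np.sum((u - (2 * i - 1) / (2.0 * n)) ** 2))
    g3 = float(max(np.max(i / n - u), np.max(u - (i - 1) / n)))
    g3_p = float(special.kolmogorov(math.sqrt(n) * g3))
    return {"G1": g1, "G2": g2, "G3": g3, "G3_p": g3_p}


# ---------------------------------------------------------------------------
# baseline fitting
# ---------------------------------------------------------------------------


def _hessian_se(nll: Callable[[np.ndarray], float], p: np.ndarray) -> list[Optional[float]]:
    """SEs from the numeric observed information, central differences."""
    p = np.asarray(p, dtype=float)
    d = p.size
    step = 1e-4 * np.maximum(np.abs(p), 1.0)
    H = np.empty((d, d))
    try:
        for a in range(d):
            for b in range(a, d):
                ea = np.zeros(d); ea[a] = step[a]
                eb = np.zeros(d); eb[b] = step[b]
                H[a, b] = H[b, a] = (
                    nll(p + ea + eb) - nll(p + ea - eb) - nll(p - ea + eb) + nll(p - ea - eb)
                ) / (4.0 * step[a] * step[b])
        var = np.diag(np.linalg.inv(H))
        return [float(math.sqrt(v)) if v > 0 else None for v in var]
    except (np.linalg.LinAlgError, ValueError, FloatingPointError):
        return [None] * d


def _fit_gd(x: np.ndarray) -> FittedModel:
    res = _gd_fit(x, "MLE", n_starts=9, compute_se=True)
    if not res.converged:
        raise RuntimeError("GD maximum-likelihood fit did not converge")
    from .distribution import gd as _gd

    law = _gd(res.theta, res.k)
    se = res.standard_errors or (None, None)
    return FittedModel(
        name="GD", n_params=2,
        params={"theta": res.theta, "k": res.k},
        standard_errors={"theta": se[0], "k": se[1]},
        loglik=-neg_log_likelihood(x, res.theta, res.k),
        cdf=law.cdf, pdf=law.pdf,
    )


def _fit_ed(x: np.ndarray) -> FittedModel:
    # closed-form MLE for the exponential rate
    a = 1.0 / float(np.mean(x))
    n = x.size
    loglik = n * math.log(a) - a * float(np.sum(x))
    frozen = stats.expon(scale=1.0 / a)
    return FittedModel(
        "ED", 1, {"a": a}, {"a": a / math.sqrt(n)}, loglik, frozen.cdf, frozen.pdf
    )


def _fit_ld(x: np.ndarray) -> FittedModel:
    """Lindley: f = alpha^2 (1 + x) e^(-alpha x) / (1 + alpha); closed-form MLE."""
    m = float(np.mean(x))
    alpha = (-(m - 1.0) + math.sqrt((m - 1.0) ** 2 + 8.0 * m)) / (2.0 * m)

    def logpdf(t, a):
        return 2.0 * np.log(a) + np.log1p(t) - a * t - np.log1p(a)

    loglik = float(np.sum(logpdf(x, alpha)))
    se = _hessian_se(lambda q: -float(np.sum(logpdf(x, q[0]))), np.array([alpha]))

    def cdf(t, a=alpha):
        t = np.asarray(t, dtype=float)
        return 1.0 - (1.0 + a * t / (1.0 + a)) * np.exp(-a * t)

    def pdf(t, a=alpha):
        return np.exp(logpdf(np.asarray(t, dtype=float), a))

    return FittedModel("LD", 1, {"alpha": alpha}, {"alpha": se[0]}, loglik, cdf, pdf)


def _fit_md(x: np.ndarray) -> FittedModel:
    """Maxwell: f = 4/sqrt(pi) a^(3/2) x^2 e^(-a x^2); closed-form MLE a = 3n/(2 sum x^2)."""
    n = x.size
    a = 1.5 * n / float(np.sum(x * x))

    def logpdf(t, q):
        return math.log(4.0 / math.sqrt(math.pi)) + 1.5 * np.log(q) + 2.0 * np.log(t) - q * t * t

    loglik = float(np.sum(logpdf(x, a)))
    se = _hessian_se(lambda q: -float(np.sum(logpdf(x, q[0]))), np.array([a]))

    def cdf(t, q=a):
        t = np.asarray(t, dtype=float)
        return special.gammainc(1.5, q * t * t)

    def pdf(t, q=a):
        return np.exp(logpdf(np.asarray(t, dtype=float), q))

    return FittedModel("MD", 1, {"a": a}, {"a": se[0]}, loglik, cdf, pdf)


def _scipy_fit(name, dist, x, param_names, fit_kwargs):
    """MLE via scipy's fitter with location pinned at zero."""
    fitted = dist.fit(x, **fit_kwargs)
    frozen = dist(*fitted)
    loglik = float(np.sum(frozen.logpdf(x)))
    # free parameters are everything except the pinned loc (second from last)
    free = [v for j, v in enumerate(fitted) if j != len(fitted) - 2]
    params = dict(zip(param_names, free))

    def nll(q):
        args = list(q[:-1]) + [0.0, q[-1]]
        v = -float(np.sum(dist.logpdf(x, *args)))
        return v if np.isfinite(v) else 1e12

    se_vals = _hessian_se(nll, np.asarray(free, dtype=float))
    return FittedModel(
        name, len(param_names), params, dict(zip(param_names, se_vals)),
        loglik, frozen.cdf, frozen.pdf,
    )


def _fit_fd(x: np.ndarray) -> FittedModel:
    # Frechet f = a b^a x^(-a-1) exp(-(b/x)^a): scipy's invweibull with loc=0
    return _scipy_fit("FD", stats.invweibull, x, ("a", "b"), {"floc": 0})


def _fit_lod(x: np.ndarray) -> FittedModel:
    # Lomax f = (lam/beta) (1 + x/beta)^(-lam-1)
    return _scipy_fit("LoD", stats.lomax, x, ("lam", "beta"), {"floc": 0})


def _fit_hld(x: np.ndarray) -> FittedModel:
    return _scipy_fit("HLD", stats.halflogistic, x, ("scale",), {"floc": 0})


def baseline_panel() -> dict[str, Callable[[np.ndarray], FittedModel]]:
    """Registry of candidate-model builders, keyed by short model name."""
    return {
        "GD": _fit_gd,
        "ED": _fit_ed,
        "FD": _fit_fd,
        "LD": _fit_ld,
        "LoD": _fit_lod,
        "HLD": _fit_hld,
        "MD": _fit_md,
    }


def compare(sample, models: Optional[Sequence[str]] = None) -> GofReport:
    """Fit each requested model by MLE and tabulate all criteria.

    Models that fail to fit are flagged (dropped from the table with a
    warning); if every model fails a RuntimeError is raised.
    """
    x = sample.values if isinstance(sample, SortedSample) else np.sort(np.asarray(sample, float))
    n = x.size
    panel = baseline_panel()
    names = list(models) if models else list(BASELINE_ORDER)
    unknown = [m for m in names if m not in panel]
    if unknown:
        raise KeyError(f"unknown model(s) {unknown}; available: {sorted(panel)}")

    rows, fitted = {}, {}
    for name in names:
        try:
            fm = panel[name](x)
        except Exception as exc:  # noqa: BLE001 - per-model failure is reportable
            import warnings

            warnings.warn(f"model {name} failed to fit: {exc}", RuntimeWarning)
            continue
        fitted[name] = fm
        row = {"neg_loglik": -fm.loglik}
        row.update(information_criteria(fm.loglik, fm.n_params, n))
        row.update(gof_statistics(x, fm.cdf))
        rows[name] = row
    if not rows:
        raise RuntimeError("every candidate model failed to fit")
    table = pd.DataFrame.from_dict(rows, orient="index")
    rank_cols = ["Cr1", "Cr2", "Cr3", "Cr4", "G1", "G2", "G3"]
    ranks = table[rank_cols].rank(method="average")
    return GofReport(table=table, ranks=ranks, fitted=fitted)


def ttt_and_pp(sample, cdf: Optional[Callable] = None):
    """Diagnostic plot coordinates: scaled TTT transform and P-P pairs.

    TTT: (i/n, [sum_{j<=i} x_(j) + (n-i) x_(i)] / sum_j x_(j)) for i=1..n.
    P-P: ((i - 0.5)/n, F_hat(x_(i))) when a fitted CDF is supplied.
    """
    x = sample.values if isinstance(sample, SortedSample) else np.sort(np.asarray(sample, float))
    n = x.size
    i = np.arange(1, n + 1)
    csum = np.cumsum(x)
    ttt = pd.DataFrame({"u": i / n, "ttt": (csum + (n - i) * x) / csum[-1]})
    pp = None
    if cdf is not None:
        pp = pd.DataFrame({"expected": (i - 0.5) / n, "observed": np.asarray(cdf(x), dtype=float)})
    return ttt, pp
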