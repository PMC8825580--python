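"""Survival primitives: Kaplan-Meier, log-rank, univariate Cox, maxstat, BH.

These are the building blocks of the prognostic risk scores: per-gene
expression cutpoints come from maximally selected rank statistics (the maximum
standardized log-rank statistic over candidate dichotomies, with a
selection-adjusted p-value), and the score weights are Cox log hazard ratios
fitted on those dichotomies.

Conventions
-----------
* Breslow tie handling in the Cox partial likelihood.
* At a tied time, events precede censoring (both remain in the risk set at
  that time, as in the standard product-limit construction).
* Maxstat candidate cutpoints are the observed covariate values inside the
  ``eps`` quantile window (default (0.1, 0.9)); the dichotomy is
  ``x > cutpoint``.
* The default selection-adjusted p-value is the Lausen-Schumacher improved
  Bonferroni approximation evaluated at the actual candidate split sizes; an
  Ornstein-Uhlenbeck bridge approximation and a permutation test are
  available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ArgumentError, DataError

__all__ = [
    "KaplanMeierEstimate",
    "LogrankResult",
    "CoxFit",
    "MaxstatResult",
    "km_estimate",
    "logrank_test",
    "cox_beta_binary",
    "maxstat_cutpoint",
    "bh_adjust",
]


@dataclass
class SurvivalCohort:
    """Follow-up times, event indicators and aligned expression per patient.

    ``expression`` is a genes x patients DataFrame whose columns align with
    ``patient_ids``; times are months, event 1 = death.
    """

    patient_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        self.time, self.event = _as_surv(self.time, self.event)
        if len(self.patient_ids) != len(self.time):
            raise ArgumentError("patient_ids and time lengths differ")
        if list(self.expression.columns) != list(self.patient_ids):
            raise ArgumentError("expression columns must align with patient_ids")

    @property
    def n(self) -> int:
        return len(self.patient_ids)


def _as_surv(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or time.shape != event.shape:
        raise ArgumentError("time and event must be aligned 1-D arrays")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise DataError("survival times must be finite and > 0")
    if not np.all(np.isin(event, (0, 1))):
        raise DataError("event indicators must be 0/1")
    return time, event.astype(int)


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KaplanMeierEstimate:
    """Product-limit estimate: right-continuous step function S(t)."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def __call__(self, t: float | np.ndarray) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate([[1.0], self.survival])[idx]
        return float(s) if s.ndim == 0 else s

    @property
    def support(self) -> np.ndarray:
        return self.times


def km_estimate(time, event) -> KaplanMeierEstimate:
    """Kaplan-Meier product-limit estimator over distinct event times."""
    time, event = _as_surv(time, event)
    if len(time) < 1:
        raise ArgumentError("km_estimate: need n >= 1")
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq, first = np.unique(t, return_index=True)
    n = len(t)
    d = np.zeros(len(uniq))
    np.add.at(d, np.searchsorted(uniq, t[e == 1]), 1.0)
    at_risk = n - first
    keep = d > 0
    uniq, d, at_risk = uniq[keep], d[keep], at_risk[keep]
    surv = np.cumprod(1.0 - d / at_risk)
    return KaplanMeierEstimate(uniq, surv, at_risk.astype(int), d.astype(int))


# ---------------------------------------------------------------------------
# log-rank machinery (shared with maxstat)


def _logrank_uv(time, event, ind: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Observed-minus-expected and hypergeometric variance, per column of ind.

    ``ind`` is an (n, m) 0/1 matrix of group-1 membership; returns (U, V)
    of shape (m,), summed over distinct event times.
    """
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    ind = np.asarray(ind, dtype=float)[order]
    n = len(t)
    uniq, first = np.unique(t, return_index=True)
    suffix = np.cumsum(ind[::-1], axis=0)[::-1]
    idx = np.searchsorted(uniq, t)
    d = np.zeros(len(uniq))
    o1 = np.zeros((len(uniq), ind.shape[1]))
    ev = e == 1
    np.add.at(d, idx[ev], 1.0)
    np.add.at(o1, idx[ev], ind[ev])
    nd = (n - first).astype(float)
    n1 = suffix[first]
    keep = d > 0
    d, nd, n1, o1 = d[keep], nd[keep], n1[keep], o1[keep]
    frac = n1 / nd[:, None]
    U = (o1 - d[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore"):
        tiecorr = np.where(nd > 1, (nd - d) / np.maximum(nd - 1.0, 1.0), 0.0)
    V = (d[:, None] * tiecorr[:, None] * frac * (1.0 - frac)).sum(axis=0)
    return U, V


def logrank_z_splits(time, event, x, candidates) -> np.ndarray:
    """Standardized log-rank Z for every dichotomy ``x > c``, vectorised.

    Splits whose variance vanishes (degenerate risk sets) return Z = 0.
    """
    time, event = _as_surv(time, event)
    x = np.asarray(x, dtype=float)
    candidates = np.asarray(candidates, dtype=float)
    ind = (x[:, None] > candidates[None, :]).astype(float)
    U, V = _logrank_uv(time, event, ind)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(V > 0, U / np.sqrt(np.where(V > 0, V, 1.0)), 0.0)
    return z


@dataclass
class LogrankResult:
    chi_square: float
    p_value: float
    z: float


def logrank_test(time, event, group) -> LogrankResult:
    """Two-group log-rank test; Z is signed for group 1 (observed - expected)."""
    time, event = _as_surv(time, event)
    group = np.asarray(group)
    values = np.unique(group)
    if len(values) != 2:
        raise ArgumentError("logrank_test: need exactly two groups")
    ind = (group == values[1]).astype(float)[:, None]
    U, V = _logrank_uv(time, event, ind)
    if V[0] <= 0:
        return LogrankResult(0.0, 1.0, 0.0)
    z = float(U[0] / np.sqrt(V[0]))
    chi2 = z * z
    p = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(chi2, p, z)


# ---------------------------------------------------------------------------
# univariate Cox (binary covariate, Breslow ties)


@dataclass
class CoxFit:
    beta: float
    se: float
    converged: bool
    n_iter: int

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.beta))


def cox_beta_binary(
    time, event, x, tol: float = 1e-8, max_iter: int = 50, clamp: float = 10.0
) -> CoxFit:
    """Newton-Raphson on the Breslow partial likelihood for a 0/1 covariate.

    Monotone-likelihood separation is flagged when |beta| exceeds ``clamp``;
    beta is clamped there and ``converged`` set False.
    """
    time, event = _as_surv(time, event)
    x = np.asarray(x)
    if len(np.unique(x)) != 2:
        raise ArgumentError("cox_beta_binary: covariate must take both values")
    if event.sum() == 0:
        raise ArgumentError("cox_beta_binary: no events")
    xb = (x == np.max(x)).astype(float)
    order = np.argsort(time, kind="stable")
    t, e, xv = time[order], event[order], xb[order]
    n = len(t)
    uniq, first = np.unique(t, return_index=True)
    idx = np.searchsorted(uniq, t)
    d = np.zeros(len(uniq))
    d1 = np.zeros(len(uniq))
    ev = e == 1
    np.add.at(d, idx[ev], 1.0)
    np.add.at(d1, idx[ev], xv[ev])
    r1 = np.cumsum(xv[::-1])[::-1][first]  # at-risk in group 1
    r0 = (n - first) - r1
    keep = d > 0
    d, d1, r1, r0 = d[keep], d1[keep], r1[keep], r0[keep]

    beta = 0.0
    for it in range(1, max_iter + 1):
        w = r1 * np.exp(beta)
        denom = w + r0
        mu = w / denom
        U = float((d1 - d * mu).sum())
        I = float((d * mu * (1.0 - mu)).sum())
        if abs(U) < tol:
            se = 1.0 / np.sqrt(I) if I > 0 else np.inf
            return CoxFit(beta, se, True, it)
        if I <= 0:
            break
        beta += U / I
        if abs(beta) > clamp:
            beta = float(np.clip(beta, -clamp, clamp))
            w = r1 * np.exp(beta)
            mu = w / (w + r0)
            I = float((d * mu * (1.0 - mu)).sum())
            se = 1.0 / np.sqrt(I) if I > 0 else np.inf
            return CoxFit(beta, se, False, it)
    se = 1.0 / np.sqrt(I) if I > 0 else np.inf
    return CoxFit(beta, se, False, max_iter)


def cox_beta_continuous(
    time, event, x, tol: float = 1e-8, max_iter: int = 50, clamp: float = 10.0
) -> CoxFit:
    """Univariate Cox fit for a continuous covariate (Breslow ties).

    The covariate is standardised internally for numerical stability; the
    returned beta is on the original scale.
    """
    time, event = _as_surv(time, event)
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ArgumentError("cox_beta_continuous: covariate is constant")
    if event.sum() == 0:
        raise ArgumentError("cox_beta_continuous: no events")
    xs = (x - x.mean()) / sd
    order = np.argsort(time, kind="stable")
    t, e, xv = time[order], event[order], xs[order]
    uniq, first = np.unique(t, return_index=True)
    idx = np.searchsorted(uniq, t)
    ev = e == 1
    d = np.zeros(len(uniq))
    sx = np.zeros(len(uniq))
    np.add.at(d, idx[ev], 1.0)
    np.add.at(sx, idx[ev], xv[ev])
    keep = d > 0

    beta = 0.0
    for it in range(1, max_iter + 1):
        w = np.exp(beta * xv)
        s0 = np.cumsum(w[::-1])[::-1][first]
        s1 = np.cumsum((w * xv)[::-1])[::-1][first]
        s2 = np.cumsum((w * xv * xv)[::-1])[::-1][first]
        mu = s1[keep] / s0[keep]
        U = float((sx[keep] - d[keep] * mu).sum())
        I = float((d[keep] * (s2[keep] / s0[keep] - mu * mu)).sum())
        if abs(U) < tol:
            se = 1.0 / np.sqrt(I) if I > 0 else np.inf
            return CoxFit(beta / sd, se / sd, True, it)
        if I <= 0:
            break
        beta += U / I
        if abs(beta) > clamp:
            beta = float(np.clip(beta, -clamp, clamp))
            return CoxFit(beta / sd, np.inf, False, it)
    return CoxFit(beta / sd, np.inf, False, max_iter)


# ---------------------------------------------------------------------------
# maximally selected rank statistics


@dataclass
class MaxstatResult:
    cutpoint: float
    max_statistic: float  # max |Z|
    p_value: float
    eps: tuple[float, float]
    method: str
    z: float = 0.0  # signed Z at the selected cutpoint
    candidates: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def lausen_schumacher_p(b: float, n: int, split_fracs: Sequence[float]) -> float:
    """Improved-Bonferroni p-value for the maximally selected log-rank |Z|.

    ``split_fracs`` are the candidate left-group fractions m_i/n; the bound
    sums bivariate-normal crossing terms over adjacent splits.
    """
    if b <= 0:
        return 1.0
    m = np.unique(np.round(np.asarray(split_fracs, dtype=float) * n).astype(int))
    m = m[(m >= 1) & (m <= n - 1)]
    p = 2.0 * stats.norm.sf(b)
    if len(m) > 1:
        m1, m2 = m[:-1].astype(float), m[1:].astype(float)
        t = np.sqrt(1.0 - m1 * (n - m2) / (m2 * (n - m1)))
        p += float(
            np.sum(np.exp(-b * b / 2.0) / np.pi * (t - (b * b / 4.0 - 1.0) * t**3 / 6.0))
        )
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def ou_bridge_p(b: float, eps: tuple[float, float] = (0.1, 0.9)) -> float:
    """Ornstein-Uhlenbeck bridge approximation (quantile-window form)."""
    if b <= 1e-8:
        return 1.0
    lo, hi = eps
    p = 4.0 * stats.norm.pdf(b) / b + stats.norm.pdf(b) * (b - 1.0 / b) * np.log(
        ((1 - lo) * hi) / (lo * (1 - hi))
    )
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def maxstat_cutpoint(
    time,
    event,
    x,
    eps: tuple[float, float] = (0.1, 0.9),
    method: str = "approx",
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> MaxstatResult:
    """Maximally selected log-rank statistic over observed-value cutpoints.

    Candidates are the observed ``x`` values within the ``eps`` quantile
    window (values tied with the overall maximum are excluded so both groups
    stay non-empty).  The cutpoint is the argmax of |Z| (ties -> smaller
    value).  ``method="approx"`` uses the improved-Bonferroni approximation;
    ``method="permutation"`` permutes the covariate against the (time, event)
    pairs ``n_perm`` times.
    """
    time, event = _as_surv(time, event)
    x = np.asarray(x, dtype=float)
    if len(x) < 10:
        raise ArgumentError("maxstat_cutpoint: need >= 10 observations")
    if np.all(x == x[0]):
        raise ArgumentError("maxstat_cutpoint: covariate is constant")
    if not (0 <= eps[0] < eps[1] <= 1):
        raise ArgumentError("eps must satisfy 0 <= lo < hi <= 1")
    if method not in ("approx", "permutation"):
        raise ArgumentError(f"unknown method {method!r}")
    lo, hi = np.quantile(x, eps)
    candidates = np.unique(x[(x >= lo) & (x <= hi)])
    candidates = candidates[candidates < x.max()]
    if len(candidates) < 2:
        raise ArgumentError(
            "maxstat_cutpoint: need >= 2 distinct values inside the eps window"
        )
    z = logrank_z_splits(time, event, x, candidates)
    best = int(np.argmax(np.abs(z)))
    b = float(np.abs(z[best]))
    if method == "approx":
        fracs = [(x <= c).mean() for c in candidates]
        p = lausen_schumacher_p(b, len(x), fracs)
    else:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        exceed = 0
        for _ in range(n_perm):
            xp = gen.permutation(x)
            zp = logrank_z_splits(time, event, xp, candidates)
            if np.abs(zp).max() >= b - 1e-12:
                exceed += 1
        p = (1.0 + exceed) / (n_perm + 1.0)
    return MaxstatResult(
        cutpoint=float(candidates[best]),
        max_statistic=b,
        p_value=p,
        eps=eps,
        method=method,
        z=float(z[best]),
        candidates=candidates,
    )


# ---------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ArgumentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
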