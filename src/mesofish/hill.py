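"""Incidence-based Hill-number rarefaction and extrapolation (q = 0, 1, 2).

Inputs are incidence frequencies: for T sampling units (stations) and
S_obs observed clusters, Y_i counts the units in which cluster i was
detected.  Richness (q = 0) interpolates exactly by the hypergeometric
identity and extrapolates with the Chao2 unseen-cluster estimate; Shannon
(q = 1) and Simpson (q = 2) diversities follow the standard
incidence-frequency estimators (expected-frequency-counts interpolation;
entropy-estimator / closed-form inverse-Simpson extrapolation).  The full
formula sheet lives in ``docs/hill_formulas.md``.

When the data carry no evidence of unseen clusters (no uniques, Q1 = 0)
all three asymptotes reduce to the observed values and the extrapolated
curves stay flat — the same convention Chao2 itself follows.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom

from mesofish.io import ValidationError


@dataclass
class IncidenceVector:
    """Incidence frequencies for one group of sampling units."""

    T: int
    Y: np.ndarray

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=int)
        if self.T < 1:
            raise ValidationError("need at least one sampling unit")
        if self.Y.size and (self.Y.min() < 1 or self.Y.max() > self.T):
            raise ValidationError("incidence frequencies must lie in 1..T")

    @property
    def S_obs(self) -> int:
        return int(self.Y.size)

    @property
    def U(self) -> int:
        """Total incidence count (sum of Y)."""
        return int(self.Y.sum())

    @property
    def Q1(self) -> int:
        return int((self.Y == 1).sum())

    @property
    def Q2(self) -> int:
        return int((self.Y == 2).sum())


def to_incidence(matrix: pd.DataFrame) -> IncidenceVector:
    """Incidence vector from a sample x cluster matrix of one group.

    Rows are the group's sampling units; any positive value is a
    detection.  Clusters never detected are dropped.
    """
    if matrix.shape[0] == 0:
        raise ValidationError("no sampling units in group")
    Y = (matrix.to_numpy() > 0).sum(axis=0)
    return IncidenceVector(T=matrix.shape[0], Y=Y[Y > 0])


@dataclass
class DiversityCurve:
    q: int
    grid: np.ndarray
    estimates: np.ndarray
    asymptote: float
    T: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "q": self.q, "t": self.grid, "estimate": self.estimates,
            "kind": np.where(self.grid <= self.T, "interpolated",
                             "extrapolated"),
        })


# ---------------------------------------------------------------------------
# Asymptotic estimators
# ---------------------------------------------------------------------------

def _q0_unseen(inc: IncidenceVector) -> float:
    """Chao2 unseen-cluster correction term."""
    T, Q1, Q2 = inc.T, inc.Q1, inc.Q2
    if T < 2 or Q1 == 0:
        return 0.0
    if Q2 > 0:
        return (T - 1) / T * Q1 ** 2 / (2 * Q2)
    return (T - 1) / T * Q1 * (Q1 - 1) / 2


def chao2_asymptote(inc: IncidenceVector) -> float:
    """Chao2 asymptotic cluster richness (bias-corrected when Q2 = 0)."""
    if inc.T < 2:
        raise ValidationError("Chao2 needs at least two sampling units")
    return inc.S_obs + _q0_unseen(inc)


def _entropy_cwj(inc: IncidenceVector) -> float:
    """Chao-Wang-Jost entropy estimator on the incidence frequencies
    (treating Y over T units like abundances over T draws)."""
    T, Y, Q1, Q2 = inc.T, inc.Y, inc.Q1, inc.Q2
    known = Y[Y <= T - 1]
    # sum_{k=Y_i}^{T-1} 1/k  via cumulative harmonic numbers
    harm = np.concatenate([[0.0], np.cumsum(1.0 / np.arange(1, T))])
    main = float(np.sum(known / T * (harm[T - 1] - harm[known - 1])))
    if Q1 == 0:
        return main
    if Q2 > 0:
        A = 2 * Q2 / ((T - 1) * Q1 + 2 * Q2)
    elif Q1 > 1:
        A = 2 / ((T - 1) * (Q1 - 1) + 2)
    else:
        A = 1.0
    if A >= 1.0:
        return main
    r = np.arange(1, T)
    corr = Q1 / T * (1 - A) ** (1 - T) * (
        -np.log(A) - np.sum((1 - A) ** r / r))
    return main + float(corr)


def shannon_asymptote(inc: IncidenceVector) -> float:
    """Asymptotic incidence-based Shannon diversity (exp entropy scale).

    The entropy-estimator value is clipped into [observed Shannon, Chao2]:
    the order-q Hill inequality is a property of the true diversities, and
    harmonizing the separately-estimated asymptotes keeps it for the
    reported profile.
    """
    T, U = inc.T, inc.U
    if U == 0:
        raise ValidationError("empty incidence vector")
    p = inc.Y / U
    observed = float(np.exp(-np.sum(p * np.log(p))))
    if inc.Q1 == 0:
        return observed
    H = T / U * _entropy_cwj(inc) + np.log(U / T)
    upper = chao2_asymptote(inc) if T >= 2 else np.inf
    return float(np.clip(np.exp(H), observed, upper))


def simpson_asymptote(inc: IncidenceVector) -> float:
    """Asymptotic incidence-based inverse-Simpson diversity, clipped into
    [observed Simpson, Shannon asymptote] (see :func:`shannon_asymptote`)."""
    T, U, Y = inc.T, inc.U, inc.Y
    if U == 0:
        raise ValidationError("empty incidence vector")
    p = Y / U
    observed = 1.0 / float(np.sum(p ** 2))
    ss = float(np.sum(Y * (Y - 1.0)))
    if inc.Q1 == 0 or ss == 0 or T < 2:
        return observed
    est = (T - 1) / T * U ** 2 / ss
    return float(np.clip(est, observed, shannon_asymptote(inc)))


def asymptote(inc: IncidenceVector, q: int) -> float:
    if q == 0:
        return chao2_asymptote(inc)
    if q == 1:
        return shannon_asymptote(inc)
    if q == 2:
        return simpson_asymptote(inc)
    raise ValidationError(f"unsupported order q={q}")


# ---------------------------------------------------------------------------
# Rarefaction / extrapolation
# ---------------------------------------------------------------------------

def _interp_q0(inc: IncidenceVector, t: int) -> float:
    # S_obs - sum_i C(T-Y_i, t) / C(T, t), stable in log space
    T, Y = inc.T, inc.Y
    keep = (T - Y) >= t
    if not keep.any():
        return float(inc.S_obs)
    a = T - Y[keep]
    logs = (gammaln(a + 1) - gammaln(t + 1) - gammaln(a - t + 1)
            - (gammaln(T + 1) - gammaln(t + 1) - gammaln(T - t + 1)))
    return float(inc.S_obs - np.exp(logs).sum())


def _expected_counts(inc: IncidenceVector, t: int) -> np.ndarray:
    """E[Q_k(t)] for k = 0..t under hypergeometric subsampling."""
    ks = np.arange(t + 1)
    pmf = hypergeom.pmf(ks[None, :], inc.T, inc.Y[:, None], t)
    return pmf.sum(axis=0)


def _interp(inc: IncidenceVector, q: int, t: int) -> float:
    T, U = inc.T, inc.U
    if t == T:  # continuity: observed values, exactly
        p = inc.Y / U
        if q == 0:
            return float(inc.S_obs)
        if q == 1:
            return float(np.exp(-np.sum(p * np.log(p))))
        return float(1.0 / np.sum(p ** 2))
    if q == 0:
        return _interp_q0(inc, t)
    Ut = t * U / T
    if q == 2:
        # 1 / sum_k (k/Ut)^2 Q_k(t) via hypergeometric moments
        mean = t * inc.Y / T
        var = mean * (T - inc.Y) / T * (T - t) / (T - 1)
        return float(Ut ** 2 / np.sum(var + mean ** 2))
    Qk = _expected_counts(inc, t)[1:]
    k = np.arange(1, t + 1)
    H = -np.sum(np.where(Qk > 0, k / Ut * np.log(k / Ut) * Qk, 0.0))
    return float(np.exp(H))


def _extrap(inc: IncidenceVector, q: int, t: int) -> float:
    T, U, Y = inc.T, inc.U, inc.Y
    t_star = t - T
    if inc.Q1 == 0:  # no unseen evidence: flat extrapolation
        return _interp(inc, q, T)
    if q == 0:
        Q0 = _q0_unseen(inc)
        if Q0 == 0:
            return float(inc.S_obs)
        Q1 = inc.Q1
        return float(inc.S_obs + Q0 * (1 - (1 - Q1 / (Q1 + T * Q0)) ** t_star))
    if q == 1:
        w = t_star / t
        H_obs = -np.sum(Y / U * np.log(Y / U))
        H_inf = np.log(shannon_asymptote(inc))
        # never above the richness curve at the same effort
        return float(min(np.exp((1 - w) * H_obs + w * H_inf),
                         _extrap(inc, 0, t)))
    # q = 2: closed form valid at any t, increasing towards its asymptote;
    # capped by the Shannon curve at the same effort (the separately
    # estimated curves may otherwise cross)
    ss = float(np.sum(Y * (Y - 1.0)))
    inv = T / (t * U) + (t - 1) / t * ss * T ** 2 / (U ** 2 * T * (T - 1))
    return float(min(1.0 / inv, simpson_asymptote(inc), _extrap(inc, 1, t)))


def rarefy_extrapolate(inc: IncidenceVector, q: int,
                       grid: Iterable[int] | None = None) -> DiversityCurve:
    """Diversity of order ``q`` along a grid of sampling-unit counts.

    The default grid spans 1..2T (the conventional reliability limit for
    extrapolation).  Interpolated values (t <= T) are exact expectations
    under subsampling without replacement; the curve passes through the
    observed value at t = T.
    """
    if q not in (0, 1, 2):
        raise ValidationError(f"unsupported order q={q}")
    if inc.S_obs == 0:
        raise ValidationError("empty incidence vector")
    if grid is None:
        grid = np.arange(1, 2 * inc.T + 1)
    grid = np.asarray(list(grid), dtype=int)
    if grid.size == 0 or grid.min() < 1:
        raise ValidationError("grid values must be integers >= 1")
    est = np.array([
        _interp(inc, q, int(t)) if t <= inc.T else _extrap(inc, q, int(t))
        for t in grid
    ])
    return DiversityCurve(q=q, grid=grid, estimates=est,
                          asymptote=asymptote(inc, q), T=inc.T)
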