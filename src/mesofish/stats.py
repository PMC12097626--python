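"""Community matrices, dissimilarities, ordination and permutation tests.

The beta-diversity toolkit the two-island comparison runs on: cumulative
ZOTU-occurrence aggregation to family/FE units, Jaccard / Bray-Curtis /
Gower dissimilarities, non-metric multidimensional scaling (Kruskal
stress-1, isotonic fit), one-way PERMANOVA with permutation p-values,
multivariate dispersion homogeneity (group-centroid distances in a
principal-coordinates embedding that retains negative eigenvalues),
environmental/indicator vector fitting onto ordinations, and a
variance-inflation-factor screen for the environment table.

Permutation p-values follow the add-one convention (1 + hits)/(1 + n),
so 999 permutations floor at p = 0.001.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import factorial
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression

from mesofish.io import ValidationError, ZotuTable

log = logging.getLogger("mesofish")


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate(table: ZotuTable, unit_map: Mapping[str, str],
              binary: bool = False, drop_unmapped: bool = False
              ) -> pd.DataFrame:
    """Sample x unit cumulative-occurrence matrix.

    ``value(u, s)`` counts the distinct ZOTUs of unit ``u`` (family, FE or
    cluster) detected in sample ``s``; ``binary=True`` reduces it to
    presence.  Unmapped ZOTUs are an error unless ``drop_unmapped``.
    """
    unmapped = [z for z in table.zotu_ids if z not in unit_map]
    if unmapped and not drop_unmapped:
        raise ValidationError(
            f"unmapped ZOTU(s) {unmapped[:5]}; pass drop_unmapped=True to "
            f"discard them")
    detected = table.detected()
    detected = detected.loc[[z for z in table.zotu_ids if z in unit_map]]
    units = pd.Series({z: unit_map[z] for z in detected.index})
    out = detected.groupby(units).sum().T.astype(int)
    out.index.name = "sample_id"
    if binary:
        out = (out > 0).astype(int)
    return out


# ---------------------------------------------------------------------------
# Dissimilarities
# ---------------------------------------------------------------------------

def dissimilarity(matrix: pd.DataFrame, index: str) -> DistanceMatrix:
    """Sample x sample dissimilarity matrix.

    ``jaccard`` works on the binary view, ``bray_curtis`` on counts, and
    ``gower`` on mixed quantitative/categorical tables (range-scaled
    absolute differences and 0/1 mismatches averaged over non-missing
    variables).
    """
    ids = [str(s) for s in matrix.index]
    if index == "jaccard":
        X = (matrix.to_numpy() > 0)
        d = squareform(pdist(X, metric="jaccard"), checks=False)
        d = np.nan_to_num(d, nan=0.0)
    elif index == "bray_curtis":
        X = matrix.to_numpy(dtype=float)
        if (X < 0).any():
            raise ValidationError("Bray-Curtis needs non-negative values")
        with np.errstate(invalid="ignore"):
            d = squareform(pdist(X, metric="braycurtis"), checks=False)
        if np.isnan(d).any():
            log.warning("Bray-Curtis between all-zero samples set to 0")
            d = np.nan_to_num(d, nan=0.0)
    elif index == "gower":
        d = _gower(matrix)
    else:
        raise ValidationError(f"unknown dissimilarity index {index!r}")
    return DistanceMatrix(d, ids=ids)


def _gower(df: pd.DataFrame) -> np.ndarray:
    n = df.shape[0]
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col in df.columns:
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            x = s.to_numpy(dtype=float)
            ok = ~np.isnan(x)
            rng = np.nanmax(x) - np.nanmin(x) if ok.any() else 0.0
            if rng == 0:
                log.warning("Gower: constant variable %r contributes 0", col)
                contrib = np.zeros((n, n))
            else:
                contrib = np.abs(x[:, None] - x[None, :]) / rng
            valid = ok[:, None] & ok[None, :]
        else:
            vals = s.astype(object).to_numpy()
            ok = np.array([not pd.isna(v) for v in vals])
            contrib = (vals[:, None] != vals[None, :]).astype(float)
            valid = ok[:, None] & ok[None, :]
        num += np.where(valid, np.nan_to_num(contrib), 0.0)
        den += valid
    if (den == 0).any():
        raise ValidationError("Gower: some sample pair shares no variable")
    d = num / den
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coords: pd.DataFrame
    stress: float
    n_restarts: int
    converged: bool
    seed: int


def _pcoa_coords(D: np.ndarray, k: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1][:k]
    return vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))


def _stress1(dhat: np.ndarray, dconf: np.ndarray) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 and the isotonic disparities."""
    iso = IsotonicRegression(increasing=True)
    theta = iso.fit_transform(dhat, dconf)
    denom = float(np.sum(dconf ** 2))
    if denom == 0:
        return 1.0, theta
    return float(np.sqrt(np.sum((dconf - theta) ** 2) / denom)), theta


def nmds(dm: DistanceMatrix, k: int = 2, n_restarts: int = 20,
         seed: int = 0, max_iter: int = 200, tol: float = 1e-7
         ) -> OrdinationResult:
    """Non-metric multidimensional scaling by SMACOF with isotonic fits.

    Minimizes Kruskal stress-1 over ``n_restarts`` random starts plus one
    metric (principal-coordinates) start; the best configuration is
    centered and rotated to its principal axes.  Deterministic per seed.
    """
    n = dm.shape[0]
    if n < k + 1:
        raise ValidationError(f"NMDS in {k} dimensions needs > {k} samples")
    rng = np.random.default_rng(seed)
    dhat = squareform(dm.data, checks=False)
    iu = np.triu_indices(n, 1)

    def run(X: np.ndarray) -> tuple[float, np.ndarray, bool]:
        prev = np.inf
        for _ in range(max_iter):
            diff = X[:, None, :] - X[None, :, :]
            dconf_m = np.sqrt((diff ** 2).sum(-1))
            dconf = dconf_m[iu]
            stress, theta = _stress1(dhat, dconf)
            if prev - stress < tol:
                return stress, X, True
            prev = stress
            theta_m = np.zeros((n, n))
            theta_m[iu] = theta
            theta_m += theta_m.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dconf_m > 0, theta_m / dconf_m, 0.0)
            B = -ratio
            np.fill_diagonal(B, ratio.sum(axis=1))
            X = B @ X / n
        return prev, X, False

    starts = [_pcoa_coords(dm.data, k)]
    scale = max(dhat.max(), 1e-12)
    for _ in range(n_restarts):
        starts.append(rng.normal(scale=scale, size=(n, k)))
    best = (np.inf, None, False)
    for X0 in starts:
        stress, X, conv = run(X0.copy())
        if stress < best[0]:
            best = (stress, X, conv)
    stress, X, converged = best
    X = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    X = X @ vt.T
    for j in range(X.shape[1]):  # sign convention: largest loading positive
        if X[np.argmax(np.abs(X[:, j])), j] < 0:
            X[:, j] = -X[:, j]
    coords = pd.DataFrame(X, index=list(dm.ids),
                          columns=[f"NMDS{i + 1}" for i in range(k)])
    if not converged:
        log.warning("NMDS did not converge in any restart; returning best")
    return OrdinationResult(coords, float(stress), n_restarts, converged,
                            seed)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    F: float
    R2: float
    p: float
    df: tuple[int, int]
    n_permutations: int


def _check_grouping(ids: Sequence[str], grouping: Mapping[str, str]
                    ) -> np.ndarray:
    missing = [i for i in ids if i not in grouping]
    if missing:
        raise ValidationError(f"samples without group label: {missing[:5]}")
    return np.asarray([grouping[i] for i in ids])


def _permanova_stats(D2: np.ndarray, codes: np.ndarray, a: int
                     ) -> tuple[float, float]:
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(a):
        idx = np.flatnonzero(codes == g)
        if idx.size:
            ss_within += D2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    ss_between = ss_total - ss_within
    F = (ss_between / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 \
        else np.inf
    R2 = ss_between / ss_total if ss_total > 0 else 0.0
    return F, R2


def permanova(dm: DistanceMatrix, grouping: Mapping[str, str],
              n_perm: int | None = 999, seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``n_perm=None`` enumerates all label permutations (exact p; identity
    included in the reference set); otherwise Monte-Carlo permutations
    with the add-one convention.
    """
    labels = _check_grouping(dm.ids, grouping)
    groups, codes = np.unique(labels, return_counts=False), None
    groups, codes = np.unique(labels, return_inverse=True)
    a, n = len(groups), len(labels)
    if a < 2:
        raise ValidationError("PERMANOVA needs at least two groups")
    D2 = dm.data ** 2
    F_obs, R2 = _permanova_stats(D2, codes, a)
    if n_perm is None:
        total = factorial(n)
        hits = 0
        for perm in itertools.permutations(range(n)):
            F_p, _ = _permanova_stats(D2, codes[list(perm)], a)
            if F_p >= F_obs - 1e-12:
                hits += 1
        p = hits / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            F_p, _ = _permanova_stats(D2, rng.permutation(codes), a)
            if F_p >= F_obs - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        n_used = n_perm
    return PermanovaResult(float(F_obs), float(R2), float(p), (a - 1, n - a),
                           n_used)


# ---------------------------------------------------------------------------
# Dispersion homogeneity (betadisper)
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    distances: pd.Series
    F: float
    p: float                 # permutation p
    p_parametric: float


def dispersion_test(dm: DistanceMatrix, grouping: Mapping[str, str],
                    n_perm: int = 999, seed: int = 0) -> DispersionResult:
    """Homogeneity of multivariate dispersions around group centroids.

    Samples are embedded by principal coordinates keeping negative-
    eigenvalue axes; the distance of a sample to its group centroid is
    sqrt(max(0, d2_positive - d2_negative)).  F is the one-way ANOVA F on
    those distances; p comes from permuting group labels over the fixed
    distances (the convention of the reference implementation), with the
    parametric F-test p reported alongside.
    """
    from scipy.stats import f as f_dist

    labels = _check_grouping(dm.ids, grouping)
    groups, codes = np.unique(labels, return_inverse=True)
    if len(groups) < 2:
        raise ValidationError("dispersion test needs at least two groups")
    for g in range(len(groups)):
        if (codes == g).sum() < 2:
            raise ValidationError(
                f"group {groups[g]!r} has fewer than two samples")
    n = len(labels)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (dm.data ** 2) @ J
    vals, vecs = np.linalg.eigh(G)
    keep = np.abs(vals) > 1e-10 * max(np.abs(vals).max(), 1.0)
    vals, vecs = vals[keep], vecs[:, keep]
    coords = vecs * np.sqrt(np.abs(vals))
    pos = vals > 0
    dists = np.zeros(n)
    for g in range(len(groups)):
        idx = np.flatnonzero(codes == g)
        c = coords[idx].mean(axis=0)
        delta2 = (coords[idx] - c) ** 2
        d2 = delta2[:, pos].sum(1) - delta2[:, ~pos].sum(1)
        dists[idx] = np.sqrt(np.maximum(d2, 0.0))

    def anova_f(z: np.ndarray, codes: np.ndarray) -> float:
        grand = z.mean()
        ss_b = sum((codes == g).sum() * (z[codes == g].mean() - grand) ** 2
                   for g in range(len(groups)))
        ss_w = sum(((z[codes == g] - z[codes == g].mean()) ** 2).sum()
                   for g in range(len(groups)))
        eps = 1e-12 * max(float(np.sum(z ** 2)), 1.0)
        if ss_w <= eps:
            return np.inf if ss_b > eps else 0.0
        return (ss_b / (len(groups) - 1)) / (ss_w / (n - len(groups)))

    F_obs = anova_f(dists, codes)
    rng = np.random.default_rng(seed)
    hits = sum(anova_f(dists, rng.permutation(codes)) >= F_obs - 1e-12
               for _ in range(n_perm))
    p_perm = (1 + hits) / (1 + n_perm)
    dfn, dfd = len(groups) - 1, n - len(groups)
    p_param = float(f_dist.sf(F_obs, dfn, dfd)) if np.isfinite(F_obs) else 0.0
    return DispersionResult(pd.Series(dists, index=list(dm.ids)),
                            float(F_obs), float(p_perm), p_param)


# ---------------------------------------------------------------------------
# envfit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    name: str
    kind: str                     # vector | factor
    r2: float
    p: float
    direction: np.ndarray | None = None          # unit arrow (vectors)
    centroids: pd.DataFrame | None = None        # level centroids (factors)


def _vector_r2(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst == 0:
        return 0.0, np.zeros(X.shape[1])
    b, *_ = np.linalg.lstsq(X, yc, rcond=None)
    resid = yc - X @ b
    r2 = 1 - float(resid @ resid) / sst
    norm = np.linalg.norm(b)
    return max(r2, 0.0), (b / norm if norm > 0 else b)


def _factor_r2(X: np.ndarray, levels: np.ndarray) -> float:
    total = float(((X - X.mean(axis=0)) ** 2).sum())
    if total == 0:
        return 0.0
    within = 0.0
    for lv in np.unique(levels):
        sub = X[levels == lv]
        within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return max(1 - within / total, 0.0)


def envfit(ordination: OrdinationResult | pd.DataFrame,
           variables: pd.DataFrame, n_perm: int = 999,
           seed: int = 0) -> list[FitResult]:
    """Fit environment (or indicator-unit) variables onto an ordination.

    Quantitative variables get least-squares arrows with r2 = 1 - SSres /
    SStot; categorical variables get level centroids with r2 based on
    within-level coordinate deviations.  p-values permute the variable.
    """
    coords = ordination.coords if isinstance(ordination, OrdinationResult) \
        else ordination
    common = [s for s in coords.index if s in variables.index]
    if len(common) != len(coords.index):
        raise ValidationError("ordination and variable table sample ids "
                              "do not match")
    X = coords.loc[common].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    rng = np.random.default_rng(seed)
    results = []
    for name in variables.columns:
        col = variables.loc[common, name]
        if pd.api.types.is_numeric_dtype(col):
            y = col.to_numpy(dtype=float)
            r2, direction = _vector_r2(Xc, y)
            if np.ptp(y) == 0:
                log.warning("envfit: constant variable %r (r2 = 0)", name)
            hits = sum(
                _vector_r2(Xc, rng.permutation(y))[0] >= r2 - 1e-12
                for _ in range(n_perm))
            results.append(FitResult(name, "vector", r2,
                                     (1 + hits) / (1 + n_perm), direction))
        else:
            levels = col.astype(str).to_numpy()
            r2 = _factor_r2(Xc, levels)
            hits = sum(
                _factor_r2(Xc, rng.permutation(levels)) >= r2 - 1e-12
                for _ in range(n_perm))
            cent = pd.DataFrame(
                {lv: X[levels == lv].mean(axis=0)
                 for lv in np.unique(levels)},
                index=coords.columns).T
            results.append(FitResult(name, "factor", r2,
                                     (1 + hits) / (1 + n_perm),
                                     centroids=cent))
    return results


# ---------------------------------------------------------------------------
# VIF screen
# ---------------------------------------------------------------------------

def _encode(df: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    cols, names, owners = [], [], []
    for name in df.columns:
        s = df[name]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.to_numpy(dtype=float))
            names.append(name)
            owners.append(name)
        else:
            levels = sorted(s.astype(str).unique())
            for lv in levels[1:]:  # reference level dropped
                cols.append((s.astype(str) == lv).to_numpy(dtype=float))
                names.append(f"{name}[{lv}]")
                owners.append(name)
    return np.column_stack(cols), names, owners


def vif_screen(variables: pd.DataFrame, cutoff: float = 5.0
               ) -> tuple[list[str], pd.Series]:
    """Iteratively drop the variable with the largest VIF >= cutoff.

    Categorical variables are one-hot encoded against a reference level;
    a variable is dropped with all its dummy columns.  Ties resolve to
    the later column; perfect collinearity (infinite VIF) goes first.
    Returns (retained variable names, final per-column VIFs).
    """
    if variables.shape[1] < 2:
        raise ValidationError("VIF screen needs at least two variables")
    remaining = list(variables.columns)
    while True:
        X, names, owners = _encode(variables[remaining])
        n, m = X.shape
        if m < 2:
            vifs = pd.Series(np.ones(m), index=names)
            return remaining, vifs
        vifs = np.empty(m)
        for j in range(m):
            y = X[:, j] - X[:, j].mean()
            others = np.column_stack(
                [np.ones(n)] + [X[:, k] for k in range(m) if k != j])
            beta, *_ = np.linalg.lstsq(others, y, rcond=None)
            resid = y - others @ beta
            sst = float(y @ y)
            r2 = 1 - float(resid @ resid) / sst if sst > 0 else 0.0
            vifs[j] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        worst = None
        for j in range(m):  # ties resolve to the later column
            if vifs[j] >= cutoff and (worst is None or vifs[j] >= vifs[worst]):
                worst = j
        if worst is None:
            return remaining, pd.Series(vifs, index=names)
        dropped = owners[worst]
        log.info("VIF screen dropping %r (VIF=%.3g)", dropped, vifs[worst])
        remaining = [v for v in remaining if v != dropped]
        if len(remaining) < 2:
            return remaining, pd.Series(dtype=float)
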