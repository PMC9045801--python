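"""Permutation multivariate statistics for community matrices.

Distance computation, non-metric multidimensional scaling (NMDS) with
Kruskal stress-1, PERMANOVA via the distance-based linear model (Gower
centering + projection operators), the Mantel test, vector fitting of
environmental variables onto ordinations, and variation partitioning by
partial redundancy analysis with adjusted R². All permutation p-values
follow the (b + 1) / (m + 1) convention that counts the observed statistic
itself, so p is never below 1 / (m + 1); the seed of every test is recorded
in its result.

Supporting univariate tests (Spearman rank correlation, Kruskal-Wallis,
two-way ANOVA with Type II sums of squares) delegate to scipy and
statsmodels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "DistanceMatrix",
    "PermTestResult",
    "NMDSResult",
    "VarpartResult",
    "pairwise_distances",
    "nmds",
    "permanova",
    "mantel",
    "envfit",
    "variation_partitioning",
    "spearman",
    "group_tests",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal, with sample ids."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if data.shape != (n, n):
            raise ValueError(f"distance matrix shape {data.shape} does not match {n} ids")
        if not np.allclose(data, data.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if data.size and data.min() < 0:
            raise ValueError("distances must be non-negative")
        np.fill_diagonal(data, 0.0)
        self.data = data

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)


@dataclass(frozen=True)
class PermTestResult:
    """Outcome of one permutation test."""

    statistic: float
    effect_size: float
    n_permutations: int
    p_value: float
    seed: int | None = None
    name: str = ""


@dataclass
class NMDSResult:
    coordinates: np.ndarray  # samples x dims
    stress: float  # Kruskal stress-1
    n_starts: int
    converged: bool
    seed: int
    stress_history: list[float] = field(default_factory=list)
    metric_start_stress: float = float("nan")
    ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class VarpartResult:
    """Adjusted-R² decomposition over two predictor blocks.

    ``a`` is the pure fraction of block 1, ``c`` the pure fraction of block
    2, ``b`` the shared fraction, ``residual`` the unexplained remainder.
    By construction a + b = adjR²(X1), b + c = adjR²(X2) and
    a + b + c = adjR²(X1 ∪ X2).
    """

    a: float
    b: float
    c: float
    residual: float
    adj_r2_x1: float
    adj_r2_x2: float
    adj_r2_both: float
    r2_x1: float  # unadjusted R², exposed for diagnostics
    r2_x2: float
    r2_both: float
    p_values: dict


# ---------------------------------------------------------------------------
# distances


def pairwise_distances(
    matrix: np.ndarray | pd.DataFrame, metric: str = "euclidean", ids: list[str] | None = None
) -> DistanceMatrix:
    """All pairwise sample distances of a samples-by-features matrix.

    ``euclidean`` or ``bray_curtis`` (the latter requires non-negative
    features; Bray-Curtis = sum|x - y| / sum(x + y)).
    """
    if isinstance(matrix, pd.DataFrame):
        if ids is None:
            ids = [str(i) for i in matrix.index]
        matrix = matrix.to_numpy(dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows (samples)")
    if ids is None:
        ids = [f"s{i}" for i in range(matrix.shape[0])]
    if metric == "euclidean":
        cond = pdist(matrix, metric="euclidean")
    elif metric in ("bray_curtis", "bray"):
        if matrix.min() < 0:
            raise ValueError("Bray-Curtis requires non-negative features")
        cond = pdist(matrix, metric="braycurtis")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(list(ids), squareform(cond))


# ---------------------------------------------------------------------------
# NMDS


def _classical_mds(d: np.ndarray, dims: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _stress_and_disparities(delta: np.ndarray, dist: np.ndarray) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 with primary (weak) tie treatment.

    Disparities are the isotonic regression of the configuration distances
    on the dissimilarity order; within tied dissimilarities the order of
    the configuration distances is kept, so ties are not forced equal.
    """
    order = np.lexsort((dist, delta))
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(np.arange(len(delta)), dist[order])
    dhat = np.empty_like(fitted)
    dhat[order] = fitted
    denom = float((dist**2).sum())
    if denom <= 0:
        return 1.0, dhat
    stress = math.sqrt(float(((dist - dhat) ** 2).sum()) / denom)
    return stress, dhat


def _smacof_single(
    delta: np.ndarray, x0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list[float], bool]:
    n = x0.shape[0]
    iu = np.triu_indices(n, 1)
    x = x0.copy()
    dist = pdist(x)
    stress, dhat = _stress_and_disparities(delta, dist)
    history = [stress]
    converged = False
    for _ in range(max_iter):
        # Guttman transform toward the current disparities
        full_d = squareform(dist)
        full_dhat = squareform(dhat)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(full_d > 0, full_dhat / full_d, 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x_new = b @ x / n
        dist_new = pdist(x_new)
        stress_new, dhat_new = _stress_and_disparities(delta, dist_new)
        if stress_new > stress + 1e-15:
            # accept only non-increasing stress; stop otherwise
            break
        improved = stress - stress_new
        x, dist, dhat, stress = x_new, dist_new, dhat_new, stress_new
        history.append(stress)
        if improved < tol:
            converged = True
            break
    return x, stress, history, converged


def nmds(
    d: DistanceMatrix,
    dims: int = 2,
    n_starts: int = 8,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> NMDSResult:
    """Non-metric multidimensional scaling by stress majorisation.

    Alternates isotonic regression of configuration distances on the
    dissimilarity ranks with Guttman-transform configuration updates.
    Runs one start from the classical (metric) scaling solution plus
    ``n_starts`` random starts and returns the lowest-stress solution;
    within each start the recorded stress sequence is non-increasing.
    Non-convergence is flagged on the result, never raised.
    """
    n = d.n
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} samples for {dims}-D NMDS")
    delta = d.condensed()
    rng = np.random.default_rng(seed)
    scale = delta.max() if delta.max() > 0 else 1.0
    starts = [_classical_mds(d.data, dims)]
    for _ in range(n_starts):
        starts.append(rng.normal(scale=scale, size=(n, dims)))
    best = None
    metric_start_stress = float("nan")
    for k, x0 in enumerate(starts):
        x, stress, history, converged = _smacof_single(delta, x0, max_iter, tol)
        if k == 0:
            metric_start_stress = history[0]
        if best is None or stress < best[1]:
            best = (x, stress, history, converged)
    x, stress, history, converged = best
    return NMDSResult(
        coordinates=x - x.mean(axis=0),
        stress=stress,
        n_starts=len(starts),
        converged=converged,
        seed=seed,
        stress_history=history,
        metric_start_stress=metric_start_stress,
        ids=list(d.ids),
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d**2) @ j


def _hat(columns: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(columns)
    rank = int((np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())).sum())
    q = q[:, :rank]
    return q @ q.T


def _design_blocks(design: pd.DataFrame, interaction: bool) -> dict[str, np.ndarray]:
    """Dummy-coded (drop-first) column blocks per factor, plus interaction."""
    blocks: dict[str, np.ndarray] = {}
    for col in design.columns:
        levels = design[col].astype("category")
        if len(levels.cat.categories) < 2:
            raise ValueError(f"factor {col!r} has a single level")
        dummies = pd.get_dummies(levels, drop_first=True, dtype=float)
        blocks[col] = dummies.to_numpy()
    if interaction and design.shape[1] == 2:
        a, b = (blocks[c] for c in design.columns)
        inter = np.einsum("ij,ik->ijk", a, b).reshape(len(design), -1)
        blocks[":".join(design.columns)] = inter
    return blocks


def permanova(
    d: DistanceMatrix,
    design: pd.DataFrame | pd.Series | dict | list,
    n_perm: int = 9999,
    seed: int = 0,
    *,
    interaction: bool = True,
    exact: bool = False,
) -> dict[str, PermTestResult]:
    """Permutational multivariate ANOVA on a distance matrix.

    Sums of squares come from the Gower-centered matrix with projection
    operators of the dummy-coded design (the distance-based linear model),
    giving a pseudo-F per term; with two factors, term sums of squares are
    Type II (each main effect adjusted for the other, the interaction
    adjusted for both). p-values permute sample identities freely. With
    ``exact=True`` (one-way only, small n) every distinct label arrangement
    is enumerated and p is the exact fraction of arrangements with
    pseudo-F at least the observed one.
    """
    design = _as_design_frame(design, d.ids)
    if design.shape[1] not in (1, 2):
        raise ValueError("PERMANOVA supports 1 or 2 factors")
    n = d.n
    cells = design.groupby(list(design.columns), observed=True).size()
    if (cells < 1).any():
        raise ValueError("every design cell must be non-empty")
    g = _gower_center(d.data)
    ss_total = float(np.trace(g))
    blocks = _design_blocks(design, interaction)
    ones = np.ones((n, 1))
    term_names = list(blocks.keys())
    full = np.hstack([ones] + [blocks[t] for t in term_names])
    h_full = _hat(full)
    rank_full = int(round(np.trace(h_full)))
    df_res = n - rank_full
    if df_res < 1:
        raise ValueError("saturated design: no residual degrees of freedom")

    # hat matrices do not depend on the permuted distances; precompute the
    # per-term projector differences once
    resid_proj = np.eye(n) - h_full
    term_proj: dict[str, tuple[np.ndarray, int]] = {}
    for t in term_names:
        reduced = np.hstack([ones] + [blocks[u] for u in term_names if u != t])
        h_red = _hat(reduced)
        h_with = _hat(np.hstack([reduced, blocks[t]]))
        df_t = int(round(np.trace(h_with) - np.trace(h_red)))
        term_proj[t] = (h_with - h_red, df_t)

    def term_stats(gmat: np.ndarray) -> dict[str, tuple[float, float]]:
        ss_res = float(np.sum(resid_proj * gmat))
        out = {}
        for t in term_names:
            proj, df_t = term_proj[t]
            ss_t = float(np.sum(proj * gmat))
            f = (ss_t / df_t) / (ss_res / df_res) if ss_res > 0 else math.inf
            out[t] = (f, ss_t)
        return out

    observed = term_stats(g)

    if exact:
        if design.shape[1] != 1:
            raise ValueError("exact enumeration is implemented for one-way designs")
        labels = tuple(design.iloc[:, 0])
        arrangements = sorted(set(itertools.permutations(labels)))
        m = len(arrangements)
        if m > 200_000:
            raise ValueError(f"{m} distinct arrangements; exact enumeration infeasible")
        factor = design.columns[0]
        count = 0
        for arr in arrangements:
            perm_design = pd.DataFrame({factor: list(arr)}, index=design.index)
            perm_blocks = _design_blocks(perm_design, False)
            h_b = _hat(np.hstack([ones, perm_blocks[factor]]))
            h_0 = _hat(ones)
            df_t = int(round(np.trace(h_b) - np.trace(h_0)))
            ss_t = float(np.sum((h_b - h_0) * g))
            ss_res = float(np.sum((np.eye(n) - h_b) * g))
            f = (ss_t / df_t) / (ss_res / (n - df_t - 1)) if ss_res > 0 else math.inf
            if f >= observed[factor][0] - 1e-12:
                count += 1
        p = count / m
        f_obs, ss_obs = observed[factor]
        return {
            factor: PermTestResult(
                statistic=f_obs,
                effect_size=ss_obs / ss_total if ss_total > 0 else math.nan,
                n_permutations=m,
                p_value=p,
                seed=seed,
                name=f"permanova[{factor}]",
            )
        }

    rng = np.random.default_rng(seed)
    exceed = {t: 0 for t in term_names}
    for _ in range(n_perm):
        p_idx = rng.permutation(n)
        g_perm = g[np.ix_(p_idx, p_idx)]
        stats = term_stats(g_perm)
        for t in term_names:
            if stats[t][0] >= observed[t][0] - 1e-12:
                exceed[t] += 1
    results = {}
    for t in term_names:
        f_obs, ss_obs = observed[t]
        results[t] = PermTestResult(
            statistic=f_obs,
            effect_size=ss_obs / ss_total if ss_total > 0 else math.nan,
            n_permutations=n_perm,
            p_value=(exceed[t] + 1) / (n_perm + 1),
            seed=seed,
            name=f"permanova[{t}]",
        )
    return results


def _as_design_frame(design, ids: list[str]) -> pd.DataFrame:
    if isinstance(design, pd.DataFrame):
        frame = design.copy()
    elif isinstance(design, pd.Series):
        frame = design.to_frame()
    elif isinstance(design, dict):
        frame = pd.DataFrame(design)
    else:
        frame = pd.DataFrame({"factor": list(design)})
    if len(frame) != len(ids):
        raise ValueError("design length does not match distance matrix")
    frame.index = ids
    return frame


# ---------------------------------------------------------------------------
# Mantel


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 99999,
    seed: int = 0,
) -> PermTestResult:
    """Permutation test of correlation between two distance matrices.

    The statistic is the correlation of the off-diagonal entries; the null
    distribution permutes the rows and columns of the second matrix
    simultaneously (two-sided on |r|).
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices must share identical ids (same order)")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    iu = np.triu_indices(d1.n, 1)
    x = d1.data[iu]
    if method == "spearman":
        x = scipy.stats.rankdata(x)

    def corr(a, b):
        if a.std() == 0 or b.std() == 0:
            return math.nan
        return float(np.corrcoef(a, b)[0, 1])

    def stat(mat: np.ndarray) -> float:
        v = mat[iu]
        if method == "spearman":
            v = scipy.stats.rankdata(v)
        return corr(x, v)

    r_obs = stat(d2.data)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(d2.n)
        r = stat(d2.data[np.ix_(p, p)])
        if not math.isnan(r) and abs(r) >= abs(r_obs) - 1e-12:
            exceed += 1
    return PermTestResult(
        statistic=r_obs,
        effect_size=r_obs**2 if not math.isnan(r_obs) else math.nan,
        n_permutations=n_perm,
        p_value=(exceed + 1) / (n_perm + 1),
        seed=seed,
        name=f"mantel[{method}]",
    )


# ---------------------------------------------------------------------------
# envfit


@dataclass(frozen=True)
class EnvfitResult:
    direction: tuple[float, float]
    r2: float
    p_value: float
    n_permutations: int
    seed: int


def envfit(
    coordinates: np.ndarray, variable: np.ndarray, n_perm: int = 999, seed: int = 0
) -> EnvfitResult:
    """Fit one environmental variable to a 2-D ordination as a vector.

    Least-squares regression of the variable on the two ordination axes;
    the fitted direction is the unit vector of the axis coefficients and R²
    the explained fraction. Significance permutes the variable. A constant
    variable has no defined direction and is reported as missing (NaN).
    """
    coords = np.asarray(coordinates, dtype=float)
    v = np.asarray(variable, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coordinates must be samples x 2")
    if len(v) != coords.shape[0]:
        raise ValueError("variable length does not match coordinates")
    if np.any(np.isnan(v)):
        raise ValueError("variable contains missing values")
    if np.isclose(v.std(), 0.0):
        return EnvfitResult((math.nan, math.nan), math.nan, math.nan, n_perm, seed)
    design = np.column_stack([np.ones(len(v)), coords])

    def fit_r2(target: np.ndarray) -> tuple[float, np.ndarray]:
        beta, *_ = np.linalg.lstsq(design, target, rcond=None)
        resid = target - design @ beta
        ss_tot = float(((target - target.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot
        return r2, beta[1:]

    r2_obs, coef = fit_r2(v)
    norm = np.linalg.norm(coef)
    direction = tuple(coef / norm) if norm > 0 else (math.nan, math.nan)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        r2_perm, _ = fit_r2(rng.permutation(v))
        if r2_perm >= r2_obs - 1e-12:
            exceed += 1
    return EnvfitResult(direction, r2_obs, (exceed + 1) / (n_perm + 1), n_perm, seed)


# ---------------------------------------------------------------------------
# variation partitioning


def _block_matrix(x) -> np.ndarray:
    """Numeric predictor block: factors dummy-coded with drop-first."""
    if isinstance(x, pd.Series):
        x = x.to_frame()
    if isinstance(x, pd.DataFrame):
        cols = []
        for col in x.columns:
            if x[col].dtype.kind in "OUSb" or isinstance(x[col].dtype, pd.CategoricalDtype):
                cols.append(pd.get_dummies(x[col].astype("category"), drop_first=True, dtype=float).to_numpy())
            else:
                cols.append(x[col].to_numpy(dtype=float)[:, None])
        return np.hstack(cols)
    arr = np.asarray(x, dtype=float)
    return arr[:, None] if arr.ndim == 1 else arr


def _rda_r2(y: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """Redundancy-analysis R² of a (column-centered) response matrix."""
    n = y.shape[0]
    design = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    yc = y - y.mean(axis=0)
    ss_tot = float((yc**2).sum())
    fc = fitted - fitted.mean(axis=0)
    ss_fit = float((fc**2).sum())
    xc = x - x.mean(axis=0)
    rank = int(np.linalg.matrix_rank(xc)) if xc.size else 0
    return (ss_fit / ss_tot if ss_tot > 0 else math.nan), rank


def _adj_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        raise ValueError("collinear or saturated design: n <= p + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variation_partitioning(
    y: np.ndarray | pd.DataFrame,
    x1,
    x2,
    n_perm: int = 999,
    seed: int = 0,
) -> VarpartResult:
    """Partition community variance over two predictor blocks.

    ``y`` is a samples-by-features (e.g. Hellinger-transformed) matrix.
    Fractions are differences of adjusted redundancy-analysis R² values:
    a = adjR²(X1 ∪ X2) − adjR²(X2) (pure block 1), c symmetric, b the
    shared remainder. Monte Carlo permutation tests (free permutation of
    the community rows) are attached for the testable fractions: each
    block's total, the joint model, and the two pure fractions.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    m1, m2 = _block_matrix(x1), _block_matrix(x2)
    if len(m1) != n or len(m2) != n:
        raise ValueError("predictor block length does not match response rows")
    both = np.hstack([m1, m2])
    r2_1, p1 = _rda_r2(y, m1)
    r2_2, p2 = _rda_r2(y, m2)
    r2_12, p12 = _rda_r2(y, both)
    adj1 = _adj_r2(r2_1, n, p1)
    adj2 = _adj_r2(r2_2, n, p2)
    adj12 = _adj_r2(r2_12, n, p12)
    a = adj12 - adj2
    c = adj12 - adj1
    b = adj1 + adj2 - adj12
    residual = 1.0 - adj12

    rng = np.random.default_rng(seed)

    def pseudo_f(yy, xm, rank, partial_of=None):
        r2, _ = _rda_r2(yy, xm)
        if partial_of is None:
            denom = (1.0 - r2) / (n - rank - 1)
            return (r2 / rank) / denom if denom > 1e-15 else math.inf
        r2_full, rank_full = partial_of
        df1 = rank_full - rank  # added rank of the tested block
        denom = (1.0 - r2_full) / (n - rank_full - 1)
        return ((r2_full - r2) / max(df1, 1)) / denom if denom > 1e-15 else math.inf

    def perm_p(stat_fn):
        obs = stat_fn(y)
        exceed = 0
        for _ in range(n_perm):
            yp = y[rng.permutation(n)]
            if stat_fn(yp) >= obs - 1e-12:
                exceed += 1
        return (exceed + 1) / (n_perm + 1)

    p_values = {
        "X1": perm_p(lambda yy: pseudo_f(yy, m1, p1)),
        "X2": perm_p(lambda yy: pseudo_f(yy, m2, p2)),
        "X1+X2": perm_p(lambda yy: pseudo_f(yy, both, p12)),
        "a|X2": perm_p(lambda yy: pseudo_f(yy, m2, p2, partial_of=(_rda_r2(yy, both)[0], p12))),
        "c|X1": perm_p(lambda yy: pseudo_f(yy, m1, p1, partial_of=(_rda_r2(yy, both)[0], p12))),
    }
    return VarpartResult(a, b, c, residual, adj1, adj2, adj12, r2_1, r2_2, r2_12, p_values)


# ---------------------------------------------------------------------------
# univariate helpers


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties, t-approximation p).

    Returns (rho, p); both NaN when either variable has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched vectors of length >= 3")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return math.nan, math.nan
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def group_tests(
    values: np.ndarray,
    design: pd.DataFrame | pd.Series | dict | list,
    *,
    interaction: bool = True,
) -> dict:
    """Univariate group comparisons matching the multivariate designs.

    One factor: Kruskal-Wallis H (tie-corrected) plus one-way ANOVA F.
    Two factors: two-way ANOVA with Type II sums of squares (statsmodels),
    optionally with the interaction term. Returns a mapping term ->
    ``{"statistic", "p_value", "ss"}``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    values = np.asarray(values, dtype=float)
    design = _as_design_frame(design, [str(i) for i in range(len(values))])
    for col in design.columns:
        if design[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has a single level")
    data = design.copy()
    data["value"] = values
    results: dict[str, dict] = {}
    if design.shape[1] == 1:
        factor = design.columns[0]
        groups = [g["value"].to_numpy() for _, g in data.groupby(factor, observed=True)]
        if np.ptp(values) == 0:
            h, p_kw = 0.0, 1.0  # identical values: no rank variation anywhere
        else:
            h, p_kw = scipy.stats.kruskal(*groups)
        results["kruskal"] = {"statistic": float(h), "p_value": float(p_kw), "ss": math.nan}
        f, p_f = scipy.stats.f_oneway(*groups)
        results[factor] = {"statistic": float(f), "p_value": float(p_f), "ss": math.nan}
        return results
    fa, fb = design.columns
    terms = f"C({fa}) * C({fb})" if interaction else f"C({fa}) + C({fb})"
    model = smf.ols(f"value ~ {terms}", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    rename = {f"C({fa})": fa, f"C({fb})": fb, f"C({fa}):C({fb})": f"{fa}:{fb}"}
    for row_name, row in table.iterrows():
        if row_name == "Residual":
            continue
        f_val = row["F"]
        if not np.isfinite(f_val) and row["sum_sq"] > 1e-12:
            f_val = math.inf
        results[rename.get(row_name, row_name)] = {
            "statistic": float(f_val),
            "p_value": float(row["PR(>F)"]),
            "ss": float(row["sum_sq"]),
        }
    results["residual_ss"] = {
        "statistic": math.nan,
        "p_value": math.nan,
        "ss": float(table.loc["Residual", "sum_sq"]),
    }
    return results
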