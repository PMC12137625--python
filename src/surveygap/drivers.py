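"""Attribution of inventory incompleteness to explanatory covariates.

Implements the regression toolbox used to ask *why* cells are
under-surveyed: single-predictor OLS, LMG relative-importance
decomposition of R², bidirectional stepwise model selection under AIC,
maximum-likelihood spatial simultaneous autoregressive (SAR) error
regression on a grid-contiguity weight matrix, and three-set variance
partitioning of explained variance among the safety / attractiveness /
accessibility covariate groups.

Conventions fixed here (and relied on by the exact oracle tests):

* AIC = n·ln(RSS/n) + 2·(p + 2), counting the intercept and the error
  variance in the parameter count p + 2 (p = number of slope terms).
* Stepwise ties are broken by preferring a drop over an add, then by
  column order.
* Variance partitioning uses adjusted R² by default (the vegan
  convention); raw R² is available via ``mode="raw"``. Individual Venn
  fractions can be slightly negative on the adjusted scale; the seven
  fractions plus the residual always sum to 1 by construction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

__all__ = [
    "DriverFit",
    "VarPartResult",
    "SpatialWeights",
    "simple_ols",
    "lmg_importance",
    "ols_aic",
    "stepwise_aic",
    "build_weights",
    "fit_sar_error",
    "variance_partition",
]

Cell = tuple[int, int]


@dataclass
class DriverFit:
    """Coefficients and fit statistics of one regression model."""

    response: str
    terms: list[str]
    coef: dict[str, float]
    aic: float
    r2: float
    pvalues: dict[str, float]
    loglik: float = np.nan
    lam: float | None = None          # SAR error autocorrelation; None for OLS
    coef_std: dict[str, float] = field(default_factory=dict)
    loglik_ols: float = np.nan        # log-likelihood at lambda = 0 (SAR only)


@dataclass
class VarPartResult:
    """Venn fractions of explained variance for three covariate groups."""

    fractions: dict[str, float]       # unique/pairwise/triple overlaps + residual
    group_totals: dict[str, float]    # marginal (adjusted) R2 of each group alone
    mode: str                         # "adjusted" or "raw"

    def ranked_groups(self) -> list[str]:
        return sorted(self.group_totals, key=self.group_totals.get, reverse=True)


# ---------------------------------------------------------------- OLS helpers

def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    """Residual sum of squares of an intercept + X least-squares fit."""
    D = _design(X) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    return float(resid @ resid)


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("response has zero variance")
    return 1.0 - _rss(y, X) / tss


def simple_ols(y, x) -> tuple[float, float, float, float]:
    """Single-predictor least squares: (slope, intercept, r2, p).

    Any transform (e.g. log10(n+1)) is the caller's responsibility. The p
    value is the two-sided t test of the slope.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0:
        raise ValueError("predictor has zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


# -------------------------------------------------------------------- LMG

def lmg_importance(y, X: pd.DataFrame | np.ndarray) -> pd.Series:
    """LMG relative importance: each predictor's R² share averaged over all
    orderings of model entry, computed through the 2^p subset decomposition.

    Shares sum to the full-model R². Exact enumeration; p <= 12.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j + 1}" for j in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if p > 12:
        raise ValueError("exact LMG enumeration limited to p <= 12")
    if np.linalg.matrix_rank(_design(Xa)) < p + 1:
        raise ValueError("singular design matrix")

    fact = [float(math.factorial(i)) for i in range(p + 1)]
    r2_cache: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, p + 1):
        for subset in itertools.combinations(range(p), size):
            r2_cache[frozenset(subset)] = _r2(y, Xa[:, list(subset)])

    shares = np.zeros(p)
    denom = fact[p]
    for j in range(p):
        others = [i for i in range(p) if i != j]
        for size in range(0, p):
            w = fact[size] * fact[p - size - 1] / denom
            for subset in itertools.combinations(others, size):
                s = frozenset(subset)
                shares[j] += w * (r2_cache[s | {j}] - r2_cache[s])
    return pd.Series(shares, index=names)


# -------------------------------------------------------------- stepwise AIC

def ols_aic(y: np.ndarray, X: np.ndarray) -> float:
    """AIC of an intercept + X OLS fit under the convention documented in the
    module docstring: n·ln(RSS/n) + 2·(p + 2)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    rss = _rss(y, X)
    p = 0 if X.size == 0 else X.shape[1]
    return n * np.log(rss / n) + 2 * (p + 2)


def _ols_fit(y: np.ndarray, X: pd.DataFrame, response: str) -> DriverFit:
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    n, p = Xa.shape if Xa.size else (len(y), 0)
    D = _design(Xa) if p else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    rss = float(resid @ resid)
    df = n - (p + 1)
    sigma2 = rss / df if df > 0 else np.nan
    cov = sigma2 * np.linalg.inv(D.T @ D)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pv = 2 * stats.t.sf(np.abs(tvals), df)
    r2 = _r2(y, Xa) if p else 0.0
    loglik = -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1)
    sy = np.std(y, ddof=1)
    coef_std = {nm: float(beta[j + 1] * np.std(Xa[:, j], ddof=1) / sy) for j, nm in enumerate(names)}
    return DriverFit(
        response=response, terms=names,
        coef={"intercept": float(beta[0]), **{nm: float(b) for nm, b in zip(names, beta[1:])}},
        aic=ols_aic(y, Xa), r2=r2,
        pvalues={"intercept": float(pv[0]), **{nm: float(v) for nm, v in zip(names, pv[1:])}},
        loglik=loglik, lam=None, coef_std=coef_std,
    )


def stepwise_aic(y, X: pd.DataFrame, direction: str = "both",
                 response: str = "V_inc") -> tuple[list[str], DriverFit]:
    """Bidirectional stepwise selection under AIC, starting from the full
    model.

    At each step the single add or drop move that most reduces AIC is
    applied; the search stops at a local minimum. Ties prefer a drop over an
    add, then earlier column order. Deterministic.
    """
    if direction != "both":
        raise ValueError("only direction='both' is implemented")
    y = np.asarray(y, dtype=float)
    all_terms = list(X.columns)
    if len(y) <= len(all_terms) + 2:
        raise ValueError("need n > p + 2 observations")
    current = list(all_terms)

    def aic_of(terms: list[str]) -> float:
        return ols_aic(y, X[terms].to_numpy(dtype=float) if terms else np.empty((len(y), 0)))

    best_aic = aic_of(current)
    while True:
        moves: list[tuple[float, int, int, list[str]]] = []  # (aic, kind, order, terms)
        for i, t in enumerate(current):             # drops first (kind 0)
            cand = [u for u in current if u != t]
            moves.append((aic_of(cand), 0, i, cand))
        for i, t in enumerate(all_terms):           # then adds (kind 1)
            if t not in current:
                cand = current + [t]
                moves.append((aic_of(cand), 1, i, cand))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        if moves[0][0] < best_aic - 1e-10:
            best_aic, current = moves[0][0], moves[0][3]
        else:
            break
    current = [t for t in all_terms if t in current]  # restore column order
    return current, _ols_fit(y, X[current], response)


# ------------------------------------------------------------ spatial weights

@dataclass
class SpatialWeights:
    """Row-standardised contiguity weights over a list of grid cells."""

    cells: list[Cell]
    W: sparse.csr_matrix              # row-standardised
    islands: list[Cell]               # cells with no neighbour (zero rows)

    @property
    def n(self) -> int:
        return len(self.cells)


def build_weights(cells: list[Cell], scheme: str = "queen",
                  row_standardize: bool = True) -> SpatialWeights:
    """Grid-contiguity spatial weights (queen or rook), row-standardised.

    Cells with no neighbour among ``cells`` are flagged as islands and keep
    an all-zero row. Raises if every cell is isolated.
    """
    if scheme not in {"queen", "rook"}:
        raise ValueError("scheme must be 'queen' or 'rook'")
    if len(cells) < 2:
        raise ValueError("need at least 2 cells")
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if scheme == "queen":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    index = {cell: i for i, cell in enumerate(cells)}
    rows, cols = [], []
    for (r, c), i in index.items():
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                rows.append(i)
                cols.append(j)
    if not rows:
        raise ValueError("all cells are isolated; no contiguity structure")
    B = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(cells), len(cells)))
    deg = np.asarray(B.sum(axis=1)).ravel()
    islands = [cells[i] for i in np.nonzero(deg == 0)[0]]
    if islands:
        warnings.warn(f"{len(islands)} island cell(s) with no neighbours", stacklevel=2)
    if row_standardize:
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
        W = sparse.diags(inv) @ B
    else:
        W = B
    return SpatialWeights(cells=list(cells), W=W.tocsr(), islands=islands)


# ------------------------------------------------------------------ SAR error

def _sar_eigenvalues(weights: SpatialWeights) -> np.ndarray:
    """Real eigenvalues of the row-standardised W, via the symmetric
    similarity transform D^{-1/2} B D^{-1/2} (B = binary contiguity)."""
    # recover the binary contiguity matrix from the row-standardised W
    Bmat = (weights.W != 0).astype(float)
    deg = np.asarray(Bmat.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        d_isqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1)), 0.0)
    S = sparse.diags(d_isqrt) @ Bmat @ sparse.diags(d_isqrt)
    return eigh(S.toarray(), eigvals_only=True)


def fit_sar_error(y, X: pd.DataFrame | np.ndarray, weights: SpatialWeights,
                  lam: float | None = None, response: str = "V_inc") -> DriverFit:
    """Maximum-likelihood SAR error model  y = Xβ + u,  u = λWu + ε.

    The concentrated log-likelihood is profiled over λ in (-0.999, 0.999)
    using the eigenvalue form of log|I - λW| (suitable up to a few thousand
    cells). Pass ``lam`` to fix λ instead of estimating it (λ = 0 reproduces
    OLS exactly). Reports raw and standardised β, asymptotic-normal p
    values, λ, AIC, the profile log-likelihood, the λ = 0 log-likelihood,
    and a pseudo-R² (squared correlation of the trend Xβ with y).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j + 1}" for j in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if n != weights.n:
        raise ValueError("y/X length must match the number of weight cells")
    if n <= p + 2:
        raise ValueError("need n > p + 2 observations")
    D = _design(Xa)
    W = weights.W
    eigs = _sar_eigenvalues(weights)

    def concentrated_negll(lam_: float) -> float:
        A = sparse.identity(n) - lam_ * W
        ys = A @ y
        Ds = A @ D
        beta, *_ = np.linalg.lstsq(Ds, ys, rcond=None)
        e = ys - Ds @ beta
        sigma2 = float(e @ e) / n
        if not np.isfinite(sigma2) or sigma2 <= 1e-300:
            return 1e12  # degenerate (perfect) fit; keep the search away
        logdet = float(np.sum(np.log(1.0 - lam_ * eigs)))
        ll = -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0) + logdet
        return -ll

    lo, hi = -0.999, 0.999
    if lam is None:
        # coarse grid then local refinement; deterministic
        grid = np.linspace(lo + 1e-6, hi - 1e-6, 41)
        vals = [concentrated_negll(g) for g in grid]
        i0 = int(np.argmin(vals))
        a = grid[max(i0 - 1, 0)]
        b = grid[min(i0 + 1, len(grid) - 1)]
        res = minimize_scalar(concentrated_negll, bounds=(a, b), method="bounded",
                              options={"xatol": 1e-8})
        if not res.success:
            raise RuntimeError(f"SAR lambda search failed: {res.message}")
        lam_hat = float(res.x)
        # the profile likelihood must dominate the nested lambda = 0 model
        if concentrated_negll(0.0) < concentrated_negll(lam_hat):
            lam_hat = 0.0
    else:
        if not (-1 < lam < 1):
            raise ValueError("lam must lie in (-1, 1)")
        lam_hat = float(lam)

    A = sparse.identity(n) - lam_hat * W
    ys = A @ y
    Ds = A @ D
    beta, *_ = np.linalg.lstsq(Ds, ys, rcond=None)
    e = ys - Ds @ beta
    sigma2 = float(e @ e) / n
    logdet = float(np.sum(np.log(1.0 - lam_hat * eigs)))
    loglik = -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0) + logdet
    loglik0 = -concentrated_negll(0.0)

    cov = sigma2 * np.linalg.inv(Ds.T @ Ds)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pv = 2 * stats.norm.sf(np.abs(z))
    trend = D @ beta
    pseudo_r2 = float(np.corrcoef(trend, y)[0, 1] ** 2)
    n_params = (p + 1) + 2  # slopes + intercept + lambda + sigma2
    aic = -2 * loglik + 2 * n_params
    sy = np.std(y, ddof=1)
    coef_std = {nm: float(beta[j + 1] * np.std(Xa[:, j], ddof=1) / sy) for j, nm in enumerate(names)}
    return DriverFit(
        response=response, terms=names,
        coef={"intercept": float(beta[0]), **{nm: float(b) for nm, b in zip(names, beta[1:])}},
        aic=float(aic), r2=pseudo_r2,
        pvalues={"intercept": float(pv[0]), **{nm: float(v) for nm, v in zip(names, pv[1:])}},
        loglik=float(loglik), lam=lam_hat, coef_std=coef_std, loglik_ols=float(loglik0),
    )


# -------------------------------------------------------- variance partition

def _adj_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        raise ValueError("too few observations for adjusted R2")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variance_partition(y, X_by_group: dict[str, pd.DataFrame],
                       mode: str = "adjusted") -> VarPartResult:
    """Three-set variance partitioning of explained variance.

    Fits the seven regressions on all non-empty unions of the three
    covariate groups, converts each to (adjusted) R², and solves the
    inclusion–exclusion system for the unique, pairwise, and triple Venn
    fractions. The residual is 1 minus the full-model (adjusted) R²; the
    seven fractions plus the residual sum to 1 exactly. On the adjusted
    scale individual fractions can dip slightly below zero.
    """
    if mode not in {"adjusted", "raw"}:
        raise ValueError("mode must be 'adjusted' or 'raw'")
    if len(X_by_group) != 3:
        raise ValueError("exactly three covariate groups are required")
    for g, df in X_by_group.items():
        if df.shape[1] == 0:
            raise ValueError(f"group '{g}' has no covariates")
    y = np.asarray(y, dtype=float)
    n = len(y)
    g1, g2, g3 = list(X_by_group)

    def fit_union(groups: tuple[str, ...]) -> float:
        Xu = pd.concat([X_by_group[g] for g in groups], axis=1)
        p = Xu.shape[1]
        if np.linalg.matrix_rank(_design(Xu.to_numpy(dtype=float))) < p + 1:
            raise ValueError(f"singular design for group union {groups}")
        r2 = _r2(y, Xu.to_numpy(dtype=float))
        return _adj_r2(r2, n, p) if mode == "adjusted" else r2

    R = {frozenset(gs): fit_union(gs) for gs in [
        (g1,), (g2,), (g3,), (g1, g2), (g1, g3), (g2, g3), (g1, g2, g3)]}

    R1, R2_, R3 = R[frozenset((g1,))], R[frozenset((g2,))], R[frozenset((g3,))]
    R12, R13, R23 = R[frozenset((g1, g2))], R[frozenset((g1, g3))], R[frozenset((g2, g3))]
    R123 = R[frozenset((g1, g2, g3))]

    u1 = R123 - R23
    u2 = R123 - R13
    u3 = R123 - R12
    p12 = R13 - R3 - u1           # shared by g1,g2 only: (g1 \ g3) minus u1
    p13 = R12 - R2_ - u1          # shared by g1,g3 only
    p23 = R12 - R1 - u2           # shared by g2,g3 only
    t = R1 - u1 - p12 - p13       # triple overlap
    residual = 1.0 - R123
    fractions = {
        g1: u1, g2: u2, g3: u3,
        f"{g1}∩{g2}": p12, f"{g1}∩{g3}": p13, f"{g2}∩{g3}": p23,
        f"{g1}∩{g2}∩{g3}": t,
        "residual": residual,
    }
    return VarPartResult(fractions=fractions,
                         group_totals={g1: R1, g2: R2_, g3: R3},
                         mode=mode)
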