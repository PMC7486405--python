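"""Two-way fixed-effects panel regression of loss-cost ratios on weather.

The estimating equation regresses a county-year LCR on a piecewise-linear
function of season degree-day exposure (three intervals split at a fixed
10 degC cutoff and two free knots), total season precipitation and its
square, county fixed effects, year fixed effects, and state-specific
quadratic time trends:

    y_it = c_i + b1*x1 + b2*x2 + b3*x3 + g1*Prec + g2*Prec^2
           + sum_s d1s (D_s * t) + sum_s d2s (D_s * t^2) + u_t + e_it

with x1 = dd(10) - dd(c1), x2 = dd(c1) - dd(c2), x3 = dd(c2).  Standard
errors are clustered by year with the conventional small-sample factor
G/(G-1) * (n-1)/(n-k).  The free knots are selected by exhaustively
refitting over an integer-degC grid (c1 in [20, 35], c2 in [36, 43]) and
keeping the best-fitting pair; a Frisch-Waugh factorization makes the grid
search cheap by partialling the fixed covariates out once.

Fixed effects enter as explicit dummy columns: exactness over speed at the
panel sizes this package targets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import scipy.linalg

from .degree_days import PiecewiseSpec, bin_exposures

logger = logging.getLogger(__name__)

SLOPE_NAMES = ["x1", "x2", "x3", "prec", "prec_sq"]

DEFAULT_C1_GRID = tuple(range(20, 36))
DEFAULT_C2_GRID = tuple(range(36, 44))


@dataclass(frozen=True)
class ModelSpec:
    """What to estimate: dependent LCR, knots (fixed or searched), controls."""

    dependent: str = "total"  # "total" or a canonical cause
    knots: PiecewiseSpec | None = None  # None -> grid search
    c1_grid: tuple[int, ...] = DEFAULT_C1_GRID
    c2_grid: tuple[int, ...] = DEFAULT_C2_GRID
    trend_degree: int = 2
    cluster: str = "year"

    def __post_init__(self) -> None:
        if any(not 20 <= c <= 35 for c in self.c1_grid):
            raise ValueError("c1 grid must lie within [20, 35] degC")
        if any(not 36 <= c <= 43 for c in self.c2_grid):
            raise ValueError("c2 grid must lie within [36, 43] degC")

    @property
    def dependent_column(self) -> str:
        return "lcr_total" if self.dependent == "total" else f"lcr_{self.dependent}"


@dataclass
class FitResult:
    """Estimates, year-clustered covariance of the weather slopes, and fit."""

    cause: str
    knots: PiecewiseSpec
    beta: np.ndarray          # (3,) temperature slopes, LCR per degree day
    gamma: np.ndarray         # (2,) precipitation linear & quadratic terms
    cov_slopes: np.ndarray    # (5, 5) clustered covariance of SLOPE_NAMES
    params: pd.Series         # full coefficient vector incl. FE and trends
    r2: float
    r2_within: float
    sse: float
    n: int
    n_clusters: int
    candidates: pd.DataFrame | None = None
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def slopes(self) -> np.ndarray:
        return np.concatenate([self.beta, self.gamma])

    @property
    def se_slopes(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_slopes))

    def to_dict(self) -> dict:
        d = {
            "cause": self.cause,
            "knots": {"c0": self.knots.c0, "c1": self.knots.c1, "c2": self.knots.c2},
            "beta": self.beta.tolist(),
            "gamma": self.gamma.tolist(),
            "cov_slopes": self.cov_slopes.tolist(),
            "r2": self.r2,
            "r2_within": self.r2_within,
            "sse": self.sse,
            "n": self.n,
            "n_clusters": self.n_clusters,
        }
        if self.candidates is not None:
            d["candidates"] = self.candidates.to_dict(orient="list")
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            cause=d["cause"],
            knots=PiecewiseSpec(c1=d["knots"]["c1"], c2=d["knots"]["c2"]),
            beta=np.asarray(d["beta"], dtype=float),
            gamma=np.asarray(d["gamma"], dtype=float),
            cov_slopes=np.asarray(d["cov_slopes"], dtype=float),
            params=pd.Series(dtype=float),
            r2=d["r2"], r2_within=d["r2_within"], sse=d["sse"],
            n=d["n"], n_clusters=d["n_clusters"],
            candidates=(pd.DataFrame(d["candidates"])
                        if "candidates" in d else None),
        )

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def merge_exposures(lcr_panel: pd.DataFrame,
                    exposures: pd.DataFrame) -> pd.DataFrame:
    """Inner-join the LCR panel with county-year season exposures."""
    right = exposures.drop(columns=[c for c in ("state_id",)
                                    if c in exposures.columns])
    merged = lcr_panel.merge(right, on=["county_id", "year"], how="inner")
    lost = len(lcr_panel) - len(merged)
    if lost:
        logger.warning("%d LCR row(s) had no matching season exposure", lost)
    return merged


def _control_columns(panel: pd.DataFrame, trend_degree: int
                     ) -> tuple[np.ndarray, list[str]]:
    """County dummies, year dummies (first year dropped), and state trends
    (reference state dropped — its trend is collinear with the year dummies)."""
    county = pd.Categorical(panel["county_id"])
    years = np.asarray(panel["year"])
    states = pd.Categorical(panel["state_id"])

    cols, names = [], []
    cdum = pd.get_dummies(county, dtype=float)
    for c in cdum.columns:
        cols.append(cdum[c].to_numpy())
        names.append(f"county[{c}]")

    uyears = np.unique(years)
    for yv in uyears[1:]:
        cols.append((years == yv).astype(float))
        names.append(f"year[{yv}]")

    t = (years - uyears.min()).astype(float)
    ustates = list(states.categories)
    for s in ustates[1:]:
        ind = (np.asarray(states) == s).astype(float)
        for p in range(1, trend_degree + 1):
            cols.append(ind * t**p)
            names.append(f"trend[{s}]^{p}")
    return np.column_stack(cols) if cols else np.empty((len(panel), 0)), names


def _slope_columns(panel: pd.DataFrame, knots: PiecewiseSpec) -> np.ndarray:
    binned = bin_exposures(panel, knots)
    prec = panel["prec_total"].to_numpy(dtype=float)
    prec_sq = (panel["prec_sq"].to_numpy(dtype=float)
               if "prec_sq" in panel.columns else prec**2)
    return np.column_stack([binned["x1"], binned["x2"], binned["x3"],
                            prec, prec_sq])


def _drop_collinear(X: np.ndarray, names: list[str], protect: int
                    ) -> tuple[np.ndarray, list[str], list[str]]:
    """Remove linearly dependent columns (never the first ``protect``)."""
    # pivoted QR on the column-scaled matrix for a scale-free rank decision
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    _, R, piv = scipy.linalg.qr(X / scale, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    keep_piv = set(piv[:rank]) | set(range(protect))
    keep = sorted(keep_piv)
    dropped = [names[i] for i in range(X.shape[1]) if i not in keep_piv]
    if dropped:
        logger.warning("dropping %d collinear column(s): %s",
                       len(dropped), dropped[:10])
    return X[:, keep], [names[i] for i in keep], dropped


def cluster_covariance(X: np.ndarray, resid: np.ndarray,
                       groups: np.ndarray) -> np.ndarray:
    """Cluster-robust sandwich covariance with the Stata-convention
    small-sample factor G/(G-1) * (n-1)/(n-k)."""
    n, k = X.shape
    if n <= k:
        raise ValueError(f"no residual degrees of freedom (n={n}, k={k})")
    codes, uniq = pd.factorize(groups)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 clusters")
    xe = X * resid[:, None]
    u = np.zeros((g, k))
    np.add.at(u, codes, xe)
    meat = u.T @ u
    bread = _xtx_inverse(X)
    c = g / (g - 1) * (n - 1) / (n - k)
    return c * bread @ meat @ bread


def _xtx_inverse(X: np.ndarray) -> np.ndarray:
    """(X'X)^-1 via QR of X: forming X'X first would square the condition
    number of dummy-plus-trend designs and lose the smallest directions."""
    r = np.linalg.qr(X, mode="r")
    d = np.abs(np.diag(r))
    if d.min() <= d.max() * np.finfo(float).eps * max(X.shape):
        rinv = np.linalg.pinv(r)
    else:
        rinv = scipy.linalg.solve_triangular(r, np.eye(r.shape[0]))
    return rinv @ rinv.T


def fit_lcr_model(panel: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Estimate the LCR regression at fixed knots.

    ``panel`` must carry the dependent LCR column, ``dd_<T>`` columns at
    the knot thresholds, ``prec_total``, and county/state/year ids.
    """
    if spec.knots is None:
        raise ValueError("fit_lcr_model requires fixed knots; "
                         "use search_knots to select them")
    ycol = spec.dependent_column
    if ycol not in panel.columns:
        raise KeyError(f"panel lacks dependent column {ycol!r}")
    if panel["county_id"].nunique() < 2 or panel["year"].nunique() < 2:
        raise ValueError("panel needs at least 2 counties and 2 years")

    y = panel[ycol].to_numpy(dtype=float)
    Xs = _slope_columns(panel, spec.knots)
    W, wnames = _control_columns(panel, spec.trend_degree)
    X = np.column_stack([Xs, W])
    names = SLOPE_NAMES + wnames

    X, names, dropped = _drop_collinear(X, names, protect=len(SLOPE_NAMES))
    n, k = X.shape

    params, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        # can only come from a degenerate weather column (e.g. x3 all zero
        # when no county-day tops c2); the minimum-norm solution zeroes it
        logger.warning("design rank %d < %d columns; using minimum-norm "
                       "solution", rank, k)
    resid = y - X @ params
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan

    # within-R^2: fit of the weather terms after partialling out the controls
    Wk = X[:, len(SLOPE_NAMES):]
    if Wk.shape[1]:
        coefw, *_ = np.linalg.lstsq(Wk, y, rcond=None)
        ry = y - Wk @ coefw
    else:
        ry = y - y.mean()
    sst_w = float(ry @ ry)
    r2_within = 1.0 - sse / sst_w if sst_w > 0 else np.nan

    groups = panel[spec.cluster].to_numpy()
    V = cluster_covariance(X, resid, groups)

    return FitResult(
        cause=spec.dependent,
        knots=spec.knots,
        beta=params[:3].copy(),
        gamma=params[3:5].copy(),
        cov_slopes=V[:5, :5].copy(),
        params=pd.Series(params, index=names),
        r2=r2, r2_within=r2_within, sse=sse,
        n=n, n_clusters=int(pd.factorize(groups)[1].size),
        dropped_columns=dropped,
    )


def search_knots(panel: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Grid-search the two free knots and return the best-fitting model.

    Every (c1, c2) pair on the integer-degC grids is fitted; the pair
    maximizing R^2 (equivalently minimizing SSE) wins, with ties broken
    toward the smallest c1 then the smallest c2.  All candidate R^2 values
    are retained on the returned fit for inspection.

    Degree-day columns at every grid threshold must be present, which the
    default exposure schedule precomputes; candidate fits then reduce, via
    Frisch-Waugh partialling of the fixed covariates, to 3-column
    regressions and share one factorization of the controls.
    """
    if not spec.c1_grid or not spec.c2_grid:
        raise ValueError("empty knot grid")
    ycol = spec.dependent_column
    y = panel[ycol].to_numpy(dtype=float)

    thresholds = sorted({10} | set(spec.c1_grid) | set(spec.c2_grid))
    dd_cols = [f"dd_{t:g}" for t in thresholds]
    for c in dd_cols:
        if c not in panel.columns:
            raise KeyError(f"panel lacks degree-day column {c!r} needed for search")

    prec = panel["prec_total"].to_numpy(dtype=float)
    prec_sq = (panel["prec_sq"].to_numpy(dtype=float)
               if "prec_sq" in panel.columns else prec**2)
    W, wnames = _control_columns(panel, spec.trend_degree)
    W = np.column_stack([prec, prec_sq, W])
    W, _, _ = _drop_collinear(W, ["prec", "prec_sq"] + wnames, protect=2)

    # partial the fixed covariates out of y and of every dd column at once
    rhs = np.column_stack([y] + [panel[c].to_numpy(dtype=float) for c in dd_cols])
    coef, *_ = np.linalg.lstsq(W, rhs, rcond=None)
    resid = rhs - W @ coef
    ry = resid[:, 0]
    rdd = {t: resid[:, 1 + i] for i, t in enumerate(thresholds)}

    sst = float(np.sum((y - y.mean()) ** 2))
    rows = []
    best = None
    for c1 in sorted(spec.c1_grid):
        for c2 in sorted(spec.c2_grid):
            Xc = np.column_stack([rdd[10] - rdd[c1], rdd[c1] - rdd[c2], rdd[c2]])
            coefc, _, rankc, _ = np.linalg.lstsq(Xc, ry, rcond=None)
            e = ry - Xc @ coefc
            sse = float(e @ e)
            rows.append((c1, c2, sse,
                         1.0 - sse / sst if sst > 0 else np.nan))
            if best is None or sse < best[2]:
                best = (c1, c2, sse)

    candidates = pd.DataFrame(rows, columns=["c1", "c2", "sse", "r2"])
    chosen = PiecewiseSpec(c1=float(best[0]), c2=float(best[1]))
    fit = fit_lcr_model(panel, ModelSpec(dependent=spec.dependent, knots=chosen,
                                         trend_degree=spec.trend_degree,
                                         cluster=spec.cluster))
    fit.candidates = candidates
    return fit


def _temperature_gradient(knots: PiecewiseSpec, h: float) -> np.ndarray:
    c0, c1, c2 = knots.c0, knots.c1, knots.c2
    return np.array([
        max(0.0, min(h, c1) - c0),
        max(0.0, min(h, c2) - c1),
        max(0.0, h - c2),
    ])


def marginal_effect_day(fit: FitResult, h: float) -> tuple[float, float]:
    """LCR change from one additional day at constant temperature ``h``
    relative to a day below the 10 degC cutoff, with delta-method SE.
    """
    if not 0 <= h <= 45:
        raise ValueError("temperature out of the supported 0-45 degC range")
    a = _temperature_gradient(fit.knots, h)
    value = float(a @ fit.beta)
    se = float(np.sqrt(a @ fit.cov_slopes[:3, :3] @ a))
    return value, se


def precip_effect(fit: FitResult, p0: float, p1: float) -> tuple[float, float]:
    """LCR change when season precipitation moves from p0 to p1 mm."""
    if p0 < 0 or p1 < 0:
        raise ValueError("precipitation must be non-negative")
    a = np.array([p1 - p0, p1**2 - p0**2])
    value = float(a @ fit.gamma)
    se = float(np.sqrt(a @ fit.cov_slopes[3:, 3:] @ a))
    return value, se
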