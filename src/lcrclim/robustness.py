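"""Lower-frequency re-specifications of the LCR panel model.

Panel estimates identified from year-to-year weather swings hold farmer
and insurance-program behavior fixed; designs that exploit slower climatic
variation implicitly admit adaptation.  Four stand-in designs are
provided, each a simple, documented convention that can be re-aligned with
external specifications through its parameters:

* ``ma5`` / ``ma10`` — trailing within-county moving averages of the
  dependent LCR and all weather regressors; county and year fixed effects
  are kept and errors remain year-clustered.
* ``crosssec`` — one row per county of full-sample means; OLS with state
  indicators and heteroskedasticity-robust errors (HC3, whose leverage
  correction keeps test size honest in county-level cross-sections).
* ``longdiff`` — one row per county: mean of the last ``period`` years
  minus mean of the first ``period`` years (default 5) for every
  variable; OLS with state indicators and HC3 errors.

Knots are inherited from the baseline fit, never re-searched, so the
designs differ only in the temporal frequency of identifying variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .degree_days import PiecewiseSpec
from .panel_model import (FitResult, ModelSpec, SLOPE_NAMES, _slope_columns,
                          _xtx_inverse, fit_lcr_model)

logger = logging.getLogger(__name__)

DESIGN_KINDS = ("longdiff", "crosssec", "ma5", "ma10")


@dataclass(frozen=True)
class RobustDesign:
    """Which lower-frequency convention to apply.

    The conventions are deliberate stand-ins and therefore configurable:
    ``centered`` switches the moving average from trailing to centered
    windows, ``period`` sets the long-difference end-period length, and
    ``se_type`` picks the heteroskedasticity-robust flavor for the
    single-cross-section designs.
    """

    kind: str
    ma_window: int | None = None
    period: int = 5  # end-period length for the long difference
    centered: bool = False
    se_type: str = "HC3"

    def __post_init__(self) -> None:
        if self.kind not in DESIGN_KINDS:
            raise ValueError(f"unknown design {self.kind!r}")
        if self.se_type not in ("HC1", "HC3"):
            raise ValueError("se_type must be 'HC1' or 'HC3'")
        if self.kind.startswith("ma"):
            window = self.ma_window or int(self.kind[2:])
            if window not in (5, 10):
                raise ValueError("moving-average window must be 5 or 10")
            object.__setattr__(self, "ma_window", window)

    @property
    def min_years(self) -> int:
        if self.kind.startswith("ma"):
            return self.ma_window
        if self.kind == "longdiff":
            return 2 * self.period
        return 1


def _model_columns(panel: pd.DataFrame) -> list[str]:
    """The variables the estimating equation consumes: LCRs, degree-day
    schedule columns, and precipitation terms (the square averaged as its
    own variable)."""
    cols = [c for c in panel.columns
            if c.startswith("lcr_") or c.startswith("dd_")]
    cols.append("prec_total")
    return cols


def transform_panel(panel: pd.DataFrame, design: RobustDesign) -> pd.DataFrame:
    """Apply the design's temporal aggregation to every model variable."""
    panel = panel.sort_values(["county_id", "year"]).reset_index(drop=True)
    span = panel.groupby("county_id")["year"].nunique().min()
    if span < design.min_years:
        raise ValueError(f"panel span {span} too short for design {design.kind}")

    cols = _model_columns(panel)
    work = panel[["county_id", "state_id", "year"] + cols].copy()
    work["prec_sq"] = work["prec_total"] ** 2
    cols = cols + ["prec_sq"]

    if design.kind in ("ma5", "ma10"):
        w = design.ma_window
        g = work.groupby("county_id")
        out = work.copy()
        out[cols] = g[cols].transform(
            lambda s: s.rolling(w, min_periods=w, center=design.centered).mean())
        out = out.dropna(subset=cols).reset_index(drop=True)
        return out

    if design.kind == "crosssec":
        out = (work.groupby(["county_id", "state_id"], as_index=False)[cols]
               .mean())
        out["year"] = int(work["year"].max())
        return out

    # longdiff
    def _diff(grp: pd.DataFrame) -> pd.Series:
        grp = grp.sort_values("year")
        head = grp.iloc[: design.period][cols].mean()
        tail = grp.iloc[-design.period:][cols].mean()
        if grp["year"].iloc[design.period - 1] >= grp["year"].iloc[-design.period]:
            raise ValueError("long-difference end periods overlap")
        return tail - head

    out = (work.groupby(["county_id", "state_id"])
           .apply(_diff, include_groups=False).reset_index())
    out["year"] = int(work["year"].max())
    return out


def _cross_section_fit(tpanel: pd.DataFrame, dependent: str,
                       knots: PiecewiseSpec, se_type: str = "HC3") -> FitResult:
    """OLS on one row per county with state indicators and robust errors."""
    ycol = "lcr_total" if dependent == "total" else f"lcr_{dependent}"
    y = tpanel[ycol].to_numpy(dtype=float)
    Xs = _slope_columns(tpanel, knots)
    sdum = pd.get_dummies(tpanel["state_id"], dtype=float)
    X = np.column_stack([Xs, sdum.to_numpy()])
    names = SLOPE_NAMES + [f"state[{s}]" for s in sdum.columns]

    params, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.warning("cross-section design rank-deficient; minimum-norm fit")
    resid = y - X @ params
    n, k = X.shape
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))

    bread = _xtx_inverse(X)
    if se_type == "HC3":
        # residuals inflated by leverage, e_i / (1 - h_i)
        leverage = np.einsum("ij,jk,ik->i", X, bread, X)
        u = resid / np.clip(1.0 - leverage, 1e-8, None)
        meat = (X * u[:, None] ** 2).T @ X
        V = bread @ meat @ bread
    else:  # HC1
        meat = (X * resid[:, None] ** 2).T @ X
        V = n / max(n - k, 1) * bread @ meat @ bread

    return FitResult(
        cause=dependent, knots=knots,
        beta=params[:3].copy(), gamma=params[3:5].copy(),
        cov_slopes=V[:5, :5].copy(),
        params=pd.Series(params, index=names),
        r2=1.0 - sse / sst if sst > 0 else np.nan,
        r2_within=np.nan, sse=sse, n=n, n_clusters=0,
    )


def fit_robust(tpanel: pd.DataFrame, design: RobustDesign,
               knots: PiecewiseSpec, dependent: str = "total") -> FitResult:
    """Estimate the design's model on a transformed panel.

    ``knots`` should come from the baseline (annual-frequency) fit.
    """
    if design.kind in ("ma5", "ma10"):
        spec = ModelSpec(dependent=dependent, knots=knots)
        return fit_lcr_model(tpanel, spec)
    return _cross_section_fit(tpanel, dependent, knots, design.se_type)
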