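"""Loss-cost ratio (LCR) panel construction from insurance records.

The LCR for a county-year is indemnities paid divided by total insured
liability — a [0, 1] measure of realized downside yield risk.  Losses come
disaggregated by the cause a claims adjuster cited; raw cause names are
collapsed onto a five-way canonical taxonomy (drought, heat, excess
moisture, cold, other) before cause-specific LCRs are formed, with cold
defined as the sum of freeze, frost, and cold wet weather losses.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_CAUSES = ("drought", "heat", "excess_moisture", "cold", "other")

#: Raw COL cause names -> canonical cause.  Matching is case-insensitive on
#: the stripped raw name; anything unmapped collapses to "other".
DEFAULT_TAXONOMY: dict[str, str] = {
    "drought": "drought",
    "heat": "heat",
    "hot wind": "heat",
    "excess moisture/precipitation/rain": "excess_moisture",
    "excess moisture": "excess_moisture",
    "freeze": "cold",
    "frost": "cold",
    "cold wet weather": "cold",
    "cold winter": "cold",
    "other (snow, lightning, etc.)": "other",
}

COL_COLUMNS = ["year", "state_id", "county_id", "crop", "cause", "indemnity_usd"]
SOB_COLUMNS = ["year", "state_id", "county_id", "crop", "liability_usd"]


def read_col(path) -> pd.DataFrame:
    """Read a Cause-of-Loss style CSV of indemnities by cause."""
    df = pd.read_csv(path)
    missing = set(COL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"COL file missing columns: {sorted(missing)}")
    if (df["indemnity_usd"] < 0).any():
        raise ValueError("negative indemnities in COL file")
    return df


def read_sob(path) -> pd.DataFrame:
    """Read a Summary-of-Business style CSV of liabilities."""
    df = pd.read_csv(path)
    missing = set(SOB_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SOB file missing columns: {sorted(missing)}")
    if (df["liability_usd"] < 0).any():
        raise ValueError("negative liabilities in SOB file")
    return df


def normalize_causes(losses: pd.DataFrame,
                     taxonomy: dict[str, str] | None = None) -> pd.DataFrame:
    """Map raw cause names onto the canonical five-cause taxonomy.

    Indemnity amounts are preserved exactly; unmapped names become
    ``"other"`` with a logged warning.
    """
    taxonomy = DEFAULT_TAXONOMY if taxonomy is None else taxonomy
    taxonomy = {k.strip().lower(): v for k, v in taxonomy.items()}

    raw = losses["cause"].astype(str).str.strip()
    if (raw == "").any():
        raise ValueError("empty cause names in loss records")
    mapped = raw.str.lower().map(taxonomy)
    unmapped = mapped.isna()
    if unmapped.any():
        names = sorted(raw[unmapped].unique())
        logger.warning("mapping %d unrecognized cause name(s) to 'other': %s",
                       len(names), names[:10])
    out = losses.copy()
    out["cause"] = mapped.fillna("other")
    bad = set(out["cause"]) - set(CANONICAL_CAUSES)
    if bad:
        raise ValueError(f"taxonomy maps to non-canonical causes: {sorted(bad)}")
    return out


def build_lcr_panel(losses: pd.DataFrame, liabilities: pd.DataFrame,
                    crop: str | None = None,
                    taxonomy: dict[str, str] | None = None) -> pd.DataFrame:
    """Build the county-year panel of total and cause-specific LCRs.

    One row per county-year with a positive liability.  County-years with
    liability but no loss records get LCR 0 (no claims); loss records with
    no matching liability row are dropped with a warning; duplicate
    liability rows for a (county, year) are an error.  LCRs above 1 are
    clipped to 1 with a logged count (the liability is the maximum
    insurable indemnity, so larger ratios indicate over-claims).
    """
    if crop is not None:
        losses = losses[losses["crop"] == crop]
        liabilities = liabilities[liabilities["crop"] == crop]
    if len(liabilities) == 0:
        raise ValueError("no liability records (after crop filter)")

    keys = ["county_id", "year"]
    dup = liabilities.duplicated(subset=keys)
    if dup.any():
        raise ValueError(
            f"duplicate liability rows for {liabilities.loc[dup, keys].values[:5]}")

    zero = liabilities["liability_usd"] <= 0
    if zero.any():
        logger.warning("dropping %d county-year(s) with non-positive liability",
                       int(zero.sum()))
        liabilities = liabilities[~zero]

    losses = normalize_causes(losses, taxonomy)
    cause_sum = (losses.groupby(keys + ["cause"], as_index=False)["indemnity_usd"]
                 .sum()
                 .pivot_table(index=keys, columns="cause",
                              values="indemnity_usd", fill_value=0.0))
    for cause in CANONICAL_CAUSES:
        if cause not in cause_sum.columns:
            cause_sum[cause] = 0.0
    cause_sum = cause_sum[list(CANONICAL_CAUSES)]

    panel = liabilities.set_index(keys)[["state_id", "liability_usd"]].join(cause_sum)
    panel[list(CANONICAL_CAUSES)] = panel[list(CANONICAL_CAUSES)].fillna(0.0)

    orphans = cause_sum.index.difference(panel.index)
    if len(orphans) > 0:
        logger.warning("dropping losses for %d county-year(s) without liability "
                       "records", len(orphans))

    liab = panel["liability_usd"]
    out = panel[["state_id"]].copy()
    out["lcr_total"] = panel[list(CANONICAL_CAUSES)].sum(axis=1) / liab
    for cause in CANONICAL_CAUSES:
        out[f"lcr_{cause}"] = panel[cause] / liab

    over = out["lcr_total"] > 1.0
    if over.any():
        logger.warning("clipping %d county-year LCR(s) above 1", int(over.sum()))
        scale = out.loc[over, "lcr_total"]
        cols = ["lcr_total"] + [f"lcr_{c}" for c in CANONICAL_CAUSES]
        out.loc[over, cols] = out.loc[over, cols].div(scale, axis=0)

    out["liability_usd"] = liab
    return out.reset_index().sort_values(keys).reset_index(drop=True)
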