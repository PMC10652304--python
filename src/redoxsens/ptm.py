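"""Quantification of oxidative PTM changes from site-level MS evidence.

The central metric is the percent change in PTM quantity per modified site
(%d PTM/site) between a treated and a vehicle condition:

    100 * (mean_treated - mean_vehicle) / mean_vehicle

computed per (protein, site, modification) after averaging technical
replicates within each condition.  Site-level changes are then averaged
(unweighted by default) per protein or per modification; grand sums and
sign censuses summarize a whole table.  Sites detected only under
treatment have no defined percent change from a zero baseline and are
recorded with a sentinel rather than a number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NEW_SITE",
    "PTMChangeEntry",
    "CorrelationResult",
    "site_percent_change",
    "protein_ptm_change",
    "modification_ptm_change",
    "ptm_change_table",
    "grand_sum",
    "sign_census",
    "overlay_lfq",
    "correlate",
]


class _NewSite:
    """Sentinel for a site detected under treatment but not in vehicle."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NEW_SITE"


NEW_SITE = _NewSite()

NewSitePolicy = Literal["exclude", "pseudocount"]


@dataclass(frozen=True)
class PTMChangeEntry:
    """Aggregated percent PTM change for one protein or one modification."""

    key: str
    pct_change_per_site: float  # NaN when insufficient data
    n_sites: int
    net_sign: int  # -1, 0, +1; 0 also for insufficient data

    @property
    def insufficient(self) -> bool:
        return self.n_sites == 0


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with a least-squares line and bootstrap band."""

    pearson_r: float
    slope: float
    intercept: float
    ci_low: float  # 95% bootstrap CI on the slope
    ci_high: float
    n_points: int
    n_boot: int
    seed: int


def site_percent_change(
    vehicle_quantities: Sequence[float],
    treated_quantities: Sequence[float],
    pseudocount: float = 0.0,
):
    """Percent change of the condition-mean quantity at one modified site.

    Returns a signed percent, ``NEW_SITE`` when the vehicle mean is zero
    but treatment shows signal (undefined percent change from zero), or
    ``None`` when both conditions are zero.  A positive ``pseudocount`` is
    added to both means, turning new sites into large finite changes.
    """
    v = float(np.mean(vehicle_quantities)) + pseudocount
    t = float(np.mean(treated_quantities)) + pseudocount
    if v == 0.0:
        return NEW_SITE if t > 0 else None
    return 100.0 * (t - v) / v


def _site_changes(
    evidence: pd.DataFrame,
    condition_pair: tuple[str, str],
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Valid per-(protein, site, modification) percent changes."""
    vehicle, treated = condition_pair
    means = (
        evidence[evidence["condition"].isin(condition_pair)]
        .groupby(["protein_id", "site", "modification", "condition"])["quantity"]
        .mean()
        .unstack("condition")
    )
    rows = []
    for (protein, site, mod), row in means.iterrows():
        v = row.get(vehicle)
        t = row.get(treated)
        if pd.isna(v) and pd.isna(t):
            continue
        change = site_percent_change(
            [0.0 if pd.isna(v) else v], [0.0 if pd.isna(t) else t], pseudocount
        )
        if change is None or change is NEW_SITE:
            continue
        rows.append(
            {"protein_id": protein, "site": site, "modification": mod, "pct_change": change}
        )
    return pd.DataFrame(rows, columns=["protein_id", "site", "modification", "pct_change"])


def _aggregate(
    changes: pd.DataFrame,
    key: str,
    group_column: str,
    zero_tolerance: float,
    statistic: Literal["mean", "sum"],
) -> PTMChangeEntry:
    vals = changes.loc[changes[group_column] == key, "pct_change"].to_numpy(float)
    if vals.size == 0:
        return PTMChangeEntry(key=key, pct_change_per_site=np.nan, n_sites=0, net_sign=0)
    value = float(vals.mean() if statistic == "mean" else vals.sum())
    sign = 0 if abs(value) <= zero_tolerance else (1 if value > 0 else -1)
    return PTMChangeEntry(key=key, pct_change_per_site=value, n_sites=int(vals.size),
                          net_sign=sign)


def protein_ptm_change(
    evidence: pd.DataFrame,
    protein_id: str,
    condition_pair: tuple[str, str],
    zero_tolerance: float = 1e-9,
    statistic: Literal["mean", "sum"] = "mean",
    pseudocount: float = 0.0,
) -> PTMChangeEntry:
    """%d PTM/site for one protein: mean of its valid site-level changes."""
    changes = _site_changes(evidence, condition_pair, pseudocount)
    return _aggregate(changes, protein_id, "protein_id", zero_tolerance, statistic)


def modification_ptm_change(
    evidence: pd.DataFrame,
    modification: str,
    condition_pair: tuple[str, str],
    zero_tolerance: float = 1e-9,
    statistic: Literal["mean", "sum"] = "mean",
    pseudocount: float = 0.0,
) -> PTMChangeEntry:
    """%d PTM/site for one modification, pooled across proteins."""
    changes = _site_changes(evidence, condition_pair, pseudocount)
    return _aggregate(changes, modification, "modification", zero_tolerance, statistic)


def ptm_change_table(
    evidence: pd.DataFrame,
    condition_pair: tuple[str, str],
    by: Literal["protein_id", "modification"] = "protein_id",
    zero_tolerance: float = 1e-9,
    statistic: Literal["mean", "sum"] = "mean",
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Aggregated %d PTM/site for every protein (or modification).

    Returns a DataFrame indexed by the grouping key with columns
    ``pct_change_per_site``, ``n_sites`` and ``net_sign``.
    """
    changes = _site_changes(evidence, condition_pair, pseudocount)
    keys = sorted(evidence[by].unique())
    entries = [_aggregate(changes, k, by, zero_tolerance, statistic) for k in keys]
    return pd.DataFrame(
        {
            by: [e.key for e in entries],
            "pct_change_per_site": [e.pct_change_per_site for e in entries],
            "n_sites": [e.n_sites for e in entries],
            "net_sign": [e.net_sign for e in entries],
        }
    ).set_index(by)


def grand_sum(table: pd.DataFrame) -> float:
    """Sum of per-entry percent changes over a PTM change table."""
    vals = table["pct_change_per_site"].dropna()
    if vals.empty:
        raise ValueError("grand sum of an empty PTM change table is undefined")
    return float(vals.sum())


def sign_census(
    values, zero_tolerance: float = 1e-9
) -> tuple[int, int, int]:
    """Counts of (decreasing, increasing, unchanged) entries.

    ``values`` may be a PTM change table (its ``pct_change_per_site``
    column is used) or any sequence of signed numbers; NaNs count as
    unchanged/insufficient.
    """
    if isinstance(values, pd.DataFrame):
        values = values["pct_change_per_site"]
    arr = np.asarray(values, dtype=float)
    nan = np.isnan(arr)
    decreasing = int((arr[~nan] < -zero_tolerance).sum())
    increasing = int((arr[~nan] > zero_tolerance).sum())
    unchanged = int(arr.size - decreasing - increasing)
    return decreasing, increasing, unchanged


def overlay_lfq(ptm_table: pd.DataFrame, lfq_table: pd.DataFrame) -> pd.DataFrame:
    """Outer join of per-protein PTM changes onto LFQ abundance changes.

    Proteins without PTM evidence keep NaN in the PTM columns (the
    insufficient-data marker); proteins without LFQ keep NaN on that side.
    """
    return ptm_table.join(lfq_table, how="outer")


def lfq_log2_table(
    lfq: pd.DataFrame, condition_pair: tuple[str, str]
) -> pd.DataFrame:
    """Per-protein log2 abundance ratio (treated/vehicle) with a Welch t-test.

    The t-test compares log-transformed replicate intensities between the
    two conditions; proteins with fewer than 2 replicates per condition
    get a NaN p-value.
    """
    vehicle, treated = condition_pair
    sub = lfq[lfq["condition"].isin(condition_pair)]
    rows = []
    for protein, grp in sub.groupby("protein_id"):
        v = grp.loc[grp["condition"] == vehicle, "intensity"].to_numpy(float)
        t = grp.loc[grp["condition"] == treated, "intensity"].to_numpy(float)
        if v.size == 0 or t.size == 0 or v.mean() <= 0 or t.mean() <= 0:
            continue
        log2_ratio = float(np.log2(t.mean() / v.mean()))
        if v.size >= 2 and t.size >= 2 and (np.ptp(v) > 0 or np.ptp(t) > 0):
            pvalue = float(stats.ttest_ind(np.log(t), np.log(v), equal_var=False).pvalue)
        else:
            pvalue = np.nan
        rows.append({"protein_id": protein, "log2_ratio": log2_ratio, "pvalue": pvalue})
    return pd.DataFrame(rows, columns=["protein_id", "log2_ratio", "pvalue"]).set_index(
        "protein_id"
    )


def correlate(
    x, y, n_boot: int = 1000, seed: int = 0
) -> CorrelationResult:
    """Pearson correlation and least-squares line with a bootstrap band.

    ``x`` and ``y`` are per-protein values (Series aligned on index, or
    plain arrays of equal length).  Pairs with missing values are dropped.
    The 95% band is a percentile interval on the regression slope from
    ``n_boot`` case resamples.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        joined = pd.concat([x.rename("x"), y.rename("y")], axis=1, join="inner").dropna()
        xv, yv = joined["x"].to_numpy(float), joined["y"].to_numpy(float)
    else:
        xv, yv = np.asarray(x, float), np.asarray(y, float)
        keep = ~(np.isnan(xv) | np.isnan(yv))
        xv, yv = xv[keep], yv[keep]
    n = xv.size
    if n < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(stats.pearsonr(xv, yv).statistic)
    slope, intercept = np.polyfit(xv, yv, 1)
    rng = np.random.default_rng(seed)
    boot_slopes = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = xv[idx], yv[idx]
        if np.ptp(xb) == 0:
            boot_slopes[b] = np.nan
            continue
        boot_slopes[b] = np.polyfit(xb, yb, 1)[0]
    ci_low, ci_high = np.nanquantile(boot_slopes, [0.025, 0.975])
    return CorrelationResult(
        pearson_r=r,
        slope=float(slope),
        intercept=float(intercept),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_points=int(n),
        n_boot=n_boot,
        seed=seed,
    )
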