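"""Composite sensitivity scoring.

The raw sensitivity score (RSS) of a protein is the product of its
min-max-normalized destabilization susceptibility (|ddG|, kT) and its
min-max-normalized eigenvector centrality E, both normalized over the
scored set P.  The composite sensitivity score (CSS) is the RSS min-max
normalized once more over P, so the top-ranked protein always scores
exactly 1 and the bottom exactly 0.  Because min-max normalization is
invariant under positive affine transformations of its input, the CSS
ranking depends only on the orderings of susceptibility and centrality
products, not on their units.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "minmax",
    "compute_scores",
    "top_percentile",
    "community_summary",
    "summary_table",
]


def minmax(values) -> np.ndarray:
    """Min-max normalize to [0, 1]: (x - min) / (max - min).

    Raises on fewer than two distinct values (degenerate normalization).
    """
    arr = np.asarray(values, dtype=float)
    lo, hi = np.min(arr), np.max(arr)
    if hi == lo:
        raise ValueError("min-max normalization undefined for all-equal values")
    return (arr - lo) / (hi - lo)


def compute_scores(
    stability: pd.DataFrame,
    centrality: Mapping[str, float],
    partition: Mapping[str, int | str] | None = None,
    old_signs: Mapping[str, int] | None = None,
    young_signs: Mapping[str, int] | None = None,
    scored_set: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Score every protein of the scored set P.

    Parameters
    ----------
    stability :
        Per-protein table indexed by protein id with a ``susceptibility``
        column (kT), e.g. from :func:`redoxsens.stability.proteome_map`.
    centrality :
        Full-network-calibrated eigenvector centralities.
    partition, old_signs, young_signs :
        Optional annotations copied onto the output rows.
    scored_set :
        Explicit P; defaults to all proteins having both a susceptibility
        and a centrality value.

    Returns
    -------
    DataFrame indexed by protein id with columns ``ddg``, ``E``,
    ``ddg_norm``, ``e_norm``, ``rss``, ``css``, ``community``,
    ``old_sign``, ``young_sign``, sorted by descending CSS then id.
    """
    if hasattr(centrality, "values") and not isinstance(centrality, Mapping):
        centrality = centrality.values  # CentralityMap
    if scored_set is None:
        scored = sorted(set(stability.index) & set(centrality))
    else:
        scored = sorted(dict.fromkeys(scored_set))
        missing = [p for p in scored if p not in stability.index or p not in centrality]
        if missing:
            raise ValueError(
                f"{len(missing)} scored proteins lack susceptibility or centrality "
                f"(e.g. {missing[:5]})"
            )
    if len(scored) < 2:
        raise ValueError("scored set must contain at least 2 proteins")

    ddg = stability.loc[scored, "susceptibility"].to_numpy(float)
    e = np.array([centrality[p] for p in scored], dtype=float)
    ddg_norm = minmax(ddg)
    e_norm = minmax(e)
    rss = ddg_norm * e_norm
    css = minmax(rss)

    df = pd.DataFrame(
        {
            "ddg": ddg,
            "E": e,
            "ddg_norm": ddg_norm,
            "e_norm": e_norm,
            "rss": rss,
            "css": css,
        },
        index=pd.Index(scored, name="protein_id"),
    )
    df["community"] = pd.Series({p: (partition or {}).get(p) for p in scored})
    df["old_sign"] = pd.Series({p: (old_signs or {}).get(p) for p in scored})
    df["young_sign"] = pd.Series({p: (young_signs or {}).get(p) for p in scored})
    return df.sort_values(["css", "protein_id"], ascending=[False, True],
                          kind="mergesort")


def top_percentile(rows: pd.DataFrame, percentile: float = 50.0) -> pd.DataFrame:
    """Rows at or above the given empirical CSS percentile, ties kept.

    Ordered by (css desc, protein_id asc) for deterministic output.
    """
    cutoff = np.percentile(rows["css"].to_numpy(float), percentile)
    subset = rows[rows["css"] >= cutoff]
    return subset.sort_values(["css", "protein_id"], ascending=[False, True],
                              kind="mergesort")


def community_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-community CSS sum, member count and fraction of the scored set.

    Fractions are over proteins carrying a community label and sum to 1.
    """
    labeled = rows[rows["community"].notna()]
    if labeled.empty:
        raise ValueError("no community labels present")
    grouped = labeled.groupby("community", sort=True)
    out = pd.DataFrame(
        {
            "css_sum": grouped["css"].sum(),
            "n_members": grouped.size(),
        }
    )
    out["fraction"] = out["n_members"] / out["n_members"].sum()
    return out.sort_values("css_sum", ascending=False)


def summary_table(rows: pd.DataFrame, top_k: int = 20) -> pd.DataFrame:
    """Report-style top-k table with CSS rounded to 2 decimals for display.

    Full precision is preserved in ``css_exact``.
    """
    top = rows.head(top_k).copy()
    top["css_exact"] = top["css"]
    top["css"] = top["css"].round(2)
    cols = ["community", "old_sign", "young_sign", "css", "css_exact"]
    return top[[c for c in cols if c in top.columns]]
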