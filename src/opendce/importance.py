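"""Relative attribute importance from individual part-worth utilities.

For one respondent, an attribute's importance is the range of its level
utilities (max minus min) as a percentage of the summed ranges over all
in-design attributes; sample-level importance averages these percentages
across respondents.  Interaction utilities are excluded from the ranges:
importance is a main-effects summary of how much each attribute can swing a
product's total utility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import StudySpec

__all__ = ["respondent_importance", "importance_from_utilities", "mean_importance",
           "subgroup_contrast", "ImportanceTable"]


@dataclass
class ImportanceTable:
    """Mean attribute importances with 95% confidence intervals, plus the
    per-respondent importance matrix they were averaged from."""

    table: pd.DataFrame  # columns: attribute, mean_importance, ci_low, ci_high
    per_respondent: pd.DataFrame  # respondents x attributes, rows sum to 100


def respondent_importance(utilities: dict[str, np.ndarray] | pd.Series,
                          spec: StudySpec) -> pd.Series:
    """Importance percentages for one respondent.

    ``utilities`` maps each in-design attribute name to its per-level utility
    vector (or is a Series indexed by (attribute, level)).  Returns a Series
    of percentages over in-design attributes summing to 100.  If every
    attribute has zero range the importances are undefined; a uniform split
    is returned with a warning rather than dropping the respondent.
    """
    if isinstance(utilities, pd.Series):
        utilities = {
            attr.name: utilities.loc[attr.name].to_numpy()
            for attr in spec.design_attributes
        }
    ranges = {}
    for attr in spec.design_attributes:
        u = np.asarray(utilities[attr.name], dtype=float)
        if len(u) != attr.n_levels:
            raise ValueError(
                f"attribute {attr.name!r}: expected {attr.n_levels} level "
                f"utilities, got {len(u)}"
            )
        ranges[attr.name] = float(u.max() - u.min())
    total = sum(ranges.values())
    names = list(ranges)
    if total == 0.0:
        warnings.warn("all attribute ranges are zero; returning uniform importances")
        return pd.Series(100.0 / len(names), index=names)
    return pd.Series({k: 100.0 * r / total for k, r in ranges.items()})


def importance_from_utilities(point_utils: pd.DataFrame, spec: StudySpec) -> pd.DataFrame:
    """Per-respondent importances from a tidy per-level utility frame
    (columns respondent_id, attribute, level, utility, as produced by
    :func:`opendce.hb.point_utilities`).

    Interaction rows (attribute names containing ' x ') are ignored.
    Returns a respondents-by-attributes DataFrame of percentages.
    """
    in_design = [a.name for a in spec.design_attributes]
    main = point_utils[point_utils["attribute"].isin(in_design)]
    rows = {}
    for rid, g in main.groupby("respondent_id", sort=False):
        per_attr = {
            name: grp["utility"].to_numpy()
            for name, grp in g.groupby("attribute", sort=False)
        }
        rows[rid] = respondent_importance(per_attr, spec)
    return pd.DataFrame.from_dict(rows, orient="index")[in_design]


def mean_importance(per_respondent: pd.DataFrame) -> ImportanceTable:
    """Average per-respondent importances; 95% CI is mean +/- 1.96 SD/sqrt(n)
    across respondents.  Requires at least two respondents for a CI."""
    n = len(per_respondent)
    if n < 2:
        raise ValueError("confidence intervals need >= 2 respondents")
    m = per_respondent.mean(axis=0)
    half = 1.96 * per_respondent.std(axis=0, ddof=1) / np.sqrt(n)
    table = pd.DataFrame({
        "attribute": m.index,
        "mean_importance": m.to_numpy(),
        "ci_low": (m - half).to_numpy(),
        "ci_high": (m + half).to_numpy(),
    })
    return ImportanceTable(table=table, per_respondent=per_respondent)


def subgroup_contrast(per_respondent: pd.DataFrame,
                      grouping: np.ndarray | pd.Series) -> pd.DataFrame:
    """Welch two-sample comparison of mean importances between the two levels
    of a binary grouping variable (e.g. ever-use of modern contraception).

    Returns one row per attribute with the group means, their difference
    (group 1 minus group 0) and the Welch t-test p-value.
    """
    g = np.asarray(grouping).astype(int)
    if len(g) != len(per_respondent):
        raise ValueError("grouping length must match the number of respondents")
    mask1 = g == 1
    a = per_respondent[~mask1]
    b = per_respondent[mask1]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 respondents for a variance")
    rows = []
    for attr in per_respondent.columns:
        res = stats.ttest_ind(b[attr], a[attr], equal_var=False)
        rows.append({
            "attribute": attr,
            "mean_group0": a[attr].mean(),
            "mean_group1": b[attr].mean(),
            "difference": b[attr].mean() - a[attr].mean(),
            "p_value": float(res.pvalue),
        })
    return pd.DataFrame(rows)
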