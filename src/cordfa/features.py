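"""Feature expansion and per-feature screening t-tests.

The base table carries the four quadrant mean-FA features P, A, L, R.
Expansion adds every non-empty subset of the base regions, valued as the
unweighted arithmetic mean of its members, giving ``2**4 - 1 = 15``
features in a fixed canonical order (singletons, then pairs, then triples,
then the full set).  Because composites are row-wise means, composite group
means equal the means of component group means exactly — an invariant the
tests rely on.

Screening uses the pooled (Student) two-sample, two-tailed t-test per
feature, patient vs normal slices; Welch's correction is available as a
flag.  The pooled form is the default because a single pooled dispersion is
also what the synthetic cohort calibration inverts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .types import BASE_REGIONS, NORMAL_CLASS, PATIENT_CLASS, FeatureTable

#: The 15 expanded feature subsets in canonical order.
EXPANDED_SUBSETS: tuple[tuple[str, ...], ...] = (
    ("P",),
    ("A",),
    ("L",),
    ("R",),
    ("P", "A"),
    ("P", "L"),
    ("P", "R"),
    ("A", "L"),
    ("A", "R"),
    ("L", "R"),
    ("P", "A", "L"),
    ("A", "L", "R"),
    ("P", "A", "R"),
    ("P", "L", "R"),
    ("P", "A", "L", "R"),
)


def subset_name(subset: tuple[str, ...]) -> str:
    """Column name for a feature subset: 'P' for singletons, 'PA', 'PALR'…"""
    return "".join(subset)


#: Expanded feature column names in canonical order.
EXPANDED_NAMES: tuple[str, ...] = tuple(subset_name(s) for s in EXPANDED_SUBSETS)


def expand_features(base: FeatureTable) -> FeatureTable:
    """Expand a 4-feature base table to the 15 subset-average features.

    Rejects tables that are not exactly the base schema, so an expanded
    table can never be expanded twice.
    """
    if base.feature_names != list(BASE_REGIONS):
        raise DataError(
            "expansion requires exactly the base features "
            f"{list(BASE_REGIONS)}, got {base.feature_names}"
        )
    frame = base.frame.copy()
    for subset in EXPANDED_SUBSETS:
        if len(subset) == 1:
            continue  # base columns are copied unchanged
        frame[subset_name(subset)] = frame[list(subset)].mean(axis=1)
    return FeatureTable(frame, list(EXPANDED_NAMES))


@dataclass
class TTestReport:
    """Per-feature pooled two-sample t-test results."""

    table: pd.DataFrame  # columns: feature, t, p_value, df, mean_patient, mean_normal
    welch: bool = False

    def p_values(self) -> pd.Series:
        return self.table.set_index("feature")["p_value"]

    def to_dict(self) -> dict:
        return {
            "test": "welch" if self.welch else "pooled",
            "features": self.table.to_dict(orient="records"),
        }


def feature_ttests(table: FeatureTable, welch: bool = False) -> TTestReport:
    """Two-sample, two-tailed t-test of patient vs normal for each feature.

    Pooled variance by default (df = N - 2); Welch with ``welch=True``.
    A feature with zero variance in both groups and equal means is reported
    as t = 0, p = 1 rather than NaN.
    """
    labels = table.labels
    pat = labels == PATIENT_CLASS
    nor = labels == NORMAL_CLASS
    if pat.sum() < 2 or nor.sum() < 2:
        raise DataError("t-tests require at least two records per class")
    rows = []
    values = table.values
    for j, name in enumerate(table.feature_names):
        x = values[pat, j]
        y = values[nor, j]
        if np.var(x) == 0 and np.var(y) == 0:
            if x.mean() == y.mean():
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = np.inf, 0.0
        else:
            res = stats.ttest_ind(x, y, equal_var=not welch)
            t_stat, p = float(res.statistic), float(res.pvalue)
        df = (len(x) + len(y) - 2) if not welch else float("nan")
        rows.append(
            {
                "feature": name,
                "t": t_stat,
                "p_value": p,
                "df": df,
                "mean_patient": float(x.mean()),
                "mean_normal": float(y.mean()),
            }
        )
    return TTestReport(table=pd.DataFrame(rows), welch=welch)
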