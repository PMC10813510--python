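"""Chi-squared dataset evaluation.

Tests each categorical/binary attribute for independence from the binary
screening class via Pearson's chi-squared statistic on the contingency
table, Σ (O − E)² / E with E(i,j) = rowtotal_i · coltotal_j / N, without
continuity correction.  The p-value is the upper-tail mass of the
chi-squared distribution at df = (r − 1)(c − 1), i.e. the regularised upper
incomplete gamma function Q(df/2, statistic/2).

A small p-value is evidence against independence; attributes are flagged
significant at the conventional 0.05 level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaincc

from .data import CLASS_COLUMN, Dataset

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class ContingencyTable:
    observed: np.ndarray
    row_labels: list
    col_labels: list

    @property
    def total(self) -> int:
        return int(self.observed.sum())

    @property
    def testable(self) -> bool:
        return self.observed.shape[0] >= 2 and self.observed.shape[1] >= 2


@dataclass
class ChiSquaredResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    low_expected_flag: bool

    @property
    def significant(self) -> bool:
        return self.p_value <= SIGNIFICANCE_LEVEL


def build_contingency(feature_values, labels) -> ContingencyTable:
    """Cross-tabulate a categorical attribute against the class labels."""
    feature_values = np.asarray(feature_values)
    labels = np.asarray(labels)
    if len(feature_values) != len(labels):
        raise ValueError("feature and label vectors differ in length")
    if len(feature_values) == 0:
        raise ValueError("need at least one observation")
    table = pd.crosstab(pd.Series(feature_values), pd.Series(labels))
    return ContingencyTable(
        observed=table.to_numpy(dtype=np.int64),
        row_labels=list(table.index),
        col_labels=list(table.columns),
    )


def chi_squared_statistic(table: ContingencyTable) -> ChiSquaredResult:
    """Pearson statistic, degrees of freedom and expected counts.

    The p-value field is left at nan; combine with
    :func:`chi_squared_pvalue` or use :func:`chi_squared_test`.
    """
    obs = np.asarray(table.observed, dtype=float)
    r, c = obs.shape
    if r < 2 or c < 2:
        raise ValueError("contingency table must be at least 2x2 to test")
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    if np.any(row_tot == 0):
        empty = table.row_labels[int(np.argmin(row_tot))]
        raise ValueError(f"empty category {empty!r} (zero row total)")
    if np.any(col_tot == 0):
        empty = table.col_labels[int(np.argmin(col_tot))]
        raise ValueError(f"empty class {empty!r} (zero column total)")
    expected = np.outer(row_tot, col_tot) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    return ChiSquaredResult(
        statistic=statistic,
        df=(r - 1) * (c - 1),
        p_value=float("nan"),
        expected=expected,
        low_expected_flag=bool((expected < 5).any()),
    )


def chi_squared_pvalue(statistic: float, df: int) -> float:
    """Upper-tail probability of chi-squared(df) at ``statistic``."""
    if statistic < 0:
        raise ValueError("chi-squared statistic cannot be negative")
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(gammaincc(df / 2.0, statistic / 2.0))


def chi_squared_test(table: ContingencyTable) -> ChiSquaredResult:
    res = chi_squared_statistic(table)
    res.p_value = chi_squared_pvalue(res.statistic, res.df)
    return res


def evaluate_dataset(dataset: Dataset) -> pd.DataFrame:
    """Chi-squared report of every categorical/binary attribute vs class.

    Returns a frame (attribute, statistic, df, p_value, significant,
    low_expected) sorted by ascending p-value.  Attributes with a single
    observed level are untestable and are skipped with a warning column
    entry rather than an error.
    """
    if CLASS_COLUMN not in dataset.frame.columns:
        raise ValueError(f"dataset has no {CLASS_COLUMN!r} column")
    labels = dataset.labels
    rows = []
    for col, kind in dataset.schema.items():
        if col == CLASS_COLUMN or kind == "continuous":
            continue
        table = build_contingency(dataset.frame[col].to_numpy(), labels)
        if not table.testable:
            continue
        res = chi_squared_test(table)
        rows.append(
            {
                "attribute": col,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "significant": res.significant,
                "low_expected": res.low_expected_flag,
            }
        )
    if not rows:
        import warnings

        warnings.warn("no testable categorical attributes", UserWarning, stacklevel=2)
        return pd.DataFrame(
            columns=["attribute", "statistic", "df", "p_value", "significant", "low_expected"]
        )
    report = pd.DataFrame(rows).sort_values("p_value", kind="stable")
    return report.reset_index(drop=True)
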