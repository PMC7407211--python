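"""Cohort feature-table quality control and summary statistics.

A feature table is samples x lipids (µM, missing allowed) over the three
intervention timepoints (baseline CID1, post weight-loss CID2, post
maintenance CID3). QC discards features with more than 10 % missing
values or more than 10 % outliers by wide Tukey fences (k = 4 by
default). Downstream multivariate modelling (imputation, sPLS-DA, mixed
models) is deliberately left to dedicated tools; this module exports the
exact matrices those tools consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureTable",
    "QCDecision",
    "tukey_outlier_flags",
    "qc_filter",
    "log2_fold_change",
    "ttest_from_summary",
    "fisher_exact_2x2",
    "export_model_matrices",
]


@dataclass
class FeatureTable:
    """values: (sample_id, timepoint)-indexed frame, one column per lipid;
    sample_info: per-sample metadata with at least a ``group`` column."""

    values: pd.DataFrame
    sample_info: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate (sample, timepoint) rows")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy(dtype=float) < 0).any():
                raise ValueError("negative concentrations")

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def timepoint(self, tp: str) -> pd.DataFrame:
        frame = self.values.xs(tp, level="timepoint")
        return frame

    def groups(self) -> pd.Series:
        return self.sample_info["group"]


@dataclass
class QCDecision:
    feature: str
    fraction_missing: float
    fraction_outlier: float
    retained: bool


def tukey_outlier_flags(values, k: float = 4.0) -> np.ndarray:
    """Flag values outside the Tukey fences [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation between order statistics; missing
    values are excluded from the quartiles and never flagged. Constant
    data (IQR 0) flags nothing, by the strict-inequality fence rule.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() < 4:
        raise ValueError("need at least 4 non-missing values")
    q1, q3 = np.percentile(arr[finite], [25.0, 75.0], method="linear")
    iqr = q3 - q1
    flags = np.zeros(arr.shape, dtype=bool)
    flags[finite] = (arr[finite] < q1 - k * iqr) | (arr[finite] > q3 + k * iqr)
    return flags


def qc_filter(
    table: FeatureTable,
    max_missing: float = 0.10,
    max_outlier: float = 0.10,
    k: float = 4.0,
) -> tuple[FeatureTable, list[QCDecision]]:
    """Discard features with more than ``max_missing`` missing values or
    more than ``max_outlier`` Tukey-fence outliers (among non-missing)."""
    if table.values.empty:
        raise ValueError("empty feature table")
    decisions = []
    keep = []
    n_rows = len(table.values)
    for feature in table.features:
        col = table.values[feature].to_numpy(dtype=float)
        n_missing = int(np.count_nonzero(~np.isfinite(col)))
        frac_missing = n_missing / n_rows
        n_obs = n_rows - n_missing
        if n_obs >= 4:
            frac_outlier = tukey_outlier_flags(col, k=k).sum() / n_obs
        else:
            frac_outlier = 1.0  # effectively unmeasurable -> fails QC
        retained = frac_missing <= max_missing and frac_outlier <= max_outlier
        decisions.append(
            QCDecision(
                feature=feature,
                fraction_missing=frac_missing,
                fraction_outlier=float(frac_outlier),
                retained=retained,
            )
        )
        if retained:
            keep.append(feature)
    filtered = FeatureTable(
        values=table.values[keep], sample_info=table.sample_info
    )
    return filtered, decisions


def log2_fold_change(
    table: FeatureTable, from_tp: str = "CID1", to_tp: str = "CID2"
) -> pd.DataFrame:
    """Per-sample, per-feature log2(value_to / value_from); missing or
    zero inputs propagate to missing output."""
    a = table.timepoint(from_tp)
    b = table.timepoint(to_tp)
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = b.to_numpy(dtype=float) / a.to_numpy(dtype=float)
        out = np.log2(ratio)
    out[~np.isfinite(out)] = np.nan
    return pd.DataFrame(out, index=common, columns=a.columns)


def ttest_from_summary(
    m1: float,
    sd1: float,
    n1: int,
    m2: float,
    sd2: float,
    n2: int,
    kind: str = "welch",
) -> tuple[float, float, float]:
    """Two-sample two-sided t-test from summary statistics.

    Welch (default) uses the Satterthwaite degrees of freedom; ``pooled``
    uses the equal-variance statistic. Returns (t, df, p). Two degenerate
    zero-variance groups with equal means return t = 0, p = 1.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("negative standard deviation")
    v1, v2 = sd1**2, sd2**2
    if v1 == 0 and v2 == 0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0
        return math.inf if m1 > m2 else -math.inf, float(n1 + n2 - 2), 0.0
    if kind == "welch":
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / math.sqrt(se2)
        df = se2**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    elif kind == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        raise ValueError(f"unknown t-test kind: {kind!r}")
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]]
    (sum of hypergeometric tables no more probable than the observed)."""
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    if (a + b == 0 or c + d == 0) or (a + c == 0 or b + d == 0):
        raise ValueError("margins must be positive")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def export_model_matrices(
    table: FeatureTable,
    covariates: pd.DataFrame | None = None,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Matrices for external multivariate modelling: baseline lipid levels,
    weight-loss log2 fold-changes, optional clinical covariates, and a
    stratified (by group) train/test split with seeded randomness."""
    baseline = table.timepoint("CID1")
    fc = log2_fold_change(table, "CID1", "CID2")
    groups = table.groups().loc[baseline.index]
    rng = np.random.default_rng(seed)
    test_ids = []
    for g in sorted(groups.unique()):
        ids = np.array(sorted(groups[groups == g].index))
        n_test = int(round(test_fraction * ids.size))
        test_ids.extend(rng.choice(ids, size=n_test, replace=False))
    split = pd.DataFrame(
        {
            "group": groups,
            "partition": [
                "test" if s in set(test_ids) else "train" for s in baseline.index
            ],
        },
        index=baseline.index,
    )
    out = {"baseline": baseline, "log2_fold_change": fc, "split": split}
    if covariates is not None:
        out["covariates"] = covariates.loc[baseline.index]
    return out
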