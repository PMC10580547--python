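"""Feature-matrix reduction: outlier fences, trial averaging, pruning.

Per-trial feature values are screened against Tukey-style interquartile
fences (Q1 - 1.5*IQR, Q3 + 1.5*IQR) computed per feature *within each age
group*, so genuine age effects are not flagged as anomalies.  Flagged values
are winsorized to the nearest fence by default (keeping the matrix complete
for the projection stage) or dropped from the trial average.  After
averaging, redundant features are removed by a greedy pairwise Pearson scan
at |r| > 0.9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CORRELATION_THRESHOLD = 0.9


@dataclass
class ReductionReport:
    outlier_flags: list = field(default_factory=list)   # (participant, feature, trial)
    pruned_features: list = field(default_factory=list)  # (removed, kept_partner, r)
    constant_features: list = field(default_factory=list)
    kept_features: list = field(default_factory=list)


def iqr_fences(values) -> tuple[float, float]:
    """Tukey fences (Q1 - 1.5*IQR, Q3 + 1.5*IQR), linear-interpolation quartiles."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for quartile fences")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)


def handle_outliers(
    trial_features: pd.DataFrame,
    groups: pd.Series,
    mode: str = "winsorize",
) -> tuple[pd.DataFrame, list]:
    """Flag per-trial values outside the per-(feature, group) fences.

    ``mode='winsorize'`` clips to the nearest fence; ``mode='drop'`` sets
    the value to NaN so it is excluded from the trial average.
    Returns the treated matrix and the flag list (participant, feature,
    trial).
    """
    if mode not in ("winsorize", "drop"):
        raise ValueError("mode must be 'winsorize' or 'drop'")
    out = trial_features.copy()
    flags: list = []
    part_groups = groups.reindex(out.index.get_level_values("participant_id")).to_numpy()
    for g in np.unique(part_groups):
        sel = part_groups == g
        block = out.loc[sel]
        if block.shape[0] < 4:
            logger.warning("group %s has <4 trial rows; fences are unstable", g)
        for col in out.columns:
            vals = block[col].to_numpy(dtype=float)
            if vals.size < 4:
                continue
            lo, hi = iqr_fences(vals)
            outside = (vals < lo) | (vals > hi)
            if not outside.any():
                continue
            idx = block.index[outside]
            for pid, trial in idx:
                flags.append((pid, col, trial))
            if mode == "winsorize":
                out.loc[idx, col] = np.clip(vals[outside], lo, hi)
            else:
                out.loc[idx, col] = np.nan
    return out, flags


def average_trials(trial_features: pd.DataFrame, groups: pd.Series | None = None) -> pd.DataFrame:
    """Per-participant mean over surviving trial values.

    A (participant, feature) cell with no surviving trials is imputed with
    the group median (requires ``groups``), with a warning.
    """
    mean = trial_features.groupby(level="participant_id", sort=False).mean()
    if mean.isna().any().any():
        if groups is None:
            raise ValueError("all trials missing for some cells and no groups for imputation")
        logger.warning("imputing %d empty cells with group medians", int(mean.isna().sum().sum()))
        grp = groups.reindex(mean.index)
        med = mean.groupby(grp.to_numpy()).transform("median")
        mean = mean.fillna(med)
    return mean


def prune_correlated(
    features: pd.DataFrame,
    threshold: float = CORRELATION_THRESHOLD,
    report: ReductionReport | None = None,
) -> tuple[pd.DataFrame, ReductionReport]:
    """Greedy removal of redundant columns with |Pearson r| above threshold.

    Columns are scanned in their given (canonical) order; when a kept column
    and a later candidate correlate beyond the threshold in absolute value,
    the candidate is removed.  Constant columns are removed first.  No
    surviving pair correlates beyond the threshold.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if features.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    report = report or ReductionReport()
    values = features.to_numpy(dtype=float)
    sd = values.std(axis=0)
    constant = sd == 0.0
    if constant.any():
        report.constant_features = list(features.columns[constant])
        logger.info("removing %d constant columns", int(constant.sum()))
        features = features.loc[:, ~constant]
        values = values[:, ~constant]
    corr = np.corrcoef(values, rowvar=False)
    n = features.shape[1]
    keep = np.ones(n, dtype=bool)
    cols = list(features.columns)
    for j in range(n):
        if not keep[j]:
            continue
        for k in range(j + 1, n):
            if keep[k] and abs(corr[j, k]) > threshold:
                keep[k] = False
                report.pruned_features.append((cols[k], cols[j], float(corr[j, k])))
    kept = features.loc[:, keep]
    report.kept_features = list(kept.columns)
    return kept, report


def reduce_features(
    trial_features: pd.DataFrame,
    groups: pd.Series,
    threshold: float = CORRELATION_THRESHOLD,
    outlier_mode: str = "winsorize",
) -> tuple[pd.DataFrame, ReductionReport]:
    """Full reduction chain: outlier handling -> trial average -> pruning."""
    report = ReductionReport()
    treated, flags = handle_outliers(trial_features, groups, mode=outlier_mode)
    report.outlier_flags = flags
    averaged = average_trials(treated, groups)
    reduced, report = prune_correlated(averaged, threshold=threshold, report=report)
    return reduced, report
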