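"""Nonparametric screens and summaries around the feature grid.

The screening logic mirrors the field's standard recipe: Shapiro-Wilk per
(feature, group) to justify rank-based tests, Mann-Whitney per feature for
the pooled young (groups 1-4, under 60) vs elderly (groups 5-8) comparison
at alpha = 0.05 without multiplicity correction, Kruskal-Wallis plus
Bonferroni-corrected pairwise Mann-Whitney over the 8 x 7 / 2 = 28 group
pairs for the LDA-value, and Pearson correlation against age.  The tally
rules summarize how often each parameter, task, sensor, sensor type and
IMU appears among the significant features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .features import PARAMETER_GROUPS, PARAMETERS, TASKS, parse_feature_name
from .preprocess import SENSOR_IDS

logger = logging.getLogger(__name__)

ALPHA = 0.05
YOUNG_GROUPS = (1, 2, 3, 4)
ELDERLY_GROUPS = (5, 6, 7, 8)

SENSOR_TYPES = {"accelerometer": ("A1", "A2"), "gyroscope": ("G1", "G2"), "magnetometer": ("M1", "M2")}
IMUS = {"IMU1": ("A1", "G1", "M1"), "IMU2": ("A2", "G2", "M2")}


def normality_screen(features: pd.DataFrame, groups) -> pd.DataFrame:
    """Shapiro-Wilk p-value per (feature, group).

    Returns a DataFrame indexed by feature with one column per group; the
    attribute ``df.attrs['all_normal']`` is True iff every p >= 0.05.
    """
    groups = np.asarray(groups)
    out = {}
    for g in np.unique(groups):
        sel = groups == g
        if sel.sum() < 3:
            raise ValueError(f"group {g} has fewer than 3 members")
        pvals = []
        for col in features.columns:
            x = features.loc[sel, col].to_numpy(dtype=float)
            if np.ptp(x) == 0.0:
                logger.warning("constant sample for %s in group %s; p set to 0", col, g)
                pvals.append(0.0)
                continue
            pvals.append(float(spstats.shapiro(x).pvalue))
        out[g] = pvals
    df = pd.DataFrame(out, index=features.columns)
    df.attrs["all_normal"] = bool((df.to_numpy() >= ALPHA).all())
    return df


def young_elderly_test(
    features: pd.DataFrame,
    groups,
    young_groups=YOUNG_GROUPS,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney per feature, pooled young vs pooled elderly.

    No multiplicity correction is applied (each feature is screened at the
    nominal alpha).  Returns a significance table with ``p_value`` and
    ``significant`` columns indexed by feature.
    """
    groups = np.asarray(groups)
    young = np.isin(groups, young_groups)
    old = ~young
    if not young.any() or not old.any():
        raise ValueError("both pooled groups must be non-empty")
    pvals = []
    for col in features.columns:
        a = features.loc[young, col].to_numpy(dtype=float)
        b = features.loc[old, col].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0.0:
            logger.warning("feature %s is all-tied; p set to 1", col)
            pvals.append(1.0)
            continue
        pvals.append(float(spstats.mannwhitneyu(a, b, alternative="two-sided").pvalue))
    table = pd.DataFrame({"p_value": pvals}, index=features.columns)
    table["significant"] = table["p_value"] < alpha
    return table


@dataclass
class PairwiseGroupResult:
    """Omnibus Kruskal-Wallis plus Bonferroni-corrected pairwise matrix."""

    omnibus_p: float
    p_values: pd.DataFrame       # symmetric, NaN diagonal, corrected
    n_pairs: int
    alpha: float = ALPHA

    @property
    def significant(self) -> pd.DataFrame:
        return self.p_values < self.alpha


def pairwise_group_test(values, groups, alpha: float = ALPHA) -> PairwiseGroupResult:
    """All-pairs comparison of a scalar score across the age groups.

    Kruskal-Wallis across all groups, then two-sided Mann-Whitney for each
    of the g*(g-1)/2 pairs with Bonferroni correction (p multiplied by the
    number of pairs, capped at 1).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    samples = {g: values[groups == g] for g in labels}
    if any(s.size < 2 for s in samples.values()):
        raise ValueError("every group needs at least 2 members")
    omnibus = float(spstats.kruskal(*samples.values()).pvalue)
    n_pairs = labels.size * (labels.size - 1) // 2
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for gi, gj in combinations(labels, 2):
        p = float(
            spstats.mannwhitneyu(samples[gi], samples[gj], alternative="two-sided").pvalue
        )
        p_corr = min(1.0, p * n_pairs)
        mat.loc[gi, gj] = mat.loc[gj, gi] = p_corr
    return PairwiseGroupResult(omnibus_p=omnibus, p_values=mat, n_pairs=n_pairs, alpha=alpha)


def age_correlation(values, ages) -> tuple[float, float]:
    """Pearson correlation (r, p) between a score and age."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 participants")
    if np.ptp(values) == 0.0 or np.ptp(ages) == 0.0:
        raise ValueError("correlation undefined for a constant input")
    r, p = spstats.pearsonr(values, ages)
    return float(r), float(p)


@dataclass
class TallyReport:
    """How often each parameter/task/sensor appears among significant features."""

    per_feature: dict = field(default_factory=dict)          # parameter -> count
    per_param_group: dict = field(default_factory=dict)      # family -> count
    per_param_group_proportion: dict = field(default_factory=dict)
    per_task: dict = field(default_factory=dict)
    per_sensor: dict = field(default_factory=dict)
    per_sensor_type: dict = field(default_factory=dict)
    per_imu: dict = field(default_factory=dict)
    total: int = 0

    def as_dict(self) -> dict:
        return {
            "per_feature": self.per_feature,
            "per_param_group": self.per_param_group,
            "per_param_group_proportion": self.per_param_group_proportion,
            "per_task": self.per_task,
            "per_sensor": self.per_sensor,
            "per_sensor_type": self.per_sensor_type,
            "per_imu": self.per_imu,
            "total": self.total,
        }


def tally_significant(table: pd.DataFrame) -> TallyReport:
    """Aggregate a significance table over the feature grid (rules a-g).

    ``table`` is indexed by feature names of the form PARAM_SENSOR_Ttask
    with a boolean ``significant`` column.  Sensor types sum A1+A2, G1+G2,
    M1+M2; IMUs sum A1+G1+M1 (forearm) and A2+G2+M2 (hand).
    """
    if table.empty:
        raise ValueError("empty significance table")
    rep = TallyReport(
        per_feature={p: 0 for p in PARAMETERS},
        per_param_group={k: 0 for k in PARAMETER_GROUPS},
        per_task={t: 0 for t in TASKS},
        per_sensor={s: 0 for s in SENSOR_IDS},
    )
    family_of = {p: fam for fam, ps in PARAMETER_GROUPS.items() for p in ps}
    for name, sig in table["significant"].items():
        if not sig:
            continue
        param, sensor, task = parse_feature_name(name)
        rep.per_feature[param] += 1
        rep.per_param_group[family_of[param]] += 1
        rep.per_task[task] += 1
        rep.per_sensor[sensor] += 1
        rep.total += 1
    rep.per_sensor_type = {
        name: sum(rep.per_sensor[s] for s in sensors)
        for name, sensors in SENSOR_TYPES.items()
    }
    rep.per_imu = {
        name: sum(rep.per_sensor[s] for s in sensors) for name, sensors in IMUS.items()
    }
    total = max(rep.total, 1)
    rep.per_param_group_proportion = {
        k: v / total for k, v in rep.per_param_group.items()
    }
    return rep
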