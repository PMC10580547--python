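"""The 18 signal parameters and the 324-column feature grid.

Every conditioned resultant signal yields 18 parameters in four families:

* amplitude — MAV, MAVFD, MAVSD, RMS, Peak
* frequency — ZC, FMean, FPeak, F50, F80, Power3.5_7.5
* entropy   — ApEn, FuzzyEn
* statistics — VAR, RANGE, INTQ, SKEWNESS, KURTOSIS

Computed per sensor (A1, A2, G1, G2, M1, M2) and per task (1-3), the grid is
18 x 6 x 3 = 324 named features per participant and trial.

Conventions that the literature leaves open are fixed here and exposed on
:class:`ParamConfig`: the variance is the raw sum of squared deviations (no
1/N), skewness/kurtosis use the population standard deviation, quartiles
interpolate linearly between order statistics, and the entropies use
m=2, r=0.2*SD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .preprocess import SENSOR_IDS, preprocess_trial

logger = logging.getLogger(__name__)

PARAMETERS = (
    "MAV", "MAVFD", "MAVSD", "RMS", "Peak",
    "ZC", "FMean", "FPeak", "F50", "F80", "Power3.5_7.5",
    "ApEn", "FuzzyEn",
    "VAR", "RANGE", "INTQ", "SKEWNESS", "KURTOSIS",
)

PARAMETER_GROUPS = {
    "amplitude": ("MAV", "MAVFD", "MAVSD", "RMS", "Peak"),
    "frequency": ("ZC", "FMean", "FPeak", "F50", "F80", "Power3.5_7.5"),
    "entropy": ("ApEn", "FuzzyEn"),
    "statistic": ("VAR", "RANGE", "INTQ", "SKEWNESS", "KURTOSIS"),
}

TASKS = (1, 2, 3)

POWER_BAND = (3.5, 7.5)


@dataclass
class ParamConfig:
    """Tunable conventions for the parameter computations."""

    apen_m: int = 2
    apen_r_coeff: float = 0.2
    fuzzy_m: int = 2
    fuzzy_r_coeff: float = 0.2
    fuzzy_gradient: float = 2.0
    psd_method: str = "welch"          # or "periodogram"
    welch_segment: int = 256
    quartile_rule: str = "linear"      # numpy 'linear' interpolation
    variance_mode: str = "printed"     # raw sum of squares; "sample" for /(N-1)
    moment_sd: str = "population"      # sigma in skewness/kurtosis

    def __post_init__(self) -> None:
        if self.apen_m < 1 or self.fuzzy_m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.apen_r_coeff <= 0 or self.fuzzy_r_coeff <= 0:
            raise ValueError("tolerance coefficient must be positive")


def feature_name(param: str, sensor: str, task: int) -> str:
    return f"{param}_{sensor}_T{task}"


def all_feature_names() -> list[str]:
    """The 324 feature keys in canonical (parameter, sensor, task) order."""
    return [
        feature_name(p, s, t)
        for p in PARAMETERS
        for s in SENSOR_IDS
        for t in TASKS
    ]


def parse_feature_name(name: str) -> tuple[str, str, int]:
    param, sensor, task = name.rsplit("_", 2)
    return param, sensor, int(task.lstrip("T"))


# ---------------------------------------------------------------------------
# amplitude family


def amplitude_features(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples (second difference)")
    peak = float(np.max(x))
    if peak <= 0:
        logger.debug("no positive sample; Peak set to 0")
        peak = 0.0
    return {
        "MAV": float(np.mean(np.abs(x))),
        "MAVFD": float(np.mean(np.abs(np.diff(x)))),
        "MAVSD": float(np.mean(np.abs(x[2:] - x[:-2]))),
        "RMS": float(np.sqrt(np.mean(x**2))),
        "Peak": peak,
    }


def zero_crossings(x: np.ndarray) -> int:
    """Count strict sign changes between consecutive samples.

    Exact zeros never contribute: a crossing requires one sample strictly
    positive and the next strictly negative (or vice versa).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    a, b = x[:-1], x[1:]
    return int(np.count_nonzero(((a > 0) & (b < 0)) | ((a < 0) & (b > 0))))


# ---------------------------------------------------------------------------
# frequency family


def power_spectrum(
    x: np.ndarray, fs: float, cfg: ParamConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Power spectral density estimate (f, P)."""
    cfg = cfg or ParamConfig()
    x = np.asarray(x, dtype=float)
    if cfg.psd_method == "periodogram":
        f, P = sps.periodogram(x, fs=fs)
    elif cfg.psd_method == "welch":
        nperseg = min(cfg.welch_segment, x.size)
        f, P = sps.welch(x, fs=fs, window="hann", nperseg=nperseg)
    else:
        raise ValueError(f"unknown psd_method {cfg.psd_method!r}")
    return f, P


def spectral_features(
    x: np.ndarray, fs: float, cfg: ParamConfig | None = None
) -> dict[str, float]:
    """Mean/peak/median/80%-power frequencies and tremor-band power.

    F50 and F80 are resolved to the first grid frequency where the
    cumulative power reaches 50% / 80% of the total (grid-anchored, no
    interpolation).
    """
    cfg = cfg or ParamConfig()
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError("need at least 64 samples for a spectral estimate")
    if fs <= 2 * POWER_BAND[1]:
        raise ValueError("band edge 7.5 Hz must lie below Nyquist")
    f, P = power_spectrum(x, fs, cfg)
    total = float(P.sum())
    if total <= 0.0:
        logger.warning("degenerate (all-zero) spectrum; spectral features set to 0")
        return {k: 0.0 for k in ("FMean", "FPeak", "F50", "F80", "Power3.5_7.5")}
    cum = np.cumsum(P)
    f50 = float(f[np.searchsorted(cum, 0.5 * total)])
    f80 = float(f[np.searchsorted(cum, 0.8 * total)])
    band = (f >= POWER_BAND[0]) & (f <= POWER_BAND[1])
    return {
        "FMean": float((P * f).sum() / total),
        "FPeak": float(f[np.argmax(P)]),
        "F50": f50,
        "F80": f80,
        "Power3.5_7.5": float(P[band].sum()),
    }


# ---------------------------------------------------------------------------
# statistics family


def statistical_features(
    x: np.ndarray, cfg: ParamConfig | None = None
) -> dict[str, float]:
    cfg = cfg or ParamConfig()
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    dev = x - x.mean()
    ss = float(np.sum(dev**2))
    var = ss if cfg.variance_mode == "printed" else ss / (x.size - 1)
    q1, q3 = np.percentile(x, [25, 75])  # linear interpolation
    if ss == 0.0:
        logger.warning("constant series; SKEWNESS/KURTOSIS set to 0")
        skew = kurt = 0.0
    else:
        skew = float(spstats.skew(x, bias=True))
        kurt = float(spstats.kurtosis(x, fisher=False, bias=True))
    return {
        "VAR": var,
        "RANGE": float(np.ptp(x)),
        "INTQ": float(q3 - q1),
        "SKEWNESS": skew,
        "KURTOSIS": kurt,
    }


# ---------------------------------------------------------------------------
# entropy family


def _chebyshev_windows(diff_abs: np.ndarray, m: int, size: int) -> np.ndarray:
    """Chebyshev distance between the first ``size`` length-m templates.

    ``diff_abs[i, j] = |x_i - x_j|``; the distance between windows starting
    at i and j is the running maximum over the m shifted diagonals, which
    avoids materializing the (size, size, m) embedding differences.
    """
    d = diff_abs[:size, :size].copy()
    for k in range(1, m):
        np.maximum(d, diff_abs[k : k + size, k : k + size], out=d)
    return d


def _apen_phi(diff_abs: np.ndarray, n: int, m: int, r: float) -> float:
    size = n - m + 1
    d = _chebyshev_windows(diff_abs, m, size)
    c = np.count_nonzero(d <= r, axis=1) / size
    return float(np.mean(np.log(c)))                   # self-match keeps c > 0


def approximate_entropy(x: np.ndarray, cfg: ParamConfig | None = None) -> float:
    """Approximate entropy ApEn(m, r, N), r expressed as a fraction of SD.

    Template matching uses the Chebyshev distance and counts self-matches,
    so the log arguments are always positive.  A constant series returns 0
    (perfect predictability).
    """
    cfg = cfg or ParamConfig()
    x = np.asarray(x, dtype=float)
    m = cfg.apen_m
    if x.size < 2 * (m + 1):
        raise ValueError("series too short for ApEn")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = cfg.apen_r_coeff * sd
    diff_abs = np.abs(x[:, None] - x[None, :])
    return _apen_phi(diff_abs, x.size, m, r) - _apen_phi(diff_abs, x.size, m + 1, r)


def _fuzzy_phi(
    x: np.ndarray, diff: np.ndarray, m: int, size: int, r: float, gradient: float
) -> float:
    """Mean fuzzy similarity over the first ``size`` length-m templates.

    Templates are mean-centred; centring shifts ``x_{i+k} - x_{j+k}`` by the
    difference of the window means, so the centred Chebyshev distance is
    again a running maximum over shifted diagonals of the signed
    difference matrix.
    """
    win_means = np.convolve(x, np.ones(m) / m, mode="valid")[:size]
    dm = win_means[:, None] - win_means[None, :]
    d = np.abs(diff[:size, :size] - dm)
    for k in range(1, m):
        np.maximum(d, np.abs(diff[k : k + size, k : k + size] - dm), out=d)
    mu = np.exp(-((d / r) ** gradient))
    np.fill_diagonal(mu, 0.0)                          # j != i
    return float(np.mean(mu.sum(axis=1) / (size - 1)))


def fuzzy_entropy(x: np.ndarray, cfg: ParamConfig | None = None) -> float:
    """Fuzzy entropy FuzzyEn(m, r, N) with membership exp(-(d/r)^gradient).

    Normalizing the distance by the tolerance before exponentiation keeps
    the measure invariant under rescaling of the signal when r is expressed
    as a fraction of the SD.

    Template vectors are mean-centred, similarity excludes self-matches,
    both window lengths use the same N-m templates, and r is a fraction of
    the series SD.  A constant series returns 0 (all similarities are 1).
    """
    cfg = cfg or ParamConfig()
    x = np.asarray(x, dtype=float)
    m = cfg.fuzzy_m
    if x.size < 2 * (m + 1):
        raise ValueError("series too short for FuzzyEn")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = cfg.fuzzy_r_coeff * sd
    size = x.size - m
    diff = x[:, None] - x[None, :]
    p_m = _fuzzy_phi(x, diff, m, size, r, cfg.fuzzy_gradient)
    p_m1 = _fuzzy_phi(x, diff, m + 1, size, r, cfg.fuzzy_gradient)
    return math.log(p_m) - math.log(p_m1)


# ---------------------------------------------------------------------------
# assembly


def compute_parameters(
    x: np.ndarray, fs: float, cfg: ParamConfig | None = None
) -> dict[str, float]:
    """All 18 parameters of one resultant signal."""
    cfg = cfg or ParamConfig()
    out = amplitude_features(x)
    out["ZC"] = float(zero_crossings(x))
    out.update(spectral_features(x, fs, cfg))
    out["ApEn"] = approximate_entropy(x, cfg)
    out["FuzzyEn"] = fuzzy_entropy(x, cfg)
    out.update(statistical_features(x, cfg))
    return out


@dataclass
class FeatureExtraction:
    """Per-trial feature matrix plus participant metadata."""

    trial_features: pd.DataFrame  # index (participant_id, trial), 324 columns
    ages: pd.Series               # index participant_id
    groups: pd.Series             # index participant_id


def extract_feature_matrix(cohort, cfg: ParamConfig | None = None) -> FeatureExtraction:
    """Compute the 324-feature grid for every trial of every participant.

    ``cohort`` is a :class:`motorage.cohort.Cohort` (or anything exposing the
    same ``participants`` records).  Signals are conditioned with
    :func:`motorage.preprocess.preprocess_trial` before parameters are
    computed.
    """
    cfg = cfg or ParamConfig()
    columns = all_feature_names()
    rows: dict[tuple, dict[str, float]] = {}
    for part in cohort.participants:
        for trial in range(1, cohort.spec.n_trials + 1):
            row = rows.setdefault((part.participant_id, trial), {})
            for task in TASKS:
                for sensor in SENSOR_IDS:
                    t = part.trial_signal(task, trial, sensor)
                    res = preprocess_trial(t)
                    vals = compute_parameters(res.values, res.fs, cfg)
                    for p, v in vals.items():
                        row[feature_name(p, sensor, task)] = v
    df = pd.DataFrame.from_dict(rows, orient="index")[columns]
    df.index = pd.MultiIndex.from_tuples(df.index, names=["participant_id", "trial"])
    ages = pd.Series(
        {p.participant_id: p.age for p in cohort.participants}, name="age"
    )
    groups = pd.Series(
        {p.participant_id: p.group for p in cohort.participants}, name="group"
    )
    return FeatureExtraction(df, ages, groups)
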