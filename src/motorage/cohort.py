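"""Synthetic cohorts for the motor-aging pipeline.

The study cohort (99 adults in eight decade-wide age groups, recorded with
two 9-axis IMUs on the hand and forearm at 50 Hz) is not public, so this
module generates stand-in cohorts with the statistical structure the
pipeline assumes:

* eight age groups with the published sizes and age means/SDs;
* band-limited oscillatory signals (physiological-tremor-like, ~5 Hz) whose
  amplitude and noise-to-signal ratio drift monotonically with age;
* magnetometer channels as low-amplitude slow drift + noise, with a much
  smaller age effect (magnetometers were the least discriminative sensors);
* optional redundant feature pairs (|r| > 0.9) and trial-level outlier
  contamination, with a ground-truth registry so downstream recovery can be
  scored.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import SENSOR_IDS, TrialSignal

# Published cohort structure: sizes and age mean +/- sd per group.
DEFAULT_GROUP_SIZES = (13, 12, 13, 15, 11, 14, 13, 8)
DEFAULT_AGE_MEANS = (24.53, 35.17, 45.15, 54.87, 64.45, 74.71, 84.53, 93.62)
DEFAULT_AGE_SDS = (3.09, 3.16, 3.02, 3.02, 2.87, 2.84, 2.87, 2.67)

TASKS = (1, 2, 3)

# Baseline signal scales per sensor family (arbitrary but fixed units:
# accelerometer ~ m/s^2 tremor band, gyroscope ~ deg/s, magnetometer ~ gauss).
_BASE_AMPLITUDE = {"A": 0.5, "G": 10.0, "M": 0.05}
# Task modulation: rest, pinch (hardest, largest tremor), pronation/supination.
_TASK_AMPLITUDE = {1: 0.8, 2: 1.2, 3: 1.0}
_AXIS_WEIGHTS = np.array([0.8, 0.55, 0.3])
_AGE_REF = 20.0          # youngest age in the cohort; effects are drifts from here
_MAG_EFFECT_ATTENUATION = 0.3
_CONTAMINATION_GAIN = 8.0  # amplitude multiplier for a contaminated trial


@dataclass(frozen=True)
class CohortSpec:
    """Cohort structure: eight age groups recorded at 50 Hz, 3 tasks x 3 trials."""

    group_sizes: tuple = DEFAULT_GROUP_SIZES
    group_age_means: tuple = DEFAULT_AGE_MEANS
    group_age_sds: tuple = DEFAULT_AGE_SDS
    seed: int = 0
    fs: float = 50.0
    trial_duration: float = 10.0
    n_trials: int = 3

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if not (len(self.group_sizes) == len(self.group_age_means) == len(self.group_age_sds)):
            raise ValueError("group_sizes, group_age_means, group_age_sds must align")
        if self.trial_duration < 1.0:
            raise ValueError("trial_duration must be at least 1 s")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    @property
    def n_participants(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_duration * self.fs))


@dataclass(frozen=True)
class EffectModel:
    """How strongly, and where, age shapes the synthetic data.

    ``slope_scale`` is the fractional drift per year of the affected signal
    properties (amplitude and noise-to-signal ratio), referenced to age 20;
    0.015/yr roughly doubles tremor amplitude from age 20 to 90, a
    magnitude consistent with reported age trends in physiological tremor.
    ``noise_sd`` is the baseline noise-to-signal ratio (signals) or the
    residual SD (feature-level generator).  ``affected_fraction`` and
    ``duplicate_pairs`` only apply to the feature-level generator.
    """

    affected_fraction: float = 0.35
    slope_scale: float = 0.015
    duplicate_pairs: int = 0
    contamination_rate: float = 0.0
    noise_sd: float = 0.3
    individual_sd: float = 0.15  # between-participant lognormal spread

    def __post_init__(self) -> None:
        if not (0.0 < self.affected_fraction <= 1.0):
            raise ValueError("affected_fraction must be in (0, 1]")
        if not (0.0 <= self.contamination_rate <= 0.1):
            raise ValueError("contamination_rate must be in [0, 0.1]")
        if self.duplicate_pairs < 0:
            raise ValueError("duplicate_pairs must be non-negative")


@dataclass
class GroundTruth:
    """What the generator actually injected, for scoring recovery."""

    affected_features: list = field(default_factory=list)
    duplicate_pairs: list = field(default_factory=list)   # (copy, source, target_r)
    outliers: list = field(default_factory=list)          # signal: (pid, task, trial, sensor)
    outlier_cells: list = field(default_factory=list)     # features: (pid, feature, trial)
    amplitude_factor: dict = field(default_factory=dict)  # pid -> age+individual gain


@dataclass
class Participant:
    participant_id: str
    age: float
    group: int
    signals: dict  # (task, trial) -> {sensor: ndarray (3, n)}
    fs: float

    def trial_signal(self, task: int, trial: int, sensor: str) -> TrialSignal:
        xyz = self.signals[(task, trial)][sensor]
        return TrialSignal.from_array(
            xyz, fs=self.fs, sensor_id=sensor, task_id=task, trial_index=trial
        )


@dataclass
class Cohort:
    spec: CohortSpec
    effect: EffectModel
    participants: list
    registry: GroundTruth

    @property
    def ages(self) -> pd.Series:
        return pd.Series({p.participant_id: p.age for p in self.participants}, name="age")

    @property
    def groups(self) -> pd.Series:
        return pd.Series({p.participant_id: p.group for p in self.participants}, name="group")

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [p.participant_id for p in self.participants],
                "age": [p.age for p in self.participants],
                "group": [p.group for p in self.participants],
            }
        )

    def write_csv(self, outdir) -> None:
        """One CSV per participant-task-trial plus a cohort manifest."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.manifest().to_csv(outdir / "manifest.csv", index=False)
        n = self.spec.samples_per_trial
        time = np.arange(n) / self.spec.fs
        for p in self.participants:
            for (task, trial), sensors in p.signals.items():
                cols = {"time": time}
                for sensor in SENSOR_IDS:
                    for ax_i, ax in enumerate("xyz"):
                        cols[f"{sensor}_{ax}"] = sensors[sensor][ax_i]
                pd.DataFrame(cols).to_csv(
                    outdir / f"{p.participant_id}_T{task}_trial{trial}.csv", index=False
                )


def _draw_ages(rng: np.random.Generator, spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian ages per group, truncated to non-overlapping decade bands."""
    ages, groups = [], []
    for g, (n, mu, sd) in enumerate(
        zip(spec.group_sizes, spec.group_age_means, spec.group_age_sds), start=1
    ):
        lo, hi = 20.0 + 10.0 * (g - 1), 30.0 + 10.0 * (g - 1)
        for _ in range(n):
            a = rng.normal(mu, sd)
            for _ in range(200):
                if lo <= a < hi:
                    break
                a = rng.normal(mu, sd)
            groups.append(g)
            ages.append(float(np.clip(a, lo, hi - 1e-6)))
    return np.array(ages), np.array(groups)


def _synth_trial(
    rng: np.random.Generator,
    sensor: str,
    task: int,
    n: int,
    fs: float,
    amp_gain: float,
    nsr: float,
) -> np.ndarray:
    """One (3, n) stream: tremor-band oscillation + white noise per axis."""
    t = np.arange(n) / fs
    family = sensor[0]
    base = _BASE_AMPLITUDE[family]
    if family == "M":
        # slow orientation drift; tremor barely couples into the field reading
        drift_f = 0.2 + 0.1 * rng.random()
        carrier = np.sin(2.0 * np.pi * drift_f * t + rng.uniform(0, 2 * np.pi))
        amp = base * amp_gain * _TASK_AMPLITUDE[task]
    else:
        f0 = rng.normal(5.0, 0.5)
        carrier = np.sin(2.0 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        amp = base * amp_gain * _TASK_AMPLITUDE[task]
        if task == 3:
            # voluntary pronation/supination: strong slow component in-band
            f_move = 1.2 + 0.2 * rng.random()
            carrier = carrier + 2.0 * np.sin(2.0 * np.pi * f_move * t + rng.uniform(0, 2 * np.pi))
    xyz = np.empty((3, n))
    for i in range(3):
        noise = rng.normal(0.0, nsr * amp, size=n)
        xyz[i] = _AXIS_WEIGHTS[i] * amp * carrier + noise
    return xyz


def simulate_cohort_signals(
    spec: CohortSpec | None = None, effect: EffectModel | None = None
) -> Cohort:
    """Generate raw 3-axis streams for every (participant, task, trial, sensor).

    Tremor amplitude and noise-to-signal ratio both drift up linearly with
    age (rate ``effect.slope_scale`` per year from age 20); the magnetometer
    age effect is attenuated.  With ``contamination_rate`` > 0, whole trials
    are occasionally amplified 8x and logged in the ground-truth registry.
    """
    spec = spec or CohortSpec()
    effect = effect or EffectModel()
    rng = np.random.default_rng(spec.seed)
    ages, groups = _draw_ages(rng, spec)
    n = spec.samples_per_trial
    registry = GroundTruth()
    participants = []
    for idx, (age, group) in enumerate(zip(ages, groups)):
        pid = f"P{idx + 1:03d}"
        indiv = float(np.exp(rng.normal(0.0, effect.individual_sd)))
        age_gain = 1.0 + effect.slope_scale * (age - _AGE_REF)
        nsr = effect.noise_sd * (1.0 + effect.slope_scale * (age - _AGE_REF))
        mag_gain = 1.0 + _MAG_EFFECT_ATTENUATION * effect.slope_scale * (age - _AGE_REF)
        registry.amplitude_factor[pid] = indiv * age_gain
        signals = {}
        for task in TASKS:
            for trial in range(1, spec.n_trials + 1):
                sensors = {}
                for sensor in SENSOR_IDS:
                    gain = mag_gain if sensor[0] == "M" else age_gain
                    contaminated = (
                        effect.contamination_rate > 0
                        and rng.random() < effect.contamination_rate
                    )
                    g = indiv * gain * (_CONTAMINATION_GAIN if contaminated else 1.0)
                    sensors[sensor] = _synth_trial(rng, sensor, task, n, spec.fs, g, nsr)
                    if contaminated:
                        registry.outliers.append((pid, task, trial, sensor))
                signals[(task, trial)] = sensors
        participants.append(Participant(pid, float(age), int(group), signals, spec.fs))
    return Cohort(spec, effect, participants, registry)


def load_cohort_csv(directory) -> Cohort:
    """Rebuild a :class:`Cohort` from ``write_csv`` output.

    The manifest supplies ids/ages/groups; trial files are matched by the
    ``{pid}_T{task}_trial{k}.csv`` naming scheme and fs is inferred from
    the time column.  The ground-truth registry is not persisted.
    """
    from pathlib import Path

    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    participants = []
    fs = 50.0
    n_trials = 1
    for _, row in manifest.iterrows():
        pid = row["participant_id"]
        signals = {}
        for path in sorted(directory.glob(f"{pid}_T*_trial*.csv")):
            stem = path.stem
            task = int(stem.split("_T")[1].split("_")[0])
            trial = int(stem.rsplit("trial", 1)[1])
            df = pd.read_csv(path)
            fs = 1.0 / float(np.median(np.diff(df["time"].to_numpy())))
            sensors = {
                s: np.vstack([df[f"{s}_{ax}"].to_numpy() for ax in "xyz"])
                for s in SENSOR_IDS
            }
            signals[(task, trial)] = sensors
            n_trials = max(n_trials, trial)
        participants.append(
            Participant(pid, float(row["age"]), int(row["group"]), signals, fs)
        )
    duration = (
        next(iter(participants[0].signals.values()))["A1"].shape[1] / fs
        if participants
        else 10.0
    )
    spec = CohortSpec(
        group_sizes=tuple(manifest.groupby("group").size()),
        group_age_means=tuple(manifest.groupby("group")["age"].mean()),
        group_age_sds=tuple(manifest.groupby("group")["age"].std().fillna(1.0)),
        fs=fs,
        trial_duration=duration,
        n_trials=n_trials,
    )
    return Cohort(spec, EffectModel(), participants, GroundTruth())


@dataclass
class SimulatedFeatures:
    """Feature-level shortcut cohort (skips signal synthesis and extraction)."""

    trial_values: pd.DataFrame  # index (participant_id, trial)
    values: pd.DataFrame        # participant-level trial mean
    ages: pd.Series
    groups: pd.Series
    registry: GroundTruth


def simulate_feature_matrix(
    spec: CohortSpec | None = None,
    effect: EffectModel | None = None,
    n_features: int = 40,
) -> SimulatedFeatures:
    """Generate a feature matrix directly: mu_j + gamma_j * age + noise.

    A fraction ``effect.affected_fraction`` of columns carries a linear age
    trend with per-feature slope magnitude ~ ``slope_scale`` per year and
    random sign; the rest are pure noise.  The last ``duplicate_pairs``
    columns are near-copies (|r| > 0.9) of randomly chosen earlier columns;
    contamination replaces individual trial cells with extremes far outside
    the interquartile fences.  Everything injected is logged in the
    registry.
    """
    spec = spec or CohortSpec()
    effect = effect or EffectModel()
    if n_features < 2:
        raise ValueError("n_features must be >= 2")
    if effect.duplicate_pairs >= n_features:
        raise ValueError("duplicate_pairs must be smaller than n_features")
    rng = np.random.default_rng(spec.seed)
    ages, groups = _draw_ages(rng, spec)
    n_part = ages.size
    pids = [f"P{i + 1:03d}" for i in range(n_part)]
    n_base = n_features - effect.duplicate_pairs
    n_affected = max(1, int(round(effect.affected_fraction * n_base)))
    affected_idx = np.sort(rng.choice(n_base, size=n_affected, replace=False))
    registry = GroundTruth()

    mu = rng.normal(0.0, 1.0, size=n_base)
    slopes = np.zeros(n_base)
    slopes[affected_idx] = (
        effect.slope_scale
        * rng.uniform(0.5, 1.5, size=n_affected)
        * rng.choice([-1.0, 1.0], size=n_affected)
    )
    base = (
        mu[None, :]
        + slopes[None, :] * (ages[:, None] - _AGE_REF)
        + rng.normal(0.0, effect.noise_sd, size=(n_part, n_base))
    )
    names = [f"f{j:03d}" for j in range(n_features)]
    registry.affected_features = [names[j] for j in affected_idx]

    cols = [base]
    for k in range(effect.duplicate_pairs):
        src = int(rng.integers(0, n_base))
        col = base[:, src] + rng.normal(0.0, 0.1 * base[:, src].std() + 1e-12, size=n_part)
        cols.append(col[:, None])
        registry.duplicate_pairs.append((names[n_base + k], names[src], 0.9))
    full = np.hstack(cols)

    # trial replicates around the participant value, then cell contamination
    trial_noise = 0.2 * effect.noise_sd
    col_sd = full.std(axis=0) + 1e-12
    rows, index = [], []
    for i, pid in enumerate(pids):
        for trial in range(1, spec.n_trials + 1):
            row = full[i] + rng.normal(0.0, trial_noise, size=n_features)
            if effect.contamination_rate > 0:
                hit = rng.random(n_features) < effect.contamination_rate
                for j in np.nonzero(hit)[0]:
                    row[j] = full[:, j].mean() + rng.choice([-1.0, 1.0]) * 12.0 * col_sd[j]
                    registry.outlier_cells.append((pid, names[j], trial))
            rows.append(row)
            index.append((pid, trial))
    trial_df = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["participant_id", "trial"]),
        columns=names,
    )
    values = trial_df.groupby(level="participant_id", sort=False).mean()
    ages_s = pd.Series(ages, index=pids, name="age")
    groups_s = pd.Series(groups, index=pids, name="group")
    return SimulatedFeatures(trial_df, values, ages_s, groups_s, registry)
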