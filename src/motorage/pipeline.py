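"""End-to-end orchestration: simulate -> preprocess/extract -> reduce -> fit -> stats.

One :class:`RunConfig` (serializable, TOML-loadable) drives a fully
deterministic run.  A single global seed fans out to per-stage seeds by
fixed offsets so each stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortSpec, EffectModel, simulate_cohort_signals
from .features import ParamConfig, extract_feature_matrix
from .lda import GAConfig
from .model import LDAValueModel
from .reduction import reduce_features
from .stats import age_correlation, pairwise_group_test, tally_significant, young_elderly_test

logger = logging.getLogger(__name__)

_GA_SEED_OFFSET = 1009  # stage seeds: cohort = seed, GA = seed + offset


@dataclass
class RunConfig:
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    effect: EffectModel = field(default_factory=EffectModel)
    params: ParamConfig = field(default_factory=ParamConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    correlation_threshold: float = 0.9
    outlier_mode: str = "winsorize"

    def resolve_seeds(self) -> "RunConfig":
        """Fan the global seed out to the stage configs."""
        return replace(
            self,
            cohort=replace(self.cohort, seed=self.seed),
            ga=replace(self.ga, seed=self.seed + _GA_SEED_OFFSET),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kw = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            sub = raw[f.name]
            if f.name == "cohort":
                sub = CohortSpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()})
            elif f.name == "effect":
                sub = EffectModel(**sub)
            elif f.name == "params":
                sub = ParamConfig(**sub)
            elif f.name == "ga":
                sub = GAConfig(**sub)
            kw[f.name] = sub
        return cls(**kw)


@dataclass
class RunReport:
    """Stage-by-stage counts and headline results of one pipeline run."""

    n_participants: int = 0
    n_features_extracted: int = 0
    n_outlier_flags: int = 0
    n_features_after_pruning: int = 0
    n_relevant_features: int = 0
    ez_best: float = float("nan")
    pearson_r: float = float("nan")
    pearson_p: float = float("nan")
    n_significant_young_elderly: int = 0
    kruskal_omnibus_p: float = float("nan")
    tally: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    files: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunReport":
        return cls(**d)


@dataclass
class RunArtifacts:
    cohort: Cohort
    trial_features: pd.DataFrame
    reduced_features: pd.DataFrame
    reduction_report: object
    results: object
    significance: pd.DataFrame
    pairwise: object
    report: RunReport


def run_full_pipeline(config: RunConfig, outdir=None) -> RunArtifacts:
    """Execute every stage under one seed; optionally write all artifacts."""
    config = config.resolve_seeds()
    report = RunReport(config=config.to_dict())
    timer: dict[str, float] = {}

    def _stage(name):
        timer[name] = time.perf_counter()

    def _done(name):
        report.stage_seconds[name] = round(time.perf_counter() - timer[name], 3)
        logger.info("stage %-10s %.2fs", name, report.stage_seconds[name])

    _stage("simulate")
    cohort = simulate_cohort_signals(config.cohort, config.effect)
    report.n_participants = len(cohort.participants)
    _done("simulate")

    _stage("extract")
    extraction = extract_feature_matrix(cohort, config.params)
    report.n_features_extracted = extraction.trial_features.shape[1]
    _done("extract")

    _stage("reduce")
    reduced, red_report = reduce_features(
        extraction.trial_features,
        extraction.groups,
        threshold=config.correlation_threshold,
        outlier_mode=config.outlier_mode,
    )
    report.n_outlier_flags = len(red_report.outlier_flags)
    report.n_features_after_pruning = reduced.shape[1]
    _done("reduce")

    _stage("fit")
    model = LDAValueModel(
        reduced,
        extraction.groups.reindex(reduced.index).to_numpy(),
        ages=extraction.ages.reindex(reduced.index).to_numpy(),
        config=config.ga,
    )
    results = model.fit()
    report.n_relevant_features = results.n_relevant
    report.ez_best = results.ez_best
    _done("fit")

    _stage("stats")
    groups_arr = extraction.groups.reindex(reduced.index).to_numpy()
    significance = young_elderly_test(reduced, groups_arr)
    report.n_significant_young_elderly = int(significance["significant"].sum())
    try:
        report.tally = tally_significant(significance).as_dict()
    except (KeyError, ValueError):
        # reduced columns may not span the full grid naming scheme
        logger.info("tally skipped: columns are not grid-named")
    r, p = age_correlation(results.lda_values.to_numpy(), model.ages)
    report.pearson_r, report.pearson_p = r, p
    pairwise = pairwise_group_test(results.lda_values.to_numpy(), groups_arr)
    report.kruskal_omnibus_p = pairwise.omnibus_p
    _done("stats")

    artifacts = RunArtifacts(
        cohort=cohort,
        trial_features=extraction.trial_features,
        reduced_features=reduced,
        reduction_report=red_report,
        results=results,
        significance=significance,
        pairwise=pairwise,
        report=report,
    )
    if outdir is not None:
        _write_artifacts(artifacts, Path(outdir))
    return artifacts


def _write_artifacts(art: RunArtifacts, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "trial_features.csv": lambda p: art.trial_features.to_csv(p),
        "reduced_features.csv": lambda p: art.reduced_features.to_csv(p),
        "lda_values.csv": lambda p: pd.DataFrame(
            {
                "lda_value": art.results.lda_values,
                "age": art.results.model.ages,
                "group": art.results.model.groups,
            }
        ).to_csv(p, index_label="participant_id"),
        "significance.csv": lambda p: art.significance.to_csv(p),
        "pairwise_p.csv": lambda p: art.pairwise.p_values.to_csv(p),
        "manifest.csv": lambda p: art.cohort.manifest().to_csv(p, index=False),
    }
    for name, writer in files.items():
        writer(outdir / name)
        art.report.files.append(name)
    write_report(art.report, outdir / "report.json")
    art.report.files.append("report.json")


def write_report(report: RunReport, path, summary: bool = False) -> None:
    """Serialize the run report to JSON (optionally plus a text summary)."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=_json_default)
    if summary:
        with open(path.with_suffix(".txt"), "w") as fh:
            fh.write(render_summary(report))


def render_summary(report: RunReport) -> str:
    lines = [
        "pipeline run summary",
        f"participants                 {report.n_participants}",
        f"features extracted           {report.n_features_extracted}",
        f"outlier flags                {report.n_outlier_flags}",
        f"features after pruning       {report.n_features_after_pruning}",
        f"relevant features            {report.n_relevant_features}",
        f"E_z (best axis)              {report.ez_best:.4f}",
        f"Pearson r (LDA-value, age)   {report.pearson_r:.4f}",
        f"young/elderly significant    {report.n_significant_young_elderly}",
        f"Kruskal-Wallis omnibus p     {report.kruskal_omnibus_p:.3g}",
    ]
    for view, counts in (report.tally or {}).items():
        lines.append(f"tally {view}: {counts}")
    return "\n".join(lines)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
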