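"""Readers, writers, pipeline configuration and the end-to-end run.

File conventions: comma-separated UTF-8 CSV with a mandatory header row,
"." decimal point, empty fields for missing values, ``patient_id`` as the
join key between the cohort table and the omics matrices. All pipeline
outputs land under one declared output directory together with a run
manifest (config echo, seeds, package versions), so a run is fully
reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, OmicspredError
from .evaluation import EvaluationReport, run_repeated_workflow
from .importance import compute_importance, plot_importance
from .penalized import ModelSpec
from .spectral import fit_spectral
from .synthetic import (
    BINARY_OUTCOMES, TIME_TO_EVENT_OUTCOMES, CohortTable, GeneratorConfig,
    OmicsBlock, generate_cohort,
)

logger = logging.getLogger(__name__)

#: stage tags used in error reporting and exit codes
STAGES = ("config", "simulate", "cluster", "evaluate", "importance", "report")

_NUMERIC_COHORT_COLUMNS = (
    "age", "bmi", "fvc_pct", "dlco_pct", "fvc_change_1yr", "dlco_change_1yr",
)


class PipelineStageError(OmicspredError):
    """Failure wrapped with the pipeline stage in which it happened."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.exit_code = 2 + STAGES.index(stage)
        super().__init__(f"[{stage}] {cause}")


@dataclass
class PipelineConfig:
    """Everything one `run` needs.

    Either the three input paths or a generator config must be provided;
    a seed is mandatory because every stage past ingest is stochastic.
    """

    seed: int
    outdir: str
    cohort_path: str | None = None
    proteins_path: str | None = None
    mirnas_path: str | None = None
    generator: GeneratorConfig | None = None
    outcomes: list[str] = field(
        default_factory=lambda: ["death_transplant"])
    spec_tokens: list[str] = field(
        default_factory=lambda: ["demo", "demo+clin",
                                 "demo+raw_prot+lbl_mirna",
                                 "demo+clin+raw_prot+lbl_mirna"])
    importance_spec: str = "demo+raw_prot+lbl_mirna"
    n_repetitions: int = 64
    k_clusters: int = 2
    n_folds: int = 10
    top_k: int = 4
    assignment_strategy: str = "nystrom"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.generator is None and self.cohort_path is None:
            raise ConfigError("provide input paths or a generator config")
        if self.generator is None:
            for name in ("cohort_path", "proteins_path", "mirnas_path"):
                path = getattr(self, name)
                if path is None:
                    raise ConfigError(f"{name} is required without a generator")
                if not Path(path).exists():
                    raise ConfigError(f"{name} does not exist: {path}")
        known = set(TIME_TO_EVENT_OUTCOMES) | set(BINARY_OUTCOMES)
        unknown = set(self.outcomes) - known
        if unknown:
            raise ConfigError(f"unknown outcomes: {sorted(unknown)}")
        # validate spec tokens early, before any computation
        for token in self.spec_tokens + [self.importance_spec]:
            for outcome in self.outcomes:
                ModelSpec.for_outcome(tuple(token.split("+")), outcome)


def parse_spec_token(token: str, outcome: str) -> ModelSpec:
    """Turn a '+'-joined block token (e.g. ``demo+lbl_prot``) into a spec."""
    return ModelSpec.for_outcome(tuple(token.split("+")), outcome)


# --------------------------------------------------------------------------
# cohort and omics CSV round trips

def read_cohort(path) -> CohortTable:
    """Read a cohort CSV into a validated CohortTable."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    if len(df) == 0:
        raise ConfigError(f"cohort file {path} has a header but no rows")
    if "patient_id" not in df.columns:
        raise ConfigError("cohort file lacks the required patient_id column")
    for col in df.columns:
        if col == "patient_id":
            continue
        if col in _NUMERIC_COHORT_COLUMNS or col.endswith(("_time", "_event")) \
                or col in BINARY_OUTCOMES:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ConfigError(
                    f"non-numeric value {df[col].iloc[row]!r} in column "
                    f"{col!r} (row {row + 2} of {path})")
            df[col] = coerced
    cohort = CohortTable(df)
    logger.info("read cohort with %d patients from %s", cohort.n, path)
    return cohort


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.data.to_csv(path, index=False, na_rep="")


def read_omics(path) -> OmicsBlock:
    """Read a patients x features CSV (first column patient_id)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise ConfigError(f"omics file {path} lacks a patient_id column")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ConfigError(f"duplicate patient_id {dup!r} in omics file {path}")
    features = [c for c in df.columns if c != "patient_id"]
    return OmicsBlock(df["patient_id"].to_numpy(), features,
                      df[features].to_numpy(dtype=float))


def write_omics(block: OmicsBlock, path) -> None:
    df = pd.DataFrame(block.values, columns=block.feature_names)
    df.insert(0, "patient_id", block.patient_ids)
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# generator config as YAML

def generator_config_to_yaml(config: GeneratorConfig) -> str:
    d = dataclasses.asdict(config)
    d["endotype_props"] = list(config.endotype_props)
    d["fvc_decline_means"] = list(config.fvc_decline_means)
    d["dlco_decline_means"] = list(config.dlco_decline_means)
    d["covariate_log_hrs"] = dict(config.covariate_log_hrs)
    d["component_hazard_ratios"] = dict(config.component_hazard_ratios)
    return yaml.safe_dump(d, sort_keys=True)


def read_generator_config(path) -> GeneratorConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"generator config {path} must be a key-value mapping")
    defaults = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(raw) - defaults
    if unknown:
        raise ConfigError(f"unknown generator config keys: {sorted(unknown)}")
    for key in ("endotype_props", "fvc_decline_means", "dlco_decline_means"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return GeneratorConfig(**raw)


# --------------------------------------------------------------------------
# the end-to-end pipeline

def _augmentation_pairs(specs: list[ModelSpec]) -> list[tuple[ModelSpec, ModelSpec]]:
    """All ordered pairs where the base's blocks are a strict subset of the
    augmented model's blocks and the added blocks are omics blocks."""
    omics_blocks = {"raw_prot", "lbl_prot", "raw_mirna", "lbl_mirna"}
    pairs = []
    for base in specs:
        for aug in specs:
            if base.outcome != aug.outcome:
                continue
            b, a = set(base.blocks), set(aug.blocks)
            if b < a and (a - b) <= omics_blocks:
                pairs.append((base, aug))
    return pairs


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute simulate (optional) -> cluster -> evaluate -> importance ->
    report, writing all declared outputs under the output directory.

    Returns the output directory. Identical config and seed reproduce
    identical report files.
    """
    logging.basicConfig(level=config.log_level,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def _stage(name):
        logger.info("stage %s starting", name)
        timings[name] = _time.perf_counter()

    def _done(name):
        timings[name] = _time.perf_counter() - timings[name]
        logger.info("stage %s finished in %.1f s", name, timings[name])

    # ---- simulate or ingest
    _stage("simulate")
    try:
        if config.generator is not None:
            gen = config.generator.with_overrides(seed=config.seed)
            cohort, proteins, mirnas = generate_cohort(gen)
            write_cohort(cohort, outdir / "cohort.csv")
            write_omics(proteins, outdir / "proteins.csv")
            write_omics(mirnas, outdir / "mirnas.csv")
        else:
            cohort = read_cohort(config.cohort_path)
            proteins = read_omics(config.proteins_path)
            mirnas = read_omics(config.mirnas_path)
            for name, block in (("proteins", proteins), ("mirnas", mirnas)):
                if not np.array_equal(block.patient_ids, cohort.patient_ids):
                    raise ConfigError(
                        f"{name} patient ids do not match the cohort table")
    except OmicspredError as exc:
        raise PipelineStageError("simulate", exc) from exc
    _done("simulate")

    # ---- reference cluster models on the full cohort (for inspection /
    # decoupled scoring; the evaluation stage refits per training split)
    _stage("cluster")
    try:
        for key, block in (("proteins", proteins), ("mirnas", mirnas)):
            model = fit_spectral(block, config.k_clusters, seed=config.seed)
            (outdir / f"cluster_model_{key}.json").write_text(model.to_json())
    except OmicspredError as exc:
        raise PipelineStageError("cluster", exc) from exc
    _done("cluster")

    # ---- repeated-split evaluation
    _stage("evaluate")
    try:
        specs = [parse_spec_token(token, outcome)
                 for outcome in config.outcomes
                 for token in config.spec_tokens]
        report = run_repeated_workflow(
            cohort, proteins, mirnas, specs, config.n_repetitions,
            config.seed, k_clusters=config.k_clusters, n_folds=config.n_folds,
            assignment_strategy=config.assignment_strategy)
        report.per_repetition.to_csv(outdir / "evaluation_repetitions.tsv",
                                     sep="\t", index=False)
        report.summary.to_csv(outdir / "evaluation_summary.tsv", sep="\t",
                              index=False)
        coef_rows = []
        for key, fits in report.fits.items():
            for rep, fit in enumerate(fits):
                for c, b in zip(fit.column_names, fit.beta):
                    if b != 0.0:
                        coef_rows.append({"spec_outcome": key, "repetition": rep,
                                          "column": c, "beta": b})
        pd.DataFrame(coef_rows).to_csv(outdir / "coefficients.tsv", sep="\t",
                                       index=False)
    except OmicspredError as exc:
        raise PipelineStageError("evaluate", exc) from exc
    _done("evaluate")

    # ---- importance + top-k refit
    _stage("importance")
    try:
        for outcome in config.outcomes:
            spec = parse_spec_token(config.importance_spec, outcome)
            key = EvaluationReport._key(spec)
            fits = report.fits.get(key, [])
            if not fits:
                continue
            table = compute_importance(fits)
            stem = f"importance_{spec.label.replace('+', '-')}_{outcome}"
            table.to_csv(outdir / f"{stem}.tsv", sep="\t", index=False)
            plot_importance(table, outdir / f"{stem}.png",
                            title=f"{spec.label} | {outcome}")
    except OmicspredError as exc:
        raise PipelineStageError("importance", exc) from exc
    _done("importance")

    # ---- relative-change report + manifest
    _stage("report")
    try:
        rows = []
        for base, aug in _augmentation_pairs(specs):
            rows.append({
                "outcome": base.outcome,
                "base": base.label,
                "augmented": aug.label,
                "base_mean": report.mean_metric(base),
                "augmented_mean": report.mean_metric(aug),
                "relative_change_pct": report.relative_change(base, aug),
                "relative_change_pct_rounded_means":
                    report.relative_change_rounded_means(base, aug),
            })
        pd.DataFrame(rows).to_csv(outdir / "relative_changes.tsv", sep="\t",
                                  index=False)
        manifest = {
            "package": "omicspred",
            "version": __version__,
            "seed": config.seed,
            "config": _config_dict(config),
            "library_versions": _library_versions(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True))
    except OmicspredError as exc:
        raise PipelineStageError("report", exc) from exc
    _done("report")
    logger.info("stage timings: %s",
                {k: round(v, 2) for k, v in timings.items()})
    return outdir


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.generator is not None:
        d["generator"] = yaml.safe_load(generator_config_to_yaml(config.generator))
    return d


def _library_versions() -> dict:
    import lifelines
    import sklearn

    return {"numpy": np.__version__, "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "lifelines": lifelines.__version__}
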