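"""Synthetic IPF cohort generator.

Emulates the statistical structure of a prospective idiopathic pulmonary
fibrosis (IPF) registry cohort: demographic and clinical covariates drawn
from published marginal distributions, a latent two-group molecular
endotype expressed in a protein block and (independently) a miRNA block,
proportional-hazards composite time-to-event outcomes, binary 1-year
lung-function outcomes, and missing-completely-at-random DLco values.

Everything downstream of data ingest (clustering, penalized models,
repeated-split evaluation) is exercised against cohorts produced here, so
the generator is first-class, validated code rather than a test fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

#: Composite time-to-event outcomes: time to the first of the named events.
TIME_TO_EVENT_OUTCOMES: tuple[str, ...] = (
    "death_transplant",          # death or lung transplant
    "death_transplant_fvc10",    # + absolute decline in FVC % predicted >= 10
    "death_transplant_dlco15",   # + absolute decline in DLco % predicted >= 15
    "death_transplant_hosp",     # + respiratory hospitalization
)

#: Binary outcomes assessed at 1 year.
BINARY_OUTCOMES: tuple[str, ...] = ("fvc_decline_gt10_1yr", "progression_1yr")

#: Demographic covariate columns in canonical order.
DEMO_COLUMNS: tuple[str, ...] = (
    "age", "sex_male", "bmi", "ever_smoker", "nintedanib", "pirfenidone",
)

#: Clinical covariate columns.
CLIN_COLUMNS: tuple[str, ...] = ("fvc_pct", "dlco_pct")

# Marginal generating distributions for the covariates: binaries are
# Bernoulli(p); continuous are Normal(mean, sd) clipped to a plausible range.
COVARIATE_DISTRIBUTIONS: dict[str, dict] = {
    "sex_male": {"kind": "bernoulli", "p": 0.740},
    "age": {"kind": "normal", "mean": 69.7, "sd": 7.8, "lo": 40.0, "hi": 95.0},
    "bmi": {"kind": "normal", "mean": 29.4, "sd": 4.8, "lo": 15.0, "hi": 50.0},
    "ever_smoker": {"kind": "bernoulli", "p": 0.671},
    "fvc_pct": {"kind": "normal", "mean": 71.1, "sd": 16.9, "lo": 30.0, "hi": 130.0},
    "dlco_pct": {"kind": "normal", "mean": 40.2, "sd": 13.6, "lo": 15.0, "hi": 100.0},
    "nintedanib": {"kind": "bernoulli", "p": 0.182},
    "pirfenidone": {"kind": "bernoulli", "p": 0.359},
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    The defaults are the package's reference study conditions; hazards and
    1-year change distributions were calibrated once so that default event
    proportions match a typical IPF registry cohort (see docs/methods.md).

    Parameters
    ----------
    n_patients, n_proteins, n_mirnas : int
        Cohort size and omics block widths.
    n_endotypes : int
        Number of latent molecular endotypes (K). The hazard of endotype
        ``e`` (1-based) is multiplied by ``exp(endotype_log_hr * (e - 1))``.
    endotype_props : tuple of float
        Mixing proportions of the endotypes; must sum to 1.
    n_informative_proteins, protein_separation : int, float
        How many protein features carry the endotype, and the standardized
        mean shift (in within-group SD units) between adjacent endotypes.
    n_informative_mirnas, mirna_separation : int, float
        Same for the miRNA block, whose latent grouping is drawn
        independently of the protein endotype (different omics may cluster
        patients differently).
    endotype_log_hr : float
        Log hazard ratio of endotype 2 vs endotype 1 on every event process.
    covariate_log_hrs : mapping
        Per-unit log hazard ratios of (centered) covariates; keys must be
        covariate column names.
    baseline_hazard : float
        Events per month for the death-or-transplant process in endotype 1
        at average covariates.
    component_hazard_ratios : mapping
        Hazards of the extra composite components (``fvc10``, ``dlco15``,
        ``hosp``) as multiples of ``baseline_hazard``.
    admin_censor_time : float
        Administrative censoring time in months.
    dlco_missing_frac : float
        MCAR missingness proportion for baseline DLco % predicted.
    fvc_decline_means, fvc_decline_sd : per-endotype mean 1-year decline in
        FVC % predicted (percentage points; positive = decline) and its SD.
    dlco_decline_means, dlco_decline_sd : same for DLco.
    binary_missing_frac : float
        MCAR missingness of the 1-year FVC change measurement.
    seed : int
        Seed for the single random generator driving all draws.
    """

    n_patients: int = 231
    n_proteins: int = 44
    n_mirnas: int = 472
    n_endotypes: int = 2
    endotype_props: tuple[float, ...] = (0.5, 0.5)
    n_informative_proteins: int = 8
    protein_separation: float = 3.0
    n_informative_mirnas: int = 40
    mirna_separation: float = 2.0
    endotype_log_hr: float = math.log(2.5)
    covariate_log_hrs: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.03,
            "sex_male": 0.30,
            "bmi": -0.03,
            "ever_smoker": 0.15,
            "fvc_pct": -0.030,
            "dlco_pct": -0.025,
        }
    )
    baseline_hazard: float = 0.00816
    component_hazard_ratios: Mapping[str, float] = field(
        default_factory=lambda: {"fvc10": 1.13, "dlco15": 0.392, "hosp": 0.259}
    )
    admin_censor_time: float = 36.0
    dlco_missing_frac: float = 59 / 231
    fvc_decline_means: tuple[float, ...] = (5.3, 11.3)
    fvc_decline_sd: float = 8.0
    dlco_decline_means: tuple[float, ...] = (1.5, 4.0)
    dlco_decline_sd: float = 7.0
    binary_missing_frac: float = 1 / 231
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_patients": self.n_patients,
            "n_proteins": self.n_proteins,
            "n_mirnas": self.n_mirnas,
            "n_endotypes": self.n_endotypes,
            "n_informative_proteins": self.n_informative_proteins,
            "n_informative_mirnas": self.n_informative_mirnas,
        }
        for name, value in counts.items():
            if not (isinstance(value, (int, np.integer)) and value > 0):
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        props = np.asarray(self.endotype_props, dtype=float)
        if props.shape != (self.n_endotypes,):
            raise ConfigError(
                f"endotype_props has length {props.size}, expected {self.n_endotypes}"
            )
        if not np.isfinite(props).all() or (props < 0).any():
            raise ConfigError("endotype_props must be finite and non-negative")
        if abs(props.sum() - 1.0) > 1e-12:
            raise ConfigError(f"endotype_props must sum to 1, got {props.sum()!r}")
        if self.n_informative_proteins > self.n_proteins:
            raise ConfigError("n_informative_proteins exceeds n_proteins")
        if self.n_informative_mirnas > self.n_mirnas:
            raise ConfigError("n_informative_mirnas exceeds n_mirnas")
        scalars = {
            "protein_separation": self.protein_separation,
            "mirna_separation": self.mirna_separation,
            "endotype_log_hr": self.endotype_log_hr,
            "baseline_hazard": self.baseline_hazard,
            "admin_censor_time": self.admin_censor_time,
            "fvc_decline_sd": self.fvc_decline_sd,
            "dlco_decline_sd": self.dlco_decline_sd,
        }
        for name, value in scalars.items():
            if not np.isfinite(value):
                raise ConfigError(f"{name} must be finite, got {value!r}")
        for mapping_name, mapping in (
            ("covariate_log_hrs", self.covariate_log_hrs),
            ("component_hazard_ratios", self.component_hazard_ratios),
        ):
            for key, value in mapping.items():
                if not np.isfinite(value):
                    raise ConfigError(f"{mapping_name}[{key!r}] must be finite")
        unknown = set(self.covariate_log_hrs) - set(COVARIATE_DISTRIBUTIONS)
        if unknown:
            raise ConfigError(f"unknown covariates in covariate_log_hrs: {sorted(unknown)}")
        for name, frac in (
            ("dlco_missing_frac", self.dlco_missing_frac),
            ("binary_missing_frac", self.binary_missing_frac),
        ):
            if not (0.0 <= frac < 1.0):
                raise ConfigError(f"{name} must lie in [0, 1), got {frac!r}")
        if self.baseline_hazard <= 0 or self.admin_censor_time <= 0:
            raise ConfigError("baseline_hazard and admin_censor_time must be positive")
        for decl_name, means in (
            ("fvc_decline_means", self.fvc_decline_means),
            ("dlco_decline_means", self.dlco_decline_means),
        ):
            if len(means) != self.n_endotypes:
                raise ConfigError(f"{decl_name} needs one value per endotype")

    def with_overrides(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with the given fields replaced (validates again)."""
        return replace(self, **kwargs)


@dataclass
class CohortTable:
    """Per-patient demographics, clinical values and outcome records.

    Thin validated wrapper around a pandas DataFrame with one row per
    patient. ``true_endotype`` is present only in synthetic cohorts and is
    never entered into any model design matrix; it exists for test oracles.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "patient_id" not in df.columns:
            raise ConfigError("cohort table lacks a patient_id column")
        if df["patient_id"].duplicated().any():
            dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise ConfigError(f"duplicate patient_id {dup!r} in cohort table")
        if len(df) == 0:
            raise ConfigError("cohort table is empty")
        for outcome in TIME_TO_EVENT_OUTCOMES:
            tcol, ecol = f"{outcome}_time", f"{outcome}_event"
            if tcol in df.columns:
                if (df[tcol] <= 0).any():
                    raise ConfigError(f"{tcol} contains non-positive times")
                if not df[ecol].isin([0, 1]).all():
                    raise ConfigError(f"{ecol} contains values outside {{0,1}}")
        if "fvc_pct" in df.columns and df["fvc_pct"].isna().any():
            raise ConfigError("fvc_pct must not be missing")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.data["patient_id"].to_numpy()

    def times(self, outcome: str) -> np.ndarray:
        return self.data[f"{outcome}_time"].to_numpy(dtype=float)

    def events(self, outcome: str) -> np.ndarray:
        return self.data[f"{outcome}_event"].to_numpy(dtype=int)

    def binary(self, outcome: str) -> np.ndarray:
        """Binary outcome labels as floats; NaN marks a missing label."""
        return self.data[outcome].to_numpy(dtype=float)

    def subset(self, index: np.ndarray) -> "CohortTable":
        """Positional row subset, preserving order."""
        return CohortTable(self.data.iloc[np.asarray(index)].reset_index(drop=True))


@dataclass
class OmicsBlock:
    """Patients x features numeric matrix aligned with a cohort table."""

    patient_ids: np.ndarray
    feature_names: list[str]
    values: np.ndarray
    standardized: bool = False
    ref_means: np.ndarray | None = None
    ref_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.patient_ids = np.asarray(self.patient_ids)
        if self.values.shape != (len(self.patient_ids), len(self.feature_names)):
            raise ConfigError(
                f"omics matrix shape {self.values.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.feature_names)} features"
            )
        if np.isnan(self.values).any():
            raise ConfigError("omics matrix contains missing values")
        if self.standardized and (self.ref_means is None or self.ref_sds is None):
            raise ConfigError("standardized block must carry reference means/SDs")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def rows(self, index: np.ndarray) -> "OmicsBlock":
        index = np.asarray(index)
        return OmicsBlock(
            self.patient_ids[index], list(self.feature_names), self.values[index],
            self.standardized,
            None if self.ref_means is None else self.ref_means.copy(),
            None if self.ref_sds is None else self.ref_sds.copy(),
        )

    def subset_features(self, names: Sequence[str]) -> "OmicsBlock":
        pos = [self.feature_names.index(n) for n in names]
        return OmicsBlock(self.patient_ids.copy(), list(names), self.values[:, pos])

    def standardize(self, means: np.ndarray | None = None,
                    sds: np.ndarray | None = None) -> "OmicsBlock":
        """Standardize columns; with no arguments uses this block's own stats.

        Zero-variance columns are left on their centered scale (SD treated
        as 1) so downstream linear algebra stays finite.
        """
        if means is None:
            means = self.values.mean(axis=0)
        if sds is None:
            sds = self.values.std(axis=0, ddof=0)
        sds = np.where(np.asarray(sds) > 0, sds, 1.0)
        return OmicsBlock(
            self.patient_ids.copy(), list(self.feature_names),
            (self.values - means) / sds, True, np.asarray(means, float),
            np.asarray(sds, float),
        )


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    cols = {}
    for name in DEMO_COLUMNS + CLIN_COLUMNS:
        dist = COVARIATE_DISTRIBUTIONS[name]
        if dist["kind"] == "bernoulli":
            cols[name] = (rng.random(n) < dist["p"]).astype(int)
        else:
            draw = rng.normal(dist["mean"], dist["sd"], size=n)
            cols[name] = np.clip(draw, dist["lo"], dist["hi"])
    return pd.DataFrame(cols)


def _linear_predictor(cov: pd.DataFrame, endotype: np.ndarray,
                      config: GeneratorConfig) -> np.ndarray:
    lp = config.endotype_log_hr * (endotype - 1).astype(float)
    for name, beta in config.covariate_log_hrs.items():
        dist = COVARIATE_DISTRIBUTIONS[name]
        center = dist["p"] if dist["kind"] == "bernoulli" else dist["mean"]
        lp = lp + beta * (cov[name].to_numpy(dtype=float) - center)
    return lp


def _omics_matrix(rng: np.random.Generator, group: np.ndarray, n_features: int,
                  n_informative: int, separation: float, prefix: str
                  ) -> tuple[np.ndarray, list[str]]:
    n = group.size
    values = rng.normal(size=(n, n_features))
    # informative columns get a per-group mean shift of `separation` SD units
    values[:, :n_informative] += separation * (group - 1)[:, None]
    names = [f"{prefix}_{j + 1}" for j in range(n_features)]
    return values, names


def generate_cohort(config: GeneratorConfig
                    ) -> tuple[CohortTable, OmicsBlock, OmicsBlock]:
    """Simulate a cohort with its protein and miRNA blocks.

    Deterministic given ``config.seed``. Survival times for each composite
    outcome arise as the minimum of independent exponential component
    processes (death/transplant, FVC decline, DLco decline, respiratory
    hospitalization) sharing one proportional-hazards linear predictor;
    administrative censoring is applied at ``admin_censor_time``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    cov = _draw_covariates(rng, n)
    endotype = 1 + rng.choice(config.n_endotypes, size=n,
                              p=np.asarray(config.endotype_props, float))
    mirna_group = 1 + rng.choice(config.n_endotypes, size=n,
                                 p=np.asarray(config.endotype_props, float))

    lp = _linear_predictor(cov, endotype, config)
    hazard_scale = np.exp(lp)

    component_hazards = {"death": config.baseline_hazard}
    for comp, ratio in config.component_hazard_ratios.items():
        component_hazards[comp] = ratio * config.baseline_hazard
    comp_times = {
        comp: rng.exponential(1.0 / (h * hazard_scale))
        for comp, h in component_hazards.items()
    }

    tc = config.admin_censor_time
    df = pd.DataFrame({"patient_id": [f"P{i + 1:04d}" for i in range(n)]})
    df = pd.concat([df, cov], axis=1)

    composites = {
        "death_transplant": ["death"],
        "death_transplant_fvc10": ["death", "fvc10"],
        "death_transplant_dlco15": ["death", "dlco15"],
        "death_transplant_hosp": ["death", "hosp"],
    }
    for outcome, comps in composites.items():
        t_latent = np.minimum.reduce([comp_times[c] for c in comps])
        df[f"{outcome}_time"] = np.minimum(t_latent, tc)
        df[f"{outcome}_event"] = (t_latent <= tc).astype(int)

    # 1-year lung-function changes (negative = decline); endotype-dependent mean
    fvc_mu = -np.asarray(config.fvc_decline_means, float)[endotype - 1]
    dlco_mu = -np.asarray(config.dlco_decline_means, float)[endotype - 1]
    df["fvc_change_1yr"] = rng.normal(fvc_mu, config.fvc_decline_sd)
    df["dlco_change_1yr"] = rng.normal(dlco_mu, config.dlco_decline_sd)
    if config.binary_missing_frac > 0:
        miss = rng.random(n) < config.binary_missing_frac
        df.loc[miss, "fvc_change_1yr"] = np.nan

    if config.dlco_missing_frac > 0:
        miss = rng.random(n) < config.dlco_missing_frac
        df.loc[miss, "dlco_pct"] = np.nan

    df["true_endotype"] = endotype
    df["true_mirna_group"] = mirna_group

    cohort = derive_binary_outcomes(CohortTable(df))

    prot_values, prot_names = _omics_matrix(
        rng, endotype, config.n_proteins, config.n_informative_proteins,
        config.protein_separation, "prot")
    mir_values, mir_names = _omics_matrix(
        rng, mirna_group, config.n_mirnas, config.n_informative_mirnas,
        config.mirna_separation, "mir")
    ids = cohort.patient_ids
    proteins = OmicsBlock(ids.copy(), prot_names, prot_values)
    mirnas = OmicsBlock(ids.copy(), mir_names, mir_values)
    return cohort, proteins, mirnas


def derive_binary_outcomes(cohort: CohortTable) -> CohortTable:
    """Derive the two 1-year binary outcomes from simulated changes.

    ``fvc_decline_gt10_1yr`` is 1 iff the absolute decline in FVC %
    predicted is strictly greater than 10 percentage points (a decline of
    exactly 10.0 is not an event); a missing 1-year FVC change propagates
    to a missing label. ``progression_1yr`` is the 1-year disease
    progression composite: FVC decline > 10, DLco decline > 15, or death /
    lung transplant within 12 months.
    """
    df = cohort.data.copy()
    for col in ("fvc_change_1yr", "dlco_change_1yr"):
        if col not in df.columns:
            raise ConfigError(f"cohort lacks simulated column {col}")

    fvc_decline = -df["fvc_change_1yr"]
    dlco_decline = -df["dlco_change_1yr"]
    fvc_evt = (fvc_decline > 10.0).astype(float)
    fvc_evt[df["fvc_change_1yr"].isna()] = np.nan
    df["fvc_decline_gt10_1yr"] = fvc_evt

    death_1yr = (df["death_transplant_event"] == 1) & (df["death_transplant_time"] <= 12.0)
    prog = np.where(
        death_1yr, 1.0,
        np.where(
            (fvc_decline > 10.0) | (dlco_decline > 15.0), 1.0,
            np.where(df["fvc_change_1yr"].isna() | df["dlco_change_1yr"].isna(),
                     np.nan, 0.0),
        ),
    )
    df["progression_1yr"] = prog
    return CohortTable(df)


def summarize_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Cohort summary table: covariates as mean (SD) or n (%), outcomes as
    event count with whole-number percentage of available patients."""
    if cohort.n == 0:
        raise ConfigError("cannot summarize an empty cohort")
    df = cohort.data
    rows = []
    for name in DEMO_COLUMNS + CLIN_COLUMNS:
        if name not in df.columns:
            continue
        col = df[name]
        avail = int(col.notna().sum())
        if COVARIATE_DISTRIBUTIONS[name]["kind"] == "bernoulli":
            count = int(col.sum())
            pct = 100.0 * count / avail
            rows.append({"item": name, "kind": "covariate", "n_available": avail,
                         "value": count, "spread": round(pct, 1),
                         "formatted": f"{count} ({pct:.1f})"})
        else:
            mean, sd = float(col.mean()), float(col.std(ddof=1))
            rows.append({"item": name, "kind": "covariate", "n_available": avail,
                         "value": round(mean, 1), "spread": round(sd, 1),
                         "formatted": f"{mean:.1f} ({sd:.1f})"})
    for outcome in TIME_TO_EVENT_OUTCOMES:
        ecol = f"{outcome}_event"
        if ecol not in df.columns:
            continue
        avail = int(df[ecol].notna().sum())
        count = int(df[ecol].sum())
        pct = int(round(100.0 * count / avail))
        rows.append({"item": outcome, "kind": "event", "n_available": avail,
                     "value": count, "spread": pct,
                     "formatted": f"{count} ({pct}%)"})
    for outcome in BINARY_OUTCOMES:
        if outcome not in df.columns:
            continue
        col = df[outcome]
        avail = int(col.notna().sum())
        count = int(col.sum())
        pct = int(round(100.0 * count / avail))
        rows.append({"item": outcome, "kind": "event", "n_available": avail,
                     "value": count, "spread": pct,
                     "formatted": f"{count} ({pct}%)"})
    return pd.DataFrame(rows)
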