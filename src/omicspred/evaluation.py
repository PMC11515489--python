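"""Held-out scoring and the repeated split / cluster / fit / score workflow.

Each repetition draws an event-stratified 80/20 split, fits spectral
clustering per omics block on the training patients only, assigns
held-out cluster labels out-of-sample, tunes the penalty of every model
by inner 10-fold cross-validation on the training set, and scores the
fitted model on the test set with Harrell's C-index (time-to-event) or
AUC (binary). Metrics are averaged over repetitions with their standard
error, and relative percent changes between model families quantify what
the omics data add beyond demographic and clinical factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .errors import ConfigError, DegenerateInputError, UndefinedMetricError
from .penalized import (
    ModelSpec, PenalizedFit, build_design_matrix, fit_l1_logistic,
    fit_lasso_cox, select_lambda,
)
from .spectral import ClusterAssignment, assign_out_of_sample, fit_spectral
from .synthetic import CohortTable, OmicsBlock

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitPlan:
    """One train/test partition of the cohort (80/20 by default)."""

    repetition_id: int
    seed: int
    train_index: np.ndarray
    test_index: np.ndarray

    def __post_init__(self) -> None:
        train, test = set(self.train_index.tolist()), set(self.test_index.tolist())
        if train & test:
            raise ConfigError("train and test sets overlap")


def harrell_cindex(time, event, risk_score) -> float:
    """Harrell's concordance index under right censoring.

    Over all pairs usable under right censoring (the earlier time must be
    an event), the fraction in which the earlier-event patient carries the
    higher risk score; tied risk scores count 1/2. Higher risk means
    shorter predicted survival.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    risk = np.asarray(risk_score, float)
    if not (time.size == event.size == risk.size):
        raise ConfigError("time, event and risk_score must be aligned")
    try:
        # lifelines scores "higher = longer survival", so negate the risk
        return float(concordance_index(time, -risk, event))
    except ZeroDivisionError as exc:
        raise UndefinedMetricError("no usable pairs under censoring") from exc


def auc(y, score) -> float:
    """Area under the ROC curve via the rank-statistic formulation."""
    y = np.asarray(y, float)
    score = np.asarray(score, float)
    if y.size != score.size:
        raise ConfigError("labels and scores must be aligned")
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("AUC needs both classes present")
    return float(roc_auc_score(y, score))


def relative_change(base_mean: float, augmented_mean: float) -> float:
    """Percent change of a mean metric after augmenting a model, to one
    decimal: 100 * (augmented - base) / base."""
    if base_mean <= 0:
        raise ConfigError("relative change needs a positive base metric")
    return round(100.0 * (augmented_mean - base_mean) / base_mean, 1)


@dataclass
class EvaluationReport:
    """Per-repetition metrics and their aggregation per model family."""

    per_repetition: pd.DataFrame   # repetition, spec, outcome, family, metric, value
    summary: pd.DataFrame          # spec, outcome, metric, mean, se, median, n_repetitions
    n_repetitions: int
    master_seed: int
    fits: dict[str, list[PenalizedFit]] = field(default_factory=dict)
    n_skipped: dict[str, int] = field(default_factory=dict)

    @staticmethod
    def _key(spec: ModelSpec) -> str:
        return f"{spec.label}|{spec.outcome}"

    def mean_metric(self, spec: ModelSpec) -> float:
        row = self.summary[(self.summary["spec"] == spec.label)
                           & (self.summary["outcome"] == spec.outcome)]
        if row.empty:
            raise ConfigError(f"no summary row for {self._key(spec)}")
        return float(row["mean"].iloc[0])

    def relative_change(self, base: ModelSpec, augmented: ModelSpec) -> float:
        """Relative percent change of the mean metric, base -> augmented."""
        return relative_change(self.mean_metric(base), self.mean_metric(augmented))

    def relative_change_rounded_means(self, base: ModelSpec,
                                      augmented: ModelSpec) -> float:
        """Companion value computed from means pre-rounded to 3 decimals."""
        return relative_change(round(self.mean_metric(base), 3),
                               round(self.mean_metric(augmented), 3))


def _stratification_vector(cohort: CohortTable, outcome: str, family: str
                           ) -> np.ndarray:
    if family == "cox":
        return cohort.events(outcome)
    labels = cohort.binary(outcome)
    return np.nan_to_num(labels, nan=0.0).astype(int)


def _blocks_needing_clusters(specs) -> set[str]:
    need = set()
    for spec in specs:
        if "lbl_prot" in spec.blocks:
            need.add("prot")
        if "lbl_mirna" in spec.blocks:
            need.add("mir")
    return need


def _score_spec(spec, train_cohort, test_cohort, train_clusters, test_clusters,
                train_omics, test_omics, n_folds, cv_seed):
    """Fit one spec on the training half and score it on the test half."""
    x_train = build_design_matrix(spec, train_cohort, train_clusters, train_omics)
    x_test = build_design_matrix(spec, test_cohort, test_clusters, test_omics,
                                 reference=x_train)
    if spec.family == "cox":
        time = train_cohort.times(spec.outcome)
        event = train_cohort.events(spec.outcome)
        sel = select_lambda(x_train, family="cox", time=time, event=event,
                            n_folds=n_folds, seed=cv_seed)
        fit = fit_lasso_cox(x_train, time, event, sel.lam,
                            spec=spec, lambda_path=sel.to_frame())
        risk = fit.linear_predictor(x_test.values)
        value = harrell_cindex(test_cohort.times(spec.outcome),
                               test_cohort.events(spec.outcome), risk)
    else:
        y_all = train_cohort.binary(spec.outcome)
        keep = ~np.isnan(y_all)
        sel = select_lambda(x_train.values[keep], family="logistic",
                            y=y_all[keep], n_folds=n_folds, seed=cv_seed)
        fit = fit_l1_logistic(x_train.values[keep], y_all[keep], sel.lam,
                              spec=spec, lambda_path=sel.to_frame())
        fit.column_names = list(x_train.column_names)
        y_test = test_cohort.binary(spec.outcome)
        keep_test = ~np.isnan(y_test)
        score = fit.linear_predictor(x_test.values[keep_test])
        value = auc(y_test[keep_test], score)
    return value, fit


def run_repeated_workflow(
    cohort: CohortTable,
    proteins: OmicsBlock,
    mirnas: OmicsBlock,
    specs: list[ModelSpec],
    n_repetitions: int,
    seed: int,
    *,
    k_clusters: int = 2,
    n_folds: int = 10,
    test_frac: float = 0.2,
    assignment_strategy: str = "nystrom",
) -> EvaluationReport:
    """Run the repeated split-cluster-fit-score workflow.

    Fully reproducible given the master seed: per-repetition seeds are
    spawned deterministically. A repetition on which clustering degenerates
    for a spec that needs cluster labels is logged and skipped for the
    affected specs, and the skip count is reported.
    """
    if not specs:
        raise ConfigError("specs must be non-empty")
    if n_repetitions < 1:
        raise ConfigError("n_repetitions must be at least 1")
    available = {"raw_prot": proteins, "lbl_prot": proteins,
                 "raw_mirna": mirnas, "lbl_mirna": mirnas}
    for block, data in available.items():
        if any(block in s.blocks for s in specs) and data is None:
            raise ConfigError(f"specs require {block} but no omics block was given")

    master = np.random.SeedSequence(seed)
    rep_seeds = master.spawn(n_repetitions)
    outcomes = list(dict.fromkeys((s.outcome, s.family) for s in specs))
    records = []
    fits: dict[str, list[PenalizedFit]] = {EvaluationReport._key(s): [] for s in specs}
    n_skipped: dict[str, int] = {EvaluationReport._key(s): 0 for s in specs}

    for rep, rep_ss in enumerate(rep_seeds):
        ints = rep_ss.generate_state(3) % (2**31)
        split_seed, cluster_seed, cv_seed = (int(v) for v in ints)
        for outcome, family in outcomes:
            strat = _stratification_vector(cohort, outcome, family)
            idx = np.arange(cohort.n)
            train_idx, test_idx = train_test_split(
                idx, test_size=test_frac, stratify=strat,
                random_state=split_seed)
            plan = SplitPlan(rep, split_seed, train_idx, test_idx)
            train_cohort = cohort.subset(plan.train_index)
            test_cohort = cohort.subset(plan.test_index)

            outcome_specs = [s for s in specs
                             if s.outcome == outcome and s.family == family]
            train_omics = {"prot": proteins.rows(train_idx) if proteins is not None else None,
                           "mir": mirnas.rows(train_idx) if mirnas is not None else None}
            test_omics = {"prot": proteins.rows(test_idx) if proteins is not None else None,
                          "mir": mirnas.rows(test_idx) if mirnas is not None else None}
            train_omics = {k: v for k, v in train_omics.items() if v is not None}
            test_omics = {k: v for k, v in test_omics.items() if v is not None}

            train_clusters, test_clusters = {}, {}
            failed_blocks = set()
            for key in _blocks_needing_clusters(outcome_specs):
                try:
                    model = fit_spectral(train_omics[key], k_clusters,
                                         seed=cluster_seed)
                    train_clusters[key] = ClusterAssignment(
                        train_omics[key].patient_ids, model.training_labels,
                        model.k)
                    test_clusters[key] = assign_out_of_sample(
                        model, test_omics[key], strategy=assignment_strategy)
                except DegenerateInputError as exc:
                    logger.warning("repetition %d: clustering %s failed (%s)",
                                   rep, key, exc)
                    failed_blocks.add(key)

            for spec in outcome_specs:
                key = EvaluationReport._key(spec)
                needs = _blocks_needing_clusters([spec])
                if needs & failed_blocks:
                    n_skipped[key] += 1
                    continue
                try:
                    value, fit = _score_spec(
                        spec, train_cohort, test_cohort, train_clusters,
                        test_clusters, train_omics, test_omics, n_folds,
                        cv_seed)
                except UndefinedMetricError as exc:
                    logger.warning("repetition %d: %s unscorable (%s)",
                                   rep, key, exc)
                    n_skipped[key] += 1
                    continue
                metric = "cindex" if spec.family == "cox" else "auc"
                records.append({"repetition": rep, "spec": spec.label,
                                "outcome": spec.outcome, "family": spec.family,
                                "metric": metric, "value": value})
                fits[key].append(fit)

    per_rep = pd.DataFrame(records)
    rows = []
    for spec in specs:
        key = EvaluationReport._key(spec)
        sub = per_rep[(per_rep["spec"] == spec.label)
                      & (per_rep["outcome"] == spec.outcome)]
        values = sub["value"].to_numpy()
        r = values.size
        rows.append({
            "spec": spec.label, "outcome": spec.outcome,
            "metric": "cindex" if spec.family == "cox" else "auc",
            "mean": float(values.mean()) if r else np.nan,
            "se": float(values.std(ddof=1) / np.sqrt(r)) if r > 1 else np.nan,
            "median": float(np.median(values)) if r else np.nan,
            "n_repetitions": int(r),
            "n_skipped": n_skipped[key],
        })
    summary = pd.DataFrame(rows)
    return EvaluationReport(per_rep, summary, n_repetitions, seed, fits,
                            n_skipped)
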