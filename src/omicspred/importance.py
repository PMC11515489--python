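"""Variable importance by selection frequency across repetitions.

A covariate matters if the penalized model keeps choosing it: importance
is the fraction of repetitions in which its coefficient is nonzero,
with the mean absolute (standardized-scale) coefficient among selected
repetitions breaking ties. Reduced models refit on the top-ranked
proteins check whether a handful of biomarkers carries the signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError
from .penalized import ModelSpec, PenalizedFit
from .synthetic import CohortTable, OmicsBlock


def compute_importance(fits: list[PenalizedFit]) -> pd.DataFrame:
    """Selection frequency and mean |beta| per covariate across fits.

    Returns a DataFrame with columns ``covariate``, ``selection_frequency``,
    ``mean_abs_beta`` and ``rank`` (1 = most important), sorted by rank.
    Ranking is by selection frequency, ties by mean |beta| over the
    repetitions where the covariate was selected, remaining ties by name
    so the ordering is deterministic and independent of input order.
    """
    if not fits:
        raise ConfigError("compute_importance needs at least one fit")
    universe: list[str] = []
    for fit in fits:
        for c in fit.column_names:
            if c not in universe:
                universe.append(c)
    n_rep = len(fits)
    counts = {c: 0 for c in universe}
    abs_sums = {c: 0.0 for c in universe}
    for fit in fits:
        for c, b in zip(fit.column_names, fit.beta):
            if b != 0.0:
                counts[c] += 1
                abs_sums[c] += abs(b)
    table = pd.DataFrame({
        "covariate": universe,
        "selection_frequency": [counts[c] / n_rep for c in universe],
        "mean_abs_beta": [abs_sums[c] / counts[c] if counts[c] else 0.0
                          for c in universe],
    })
    table = table.sort_values(
        ["selection_frequency", "mean_abs_beta", "covariate"],
        ascending=[False, False, True], kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def top_features(importance: pd.DataFrame, k: int,
                 candidates: list[str]) -> list[str]:
    """The k best-ranked covariates among ``candidates`` (e.g. proteins)."""
    ranked = [c for c in importance["covariate"] if c in set(candidates)]
    if len(ranked) < k:
        raise ConfigError(
            f"asked for top {k} features but only {len(ranked)} candidates "
            "appear in the importance table")
    return ranked[:k]


def refit_top_k(
    importance: pd.DataFrame,
    k: int,
    spec: ModelSpec,
    cohort: CohortTable,
    proteins: OmicsBlock,
    mirnas: OmicsBlock,
    n_repetitions: int,
    seed: int,
    **workflow_kwargs,
):
    """Rerun the repeated workflow with proteins restricted to the top k.

    The protein block is cut down to the ``k`` best-ranked protein
    covariates (default use: k=4) before the workflow reruns, so the
    reduced report is directly comparable to the full-spec report when
    given the same master seed.
    """
    from .evaluation import run_repeated_workflow  # local: avoids cycle

    keep = set(top_features(importance, k, list(proteins.feature_names)))
    # preserve the block's own column order so k = all proteins is an
    # exact identity restriction
    reduced = proteins.subset_features(
        [f for f in proteins.feature_names if f in keep])
    return run_repeated_workflow(cohort, reduced, mirnas, [spec],
                                 n_repetitions, seed, **workflow_kwargs)


def plot_importance(importance: pd.DataFrame, path, top: int = 20,
                    title: str | None = None) -> None:
    """Horizontal-bar selection-frequency plot, most important on top."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = importance.nsmallest(top, "rank").iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(sub) + 1.2))
    ax.barh(sub["covariate"], sub["selection_frequency"], color="#2b8cbe")
    ax.set_xlabel("selection frequency across repetitions")
    ax.set_xlim(0, 1)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
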