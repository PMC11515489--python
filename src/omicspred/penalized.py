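"""L1-penalized Cox and logistic models over configurable covariate families.

The solvers are proximal-Newton coordinate descent in the glmnet style:
at each outer iteration the smooth loss (mean-scaled negative Cox partial
log-likelihood with Breslow tie handling, or mean binomial deviance) is
replaced by its diagonal-Hessian quadratic model, the penalized quadratic
is minimized by cyclic coordinate descent with soft-thresholding, and a
step-halving safeguard keeps the true penalized objective monotone.

Conventions
-----------
* Cox loss:      f(b) = -(1/n) log PL(b)            + lam * sum_j w_j |b_j|
* logistic loss: f(b) = (1/n) sum_i deviance_i(b)   + lam * sum_j w_j |b_j|
  with an unpenalized intercept (deviance_i = -2 log-likelihood_i).
* ``w_j`` are per-column penalty weights (default 1 everywhere: cluster
  indicators and demographic indicators are penalized like any other
  column; set a weight to 0 to force a column into the model).
* At ``lam >= lambda_max`` all penalized coefficients are exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigError, FoldWithoutEventError, SeparationError
from .spectral import ClusterAssignment
from .synthetic import (
    BINARY_OUTCOMES, DEMO_COLUMNS, TIME_TO_EVENT_OUTCOMES, CohortTable,
    OmicsBlock,
)

logger = logging.getLogger(__name__)

#: canonical ordering of covariate families in every design matrix
BLOCK_ORDER: tuple[str, ...] = (
    "demo", "clin", "raw_prot", "lbl_prot", "raw_mirna", "lbl_mirna",
)

_TOL = 1e-7           # outer convergence: max absolute coefficient change
_MAX_OUTER = 200
_MAX_INNER = 1000
_ETA_CLIP = 100.0     # keeps exp(eta) finite on diverging unpenalized fits
_BETA_CAP = 30.0      # separation guard for unpenalized logistic fits


@dataclass(frozen=True)
class ModelSpec:
    """Which covariate families enter the model, for which outcome."""

    blocks: tuple[str, ...]
    outcome: str
    family: str

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ConfigError("ModelSpec needs a non-empty block set")
        unknown = set(self.blocks) - set(BLOCK_ORDER)
        if unknown:
            raise ConfigError(f"unknown blocks: {sorted(unknown)}")
        # canonicalize order + dedupe
        ordered = tuple(b for b in BLOCK_ORDER if b in self.blocks)
        object.__setattr__(self, "blocks", ordered)
        if self.family not in ("cox", "logistic"):
            raise ConfigError(f"unknown family {self.family!r}")
        if self.family == "cox" and self.outcome not in TIME_TO_EVENT_OUTCOMES:
            raise ConfigError(f"{self.outcome!r} is not a time-to-event outcome")
        if self.family == "logistic" and self.outcome not in BINARY_OUTCOMES:
            raise ConfigError(f"{self.outcome!r} is not a binary outcome")

    @classmethod
    def for_outcome(cls, blocks: Sequence[str], outcome: str) -> "ModelSpec":
        """Build a spec, inferring the model family from the outcome."""
        if outcome in TIME_TO_EVENT_OUTCOMES:
            family = "cox"
        elif outcome in BINARY_OUTCOMES:
            family = "logistic"
        else:
            raise ConfigError(f"unknown outcome {outcome!r}")
        return cls(tuple(blocks), outcome, family)

    @property
    def label(self) -> str:
        return "+".join(self.blocks)


@dataclass
class DesignMatrix:
    """Numeric model matrix with the training statistics that produced it."""

    patient_ids: np.ndarray
    column_names: list[str]
    values: np.ndarray
    standardization_stats: dict[str, tuple[float, float]]
    dlco_median: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patient_ids), len(self.column_names)):
            raise ConfigError("design matrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise ConfigError("design matrix contains non-finite values")


@dataclass
class PenalizedFit:
    """A fitted penalized model: coefficients, penalty, diagnostics."""

    family: str
    column_names: list[str]
    beta: np.ndarray
    lam: float
    intercept: float = 0.0
    spec: ModelSpec | None = None
    converged: bool = True
    n_iter: int = 0
    objective_path: list[float] = field(default_factory=list)
    lambda_path: pd.DataFrame | None = None

    @property
    def selected(self) -> list[str]:
        return [c for c, b in zip(self.column_names, self.beta) if b != 0.0]

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        """Risk score (Cox) or logit (logistic) for rows of a design matrix."""
        eta = np.asarray(x, float) @ self.beta
        if self.family == "logistic":
            eta = eta + self.intercept
        return eta

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "column": self.column_names,
            "beta": self.beta,
            "selected": [b != 0.0 for b in self.beta],
        })

    def to_file(self, path) -> None:
        """Tabular coefficient file with a '#'-prefixed metadata header."""
        lines = [f"# family: {self.family}", f"# lambda: {self.lam!r}"]
        if self.family == "logistic":
            lines.append(f"# intercept: {self.intercept!r}")
        if self.spec is not None:
            lines.append(f"# spec: {self.spec.label} | {self.spec.outcome}")
        header = "\n".join(lines) + "\n"
        with open(path, "w") as fh:
            fh.write(header)
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_file(cls, path) -> "PenalizedFit":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            table = pd.read_csv(fh, sep="\t")
        return cls(meta.get("family", "cox"), table["column"].tolist(),
                   table["beta"].to_numpy(), float(meta.get("lambda", 0.0)),
                   float(meta.get("intercept", 0.0)))


class LambdaSelection(NamedTuple):
    """Cross-validated penalty choice plus the evaluated grid."""

    lam: float
    grid: np.ndarray
    cv_criterion: np.ndarray
    cv_se: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lambda": self.grid, "cv_criterion": self.cv_criterion,
            "cv_se": self.cv_se,
        })


# --------------------------------------------------------------------------
# design matrices

def build_design_matrix(
    spec: ModelSpec,
    cohort: CohortTable,
    clusters: Mapping[str, ClusterAssignment] | None = None,
    omics: Mapping[str, OmicsBlock] | None = None,
    reference: DesignMatrix | None = None,
) -> DesignMatrix:
    """Assemble the model matrix for a covariate-family spec.

    Demographics contribute six columns (age and BMI standardized;
    sex/smoking/treatment as 0/1 indicators), clinical factors contribute
    standardized FVC and DLco % predicted with DLco imputed by the
    *training* median, raw omics blocks contribute standardized feature
    columns, and a cluster-label block with k clusters contributes k-1
    indicator columns. Column order is canonical and identical across
    train and test.

    Pass ``reference=`` the training design matrix to reuse its
    standardization statistics and imputation value on held-out patients.
    """
    clusters = clusters or {}
    omics = omics or {}
    df = cohort.data
    pieces: list[tuple[str, np.ndarray, bool]] = []  # (name, column, continuous?)

    for block in spec.blocks:
        if block == "demo":
            for name in DEMO_COLUMNS:
                cont = name in ("age", "bmi")
                pieces.append((name, df[name].to_numpy(float), cont))
        elif block == "clin":
            fvc = df["fvc_pct"].to_numpy(float)
            dlco = df["dlco_pct"].to_numpy(float)
            if reference is not None:
                median = reference.dlco_median
            else:
                with_values = dlco[~np.isnan(dlco)]
                if with_values.size == 0:
                    raise ConfigError("all DLco values missing; cannot impute")
                median = float(np.median(with_values))
            dlco = np.where(np.isnan(dlco), median, dlco)
            pieces.append(("fvc_pct", fvc, True))
            pieces.append(("dlco_pct", dlco, True))
        elif block in ("raw_prot", "raw_mirna"):
            key = "prot" if block == "raw_prot" else "mir"
            if key not in omics:
                raise ConfigError(f"spec requests {block} but no {key!r} omics block given")
            ob = omics[key]
            if not np.array_equal(ob.patient_ids, cohort.patient_ids):
                raise ConfigError(f"{block} patient ids do not align with the cohort")
            for j, name in enumerate(ob.feature_names):
                pieces.append((name, ob.values[:, j], True))
        elif block in ("lbl_prot", "lbl_mirna"):
            key = "prot" if block == "lbl_prot" else "mir"
            if key not in clusters:
                raise ConfigError(f"spec requests {block} but no {key!r} cluster labels given")
            asg = clusters[key]
            if not np.array_equal(asg.patient_ids, cohort.patient_ids):
                raise ConfigError(f"{block} cluster ids do not align with the cohort")
            k = getattr(asg, "k", int(asg.labels.max(initial=0)) + 1)
            for c in range(1, k):
                pieces.append((f"{block}_{c}", (asg.labels == c).astype(float), False))
        else:  # pragma: no cover - ModelSpec already validates
            raise ConfigError(f"unknown block {block!r}")

    names = [p[0] for p in pieces]
    values = np.column_stack([p[1] for p in pieces]) if pieces else np.empty((cohort.n, 0))
    if reference is not None:
        if names != reference.column_names:
            raise ConfigError("design matrix columns do not match the reference")
        stats = reference.standardization_stats
        dlco_median = reference.dlco_median
    else:
        stats = {}
        for j, (name, _, cont) in enumerate(pieces):
            if cont:
                col = values[:, j]
                sd = float(col.std(ddof=0))
                stats[name] = (float(col.mean()), sd if sd > 0 else 1.0)
        dlco_median = locals().get("median") if "clin" in spec.blocks else None

    for j, name in enumerate(names):
        if name in stats:
            mean, sd = stats[name]
            values[:, j] = (values[:, j] - mean) / sd

    return DesignMatrix(cohort.patient_ids.copy(), names, values, stats,
                        dlco_median)


# --------------------------------------------------------------------------
# smooth-loss ingredients

def _cox_parts(eta: np.ndarray, time: np.ndarray, event: np.ndarray
               ) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean-scaled Cox negative partial log-likelihood (Breslow ties) with
    per-observation gradient ``g`` and curvature ``h`` in eta.

    Returns (nll, g, h) where d nll/d eta_i = g_i / n and the diagonal
    Hessian approximation is diag(h)/n.
    """
    n = time.size
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    eta_s = np.clip(eta[order], -_ETA_CLIP, _ETA_CLIP)
    w_s = np.exp(eta_s)

    rev = np.cumsum(w_s[::-1])[::-1]                # sum of w over risk set
    new_group = np.r_[True, t_s[1:] != t_s[:-1]]
    group_id = np.cumsum(new_group) - 1
    s0 = rev[np.flatnonzero(new_group)]             # risk-set sum per unique time
    d = np.bincount(group_id, weights=e_s.astype(float))

    with np.errstate(divide="ignore"):
        log_s0 = np.where(d > 0, np.log(s0), 0.0)
    ll = float((eta_s * e_s).sum() - (d * log_s0).sum())

    dh1 = np.where(d > 0, d / s0, 0.0)              # Breslow hazard increments
    dh2 = np.where(d > 0, d / s0**2, 0.0)
    r1 = np.cumsum(dh1)[group_id]
    r2 = np.cumsum(dh2)[group_id]

    g_s = -(e_s - w_s * r1)
    h_s = np.maximum(w_s * r1 - w_s**2 * r2, 1e-12)

    g = np.empty(n); g[order] = g_s
    h = np.empty(n); h[order] = h_s
    return -ll / n, g, h


def _logistic_parts(eta: np.ndarray, y: np.ndarray
                    ) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean binomial deviance with per-observation gradient and curvature."""
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    p = 1.0 / (1.0 + np.exp(-eta))
    # deviance via log1p(exp(.)) for stability
    dev = 2.0 * (np.logaddexp(0.0, eta) - y * eta)
    g = 2.0 * (p - y)
    h = np.maximum(2.0 * p * (1.0 - p), 1e-10)
    return float(dev.mean()), g, h


# --------------------------------------------------------------------------
# the solver

def _cd_kernel(x, beta, intercept, z, h, lam, pen, fit_intercept, inner_tol,
               max_inner):
    """Cyclic coordinate descent on the penalized weighted least squares
    (1/2n) sum h_i (z_i - b0 - x_i b)^2 + lam * sum pen_j |b_j|.

    Full sweeps alternate with sweeps over the active (nonzero) set until
    a full sweep moves no coefficient by more than ``inner_tol``. Compiled
    with numba when available; updates ``beta`` in place, returns the
    intercept.
    """
    n, p = x.shape
    denom = np.zeros(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += h[i] * x[i, j] * x[i, j]
        denom[j] = s / n
    h_mean = 0.0
    for i in range(n):
        h_mean += h[i]
    h_mean /= n

    eta = np.zeros(n)
    for i in range(n):
        v = intercept if fit_intercept else 0.0
        for j in range(p):
            if beta[j] != 0.0:
                v += x[i, j] * beta[j]
        eta[i] = v

    full_sweep = True
    for _ in range(max_inner):
        max_step = 0.0
        if fit_intercept:
            s = 0.0
            for i in range(n):
                s += h[i] * (z[i] - eta[i])
            step = s / (n * h_mean)
            intercept += step
            for i in range(n):
                eta[i] += step
            if abs(step) > max_step:
                max_step = abs(step)
        for j in range(p):
            if denom[j] <= 0.0:
                continue
            if not full_sweep and beta[j] == 0.0:
                continue
            b_old = beta[j]
            s = 0.0
            for i in range(n):
                s += h[i] * x[i, j] * (z[i] - eta[i])
            rho = s / n + denom[j] * b_old
            thr = lam * pen[j]
            if rho > thr:
                b_new = (rho - thr) / denom[j]
            elif rho < -thr:
                b_new = (rho + thr) / denom[j]
            else:
                b_new = 0.0
            if b_new != b_old:
                d = b_new - b_old
                for i in range(n):
                    eta[i] += x[i, j] * d
                beta[j] = b_new
                if abs(d) > max_step:
                    max_step = abs(d)
        if max_step < inner_tol:
            if full_sweep:
                break
            full_sweep = True       # verify convergence with a full sweep
        else:
            full_sweep = False      # iterate the active set only
    return intercept


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _cd_kernel = njit(cache=False)(_cd_kernel)
except ImportError:  # pragma: no cover
    pass


def _coordinate_descent(x, beta, intercept, z, h, lam, pen, fit_intercept,
                        inner_tol):
    beta = beta.copy()
    intercept = _cd_kernel(
        np.ascontiguousarray(x), beta, float(intercept),
        np.ascontiguousarray(z), np.ascontiguousarray(h), float(lam),
        np.ascontiguousarray(pen), fit_intercept, float(inner_tol),
        _MAX_INNER)
    return beta, intercept


def _cox_loss_kernel(eta_s, e_s, group_id, d_group):
    """Mean-scaled Cox negative partial log-likelihood on time-sorted data."""
    n = eta_s.size
    w = np.empty(n)
    ll = 0.0
    for i in range(n):
        e = eta_s[i]
        if e > _ETA_CLIP:
            e = _ETA_CLIP
        elif e < -_ETA_CLIP:
            e = -_ETA_CLIP
        w[i] = np.exp(e)
        ll += e * e_s[i]
    n_groups = d_group.size
    s0 = np.zeros(n_groups)
    acc = 0.0
    for i in range(n - 1, -1, -1):
        acc += w[i]
        s0[group_id[i]] = acc       # last write lands on the group's first row
    for gi in range(n_groups):
        if d_group[gi] > 0.0:
            ll -= d_group[gi] * np.log(s0[gi])
    return -ll / n


def _cox_parts_kernel(eta_s, e_s, group_id, d_group, g, h):
    """Loss plus per-observation gradient/curvature, filled into g and h."""
    n = eta_s.size
    w = np.empty(n)
    ll = 0.0
    for i in range(n):
        e = eta_s[i]
        if e > _ETA_CLIP:
            e = _ETA_CLIP
        elif e < -_ETA_CLIP:
            e = -_ETA_CLIP
        w[i] = np.exp(e)
        ll += e * e_s[i]
    n_groups = d_group.size
    s0 = np.zeros(n_groups)
    acc = 0.0
    for i in range(n - 1, -1, -1):
        acc += w[i]
        s0[group_id[i]] = acc
    cum1 = np.zeros(n_groups)       # Breslow cumulative hazard at each time
    cum2 = np.zeros(n_groups)
    c1 = 0.0
    c2 = 0.0
    for gi in range(n_groups):
        if d_group[gi] > 0.0:
            ll -= d_group[gi] * np.log(s0[gi])
            c1 += d_group[gi] / s0[gi]
            c2 += d_group[gi] / (s0[gi] * s0[gi])
        cum1[gi] = c1
        cum2[gi] = c2
    for i in range(n):
        r1 = cum1[group_id[i]]
        r2 = cum2[group_id[i]]
        g[i] = -(e_s[i] - w[i] * r1)
        hv = w[i] * r1 - w[i] * w[i] * r2
        h[i] = hv if hv > 1e-12 else 1e-12
    return -ll / n


def _logit_loss_kernel(eta, y):
    """Mean binomial deviance."""
    n = eta.size
    dev = 0.0
    for i in range(n):
        e = eta[i]
        if e > _ETA_CLIP:
            e = _ETA_CLIP
        elif e < -_ETA_CLIP:
            e = -_ETA_CLIP
        # logaddexp(0, e) computed stably
        m = e if e > 0.0 else 0.0
        dev += 2.0 * (m + np.log1p(np.exp(-abs(e))) - y[i] * e)
    return dev / n


def _logit_parts_kernel(eta, y, g, h):
    n = eta.size
    dev = 0.0
    for i in range(n):
        e = eta[i]
        if e > _ETA_CLIP:
            e = _ETA_CLIP
        elif e < -_ETA_CLIP:
            e = -_ETA_CLIP
        m = e if e > 0.0 else 0.0
        dev += 2.0 * (m + np.log1p(np.exp(-abs(e))) - y[i] * e)
        p = 1.0 / (1.0 + np.exp(-e))
        g[i] = 2.0 * (p - y[i])
        hv = 2.0 * p * (1.0 - p)
        h[i] = hv if hv > 1e-10 else 1e-10
    return dev / n


def _solve_kernel(x, lam, pen, family, resp, group_id, d_group, beta,
                  intercept, tol, max_outer, max_inner, obj_path):
    """Proximal Newton: quadratic model via per-observation curvature,
    coordinate descent on the penalized quadratic, monotone step halving
    on the true objective. ``family`` 0 = Cox (x sorted by time, ``resp``
    the event indicator), 1 = logistic (``resp`` the labels; intercept
    unpenalized). Updates ``beta`` in place.
    """
    n, p = x.shape
    fit_intercept = family == 1
    g = np.empty(n)
    h = np.empty(n)
    inner_tol = tol * 0.1 if tol * 0.1 < 1e-8 else 1e-8

    eta = x @ beta
    if fit_intercept:
        for i in range(n):
            eta[i] += intercept

    if family == 0:
        obj = _cox_parts_kernel(eta, resp, group_id, d_group, g, h)
    else:
        obj = _logit_parts_kernel(eta, resp, g, h)
    for j in range(p):
        obj += lam * pen[j] * abs(beta[j])
    obj_path[0] = obj

    it = 0
    converged = False
    stagnant = 0
    b_try = np.empty(p)
    for it in range(1, max_outer + 1):
        z = np.empty(n)
        for i in range(n):
            z[i] = eta[i] - g[i] / h[i]
        beta_new = beta.copy()
        b0_new = _cd_kernel(x, beta_new, intercept, z, h, lam, pen,
                            fit_intercept, inner_tol, max_inner)

        def _objective_at(t):
            for j in range(p):
                b_try[j] = beta[j] + t * (beta_new[j] - beta[j])
            i_t = intercept + t * (b0_new - intercept)
            eta_t = x @ b_try
            if fit_intercept:
                for i in range(n):
                    eta_t[i] += i_t
            if family == 0:
                loss = _cox_loss_kernel(eta_t, resp, group_id, d_group)
            else:
                loss = _logit_loss_kernel(eta_t, resp)
            for j in range(p):
                loss += lam * pen[j] * abs(b_try[j])
            return loss, i_t, eta_t

        t = 1.0
        accepted = False
        obj_try, i_try, eta_try = _objective_at(1.0)
        if obj_try <= obj + 1e-13:
            accepted = True
            # expansion: the damped quadratic model under-steps along flat
            # valleys, so extrapolate while the objective keeps improving
            t_exp = 2.0
            for _ in range(6):
                obj_e, i_e, eta_e = _objective_at(t_exp)
                if obj_e < obj_try:
                    obj_try, i_try, eta_try, t = obj_e, i_e, eta_e, t_exp
                    t_exp *= 2.0
                else:
                    break
            _objective_at(t)  # restore b_try to the accepted step
        else:
            for _ in range(30):
                t *= 0.5
                obj_try, i_try, eta_try = _objective_at(t)
                if obj_try <= obj + 1e-13:
                    accepted = True
                    break
        if not accepted:
            obj_path[it] = obj
            converged = True        # no descent direction left at this tol
            break

        delta = 0.0
        for j in range(p):
            d = abs(b_try[j] - beta[j])
            if d > delta:
                delta = d
            beta[j] = b_try[j]
        if fit_intercept:
            d = abs(i_try - intercept)
            if d > delta:
                delta = d
        intercept = i_try
        obj = obj_try
        eta = eta_try
        obj_path[it] = obj
        if family == 0:
            _cox_parts_kernel(eta, resp, group_id, d_group, g, h)
        else:
            _logit_parts_kernel(eta, resp, g, h)
        # convergence is only declared after a plain (t=1) CD step so the
        # final iterate carries the exact soft-threshold sparsity pattern
        if t == 1.0:
            if delta < tol:
                converged = True
                break
            # stagnation stop: objective improvement below double-precision
            # resolution twice in a row means further polishing cannot
            # change the solution in any measurable way
            if obj_path[it - 1] - obj <= 1e-13 * (1.0 + abs(obj)):
                stagnant += 1
                if stagnant >= 2:
                    converged = True
                    break
            else:
                stagnant = 0
        else:
            stagnant = 0
    return intercept, it, converged


def _path_kernel(x, lam_grid, pen, family, resp, group_id, d_group,
                 intercept0, tol, max_outer, max_inner):
    """Warm-started descending-lambda path; returns all coefficients."""
    m = lam_grid.size
    p = x.shape[1]
    betas = np.zeros((m, p))
    intercepts = np.zeros(m)
    beta = np.zeros(p)
    intercept = intercept0
    obj_path = np.zeros(max_outer + 1)
    for i in range(m):
        intercept, _, _ = _solve_kernel(
            x, lam_grid[i], pen, family, resp, group_id, d_group, beta,
            intercept, tol, max_outer, max_inner, obj_path)
        for j in range(p):
            betas[i, j] = beta[j]
        intercepts[i] = intercept
    return betas, intercepts


try:  # pragma: no cover - exercised indirectly through every fit
    from numba import njit as _njit

    _cox_loss_kernel = _njit(cache=False)(_cox_loss_kernel)
    _cox_parts_kernel = _njit(cache=False)(_cox_parts_kernel)
    _logit_loss_kernel = _njit(cache=False)(_logit_loss_kernel)
    _logit_parts_kernel = _njit(cache=False)(_logit_parts_kernel)
    _solve_kernel = _njit(cache=False)(_solve_kernel)
    _path_kernel = _njit(cache=False)(_path_kernel)
except ImportError:  # pragma: no cover - pure-Python fallback
    pass


def _prepare_cox(x, time, event):
    """Sort by time and precompute Breslow tie-group structures."""
    order = np.argsort(time, kind="stable")
    x_s = np.ascontiguousarray(x[order])
    t_s = time[order]
    e_s = event[order].astype(float)
    new_group = np.r_[True, t_s[1:] != t_s[:-1]]
    group_id = (np.cumsum(new_group) - 1).astype(np.int64)
    d_group = np.bincount(group_id, weights=e_s)
    return x_s, e_s, group_id, d_group


_NO_GROUPS = (np.zeros(1, dtype=np.int64), np.zeros(1))


def _check_design(x):
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ConfigError("design matrix contains non-finite values")
    return x


def _resolve_penalty(p, penalty_weights):
    if penalty_weights is None:
        return np.ones(p)
    pen = np.asarray(penalty_weights, float)
    if pen.shape != (p,):
        raise ConfigError("penalty_weights length must match the column count")
    if (pen < 0).any():
        raise ConfigError("penalty_weights must be non-negative")
    return pen


def _unwrap(X):
    if isinstance(X, DesignMatrix):
        return _check_design(X.values), list(X.column_names)
    x = _check_design(X)
    return x, [f"x{j}" for j in range(x.shape[1])]


def lambda_max_cox(X, time, event, penalty_weights=None) -> float:
    """Smallest penalty that zeroes every (penalized) Cox coefficient."""
    x, names = _unwrap(X)
    pen = _resolve_penalty(x.shape[1], penalty_weights)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    eta = np.zeros(time.size)
    if (pen == 0).any():
        free = pen == 0
        fit = fit_lasso_cox(x[:, free], time, event, 0.0)
        eta = x[:, free] @ fit.beta
    _, g, _ = _cox_parts(eta, time, event)
    score = np.abs(x.T @ g) / time.size
    vals = np.where(pen > 0, score / np.where(pen > 0, pen, 1.0), 0.0)
    # tiny inflation so the zero solution survives float rounding at lam_max
    return float(vals.max()) * (1.0 + 1e-10)


def lambda_max_logistic(X, y, penalty_weights=None) -> float:
    """Smallest penalty that zeroes every penalized logistic coefficient."""
    x, names = _unwrap(X)
    pen = _resolve_penalty(x.shape[1], penalty_weights)
    y = np.asarray(y, float)
    prev = y.mean()
    eta = np.full(y.size, np.log(prev / (1 - prev)))
    if (pen == 0).any():
        free = pen == 0
        fit = fit_l1_logistic(x[:, free], y, 0.0)
        eta = fit.intercept + x[:, free] @ fit.beta
    _, g, _ = _logistic_parts(eta, y)
    score = np.abs(x.T @ g) / y.size
    vals = np.where(pen > 0, score / np.where(pen > 0, pen, 1.0), 0.0)
    return float(vals.max()) * (1.0 + 1e-10)


def fit_lasso_cox(X, time, event, lam: float, *, penalty_weights=None,
                  beta0=None, spec: ModelSpec | None = None,
                  lambda_path: pd.DataFrame | None = None) -> PenalizedFit:
    """Fit an L1-penalized Cox proportional-hazards model (Breslow ties).

    Minimizes -(1/n) log PL(beta) + lam * sum_j w_j |beta_j| to a maximum
    coefficient change below 1e-7 between outer iterations.
    """
    x, names = _unwrap(X)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if time.size != x.shape[0] or event.size != x.shape[0]:
        raise ConfigError("time/event length must match the design matrix")
    if (time <= 0).any():
        raise ConfigError("survival times must be positive")
    if event.sum() < 1:
        raise ConfigError("Cox fit requires at least one event")
    if lam < 0:
        raise ConfigError("lambda must be non-negative")
    pen = _resolve_penalty(x.shape[1], penalty_weights)

    x_s, e_s, group_id, d_group = _prepare_cox(x, time, event)
    beta = np.zeros(x.shape[1]) if beta0 is None else np.asarray(beta0, float).copy()
    obj_path = np.zeros(_MAX_OUTER + 1)
    _, n_iter, converged = _solve_kernel(
        x_s, float(lam), pen, 0, e_s, group_id, d_group, beta, 0.0,
        _TOL, _MAX_OUTER, _MAX_INNER, obj_path)
    if not converged:
        logger.warning("Cox solver hit the outer-iteration limit (%d)", n_iter)
    return PenalizedFit("cox", names, beta, float(lam), 0.0, spec, converged,
                        n_iter, obj_path[:n_iter + 1].tolist(), lambda_path)


def fit_l1_logistic(X, y, lam: float, *, penalty_weights=None, beta0=None,
                    intercept0=None, spec: ModelSpec | None = None,
                    lambda_path: pd.DataFrame | None = None) -> PenalizedFit:
    """Fit an L1-penalized logistic model with an unpenalized intercept.

    Minimizes the mean binomial deviance + lam * sum_j w_j |beta_j|. At
    lam = 0 a coefficient escaping a generous cap raises SeparationError
    (perfectly separable classes have no finite optimum).
    """
    x, names = _unwrap(X)
    y = np.asarray(y, float)
    if y.size != x.shape[0]:
        raise ConfigError("label length must match the design matrix")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ConfigError("labels must be 0/1 without missing values")
    if len(np.unique(y)) < 2:
        raise ConfigError("logistic fit requires both classes present")
    if lam < 0:
        raise ConfigError("lambda must be non-negative")
    pen = _resolve_penalty(x.shape[1], penalty_weights)

    prev = y.mean()
    i0 = float(np.log(prev / (1 - prev))) if intercept0 is None else float(intercept0)
    beta = np.zeros(x.shape[1]) if beta0 is None else np.asarray(beta0, float).copy()
    obj_path = np.zeros(_MAX_OUTER + 1)
    intercept, n_iter, converged = _solve_kernel(
        np.ascontiguousarray(x), float(lam), pen, 1, y, *_NO_GROUPS, beta,
        i0, _TOL, _MAX_OUTER, _MAX_INNER, obj_path)
    if lam == 0 and np.abs(beta).max(initial=0.0) > _BETA_CAP:
        raise SeparationError(
            f"unpenalized fit diverged (coefficients exceeded {_BETA_CAP}); "
            "the classes are likely perfectly separable")
    if not converged:
        logger.warning("logistic solver hit the outer-iteration limit (%d)", n_iter)
    return PenalizedFit("logistic", names, beta, float(lam), float(intercept),
                        spec, converged, n_iter,
                        obj_path[:n_iter + 1].tolist(), lambda_path)


def fit_path(X, lam_grid, *, family: str, time=None, event=None, y=None,
             penalty_weights=None) -> list[PenalizedFit]:
    """Fit a descending lambda grid with warm starts."""
    x, names = _unwrap(X)
    pen = _resolve_penalty(x.shape[1], penalty_weights)
    lam_grid = np.asarray(lam_grid, float)
    if family == "cox":
        betas, intercepts = _cox_path(x, np.asarray(time, float),
                                      np.asarray(event, int), lam_grid, pen)
    elif family == "logistic":
        betas, intercepts = _logistic_path(x, np.asarray(y, float), lam_grid, pen)
    else:
        raise ConfigError(f"unknown family {family!r}")
    return [PenalizedFit(family, names, betas[i], float(lam_grid[i]),
                         float(intercepts[i]))
            for i in range(lam_grid.size)]


def _cox_path(x, time, event, lam_grid, pen):
    x_s, e_s, group_id, d_group = _prepare_cox(x, time, event)
    return _path_kernel(x_s, lam_grid, pen, 0, e_s, group_id, d_group,
                        0.0, _TOL, _MAX_OUTER, _MAX_INNER)


def _logistic_path(x, y, lam_grid, pen):
    prev = y.mean()
    i0 = float(np.log(prev / (1 - prev)))
    return _path_kernel(np.ascontiguousarray(x), lam_grid, pen, 1, y,
                        *_NO_GROUPS, i0, _TOL, _MAX_OUTER, _MAX_INNER)


def select_lambda(X, *, family: str, time=None, event=None, y=None,
                  n_folds: int = 10, seed: int = 0, n_lambda: int = 100,
                  lambda_min_ratio: float = 1e-3,
                  penalty_weights=None) -> LambdaSelection:
    """Choose the penalty by event-stratified K-fold cross-validation.

    The grid is ``n_lambda`` log-spaced values from lambda_max down to
    ``lambda_min_ratio * lambda_max``; the fold-averaged criterion is the
    held-out partial-likelihood deviance per event (Cox) or the held-out
    mean binomial deviance (logistic), minimized over the grid (ties
    break toward the sparser, larger penalty).
    """
    if n_folds < 2:
        raise ConfigError("n_folds must be at least 2")
    x, names = _unwrap(X)
    pen = _resolve_penalty(x.shape[1], penalty_weights)
    if family == "cox":
        time = np.asarray(time, float)
        event = np.asarray(event, int)
        strat = event
        if strat.sum() < n_folds:
            raise FoldWithoutEventError(
                f"{int(strat.sum())} events cannot cover {n_folds} folds")
        lam_max = lambda_max_cox(x, time, event, penalty_weights)
    elif family == "logistic":
        y = np.asarray(y, float)
        strat = y.astype(int)
        if min((strat == 0).sum(), (strat == 1).sum()) < n_folds:
            raise FoldWithoutEventError("minority class cannot cover all folds")
        lam_max = lambda_max_logistic(x, y, penalty_weights)
    else:
        raise ConfigError(f"unknown family {family!r}")

    if lam_max <= 0:  # degenerate: nothing correlates with the outcome
        lam_max = 1e-8
    grid = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambda)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(seed) % (2**31))
    crit = np.full((n_folds, n_lambda), np.nan)
    for f, (tr, va) in enumerate(skf.split(x, strat)):
        if family == "cox":
            if event[tr].sum() < 1 or event[va].sum() < 1:
                raise FoldWithoutEventError(f"fold {f} has no events")
            betas, _ = _cox_path(x[tr], time[tr], event[tr], grid, pen)
            d_va = float(event[va].sum())
            for i in range(n_lambda):
                nll, _, _ = _cox_parts(x[va] @ betas[i], time[va], event[va])
                crit[f, i] = 2.0 * nll * va.size / d_va
        else:
            betas, intercepts = _logistic_path(x[tr], y[tr], grid, pen)
            for i in range(n_lambda):
                dev, _, _ = _logistic_parts(intercepts[i] + x[va] @ betas[i],
                                            y[va])
                crit[f, i] = dev

    mean = crit.mean(axis=0)
    se = crit.std(axis=0, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmin(mean))  # argmin takes the first (largest) lambda on ties
    return LambdaSelection(float(grid[best]), grid, mean, se)


def kkt_violation(fit: PenalizedFit, X, *, time=None, event=None, y=None
                  ) -> float:
    """Largest KKT violation of a fit (diagnostic; ~0 at a true optimum)."""
    x, _ = _unwrap(X)
    eta = fit.linear_predictor(x)
    if fit.family == "cox":
        _, g, _ = _cox_parts(eta, np.asarray(time, float), np.asarray(event, int))
    else:
        _, g, _ = _logistic_parts(eta, np.asarray(y, float))
    grad = x.T @ g / x.shape[0]
    viol = np.where(fit.beta == 0.0,
                    np.maximum(np.abs(grad) - fit.lam, 0.0),
                    np.abs(grad + fit.lam * np.sign(fit.beta)))
    return float(viol.max(initial=0.0))
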