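"""Candidate-level stacked generalization with a non-negative LASSO blender.

The candidate library holds the top-m configurations per tuned family
(not just each family's single winner).  Their out-of-fold (OOF)
predictions — held-out predictions from the shared repeated-CV resample
set, averaged over repeats — form the meta-learner's design matrix, so
the blend weights are estimated on predictions the base learners never
fit to.

The meta-learner solves

    min_{w >= 0, b}  (1/2n) * sum_i (y_i - b - sum_c w_c * oof_ic)^2
                     + lambda * sum_c w_c

by cyclic coordinate descent with non-negativity clipping (for w >= 0
the L1 penalty is linear, so each coordinate update is closed-form).
The intercept is unpenalized and no sum-to-one constraint is imposed.
The default penalty is fixed at lambda = 1e-6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .learner_zoo import (CandidateModel, CVSpec, MetricPair, PrepConfig,
                          finalize_candidate, rmse_r2)
from .spectra_core import Dataset

__all__ = [
    "OOFMatrix",
    "StackModel",
    "WeightReport",
    "build_candidate_library",
    "assemble_oof",
    "blend",
    "finalize_stack",
    "predict_stack",
    "evaluate_stack",
    "report_weights",
]


@dataclass
class OOFMatrix:
    """n_train x n_candidates out-of-fold prediction matrix (DM %)."""

    sample_ids: list[str]
    candidate_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        if V.shape != (len(self.sample_ids), len(self.candidate_ids)):
            raise ValueError("OOF matrix shape inconsistent with ids")
        if not np.all(np.isfinite(V)):
            raise ValueError("OOF matrix has missing cells")
        self.values = V


@dataclass
class StackModel:
    members: list[CandidateModel]          # weight > 0, refit on full train
    weights: np.ndarray                    # aligned with members, all > 0
    intercept: float
    penalty: float
    cv_provenance: tuple                   # (folds, repeats, seed)

    def __post_init__(self):
        if np.any(self.weights < 0):
            raise ValueError("stack weights must be non-negative")


def build_candidate_library(results: dict[str, list[CandidateModel]],
                            top_m: int = 20) -> list[CandidateModel]:
    """Top-m configurations per family, id'd family_rank (e.g. gpr_4)."""
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    library = []
    for family, cands in results.items():
        good = [c for c in cands if not c.failed]
        if not good:
            warnings.warn(f"family {family}: no successful candidates, skipped",
                          stacklevel=2)
            continue
        good = sorted(good, key=lambda c: (c.cv_rmse_mean, c.config_hash()))
        for rank, c in enumerate(good[:top_m], start=1):
            c.candidate_id = f"{family}_{rank}"
            library.append(c)
    return library


def assemble_oof(candidates: list[CandidateModel], cv: CVSpec,
                 sample_ids: list[str]) -> OOFMatrix:
    """Stack per-candidate OOF vectors (repeat-averaged) into a matrix.

    All candidates must carry the identical resample provenance; a
    mismatch means their held-out predictions are not comparable and
    would leak training information into the meta-fit.
    """
    if not candidates:
        raise ValueError("no candidates to assemble")
    expected = (cv.folds, cv.repeats, cv.seed)
    cols = []
    for c in candidates:
        if c.cv_provenance != expected:
            raise ValueError(
                f"candidate {c.candidate_id or c.family}: resample provenance "
                f"{c.cv_provenance} != expected {expected}")
        cols.append(c.oof)
    return OOFMatrix(sample_ids, [c.candidate_id for c in candidates],
                     np.column_stack(cols))


def blend(oof: OOFMatrix | np.ndarray, y: np.ndarray, lam: float = 1e-6,
          tol: float = 1e-8, max_sweeps: int = 100_000) -> tuple[np.ndarray, float]:
    """Non-negative LASSO of y on the OOF columns; returns (weights, intercept).

    Cyclic coordinate descent; converged when the largest weight change in
    a sweep falls below ``tol``.
    """
    X = oof.values if isinstance(oof, OOFMatrix) else np.asarray(oof, float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y misaligned with OOF matrix")
    # the unpenalized intercept makes the problem equivalent to coordinate
    # descent on column-centered data, with b recovered afterwards
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    col_sq = (Xc * Xc).sum(axis=0) / n
    w = np.zeros(p)
    r = y - y_mean
    delta = np.inf
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            if col_sq[j] == 0.0:
                continue
            rho = (Xc[:, j] @ r) / n + col_sq[j] * w[j]
            new = max(0.0, (rho - lam) / col_sq[j])
            if new != w[j]:
                r += Xc[:, j] * (w[j] - new)
                delta = max(delta, abs(new - w[j]))
                w[j] = new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"non-negative LASSO did not converge in {max_sweeps} sweeps "
            f"(last sweep max change {delta:.3e})")
    b = y_mean - float(x_mean @ w)
    return w, b


def finalize_stack(weights: np.ndarray, intercept: float,
                   candidates: list[CandidateModel], train: Dataset,
                   prep: PrepConfig = PrepConfig(),
                   penalty: float = 1e-6) -> StackModel:
    """Refit the positively weighted members on the full training set."""
    weights = np.asarray(weights, float)
    if weights.shape != (len(candidates),):
        raise ValueError("weights misaligned with candidates")
    keep = weights > 0
    if not keep.any():
        raise ValueError("meta-learner retained no members")
    members, w = [], []
    for c, wc, k in zip(candidates, weights, keep):
        if k:
            members.append(finalize_candidate(c, train, prep))
            w.append(wc)
    return StackModel(members=members, weights=np.asarray(w),
                      intercept=float(intercept), penalty=penalty,
                      cv_provenance=candidates[0].cv_provenance)


def predict_stack(model: StackModel, X_raw: np.ndarray) -> np.ndarray:
    """b + sum_c w_c * member_c(x) on raw reflectance spectra."""
    pred = np.full(X_raw.shape[0], model.intercept, dtype=float)
    for w, member in zip(model.weights, model.members):
        pred += w * member.predict(X_raw)
    return pred


def evaluate_stack(model: StackModel, test: Dataset) -> MetricPair:
    return rmse_r2(test.y, predict_stack(model, test.X))


@dataclass
class WeightReport:
    members: pd.DataFrame          # Family, Model, Weight + hyperparameters
    family_totals: pd.DataFrame    # Family, Weight


_PARAM_COLUMNS = {"num_comp": "K", "sigma": "sigma", "trees": "Trees",
                  "depth": "Depth", "learning_rate": "LR", "mtry": "mtry",
                  "min_n": "min_n", "lambda": "lambda", "alpha": "alpha"}


def report_weights(model: StackModel) -> WeightReport:
    """Member weight table plus per-family aggregated weights."""
    rows = []
    for w, m in zip(model.weights, model.members):
        row = {"Family": m.family, "Model": m.candidate_id, "Weight": float(w)}
        for key, col in _PARAM_COLUMNS.items():
            if key in m.params:
                row[col] = m.params[key]
        rows.append(row)
    members = pd.DataFrame(rows).sort_values("Weight", ascending=False,
                                             kind="stable").reset_index(drop=True)
    totals = (members.groupby("Family", sort=True)["Weight"].sum()
              .reset_index().sort_values("Weight", ascending=False,
                                         kind="stable").reset_index(drop=True))
    return WeightReport(members=members, family_totals=totals)
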