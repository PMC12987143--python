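"""Base-learner families, hyperparameter search, repeated-CV tuning.

Seven regression families are tuned for DM prediction: PCR, PLSR and
elastic net (linear, latent-variable); random forest, XGBoost and
LightGBM (tree ensembles); and Gaussian process regression (kernel).
All families except PLSR are trained on PCA scores of the standardized
spectra (the number of retained components ``num_comp`` is itself a
hyperparameter bounded by the 99%-variance component budget K_max);
PLSR is trained on the standardized full spectrum and tunes its own
latent dimension.

Tuning uses seeded repeated K-fold cross-validation (default 10-fold,
3 repeats) with the preprocessing chain refit inside every training
fold.  Held-out fold predictions are retained per candidate — they are
the raw material for candidate-level stacking.  Configuration selection
follows the one-standard-error rule: the simplest configuration whose
mean CV RMSE is within one SE of the minimum.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import RepeatedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .preprocess import PreprocessModel, fit_preprocess, transform
from .spectra_core import Dataset

__all__ = [
    "FAMILIES",
    "CVSpec",
    "PrepConfig",
    "CandidateModel",
    "MetricPair",
    "sample_space",
    "tune",
    "select_one_se",
    "finalize_and_evaluate",
    "rmse_r2",
]

FAMILIES = ("pcr", "pls", "enet", "rf", "xgb", "lgbm", "gpr")

#: printed search bounds per family; log10-scaled dims listed in _LOG_DIMS
_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "pcr": {"num_comp": (10, 150)},
    "pls": {"num_comp": (2, 120)},
    "enet": {"num_comp": (10, 150), "lambda": (1e-6, 1.0), "alpha": (0.0, 1.0)},
    "rf": {"num_comp": (20, 150), "trees": (500, 2000), "mtry": (5, 150),
           "min_n": (2, 20)},
    "xgb": {"num_comp": (15, 150), "trees": (500, 2500),
            "learning_rate": (10**-3.5, 10**-1.0), "depth": (3, 8),
            "min_n": (2, 20), "mtry": (5, 150),
            "subsample": (0.5, 1.0), "colsample": (0.5, 1.0)},
    "lgbm": {"num_comp": (10, 120), "trees": (600, 3000),
             "learning_rate": (10**-3.5, 10**-1.0), "depth": (3, 8),
             "min_n": (2, 20), "mtry": (5, 150),
             "subsample": (0.5, 1.0), "colsample": (0.5, 1.0)},
    "gpr": {"num_comp": (10, 120), "sigma": (1e-3, 10.0)},
}
_LOG_DIMS = {"lambda", "learning_rate", "sigma"}
_INT_DIMS = {"num_comp", "trees", "depth", "min_n", "mtry"}


@dataclass(frozen=True)
class CVSpec:
    folds: int = 10
    repeats: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class PrepConfig:
    sg_window: int = 0
    variance_target: float = 0.99
    refit_per_fold: bool = True


@dataclass
class MetricPair:
    rmse: float
    r2: float


@dataclass
class CandidateModel:
    """One (family, hyperparameters) configuration with its CV record."""

    family: str
    params: dict
    cv_rmse_mean: float = np.nan
    cv_rmse_se: float = np.nan
    fold_rmses: np.ndarray | None = None        # repeats x folds
    oof_by_repeat: np.ndarray | None = None     # repeats x n_train
    cv_provenance: tuple | None = None          # (folds, repeats, seed)
    candidate_id: str = ""
    failed: bool = False
    # fitted state after finalization
    prep_model: PreprocessModel | None = None
    estimator: object = None

    @property
    def uses_pca(self) -> bool:
        return self.family != "pls"

    @property
    def oof(self) -> np.ndarray:
        """OOF predictions averaged over repeats."""
        if self.oof_by_repeat is None:
            raise ValueError("candidate has no fold predictions")
        return self.oof_by_repeat.mean(axis=0)

    def config_hash(self) -> str:
        payload = json.dumps({"family": self.family, "params": self.params},
                             sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        if self.estimator is None or self.prep_model is None:
            raise ValueError("candidate not finalized")
        Z = transform(self.prep_model, X_raw,
                      K=self._effective_num_comp() if self.uses_pca else None,
                      pca=self.uses_pca)
        return np.asarray(self.estimator.predict(Z)).ravel()

    def _effective_num_comp(self) -> int:
        k_max = self.prep_model.k_max
        return int(min(self.params["num_comp"], k_max))


def _midpoint(lo: float, hi: float, log: bool) -> float:
    return float(np.sqrt(lo * hi)) if log else 0.5 * (lo + hi)


def sample_space(family: str, budget: int, seed: int,
                 bounds: dict[str, tuple[float, float]] | None = None) -> list[dict]:
    """Sample ``budget`` configurations inside the family's printed bounds.

    Latent-dimension-only families (PCR, PLSR) use an evenly spaced integer
    grid over ``num_comp``; multi-dimensional families use a seeded Latin
    hypercube with log scaling where the bounds span decades.  GPR returns
    its stage-1 grid: ``num_comp`` varies while sigma is pinned at the
    log-midpoint of its range (stage 2 is run inside :func:`tune`).
    """
    if family not in _BOUNDS:
        raise ValueError(f"unknown family {family!r}; known: {FAMILIES}")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    b = dict(_BOUNDS[family])
    if bounds:
        for k, v in bounds.items():
            if k not in b:
                raise ValueError(f"family {family!r} has no dimension {k!r}")
            b[k] = tuple(v)

    if family in ("pcr", "pls"):
        lo, hi = b["num_comp"]
        if budget == 1:
            vals = [int(round(_midpoint(lo, hi, False)))]
        else:
            vals = np.unique(np.round(np.linspace(lo, hi, budget)).astype(int)).tolist()
        return [{"num_comp": int(v)} for v in vals]

    if family == "gpr":
        lo, hi = b["num_comp"]
        sig_mid = _midpoint(*b["sigma"], log=True)
        if budget == 1:
            vals = [int(round(_midpoint(lo, hi, False)))]
        else:
            vals = np.unique(np.round(np.linspace(lo, hi, budget)).astype(int)).tolist()
        return [{"num_comp": int(v), "sigma": sig_mid} for v in vals]

    dims = list(b)
    if budget == 1:
        cfg = {k: _midpoint(*b[k], log=k in _LOG_DIMS) for k in dims}
    else:
        u = qmc.LatinHypercube(d=len(dims), seed=seed).random(budget)
        cfgs = []
        for row in u:
            cfg = {}
            for k, x in zip(dims, row):
                lo, hi = b[k]
                if k in _LOG_DIMS:
                    val = 10 ** (np.log10(lo) + x * (np.log10(hi) - np.log10(lo)))
                else:
                    val = lo + x * (hi - lo)
                cfg[k] = val
            cfgs.append(cfg)
        return [_round_ints(c) for c in cfgs]
    return [_round_ints(cfg)]


def _round_ints(cfg: dict) -> dict:
    return {k: (int(round(v)) if k in _INT_DIMS else float(v)) for k, v in cfg.items()}


def _make_estimator(family: str, params: dict, n_features: int, seed: int):
    """Estimator for a configuration; feature counts clip search values."""
    p = params
    if family == "pcr":
        return LinearRegression()
    if family == "pls":
        nc = int(min(p["num_comp"], n_features))
        return PLSRegression(n_components=nc, scale=False)
    if family == "enet":
        return make_pipeline(
            StandardScaler(),
            ElasticNet(alpha=p["lambda"], l1_ratio=p["alpha"], max_iter=50_000))
    if family == "rf":
        return RandomForestRegressor(
            n_estimators=int(p["trees"]),
            max_features=int(np.clip(p["mtry"], 1, n_features)),
            min_samples_leaf=int(p["min_n"]),
            random_state=seed, n_jobs=1)
    if family == "xgb":
        from xgboost import XGBRegressor
        return XGBRegressor(
            n_estimators=int(p["trees"]), learning_rate=p["learning_rate"],
            max_depth=int(p["depth"]), min_child_weight=int(p["min_n"]),
            subsample=p.get("subsample", 1.0),
            colsample_bytree=float(np.clip(p["mtry"] / max(n_features, 1), 0.05, 1.0)),
            random_state=seed, n_jobs=1, verbosity=0, tree_method="hist")
    if family == "lgbm":
        from lightgbm import LGBMRegressor
        return LGBMRegressor(
            n_estimators=int(p["trees"]), learning_rate=p["learning_rate"],
            max_depth=int(p["depth"]),
            num_leaves=int(min(2 ** int(p["depth"]) - 1, 63)),
            min_child_samples=int(p["min_n"]),
            subsample=p.get("subsample", 1.0), subsample_freq=1,
            colsample_bytree=float(np.clip(p["mtry"] / max(n_features, 1), 0.05, 1.0)),
            random_state=seed, n_jobs=1, verbose=-1)
    if family == "gpr":
        # kernlab convention: k(x, x') = exp(-sigma * ||x - x'||^2)
        ls = 1.0 / np.sqrt(2.0 * p["sigma"])
        kernel = ConstantKernel(1.0, "fixed") * RBF(ls, "fixed")
        return make_pipeline(
            StandardScaler(),
            GaussianProcessRegressor(kernel=kernel, alpha=1e-6, optimizer=None,
                                     normalize_y=True))
    raise ValueError(f"unknown family {family!r}")


def _cv_splits(n: int, cv: CVSpec):
    rkf = RepeatedKFold(n_splits=cv.folds, n_repeats=cv.repeats,
                        random_state=cv.seed)
    return list(rkf.split(np.arange(n)))


def _evaluate_configs(configs: list[dict], family: str, train: Dataset,
                      prep: PrepConfig, cv: CVSpec) -> list[CandidateModel]:
    n = train.n
    if n < cv.folds:
        raise ValueError("training n must be >= number of folds")
    splits = _cv_splits(n, cv)
    n_cfg = len(configs)
    fold_rmse = np.full((n_cfg, cv.repeats, cv.folds), np.nan)
    oof = np.full((n_cfg, cv.repeats, n), np.nan)
    ok = np.ones(n_cfg, dtype=bool)

    shared_prep = None
    if not prep.refit_per_fold:
        shared_prep = fit_preprocess(train.X, train.spectra.grid,
                                     sg_window=prep.sg_window,
                                     variance_target=prep.variance_target,
                                     pca=(family != "pls"))

    for s, (tr_idx, va_idx) in enumerate(splits):
        rep, fold = divmod(s, cv.folds)
        X_tr, y_tr = train.X[tr_idx], train.y[tr_idx]
        X_va, y_va = train.X[va_idx], train.y[va_idx]
        pm = shared_prep or fit_preprocess(
            X_tr, train.spectra.grid, sg_window=prep.sg_window,
            variance_target=prep.variance_target, pca=(family != "pls"))
        if family == "pls":
            Z_tr_full = transform(pm, X_tr, pca=False)
            Z_va_full = transform(pm, X_va, pca=False)
        else:
            Z_tr_full = transform(pm, X_tr, K=pm.k_max)
            Z_va_full = transform(pm, X_va, K=pm.k_max)
        for c, cfg in enumerate(configs):
            if not ok[c]:
                continue
            try:
                if family == "pls":
                    nf = min(int(cfg["num_comp"]), Z_tr_full.shape[1],
                             len(tr_idx) - 1)
                    Z_tr, Z_va = Z_tr_full, Z_va_full
                    est = _make_estimator(family, {**cfg, "num_comp": nf},
                                          Z_tr.shape[1], cv.seed)
                else:
                    k = int(np.clip(cfg["num_comp"], 1, pm.k_max))
                    Z_tr, Z_va = Z_tr_full[:, :k], Z_va_full[:, :k]
                    est = _make_estimator(family, cfg, k, cv.seed)
                with warnings.catch_warnings():
                    # over-large PLS component counts are legitimate search
                    # points; sklearn warns when the residual rank runs out
                    warnings.filterwarnings(
                        "ignore", message="y residual is constant")
                    est.fit(Z_tr, y_tr)
                pred = np.asarray(est.predict(Z_va)).ravel()
                oof[c, rep, va_idx] = pred
                fold_rmse[c, rep, fold] = np.sqrt(np.mean((y_va - pred) ** 2))
            except Exception as e:  # noqa: BLE001 — a failing config never aborts tuning
                ok[c] = False
                warnings.warn(f"{family} config {cfg} failed: {e}", stacklevel=2)

    out = []
    denom = np.sqrt(cv.folds * cv.repeats)
    for c, cfg in enumerate(configs):
        cand = CandidateModel(family=family, params=dict(cfg),
                              cv_provenance=(cv.folds, cv.repeats, cv.seed))
        if ok[c]:
            r = fold_rmse[c]
            cand.cv_rmse_mean = float(r.mean())
            cand.cv_rmse_se = float(r.std(ddof=1) / denom) if r.size > 1 else 0.0
            cand.fold_rmses = r
            cand.oof_by_repeat = oof[c]
        else:
            cand.failed = True
        out.append(cand)
    return out


def tune(family: str, train: Dataset, prep: PrepConfig = PrepConfig(),
         cv: CVSpec = CVSpec(), budget: int = 60,
         bounds: dict | None = None) -> list[CandidateModel]:
    """Tune one family; returns successful candidates sorted by CV RMSE.

    GPR uses a two-stage search: stage 1 varies ``num_comp`` with sigma at
    the log-midpoint of its range; stage 2 tunes sigma at the stage-1
    winner's ``num_comp``.
    """
    configs = sample_space(family, budget, cv.seed, bounds)
    cands = _evaluate_configs(configs, family, train, prep, cv)
    if family == "gpr":
        stage1 = [c for c in cands if not c.failed]
        if stage1:
            best_nc = min(stage1, key=lambda c: c.cv_rmse_mean).params["num_comp"]
            b = dict(_BOUNDS["gpr"])
            if bounds:
                b.update({k: tuple(v) for k, v in bounds.items()})
            lo, hi = b["sigma"]
            sig_mid = _midpoint(lo, hi, log=True)
            sigmas = np.logspace(np.log10(lo), np.log10(hi), max(budget, 2))
            stage2_cfgs = [{"num_comp": int(best_nc), "sigma": float(s)}
                           for s in sigmas if not np.isclose(s, sig_mid)]
            cands += _evaluate_configs(stage2_cfgs, family, train, prep, cv)
    good = [c for c in cands if not c.failed]
    if not good:
        warnings.warn(f"family {family}: no successful candidates", stacklevel=2)
    good.sort(key=lambda c: (c.cv_rmse_mean, c.config_hash()))
    for rank, c in enumerate(good, start=1):
        c.candidate_id = f"{family}_{rank}"
    return good


# documented simplicity order: fewer components, shallower trees, fewer
# trees, larger min_n, smaller mtry, larger lambda
def _simplicity_key(c: CandidateModel) -> tuple:
    p = c.params
    return (p.get("num_comp", 0), p.get("depth", 0), p.get("trees", 0),
            -p.get("min_n", 0), p.get("mtry", 0), -p.get("lambda", 0.0))


def select_one_se(candidates: list[CandidateModel]) -> CandidateModel:
    """One-standard-error rule over tuned candidates.

    Among configurations whose mean CV RMSE is within one SE (of the
    best configuration) of the minimum, return the simplest; ties break
    by lower mean RMSE, then by configuration hash.
    """
    good = [c for c in candidates if not c.failed]
    if not good:
        raise ValueError("no successful candidates to select from")
    best = min(good, key=lambda c: c.cv_rmse_mean)
    threshold = best.cv_rmse_mean + best.cv_rmse_se
    eligible = [c for c in good if c.cv_rmse_mean <= threshold]
    return min(eligible,
               key=lambda c: (_simplicity_key(c), c.cv_rmse_mean, c.config_hash()))


def candidate_to_dict(c: CandidateModel) -> dict:
    """JSON-serializable CV record (fitted state is not serialized)."""
    return {
        "family": c.family,
        "params": c.params,
        "cv_rmse_mean": None if np.isnan(c.cv_rmse_mean) else c.cv_rmse_mean,
        "cv_rmse_se": None if np.isnan(c.cv_rmse_se) else c.cv_rmse_se,
        "fold_rmses": None if c.fold_rmses is None else c.fold_rmses.tolist(),
        "oof_by_repeat": None if c.oof_by_repeat is None else c.oof_by_repeat.tolist(),
        "cv_provenance": list(c.cv_provenance) if c.cv_provenance else None,
        "candidate_id": c.candidate_id,
        "failed": c.failed,
    }


def candidate_from_dict(d: dict) -> CandidateModel:
    return CandidateModel(
        family=d["family"], params=dict(d["params"]),
        cv_rmse_mean=np.nan if d["cv_rmse_mean"] is None else d["cv_rmse_mean"],
        cv_rmse_se=np.nan if d["cv_rmse_se"] is None else d["cv_rmse_se"],
        fold_rmses=None if d["fold_rmses"] is None else np.asarray(d["fold_rmses"]),
        oof_by_repeat=None if d["oof_by_repeat"] is None
        else np.asarray(d["oof_by_repeat"]),
        cv_provenance=tuple(d["cv_provenance"]) if d["cv_provenance"] else None,
        candidate_id=d.get("candidate_id", ""), failed=d.get("failed", False))


def rmse_r2(y: np.ndarray, yhat: np.ndarray) -> MetricPair:
    """Test metrics: RMSE and R^2 = 1 - SS_res / SS_tot (test-mean based)."""
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return MetricPair(rmse=rmse, r2=r2)


def finalize_candidate(candidate: CandidateModel, train: Dataset,
                       prep: PrepConfig = PrepConfig()) -> CandidateModel:
    """Refit preprocessing + learner on the full training set."""
    pm = fit_preprocess(train.X, train.spectra.grid, sg_window=prep.sg_window,
                        variance_target=prep.variance_target,
                        pca=candidate.uses_pca)
    if candidate.uses_pca:
        k = int(np.clip(candidate.params["num_comp"], 1, pm.k_max))
        Z = transform(pm, train.X, K=k)
        est = _make_estimator(candidate.family, candidate.params, k,
                              candidate.cv_provenance[2] if candidate.cv_provenance else 0)
    else:
        Z = transform(pm, train.X, pca=False)
        nf = min(int(candidate.params["num_comp"]), Z.shape[1], train.n - 1)
        est = _make_estimator(candidate.family,
                              {**candidate.params, "num_comp": nf},
                              Z.shape[1],
                              candidate.cv_provenance[2] if candidate.cv_provenance else 0)
    est.fit(Z, train.y)
    candidate.prep_model = pm
    candidate.estimator = est
    return candidate


def finalize_and_evaluate(candidate: CandidateModel, train: Dataset,
                          test: Dataset,
                          prep: PrepConfig = PrepConfig()) -> MetricPair:
    """Refit on full training data; report RMSE/R^2 on the held-out test set."""
    if test.n < 2:
        raise ValueError("test set must have n >= 2")
    finalize_candidate(candidate, train, prep)
    return rmse_r2(test.y, candidate.predict(test.X))
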