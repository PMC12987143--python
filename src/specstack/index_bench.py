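"""Narrow-band spectral index library and index-based DM baselines.

Ships the printed registry of 23 water-, lignin/cellulose- and
dry-matter-sensitive indices (plus the NWI 900/970 numerator-swapped
variant) and two baselines: simple linear regression on each index alone,
and elastic net on the standardized index table.  R_lambda denotes
reflectance at wavelength lambda (nm), resolved exactly on the 1 nm grid.

Index kinds and their algebraic identities (tested):

* ``normalized_difference`` (Ra-Rb)/(Ra+Rb): 0 on any flat spectrum and
  invariant to scaling the whole spectrum.
* ``ratio`` Ra/Rb: 1 on flat spectra, scale-invariant.
* ``composite`` (Ra-Rb)/(Rc+Rd): 0 on flat spectra, scale-invariant.
* ``log_normalized_difference`` (NDLI): built from log(1/R) terms; the
  logarithm base cancels in the ratio.
* ``linear_combination`` (CAI): linear in reflectance, hence NOT
  scale-invariant; 0 on flat spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .spectra_core import Dataset, SpectraMatrix

__all__ = [
    "IndexDefinition",
    "IndexTable",
    "BaselineResult",
    "INDEX_REGISTRY",
    "register_index",
    "compute_index",
    "compute_index_table",
    "single_index_baseline",
    "enet_on_indices",
]


@dataclass(frozen=True)
class IndexDefinition:
    name: str
    required_wavelengths: tuple[float, ...]
    kind: str
    formula: Callable[..., np.ndarray]
    scale_invariant: bool = True

    def __call__(self, spectra: SpectraMatrix) -> np.ndarray:
        bands = [spectra.band(w) for w in self.required_wavelengths]
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.formula(*bands)


def _nd(a, b):
    return (a - b) / (a + b)


def _make_nd(name, wa, wb):
    return IndexDefinition(name, (wa, wb), "normalized_difference", _nd)


def _make_ratio(name, wa, wb):
    return IndexDefinition(name, (wa, wb), "ratio", lambda a, b: a / b)


def _make_composite(name, wa, wb, wc, wd):
    return IndexDefinition(name, (wa, wb, wc, wd), "composite",
                           lambda a, b, c, d: (a - b) / (c + d))


def _ndli(r1680, r1754):
    la, lb = np.log10(1.0 / r1680), np.log10(1.0 / r1754)
    return (la - lb) / (la + lb)


def _cai(r2000, r2100, r1900):
    return r2000 - 0.5 * (r2100 + r1900)


_DEFINITIONS = [
    _make_nd("NDII", 820, 1600),
    _make_ratio("WI", 900, 970),
    _make_ratio("SRWI", 860, 1240),
    _make_ratio("LWI", 1300, 1450),
    IndexDefinition("NDLI", (1680, 1754), "log_normalized_difference", _ndli),
    IndexDefinition("CAI", (2000, 2100, 1900), "linear_combination", _cai,
                    scale_invariant=False),
    _make_nd("NDWI-1640", 858, 1640),
    _make_nd("NDWI", 860, 1240),
    _make_nd("NDVI", 760, 670),
    _make_nd("NWI", 970, 900),
    _make_composite("SWSI-1", 803, 681, 905, 972),
    _make_composite("SWSI-2", 803, 681, 1326, 1507),
    _make_composite("SWSI-3", 803, 681, 972, 1174),
    _make_ratio("MSI", 1600, 820),
    _make_nd("NDII-2", 819, 1649),
    _make_nd("NDWI-Hyp", 1070, 1200),
    _make_ratio("DWSI-1", 800, 1660),
    _make_ratio("DWSI-2", 1660, 550),
    _make_ratio("DWSI-3", 1600, 680),
    _make_ratio("DWSI-4", 550, 680),
    _make_composite("DWSI-5", 800, 550, 1660, 680),
    _make_nd("NDMI", 1649, 1720),
    _make_nd("DMCI", 2305, 1495),
    # numerator-swapped NWI variant named separately in the elastic-net report
    _make_nd("NWI-970/900", 900, 970),
]

#: name -> definition; user-extensible via :func:`register_index`.
INDEX_REGISTRY: dict[str, IndexDefinition] = {d.name: d for d in _DEFINITIONS}


def register_index(definition: IndexDefinition, overwrite: bool = False) -> None:
    if definition.name in INDEX_REGISTRY and not overwrite:
        raise ValueError(f"index {definition.name!r} already registered")
    INDEX_REGISTRY[definition.name] = definition


def compute_index(spectra: SpectraMatrix, definition: IndexDefinition | str) -> np.ndarray:
    """Evaluate one index per sample; zero denominators yield NaN + warning."""
    d = INDEX_REGISTRY[definition] if isinstance(definition, str) else definition
    vals = np.asarray(d(spectra), dtype=float)
    if not np.all(np.isfinite(vals)):
        warnings.warn(
            f"index {d.name}: {int((~np.isfinite(vals)).sum())} non-finite "
            "value(s) (zero denominator) propagated as missing", stacklevel=2)
        vals = np.where(np.isfinite(vals), vals, np.nan)
    return vals


@dataclass
class IndexTable:
    sample_ids: list[str]
    names: list[str]
    values: np.ndarray              # n x n_indices, may contain NaN
    train_mean: np.ndarray | None = None
    train_sd: np.ndarray | None = None

    def standardized(self) -> np.ndarray:
        if self.train_mean is None:
            raise ValueError("no training statistics attached")
        return (self.values - self.train_mean) / self.train_sd


def compute_index_table(spectra: SpectraMatrix,
                        names: list[str] | None = None) -> IndexTable:
    names = list(INDEX_REGISTRY) if names is None else list(names)
    vals = np.column_stack([compute_index(spectra, n) for n in names])
    return IndexTable(spectra.sample_ids, names, vals)


@dataclass
class BaselineResult:
    rmse: float
    r2: float


def _rmse_r2(y, yhat):
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return rmse, r2


def single_index_baseline(train: Dataset, test: Dataset,
                          definition: IndexDefinition | str) -> BaselineResult:
    """OLS of DM on one index, fit on train, scored on test.

    Samples with a non-finite index value are excluded from the
    respective set rather than aborting the run.
    """
    x_tr = compute_index(train.spectra, definition)
    x_te = compute_index(test.spectra, definition)
    m_tr, m_te = np.isfinite(x_tr), np.isfinite(x_te)
    x, y = x_tr[m_tr], train.y[m_tr]
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("degenerate fit: index has no variance on training data")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = intercept + slope * x_te[m_te]
    rmse, r2 = _rmse_r2(test.y[m_te], yhat)
    return BaselineResult(rmse=rmse, r2=r2)


@dataclass
class EnetIndexModel:
    names: list[str]
    coefs: np.ndarray               # standardized-scale coefficients
    intercept: float
    lam: float
    alpha_mix: float
    test_rmse: float
    test_r2: float

    @property
    def retained(self) -> list[str]:
        return [n for n, c in zip(self.names, self.coefs) if c != 0.0]

    def equation(self, digits: int = 2) -> str:
        """Human-readable fitted equation on standardized indices."""
        terms = [f"{self.intercept:.{digits}f}"]
        for n, c in zip(self.names, self.coefs):
            if c != 0.0:
                terms.append(f"{c:+.{digits}f}*{n}")
        return "DM^ = " + " ".join(terms)


def enet_on_indices(train: Dataset, test: Dataset,
                    names: list[str] | None = None,
                    l1_ratios=(0.05, 0.25, 0.5, 0.75, 0.95, 1.0),
                    n_lambdas: int = 30, cv_folds: int = 10,
                    seed: int = 0) -> EnetIndexModel:
    """Elastic net of DM on the standardized index table.

    (lambda, alpha) are tuned by seeded K-fold CV on the training set;
    coefficients are reported on the standardized-index scale so their
    magnitudes are directly comparable.
    """
    tab_tr = compute_index_table(train.spectra, names)
    tab_te = compute_index_table(test.spectra, names)
    if len(tab_tr.names) < 2:
        raise ValueError("need at least 2 indices for the elastic net baseline")
    X_tr, X_te = tab_tr.values, tab_te.values
    # training-only standardization; NaN cells imputed at the training mean
    mean = np.nanmean(X_tr, axis=0)
    sd = np.nanstd(X_tr, axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    Z_tr = (np.where(np.isfinite(X_tr), X_tr, mean) - mean) / sd
    Z_te = (np.where(np.isfinite(X_te), X_te, mean) - mean) / sd
    y = train.y

    lambdas = np.logspace(-6, 0, n_lambdas)
    folds = KFold(n_splits=min(cv_folds, len(y)), shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Objective did not converge")
        search = ElasticNetCV(l1_ratio=list(l1_ratios), alphas=lambdas,
                              cv=folds, max_iter=20_000)
        search.fit(Z_tr, y)
    lam, a = float(search.alpha_), float(search.l1_ratio_)
    model = ElasticNet(alpha=lam, l1_ratio=a, max_iter=200_000)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Objective did not converge")
        model.fit(Z_tr, y)
    if np.all(model.coef_ == 0.0):
        warnings.warn("elastic net shrank all coefficients to zero; "
                      "returning intercept-only model", stacklevel=2)
    rmse, r2 = _rmse_r2(test.y, model.predict(Z_te))
    return EnetIndexModel(names=tab_tr.names, coefs=model.coef_.copy(),
                          intercept=float(model.intercept_), lam=float(lam),
                          alpha_mix=float(a), test_rmse=rmse, test_r2=r2)
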