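"""Spectral preprocessing: artifact screening, smoothing, standardization, PCA.

The modeling recipe is: (optional) Savitzky-Golay smoothing, per-band
mean-centering and unit-variance scaling, then PCA with the component
budget K_max set by a cumulative explained-variance target (default 99%).
All statistics are estimated on training data only and re-applied to new
spectra; zero-variance bands are dropped from the model (with their
wavelength identity preserved for reporting) rather than producing NaNs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra_core import SpectraMatrix, WavelengthGrid

__all__ = [
    "ArtifactReport",
    "PreprocessModel",
    "screen_artifacts",
    "savgol_smooth",
    "fit_standardizer",
    "apply_standardizer",
    "fit_pca",
    "project",
    "fit_preprocess",
    "transform",
]

ALLOWED_SG_WINDOWS = (7, 9, 11, 13)


@dataclass
class ArtifactReport:
    """Per-sample artifact flags with offending wavelengths (nm)."""

    out_of_range: dict[str, list[int]]
    spike: dict[str, list[int]]
    non_finite: dict[str, list[int]]

    @property
    def flagged_ids(self) -> list[str]:
        ids = set(self.out_of_range) | set(self.spike) | set(self.non_finite)
        return sorted(ids)


@dataclass
class PreprocessModel:
    """Training-set statistics for standardization and PCA projection."""

    grid: WavelengthGrid
    band_mean: np.ndarray
    band_sd: np.ndarray
    kept: np.ndarray                      # boolean mask of non-constant bands
    sg_window: int = 0                    # 0 = smoothing disabled
    sg_polyorder: int = 2
    loadings: np.ndarray | None = None    # B_kept x K_max, orthonormal columns
    eigenvalues: np.ndarray | None = None
    k_max: int = 0
    variance_target: float = 0.99

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())


def screen_artifacts(spectra: SpectraMatrix, max_reflectance: float = 1.0,
                     max_abs_step: float = 0.2) -> ArtifactReport:
    """Flag physically implausible spectra.

    A sample is flagged when any reflectance is negative or exceeds
    ``max_reflectance``, any first difference between adjacent bands
    exceeds ``max_abs_step`` in magnitude, or any value is non-finite.
    """
    if max_reflectance <= 0 or max_abs_step <= 0:
        raise ValueError("thresholds must be > 0")
    wl = spectra.grid.wavelengths
    R = spectra.reflectance
    oor, spk, nf = {}, {}, {}
    with np.errstate(invalid="ignore"):
        bad_range = (R < 0) | (R > max_reflectance)
        steps = np.abs(np.diff(R, axis=1)) > max_abs_step
        nonfin = ~np.isfinite(R)
    for i, sid in enumerate(spectra.sample_ids):
        if bad_range[i].any():
            oor[sid] = wl[bad_range[i]].tolist()
        if steps[i].any():
            spk[sid] = wl[1:][steps[i]].tolist()
        if nonfin[i].any():
            nf[sid] = wl[nonfin[i]].tolist()
    return ArtifactReport(oor, spk, nf)


def savgol_smooth(X: np.ndarray, window: int, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing along the wavelength axis.

    Each band is replaced by the centre value of a local least-squares
    quadratic; edges are handled by mirror-padding so the grid length is
    preserved.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    X = np.asarray(X, dtype=float)
    return savgol_filter(X, window_length=window, polyorder=polyorder,
                         axis=-1, mode="mirror")


def fit_standardizer(train: np.ndarray, grid: WavelengthGrid,
                     sg_window: int = 0,
                     min_band_sd: float = 1e-12) -> PreprocessModel:
    """Per-band mean/sd (n-1 denominator) from training spectra only.

    Bands with sd below ``min_band_sd`` are treated as constant: their
    apparent variation is at the level of double-precision cancellation
    noise, which unit-variance scaling would amplify into spurious
    full-scale predictors.
    """
    X = np.asarray(train, dtype=float)
    if sg_window:
        X = savgol_smooth(X, sg_window)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    kept = sd > min_band_sd
    if not kept.all():
        warnings.warn(
            f"{int((~kept).sum())} zero-variance band(s) dropped from "
            "standardization/PCA", stacklevel=2)
    return PreprocessModel(grid=grid, band_mean=mean, band_sd=sd, kept=kept,
                           sg_window=sg_window)


def apply_standardizer(model: PreprocessModel, X: np.ndarray) -> np.ndarray:
    """Standardize spectra with training statistics; constant bands dropped."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.band_mean.size:
        raise ValueError("grid mismatch between model and spectra")
    if model.sg_window:
        X = savgol_smooth(X, model.sg_window)
    k = model.kept
    return (X[:, k] - model.band_mean[k]) / model.band_sd[k]


def fit_pca(model: PreprocessModel, train: np.ndarray,
            variance_target: float = 0.99) -> PreprocessModel:
    """PCA of the standardized training spectra.

    K_max is the smallest component count whose cumulative explained
    variance reaches ``variance_target``.  Loading signs are fixed so each
    component's largest-magnitude element is positive.
    """
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must be in (0, 1]")
    Z = apply_standardizer(model, train)
    if Z.shape[1] == 0:
        raise ValueError("no non-constant bands available for PCA")
    n = Z.shape[0]
    # standardized training data is already column-centered
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / max(n - 1, 1)
    pos = eig > max(n, Z.shape[1]) * np.finfo(float).eps * (eig[0] if eig.size else 1.0)
    eig, Vt = eig[pos], Vt[pos]
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    Vt = Vt * flip[:, None]
    cum = np.cumsum(eig) / eig.sum()
    k_max = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    model.loadings = Vt.T
    model.eigenvalues = eig
    model.k_max = k_max
    model.variance_target = variance_target
    return model


def project(model: PreprocessModel, X: np.ndarray, K: int | None = None) -> np.ndarray:
    """Scores of ``X`` on the first K principal components."""
    if model.loadings is None:
        raise ValueError("PCA not fitted")
    K = model.k_max if K is None else K
    if not 1 <= K <= model.k_max:
        raise ValueError(f"K must be in [1, {model.k_max}]")
    return apply_standardizer(model, X) @ model.loadings[:, :K]


def fit_preprocess(train: np.ndarray, grid: WavelengthGrid, sg_window: int = 0,
                   variance_target: float = 0.99, pca: bool = True) -> PreprocessModel:
    """Convenience: fit standardizer (and PCA) on training spectra."""
    model = fit_standardizer(train, grid, sg_window=sg_window)
    if pca:
        fit_pca(model, train, variance_target=variance_target)
    return model


def transform(model: PreprocessModel, X: np.ndarray, K: int | None = None,
              pca: bool = True) -> np.ndarray:
    return project(model, X, K) if pca else apply_standardizer(model, X)
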