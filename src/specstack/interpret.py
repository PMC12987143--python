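"""Model diagnostics: spectral band permutation importance and residuals.

Band importance asks where in the spectrum a fitted stack looks: for
each contiguous wavelength block (default 10 nm) the raw reflectance
rows of all bands in the block are jointly shuffled across test samples
(one shared row permutation per repeat, preserving within-block
correlation), the full preprocessing + prediction path is re-run, and
the increase in test RMSE over the unpermuted baseline is recorded.
Permutation happens on RAW reflectance, before standardization and PCA,
so importance propagates through the whole pipeline.

Residual diagnostics plot observed-minus-predicted DM against predicted
DM with a tri-cube-weighted local linear (LOESS) trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .spectra_core import Dataset
from .stack_engine import StackModel, predict_stack

__all__ = [
    "ImportanceProfile",
    "ResidualDiagnostics",
    "band_permutation_importance",
    "residual_diagnostics",
]


@dataclass
class ImportanceProfile:
    band_start_nm: np.ndarray
    band_end_nm: np.ndarray          # inclusive
    delta_rmse_mean: np.ndarray
    delta_rmse_sd: np.ndarray
    baseline_rmse: float
    repeats: int
    seed: int
    short_final_band: bool = False

    @property
    def band_center_nm(self) -> np.ndarray:
        return 0.5 * (self.band_start_nm + self.band_end_nm)

    def top_band(self) -> tuple[float, float]:
        """(center nm, mean delta-RMSE) of the most important band."""
        i = int(np.argmax(self.delta_rmse_mean))
        return float(self.band_center_nm[i]), float(self.delta_rmse_mean[i])


def _tile_bands(wavelengths: np.ndarray, band_nm: int):
    """Contiguous non-overlapping index blocks of ~band_nm width."""
    start_wl = wavelengths[0]
    bands, cur, cur_block = [], [], 0
    for j, w in enumerate(wavelengths):
        block = int((w - start_wl) // band_nm)
        if block != cur_block and cur:
            bands.append(np.asarray(cur))
            cur, cur_block = [], block
        cur.append(j)
    if cur:
        bands.append(np.asarray(cur))
    return bands


def band_permutation_importance(model: StackModel, test: Dataset,
                                band_nm: int = 10, repeats: int = 10,
                                seed: int = 0) -> ImportanceProfile:
    """Permutation importance of contiguous wavelength bands on the test set."""
    if test.n < 5:
        raise ValueError("need test n >= 5 for permutation importance")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    wl = test.spectra.grid.wavelengths
    span = int(wl[-1] - wl[0] + 1)
    if band_nm > span:
        raise ValueError(f"band width {band_nm} nm exceeds grid span {span} nm")
    blocks = _tile_bands(wl, band_nm)
    baseline_pred = predict_stack(model, test.X)
    baseline_rmse = float(np.sqrt(np.mean((test.y - baseline_pred) ** 2)))

    rng = np.random.default_rng(seed)
    deltas = np.zeros((len(blocks), repeats))
    X = test.X
    for r in range(repeats):
        perm = rng.permutation(test.n)  # one shared row shuffle per repeat
        for bi, cols in enumerate(blocks):
            if np.all(np.ptp(X[:, cols], axis=0) == 0):
                continue  # permutation is the identity on constant bands
            Xp = X.copy()
            Xp[:, cols] = X[np.ix_(perm, cols)]
            pred = predict_stack(model, Xp)
            rmse = np.sqrt(np.mean((test.y - pred) ** 2))
            deltas[bi, r] = rmse - baseline_rmse

    starts = np.array([wl[b[0]] for b in blocks], dtype=float)
    ends = np.array([wl[b[-1]] for b in blocks], dtype=float)
    short_final = (ends[-1] - starts[-1] + 1) < band_nm
    return ImportanceProfile(
        band_start_nm=starts, band_end_nm=ends,
        delta_rmse_mean=deltas.mean(axis=1),
        delta_rmse_sd=deltas.std(axis=1, ddof=1) if repeats > 1
        else np.zeros(len(blocks)),
        baseline_rmse=baseline_rmse, repeats=repeats, seed=seed,
        short_final_band=bool(short_final))


@dataclass
class ResidualDiagnostics:
    predicted: np.ndarray
    residuals: np.ndarray            # observed - predicted, DM %
    smoother_x: np.ndarray
    smoother_y: np.ndarray
    span: float


def residual_diagnostics(model: StackModel, test: Dataset,
                         span: float = 0.75,
                         n_grid: int = 100) -> ResidualDiagnostics:
    """Residual-vs-predicted analysis with a LOESS trend.

    The smoother is a tri-cube-weighted local linear fit evaluated on a
    uniform grid over the predicted range.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    if test.n < 10:
        raise ValueError("need test n >= 10 for residual smoothing")
    pred = predict_stack(model, test.X)
    resid = test.y - pred
    grid = np.linspace(pred.min(), pred.max(), n_grid)
    smooth = lowess(resid, pred, frac=span, it=0, xvals=grid)
    return ResidualDiagnostics(predicted=pred, residuals=resid,
                               smoother_x=grid, smoother_y=np.asarray(smooth),
                               span=span)
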