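"""Core data model for leaf reflectance spectra and dry matter traits.

A sample is one detached leaf: a reflectance spectrum on the fixed
350-2500 nm grid (1 nm resolution, 2151 bands) plus its gravimetric dry
matter content in percent of fresh mass.  This module owns the on-disk
wide-CSV format, the train/test split, and the descriptive/comparability
statistics used to check that the two partitions are distributionally
exchangeable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WavelengthGrid",
    "SpectraMatrix",
    "TraitVector",
    "Dataset",
    "CohortStats",
    "default_grid",
    "compute_dm",
    "load_dataset",
    "write_dataset",
    "split_dataset",
    "cohort_stats",
]

GRID_START = 350
GRID_STOP = 2500  # inclusive


def default_grid() -> "WavelengthGrid":
    """The instrument grid: every integer wavelength from 350 to 2500 nm."""
    return WavelengthGrid(np.arange(GRID_START, GRID_STOP + 1))


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing integer wavelengths in nanometres."""

    wavelengths: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=int)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing (no duplicates)")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return self.wavelengths.size

    def index_of(self, nm: float, tolerance_nm: float = 1.0) -> int:
        """Index of the band closest to ``nm``; exact on the 1 nm grid."""
        i = int(np.argmin(np.abs(self.wavelengths - nm)))
        if abs(self.wavelengths[i] - nm) > tolerance_nm:
            raise KeyError(f"wavelength {nm} nm not on grid (nearest: {self.wavelengths[i]} nm)")
        return i


@dataclass
class SpectraMatrix:
    """n x B reflectance (unitless fraction) on a wavelength grid."""

    sample_ids: list[str]
    grid: WavelengthGrid
    reflectance: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        R = np.asarray(self.reflectance, dtype=float)
        if R.ndim != 2:
            raise ValueError("reflectance must be 2-D (samples x bands)")
        if R.shape != (len(self.sample_ids), len(self.grid)):
            raise ValueError(
                f"reflectance shape {R.shape} inconsistent with "
                f"{len(self.sample_ids)} ids and {len(self.grid)} bands"
            )
        if not np.all(np.isfinite(R)):
            bad = sorted({self.sample_ids[i] for i in np.nonzero(~np.isfinite(R))[0]})
            raise ValueError(f"non-finite reflectance in samples: {bad}")
        self.reflectance = R

    @property
    def n(self) -> int:
        return self.reflectance.shape[0]

    def band(self, nm: float) -> np.ndarray:
        """Reflectance column at wavelength ``nm`` (R_lambda)."""
        return self.reflectance[:, self.grid.index_of(nm)]

    def take(self, idx: np.ndarray) -> "SpectraMatrix":
        return SpectraMatrix(
            [self.sample_ids[i] for i in idx], self.grid, self.reflectance[idx]
        )


@dataclass
class TraitVector:
    """Per-sample dry matter content in percent of fresh mass."""

    dm_percent: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.dm_percent, dtype=float)
        if y.ndim != 1:
            raise ValueError("dm_percent must be 1-D")
        if not np.all(np.isfinite(y)):
            raise ValueError("dm_percent contains non-finite values")
        if np.any(y < 0) or np.any(y > 100):
            raise ValueError("dm_percent must lie in [0, 100]")
        self.dm_percent = y

    def __len__(self) -> int:
        return self.dm_percent.size

    def take(self, idx: np.ndarray) -> "TraitVector":
        return TraitVector(self.dm_percent[idx])


@dataclass
class Dataset:
    """Row-aligned spectra and traits with unique sample ids."""

    spectra: SpectraMatrix
    traits: TraitVector

    def __post_init__(self):
        if self.spectra.n != len(self.traits):
            raise ValueError("spectra and traits are not row-aligned")
        if len(set(self.spectra.sample_ids)) != self.spectra.n:
            raise ValueError("sample_ids must be unique")

    @property
    def n(self) -> int:
        return self.spectra.n

    @property
    def X(self) -> np.ndarray:
        return self.spectra.reflectance

    @property
    def y(self) -> np.ndarray:
        return self.traits.dm_percent

    def take(self, idx) -> "Dataset":
        idx = np.asarray(idx, dtype=int)
        return Dataset(self.spectra.take(idx), self.traits.take(idx))


@dataclass
class CohortStats:
    """Descriptive and comparability statistics for one DM cohort.

    The comparability triple (normality / variance homogeneity / location)
    mirrors the Shapiro-Wilk, Fligner-Killeen and Wilcoxon rank-sum tests;
    the latter two compare this cohort against the companion cohort and are
    therefore identical in both returned objects.
    """

    n: int
    mean: float
    median: float
    sd: float
    min: float
    max: float
    skewness: float
    kurtosis: float
    normality_stat: float = np.nan
    normality_p: float = np.nan
    variance_hom_stat: float = np.nan
    variance_hom_p: float = np.nan
    location_stat: float = np.nan
    location_p: float = np.nan
    estimator_note: str = field(
        default="skewness: bias-corrected (adjusted Fisher-Pearson); "
        "kurtosis: bias-corrected excess; sd: n-1 denominator"
    )

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "n mean median sd min max skewness kurtosis normality_stat "
                "normality_p variance_hom_stat variance_hom_p location_stat "
                "location_p"
            ).split()
        }


# ---------------------------------------------------------------------------
# operations


def compute_dm(mfresh, mdry):
    """Dry matter content (%) from fresh and oven-dry leaf mass.

    DM(%) = 100 * mdry / mfresh.  Accepts scalars or arrays.
    """
    mf = np.asarray(mfresh, dtype=float)
    md = np.asarray(mdry, dtype=float)
    if np.any(mf <= 0):
        raise ValueError("mfresh must be > 0")
    if np.any(md < 0) or np.any(md > mf):
        raise ValueError("mdry must satisfy 0 <= mdry <= mfresh")
    out = 100.0 * md / mf
    return float(out) if out.ndim == 0 else out


def _wavelength_columns(columns) -> dict[str, int]:
    out = {}
    for c in columns:
        if isinstance(c, str) and len(c) > 1 and c[0] == "R" and c[1:].isdigit():
            out[c] = int(c[1:])
    return out


def load_dataset(path) -> Dataset:
    """Read a wide CSV: sample_id, dm (or mfresh+mdry), R350..R2500.

    Wavelength columns are reordered to ascending wavelength and validated
    against the default 1 nm grid.  When both a ``dm`` column and mass
    columns are present, ``dm`` takes precedence.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("missing required column 'sample_id'")
    wl_cols = _wavelength_columns(df.columns)
    grid = default_grid()
    expected = {f"R{w}" for w in grid.wavelengths}
    present = set(wl_cols)
    if present != expected:
        missing = sorted(expected - present)[:5]
        extra = sorted(present - expected)[:5]
        raise ValueError(
            f"wavelength columns do not match the 350-2500 nm 1 nm grid "
            f"(missing e.g. {missing}, unexpected e.g. {extra})"
        )
    ordered = [f"R{w}" for w in grid.wavelengths]
    R = df[ordered].to_numpy(dtype=float)
    nan_rows = df.loc[np.any(~np.isfinite(R), axis=1), "sample_id"].tolist()
    if nan_rows:
        raise ValueError(f"non-finite reflectance values in rows: {nan_rows}")

    if "dm" in df.columns:
        y = df["dm"].to_numpy(dtype=float)
    elif "mfresh" in df.columns and "mdry" in df.columns:
        y = compute_dm(df["mfresh"].to_numpy(float), df["mdry"].to_numpy(float))
    else:
        raise ValueError("need a 'dm' column or paired 'mfresh'/'mdry' columns")
    if np.any(~np.isfinite(y)):
        bad = df.loc[~np.isfinite(y), "sample_id"].tolist()
        raise ValueError(f"non-finite dry matter values in rows: {bad}")

    spectra = SpectraMatrix(df["sample_id"].tolist(), grid, R)
    return Dataset(spectra, TraitVector(y))


def write_dataset(ds: Dataset, path) -> None:
    """Write the wide-CSV format read by :func:`load_dataset`."""
    cols = {"sample_id": ds.spectra.sample_ids, "dm": ds.y}
    for j, w in enumerate(ds.spectra.grid.wavelengths):
        cols[f"R{w}"] = ds.X[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


def split_dataset(ds: Dataset, train_frac: float, seed: int) -> tuple[Dataset, Dataset]:
    """Seeded uniform-permutation split into train/test partitions.

    Train size is floor(train_frac * n); the partition is disjoint and
    exhaustive, and identical for identical seeds.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    if ds.n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(np.floor(train_frac * ds.n))
    n_train = min(max(n_train, 1), ds.n - 1)
    perm = np.random.default_rng(seed).permutation(ds.n)
    return ds.take(np.sort(perm[:n_train])), ds.take(np.sort(perm[n_train:]))


def _descriptives(y: np.ndarray) -> CohortStats:
    n = y.size
    const = np.ptp(y) == 0
    if const:
        warnings.warn("constant trait vector: skewness/kurtosis undefined", stacklevel=3)
    return CohortStats(
        n=n,
        mean=float(np.mean(y)),
        median=float(np.median(y)),
        sd=float(np.std(y, ddof=1)) if n > 1 else 0.0,
        min=float(np.min(y)),
        max=float(np.max(y)),
        skewness=np.nan if const else float(stats.skew(y, bias=False)),
        kurtosis=np.nan if const else float(stats.kurtosis(y, bias=False)),
    )


def cohort_stats(train_y: TraitVector, test_y: TraitVector) -> tuple[CohortStats, CohortStats]:
    """Descriptive statistics per cohort plus train-vs-test comparability tests.

    Runs Shapiro-Wilk normality per cohort, Fligner-Killeen variance
    homogeneity and the Wilcoxon rank-sum (Mann-Whitney) location test across
    cohorts.  Tests require n >= 8 per cohort and non-constant data;
    otherwise they are skipped with a warning and left as NaN.
    """
    a, b = train_y.dm_percent, test_y.dm_percent
    if min(a.size, b.size) < 3:
        raise ValueError("need n >= 3 per cohort for descriptive statistics")
    sa, sb = _descriptives(a), _descriptives(b)

    if min(a.size, b.size) < 8 or np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("comparability tests skipped (n < 8 or constant cohort)", stacklevel=2)
        return sa, sb

    wa = stats.shapiro(a)
    wb = stats.shapiro(b)
    fl = stats.fligner(a, b)
    mw = stats.mannwhitneyu(a, b, alternative="two-sided")
    for s, sh in ((sa, wa), (sb, wb)):
        s.normality_stat, s.normality_p = float(sh.statistic), float(sh.pvalue)
        s.variance_hom_stat, s.variance_hom_p = float(fl.statistic), float(fl.pvalue)
        s.location_stat, s.location_p = float(mw.statistic), float(mw.pvalue)
    return sa, sb
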