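"""Spectral pretreatments as scikit-learn transformers.

All pretreatments operate row-wise on a (samples x bands) matrix and are
row-local -- no statistic leaks between samples -- with one exception:
multiplicative scatter correction (MSC) needs a reference spectrum, which is
learned in ``fit`` (column mean of the calibration rows) and frozen for any
later ``transform``.

Available chains, by the names used in the comparison tables:

========== ==================================================
name        transform
========== ==================================================
none        identity
normalization  row scaling to unit Euclidean norm (or area/max)
snv         standard normal variate (row centre + scale, n-1 SD)
msc         multiplicative scatter correction vs. fitted reference
snv+detrend SNV followed by order-2 polynomial detrending
d1          1st Savitzky-Golay derivative, window 15, polyorder 2
d2          2nd Savitzky-Golay derivative, window 15, polyorder 2
========== ==================================================
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline

__all__ = [
    "SpectraTable",
    "SNV",
    "MSC",
    "SavitzkyGolayDerivative",
    "Detrend",
    "Normalize",
    "PRETREATMENTS",
    "make_pretreatment",
    "snv",
    "msc",
    "savgol_derivative",
    "detrend",
    "normalize",
]


@dataclass
class SpectraTable:
    """Sample-mean spectra with reference levels and a calibration split.

    Parameters
    ----------
    X : ndarray, (samples, bands)
    wavelengths : ndarray, (bands,) in nm
    y : ndarray, (samples,) reference adulteration level, % w/w in [0, 100]
    split : ndarray of {"calibration", "prediction"}
    sample_ids : optional sample identifiers
    pretreatment_tag : name of the pretreatment chain already applied
    """

    X: np.ndarray
    wavelengths: np.ndarray
    y: np.ndarray
    split: np.ndarray
    sample_ids: np.ndarray | None = None
    pretreatment_tag: str = "none"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.split = np.asarray(self.split, dtype=object)
        n, b = self.X.shape
        if len(self.y) != n or len(self.split) != n:
            raise ValueError("X, y and split must have aligned rows")
        if len(self.wavelengths) != b:
            raise ValueError("wavelength axis does not match band count")
        if np.any((self.y < 0) | (self.y > 100)):
            raise ValueError("reference levels must lie in [0, 100] % w/w")
        bad = set(self.split) - {"calibration", "prediction"}
        if bad:
            raise ValueError(f"unknown split labels: {sorted(bad)}")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"S{i:03d}" for i in range(n)], dtype=object)

    @property
    def is_cal(self) -> np.ndarray:
        return self.split == "calibration"

    @property
    def X_cal(self) -> np.ndarray:
        return self.X[self.is_cal]

    @property
    def y_cal(self) -> np.ndarray:
        return self.y[self.is_cal]

    @property
    def X_pred(self) -> np.ndarray:
        return self.X[~self.is_cal]

    @property
    def y_pred(self) -> np.ndarray:
        return self.y[~self.is_cal]

    def restrict(self, band_indices) -> "SpectraTable":
        """Column-subset view onto selected bands."""
        idx = np.asarray(band_indices, dtype=int)
        return replace(self, X=self.X[:, idx], wavelengths=self.wavelengths[idx])

    def pretreated(self, chain, tag: str) -> "SpectraTable":
        """Apply a pretreatment chain: fit on calibration rows, transform all.

        Any learned statistic (e.g. the MSC reference) therefore comes from
        the calibration rows only and is frozen for the prediction rows.
        """
        chain.fit(self.X_cal)
        return replace(self, X=chain.transform(self.X), pretreatment_tag=tag)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"{w:.4f}" for w in self.wavelengths])
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "level_percent", self.y)
        df.insert(2, "split", self.split)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, pretreatment_tag: str = "none") -> "SpectraTable":
        meta = {"sample_id", "level_percent", "split"}
        wl_cols = [c for c in df.columns if c not in meta]
        return cls(
            X=df[wl_cols].to_numpy(float),
            wavelengths=np.array([float(c) for c in wl_cols]),
            y=df["level_percent"].to_numpy(float),
            split=df["split"].to_numpy(object),
            sample_ids=df["sample_id"].to_numpy(object),
            pretreatment_tag=pretreatment_tag,
        )

    @classmethod
    def read_csv(cls, path) -> "SpectraTable":
        return cls.from_frame(pd.read_csv(path))


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError(f"expected a (samples, bands) matrix, got shape {X.shape}")
    return X


class SNV(TransformerMixin, BaseEstimator):
    """Standard normal variate: centre each spectrum by its own mean and
    scale by its own standard deviation (n-1 denominator).

    Removes per-spectrum multiplicative scatter and additive offsets.
    Stateless; ``fit`` only validates.
    """

    def fit(self, X, y=None):
        self.n_features_in_ = _as_2d(X).shape[1]
        return self

    def transform(self, X):
        X = _as_2d(X)
        if X.shape[1] < 2:
            raise ValueError("SNV needs at least 2 bands per spectrum")
        sd = X.std(axis=1, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(f"SNV undefined for zero-variance spectrum (sample {zero[0]})")
        return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


class MSC(TransformerMixin, BaseEstimator):
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference r, ``x ~ a + b*r``, and
    corrected to ``(x - a)/b``.  The reference defaults to the column mean
    of the rows seen in ``fit`` and stays frozen afterwards, so prediction
    samples are corrected against the calibration reference.
    """

    def __init__(self, reference: np.ndarray | None = None):
        self.reference = reference

    def fit(self, X, y=None):
        X = _as_2d(X)
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
            if ref.shape != (X.shape[1],):
                raise ValueError("reference length does not match band count")
            self.reference_ = ref
        else:
            self.reference_ = X.mean(axis=0)
        return self

    def transform(self, X):
        if not hasattr(self, "reference_"):
            raise RuntimeError("MSC must be fitted before transform")
        X = _as_2d(X)
        ref = self.reference_
        ref_c = ref - ref.mean()
        denom = ref_c @ ref_c
        if denom == 0:
            raise ValueError("MSC reference spectrum is constant")
        b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
        zero = np.flatnonzero(b == 0)
        if zero.size:
            raise ValueError(f"MSC slope is zero for sample {zero[0]}")
        a = X.mean(axis=1) - b * ref.mean()
        return (X - a[:, None]) / b[:, None]


class SavitzkyGolayDerivative(TransformerMixin, BaseEstimator):
    """Savitzky-Golay derivative spectra (order 1 or 2).

    Defaults follow the usual chemometric setting: a 15-point moving window
    and a second-order fitting polynomial.  Derivatives are taken with
    respect to band index.  Only the window interior is differentiated;
    the ``window//2`` edge bands on each side are filled with the nearest
    interior value, a negligible effect when bands >> window.
    """

    def __init__(self, order: int = 1, window: int = 15, polyorder: int = 2):
        self.order = order
        self.window = window
        self.polyorder = polyorder

    def _check(self, n_bands: int) -> None:
        if self.order not in (1, 2):
            raise ValueError("derivative order must be 1 or 2")
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError("window must be odd and greater than polyorder")
        if self.order > self.polyorder:
            raise ValueError("derivative order cannot exceed polyorder")
        if n_bands < self.window:
            raise ValueError(f"need at least {self.window} bands, got {n_bands}")

    def fit(self, X, y=None):
        X = _as_2d(X)
        self._check(X.shape[1])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_2d(X)
        self._check(X.shape[1])
        d = savgol_filter(
            X, self.window, self.polyorder, deriv=self.order, axis=1, mode="interp"
        )
        half = self.window // 2
        d[:, :half] = d[:, half : half + 1]
        d[:, -half:] = d[:, -half - 1 : -half]
        return d


class Detrend(TransformerMixin, BaseEstimator):
    """Remove a least-squares polynomial baseline (in band index) per spectrum.

    Order 2 by default, targeting baseline shift and curvilinearity; usually
    chained after SNV.  The subtraction is an orthogonal projection, hence
    idempotent.
    """

    def __init__(self, polyorder: int = 2):
        self.polyorder = polyorder

    def fit(self, X, y=None):
        X = _as_2d(X)
        if X.shape[1] <= self.polyorder:
            raise ValueError("need more bands than the detrend polynomial order")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_2d(X)
        n = X.shape[1]
        if n <= self.polyorder:
            raise ValueError("need more bands than the detrend polynomial order")
        # Legendre-ish scaled basis for conditioning
        t = np.linspace(-1.0, 1.0, n)
        basis = np.vander(t, self.polyorder + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(basis, X.T, rcond=None)
        return X - (basis @ coef).T


class Normalize(TransformerMixin, BaseEstimator):
    """Row normalization: ``vector`` (unit Euclidean norm, default),
    ``area`` (unit sum of absolute values) or ``max`` (unit maximum)."""

    MODES = ("vector", "area", "max")

    def __init__(self, mode: str = "vector"):
        self.mode = mode

    def fit(self, X, y=None):
        if self.mode not in self.MODES:
            raise ValueError(f"mode must be one of {self.MODES}, got {self.mode!r}")
        self.n_features_in_ = _as_2d(X).shape[1]
        return self

    def transform(self, X):
        X = _as_2d(X)
        if self.mode == "vector":
            denom = np.linalg.norm(X, axis=1)
        elif self.mode == "area":
            denom = np.abs(X).sum(axis=1)
        elif self.mode == "max":
            denom = X.max(axis=1)
        else:
            raise ValueError(f"mode must be one of {self.MODES}, got {self.mode!r}")
        zero = np.flatnonzero(denom == 0)
        if zero.size:
            raise ValueError(f"normalization undefined for sample {zero[0]} (zero {self.mode})")
        return X / denom[:, None]


class _Identity(TransformerMixin, BaseEstimator):
    def fit(self, X, y=None):
        self.n_features_in_ = _as_2d(X).shape[1]
        return self

    def transform(self, X):
        return _as_2d(X)


PRETREATMENTS = ("none", "normalization", "snv", "msc", "snv+detrend", "d1", "d2")


def make_pretreatment(name: str) -> Pipeline:
    """Build an unfitted pretreatment chain by its table name."""
    if name == "none":
        steps = [("identity", _Identity())]
    elif name == "normalization":
        steps = [("normalize", Normalize())]
    elif name == "snv":
        steps = [("snv", SNV())]
    elif name == "msc":
        steps = [("msc", MSC())]
    elif name == "snv+detrend":
        steps = [("snv", SNV()), ("detrend", Detrend())]
    elif name == "d1":
        steps = [("sg1", SavitzkyGolayDerivative(order=1))]
    elif name == "d2":
        steps = [("sg2", SavitzkyGolayDerivative(order=2))]
    else:
        raise ValueError(f"unknown pretreatment {name!r}; choose from {PRETREATMENTS}")
    return Pipeline(steps)


# -- thin functional wrappers ------------------------------------------------


def snv(X) -> np.ndarray:
    return SNV().fit_transform(X)


def msc(X, reference: np.ndarray | None = None) -> np.ndarray:
    return MSC(reference=reference).fit_transform(X)


def savgol_derivative(X, order: int, window: int = 15, polyorder: int = 2) -> np.ndarray:
    return SavitzkyGolayDerivative(order=order, window=window, polyorder=polyorder).fit_transform(X)


def detrend(X, polyorder: int = 2) -> np.ndarray:
    return Detrend(polyorder=polyorder).fit_transform(X)


def normalize(X, mode: str = "vector") -> np.ndarray:
    return Normalize(mode=mode).fit_transform(X)
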