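"""Wavelength selection: PC-loading extrema, 2D-COS autopeaks, and
regression-coefficient (RC) thresholding.

Three routes to a small "multispectral" band subset:

* **PC loadings** -- PCA of the spectra; pronounced peaks and valleys of the
  loading curves of informative PCs (default PC1 and PC3) mark bands that
  drive between-level variance.
* **2D-COS** -- generalized two-dimensional correlation spectroscopy with
  adulteration level as the perturbation.  The synchronous spectrum is
  Phi(v1, v2) = (1/(m-1)) sum_j  y~_j(v1) y~_j(v2)  over the m perturbation
  points, with dynamic spectra y~ taken about the across-level mean spectrum
  (Noda's convention).  Autopeaks -- local maxima on the diagonal -- mark
  bands whose intensity changes sharply with level.
* **RC** -- local extrema of a fitted PLSR coefficient curve whose absolute
  value exceeds a cut-off (default 5), or alternatively the top-k extrema by
  absolute coefficient when the coefficient scale of the data differs from
  the scale the fixed cut-off assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from sklearn.decomposition import PCA

__all__ = [
    "WavelengthSet",
    "SyncSpectrum",
    "pca_decompose",
    "pick_loading_extrema",
    "sync_2dcos",
    "autopeaks",
    "rc_select",
]


@dataclass
class WavelengthSet:
    """An ordered subset of spectral bands and the method that produced it."""

    method: str
    band_indices: np.ndarray
    nm_values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.band_indices = np.asarray(self.band_indices, dtype=int)
        self.nm_values = np.asarray(self.nm_values, dtype=float)
        if len(self.band_indices) != len(self.nm_values):
            raise ValueError("band_indices and nm_values lengths differ")
        if len(np.unique(self.band_indices)) != len(self.band_indices):
            raise ValueError("band indices must be unique")

    def __len__(self) -> int:
        return len(self.band_indices)

    def reduction_percent(self, n_total_bands: int) -> float:
        """Variable reduction 100*(B - s)/B, rounded to one decimal."""
        return round(100.0 * (n_total_bands - len(self)) / n_total_bands, 1)


@dataclass
class SyncSpectrum:
    """Synchronous 2D correlation spectrum over a wavelength x wavelength grid."""

    matrix: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("synchronous spectrum must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("synchronous spectrum must be symmetric")

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix)


def pca_decompose(X, n_components: int | None = None):
    """PCA of (samples x bands) spectra with deterministic loading signs.

    Columns are mean-centered internally.  Components are ordered by
    explained variance; each loading is flipped so its largest-magnitude
    element is positive.  Returns ``(scores, loadings, explained_pct)`` with
    loadings shaped (n_components, bands) and explained variance in percent.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 samples")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    flip = np.sign(loadings[np.arange(len(loadings)), np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    scores = scores * flip[None, :]
    return scores, loadings, pca.explained_variance_ratio_ * 100.0


def _curve_extrema(curve: np.ndarray, prominence: float | None = None) -> np.ndarray:
    """Indices of local maxima and minima of a curve (interior only)."""
    peaks, _ = find_peaks(curve, prominence=prominence)
    valleys, _ = find_peaks(-curve, prominence=prominence)
    return np.union1d(peaks, valleys)


def _dedupe_adjacent(indices: np.ndarray, scores: np.ndarray, min_gap: int = 2) -> np.ndarray:
    """Greedily drop indices within ``min_gap - 1`` bands of a kept, better-scoring one."""
    order = np.argsort(-scores)
    kept: list[int] = []
    for i in order:
        if all(abs(indices[i] - indices[j]) >= min_gap for j in kept):
            kept.append(i)
    return np.sort(indices[kept])


def pick_loading_extrema(
    loadings: np.ndarray,
    wavelengths: np.ndarray,
    pcs: tuple[int, ...] = (1, 3),
    min_prominence: float | None = None,
) -> WavelengthSet:
    """Bands at pronounced peaks/valleys of the chosen PC loading curves.

    ``pcs`` are 1-based PC numbers (default PC1 and PC3).  The prominence
    threshold defaults to 10 % of each loading's range.  Extrema are merged
    across PCs and deduplicated within one band of each other.
    """
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    wavelengths = np.asarray(wavelengths, dtype=float)
    for pc in pcs:
        if not 1 <= pc <= loadings.shape[0]:
            raise ValueError(f"PC{pc} not available (have {loadings.shape[0]} components)")
    all_idx: list[int] = []
    all_score: list[float] = []
    for pc in pcs:
        curve = loadings[pc - 1]
        rng = np.ptp(curve)
        prom = min_prominence if min_prominence is not None else 0.1 * rng
        if rng == 0:
            continue
        idx = _curve_extrema(curve, prominence=prom)
        all_idx.extend(idx.tolist())
        all_score.extend(np.abs(curve[idx]).tolist())
    if not all_idx:
        warnings.warn("no pronounced loading extrema found; empty wavelength set", stacklevel=2)
        return WavelengthSet("pc_loadings", np.array([], int), np.array([]), {"pcs": pcs})
    idx = np.asarray(all_idx)
    # merge duplicates across PCs before adjacency dedupe
    uniq, first = np.unique(idx, return_index=True)
    scores = np.asarray(all_score)[first]
    sel = _dedupe_adjacent(uniq, scores, min_gap=2)
    return WavelengthSet(
        "pc_loadings",
        sel,
        wavelengths[sel],
        {"pcs": tuple(pcs), "min_prominence": min_prominence},
    )


def sync_2dcos(level_mean_spectra: np.ndarray, wavelengths: np.ndarray) -> SyncSpectrum:
    """Synchronous 2D correlation spectrum with level as perturbation.

    ``level_mean_spectra`` is (levels x bands), one average spectrum per
    perturbation point, ordered by level.  Dynamic spectra are deviations
    from the across-level mean; Phi = dyn' dyn / (m - 1).  Its diagonal is
    the per-band variance across levels.
    """
    Y = np.asarray(level_mean_spectra, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2:
        raise ValueError("2D-COS needs at least 2 perturbation levels")
    dyn = Y - Y.mean(axis=0)
    phi = dyn.T @ dyn / (Y.shape[0] - 1)
    phi = (phi + phi.T) / 2.0  # enforce exact symmetry against rounding
    return SyncSpectrum(phi, np.asarray(wavelengths, dtype=float))


def autopeaks(
    sync: SyncSpectrum,
    k: int | None = 3,
    min_prominence: float | None = None,
) -> WavelengthSet:
    """Top-k autopeaks (local maxima of the synchronous diagonal)."""
    diag = sync.diagonal
    idx, _ = find_peaks(diag, prominence=min_prominence)
    if idx.size == 0:
        warnings.warn("no autopeaks found on the synchronous diagonal", stacklevel=2)
        return WavelengthSet("2dcos", np.array([], int), np.array([]), {"k": k})
    if k is not None:
        if k > idx.size:
            warnings.warn(
                f"requested top-{k} autopeaks but only {idx.size} exist; returning all",
                stacklevel=2,
            )
        keep = idx[np.argsort(-diag[idx])][:k]
        idx = np.sort(keep)
    return WavelengthSet(
        "2dcos", idx, sync.wavelengths[idx], {"k": k, "min_prominence": min_prominence}
    )


def rc_select(
    coefficients: np.ndarray,
    wavelengths: np.ndarray,
    threshold: float = 5.0,
    n_top: int | None = None,
) -> WavelengthSet:
    """Bands at local extrema of the regression-coefficient curve.

    With ``threshold`` (default 5), keep extrema whose absolute coefficient
    exceeds it -- the fixed-cut-off rule.  With ``n_top`` set, keep instead
    the top-``n_top`` extrema by absolute coefficient (a quantile-style rule
    for data whose coefficient scale differs); the threshold is then ignored.
    """
    coefficients = getattr(coefficients, "coef_", coefficients)  # accept fitted models
    coef = np.asarray(coefficients, dtype=float).ravel()
    wavelengths = np.asarray(wavelengths, dtype=float)
    if len(coef) != len(wavelengths):
        raise ValueError("coefficient and wavelength lengths differ")
    extrema = _curve_extrema(coef)
    prov = {"threshold": threshold, "n_top": n_top}
    if extrema.size == 0:
        warnings.warn("coefficient curve has no interior extrema", stacklevel=2)
        return WavelengthSet("rc", np.array([], int), np.array([]), prov)
    if n_top is not None:
        keep = extrema[np.argsort(-np.abs(coef[extrema]))][:n_top]
        idx = np.sort(keep)
    else:
        idx = extrema[np.abs(coef[extrema]) > threshold]
        if idx.size == 0:
            warnings.warn(
                f"no coefficient extremum exceeds |{threshold}|; empty wavelength set",
                stacklevel=2,
            )
    return WavelengthSet("rc", idx, wavelengths[idx], prov)
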