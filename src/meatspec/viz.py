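"""Pixel-wise adulteration maps and false-color composites.

The distribution map applies a fitted (multispectral) PLSR model to every
ROI pixel's spectrum: the pixel spectrum is restricted to the model's band
subset, pretreated with the same chain the model was trained on, and passed
through the model.  Out-of-range predictions are kept in the data layer and
clipped only for display (the clipped fraction is logged).

The false-color composite mimics a near-true-color view by mapping the
bands nearest 700.9 / 545.4 / 436.4 nm to the R/G/B channels with a 1st-99th
percentile stretch.  Rendered maps use a linear black -> yellow -> red scale
over 0-100 % adulteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap

from .hsi_io import Hypercube, RoiMask, nearest_band
from .preprocess import make_pretreatment

logger = logging.getLogger(__name__)

__all__ = [
    "DistributionMap",
    "ADULTERATION_CMAP",
    "PretreatmentMismatchError",
    "predict_map",
    "false_color",
    "render_map",
    "sector_stats",
]

# linear scale: 0 % black through yellow to 100 % red
ADULTERATION_CMAP = LinearSegmentedColormap.from_list(
    "adulteration", [(0.0, "black"), (0.5, "#ffd21f"), (1.0, "#d40000")]
)


class PretreatmentMismatchError(ValueError):
    """Model was trained under a different pretreatment than requested."""


@dataclass
class DistributionMap:
    """Per-pixel predicted adulteration level (%), defined inside the ROI.

    ``values`` is NaN outside the mask.  Raw predictions are preserved;
    rendering clips the display range to [0, 100].
    """

    values: np.ndarray
    mask: RoiMask
    color_scale: tuple[float, float] = (0.0, 100.0)
    out_of_range_fraction: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.mask.shape:
            raise ValueError("map shape does not match mask shape")

    @property
    def roi_values(self) -> np.ndarray:
        return self.values[self.mask.mask]

    @property
    def roi_mean(self) -> float:
        return float(self.roi_values.mean())


def predict_map(
    cube: Hypercube,
    mask: RoiMask,
    model,
    bands=None,
    pretreatment: str = "none",
    pretreat_on: str = "subset",
) -> DistributionMap:
    """Predict the adulteration level of every ROI pixel.

    ``bands`` (a WavelengthSet or index array) defaults to the band subset
    stored on the model, or all bands.  ``pretreat_on="subset"`` pretreats
    the pixel spectra after band restriction (matching a multispectral
    instrument); ``"full"`` pretreats the full spectra first.  If the model
    records its training pretreatment and it differs from ``pretreatment``,
    a :class:`PretreatmentMismatchError` is raised.
    """
    tag = getattr(model, "pretreatment_tag_", None)
    if tag is not None and tag != pretreatment:
        raise PretreatmentMismatchError(
            f"model was trained with pretreatment {tag!r}, requested {pretreatment!r}"
        )
    if bands is None:
        idx = getattr(model, "band_indices_", None)
        idx = np.arange(cube.n_bands) if idx is None else np.asarray(idx, int)
    else:
        idx = np.asarray(getattr(bands, "band_indices", bands), dtype=int)
    if mask.n_pixels == 0:
        raise ValueError("empty ROI mask; nothing to predict")

    pixels = cube.data[mask.mask].astype(float)  # (n_pixels, bands)
    chain = make_pretreatment(pretreatment)
    if pretreat_on == "full":
        pixels = chain.fit(pixels).transform(pixels)[:, idx]
    elif pretreat_on == "subset":
        pixels = pixels[:, idx]
        pixels = chain.fit(pixels).transform(pixels)
    else:
        raise ValueError("pretreat_on must be 'subset' or 'full'")
    yhat = model.predict(pixels)

    values = np.full(mask.mask.shape, np.nan)
    values[mask.mask] = yhat
    frac = float(((yhat < 0) | (yhat > 100)).mean())
    if frac:
        logger.info("predict_map: %.1f%% of pixel predictions outside [0, 100]", 100 * frac)
    return DistributionMap(values=values, mask=mask, out_of_range_fraction=frac)


def false_color(
    cube: Hypercube,
    r_nm: float = 700.9,
    g_nm: float = 545.4,
    b_nm: float = 436.4,
) -> np.ndarray:
    """Three-band false-color composite, (rows, cols, 3) floats in [0, 1].

    Each channel is the nearest band to the requested wavelength, stretched
    to [0, 1] between its 1st and 99th percentiles.  A constant channel maps
    to mid-gray.
    """
    rgb = np.empty(cube.data.shape[:2] + (3,))
    for ch, nm in enumerate((r_nm, g_nm, b_nm)):
        band = cube.data[:, :, nearest_band(cube.wavelengths, nm)].astype(float)
        lo, hi = np.percentile(band, [1, 99])
        if hi == lo:
            rgb[:, :, ch] = 0.5
        else:
            rgb[:, :, ch] = np.clip((band - lo) / (hi - lo), 0.0, 1.0)
    return rgb


def render_map(dmap: DistributionMap, path=None, ax=None, title: str | None = None):
    """Render a distribution map with the black->red 0-100 % color scale.

    Returns the matplotlib Axes.  If ``path`` is given the figure is saved
    (and closed) there.
    """
    import matplotlib.pyplot as plt

    created = ax is None
    if created:
        fig, ax = plt.subplots(figsize=(4.5, 4))
    else:
        fig = ax.figure
    lo, hi = dmap.color_scale
    shown = np.clip(dmap.values, lo, hi)
    im = ax.imshow(shown, cmap=ADULTERATION_CMAP, vmin=lo, vmax=hi)
    ax.set_facecolor("dimgray")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="Adulteration level (% w/w)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax


def sector_stats(dmap: DistributionMap, true_map: np.ndarray) -> pd.DataFrame:
    """Per-region prediction statistics of a control sample.

    Groups ROI pixels by their true level (the control layouts are piecewise
    constant) and reports mean/SD/count of the predictions per region.
    """
    sel = dmap.mask.mask & np.isfinite(true_map)
    truth = true_map[sel]
    pred = dmap.values[sel]
    rows = []
    for level in np.unique(truth):
        p = pred[truth == level]
        rows.append(
            {
                "true_level": float(level),
                "n_pixels": int(p.size),
                "pred_mean": float(p.mean()),
                "pred_sd": float(p.std(ddof=1)) if p.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
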