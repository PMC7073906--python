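"""Hypercube container, ENVI-style I/O, reflectance calibration and ROI masking.

A hypercube is stored in memory as a ``(rows, cols, bands)`` array with a
strictly increasing wavelength axis in nanometres.  Raw cubes hold detector
counts; calibrated cubes hold relative reflectance on a 0-100 % scale, the
scale on which the calibration equation

    R_c = (R_o - D) / (W - D) x 100 %

is defined (``W`` = white reference, ~99.9 % target; ``D`` = dark reference).
The ROI mask follows the band-math rule: reflectance at 890 nm minus
reflectance at 450 nm, thresholded at 0.2 on the fractional (0-1) scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Hypercube",
    "ReferencePair",
    "RoiMask",
    "EnviFormatError",
    "CalibrationError",
    "read_cube",
    "write_cube",
    "calibrate",
    "build_mask",
    "mean_spectrum",
    "nearest_band",
]


class EnviFormatError(ValueError):
    """Malformed or inconsistent ENVI header/raster."""


class CalibrationError(ValueError):
    """White/dark references unusable for reflectance calibration."""


@dataclass
class Hypercube:
    """A ``(rows, cols, bands)`` raster with a wavelength axis.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
        Detector counts (``kind="raw"``) or relative reflectance in percent
        (``kind="reflectance"``).
    wavelengths : ndarray, shape (bands,)
        Band centres in nm, strictly increasing.
    kind : {"raw", "reflectance"}
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength axis length {len(self.wavelengths)} does not match "
                f"band count {self.data.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"kind must be 'raw' or 'reflectance', got {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class ReferencePair:
    """White (~99.9 % target) and dark (~0 % target) reference cubes."""

    white: Hypercube
    dark: Hypercube

    def __post_init__(self) -> None:
        if self.white.n_bands != self.dark.n_bands:
            raise ValueError("white and dark references have different band counts")

    def mean_spectra(self) -> tuple[np.ndarray, np.ndarray]:
        """Spatially averaged white and dark spectra, one value per band."""
        w = self.white.data.reshape(-1, self.white.n_bands).mean(axis=0)
        d = self.dark.data.reshape(-1, self.dark.n_bands).mean(axis=0)
        return w, d


@dataclass
class RoiMask:
    """Boolean region-of-interest mask over the spatial grid."""

    mask: np.ndarray
    n_pixels: int = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.n_pixels = int(self.mask.sum())


# ---------------------------------------------------------------------------
# ENVI I/O
# ---------------------------------------------------------------------------

# ENVI numeric data-type codes
_DTYPE_TO_CODE = {
    np.dtype("int16"): 2,
    np.dtype("int32"): 3,
    np.dtype("float32"): 4,
    np.dtype("float64"): 5,
    np.dtype("uint16"): 12,
}
_CODE_TO_DTYPE = {v: k for k, v in _DTYPE_TO_CODE.items()}

_INTERLEAVES = ("bil", "bip", "bsq")


def _header_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hdr")


def write_cube(cube: Hypercube, path: str | Path, interleave: str = "bil") -> Path:
    """Write a cube as an ENVI raster (binary) plus ``<path>.hdr`` text header.

    Float data are stored as float32, integer data in their native width.
    Returns the data-file path.
    """
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    data = cube.data
    if data.dtype not in _DTYPE_TO_CODE:
        data = data.astype(np.float32)
    rows, cols, bands = data.shape
    if interleave == "bip":  # (lines, samples, bands)
        raster = data
    elif interleave == "bil":  # (lines, bands, samples)
        raster = np.transpose(data, (0, 2, 1))
    else:  # bsq: (bands, lines, samples)
        raster = np.transpose(data, (2, 0, 1))
    np.ascontiguousarray(raster).tofile(path)

    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {meatspec hypercube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_CODE[data.dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"data kind = {cube.kind}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    _header_path(path).write_text(header)
    return path


def _parse_header(text: str) -> dict[str, str]:
    """Parse ENVI header ``key = value`` lines, honouring {...} blocks."""
    if not text.lstrip().startswith("ENVI"):
        raise EnviFormatError("missing ENVI magic line in header")
    fields: dict[str, str] = {}
    buf = text.split("\n", 1)[1] if "\n" in text else ""
    i = 0
    while i < len(buf):
        eq = buf.find("=", i)
        if eq == -1:
            break
        key = buf[i:eq].strip().lower()
        rest = buf[eq + 1 :].lstrip()
        if rest.startswith("{"):
            close = rest.find("}")
            if close == -1:
                raise EnviFormatError(f"unterminated {{...}} block for key {key!r}")
            value = rest[1:close]
            consumed = (eq + 1) + (len(buf[eq + 1 :]) - len(rest)) + close + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl == -1 else nl
            value = rest[:nl].strip()
            consumed = (eq + 1) + (len(buf[eq + 1 :]) - len(rest)) + nl
        if key:
            fields[key] = value
        i = consumed
    return fields


def read_cube(path: str | Path) -> Hypercube:
    """Read an ENVI raster + header written by :func:`write_cube` (or alike).

    ``path`` may point at either the data file or the ``.hdr`` file.
    Supports BIL/BIP/BSQ interleaves and int16/int32/float32/float64/uint16.
    """
    path = Path(path)
    if path.suffix == ".hdr":
        hdr_path, data_path = path, path.with_suffix("")
    else:
        hdr_path, data_path = _header_path(path), path
    if not hdr_path.exists():
        raise EnviFormatError(f"header file not found: {hdr_path}")
    fields = _parse_header(hdr_path.read_text())

    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise EnviFormatError(f"header missing required key: {exc}") from exc
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    if code not in _CODE_TO_DTYPE:
        raise EnviFormatError(f"unsupported ENVI data type code {code}")
    if "wavelength" not in fields:
        raise EnviFormatError("header has no wavelength list")
    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].replace("\n", " ").split(",") if tok.strip()]
    )
    if len(wavelengths) != bands:
        raise EnviFormatError(
            f"header declares bands={bands} but lists {len(wavelengths)} wavelengths"
        )

    offset = int(fields.get("header offset", "0"))
    raw = np.fromfile(data_path, dtype=_CODE_TO_DTYPE[code], offset=offset)
    expected = rows * cols * bands
    if raw.size != expected:
        raise EnviFormatError(
            f"raster size {raw.size} does not match header dimensions "
            f"{rows}x{cols}x{bands}={expected}"
        )
    if interleave == "bip":
        data = raw.reshape(rows, cols, bands)
    elif interleave == "bil":
        data = np.transpose(raw.reshape(rows, bands, cols), (0, 2, 1))
    else:  # bsq
        data = np.transpose(raw.reshape(bands, rows, cols), (1, 2, 0))
    kind = fields.get("data kind", "reflectance" if code in (4, 5) else "raw")
    return Hypercube(np.ascontiguousarray(data), wavelengths, kind=kind)


# ---------------------------------------------------------------------------
# Calibration, masking, extraction
# ---------------------------------------------------------------------------


def calibrate(
    raw: Hypercube,
    refs: ReferencePair,
    clip_low: float = 0.0,
    clip_high: float = 110.0,
) -> Hypercube:
    """Convert raw counts to relative reflectance (percent).

    The white and dark references are spatially averaged to one spectrum
    each, then ``R_c = (R_o - D) / (W - D) x 100`` is applied per pixel and
    band.  Reflectance outside ``[clip_low, clip_high]`` percent is clipped;
    the affected fraction is logged.
    """
    if raw.kind != "raw":
        raise CalibrationError("input cube is already calibrated (kind != 'raw')")
    if refs.white.n_bands != raw.n_bands:
        raise CalibrationError(
            f"reference band count {refs.white.n_bands} != cube band count {raw.n_bands}"
        )
    w, d = refs.mean_spectra()
    bad = np.flatnonzero(w <= d)
    if bad.size:
        nm = raw.wavelengths[bad[0]]
        raise CalibrationError(
            f"white reference does not exceed dark reference at band {bad[0]} "
            f"({nm:.1f} nm)"
        )
    refl = (raw.data.astype(np.float64) - d) / (w - d) * 100.0
    n_out = int(((refl < clip_low) | (refl > clip_high)).sum())
    if n_out:
        logger.info(
            "calibrate: clipped %d/%d values outside [%.1f, %.1f] %%",
            n_out, refl.size, clip_low, clip_high,
        )
    np.clip(refl, clip_low, clip_high, out=refl)
    return Hypercube(refl, raw.wavelengths, kind="reflectance")


def nearest_band(wavelengths: np.ndarray, nm: float) -> int:
    """Index of the band closest to ``nm`` (ties go to the lower index)."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    if nm < wavelengths[0] or nm > wavelengths[-1]:
        raise ValueError(
            f"requested wavelength {nm} nm outside cube range "
            f"[{wavelengths[0]}, {wavelengths[-1]}] nm"
        )
    return int(np.argmin(np.abs(wavelengths - nm)))


def build_mask(
    cube: Hypercube,
    low_nm: float = 450.0,
    high_nm: float = 890.0,
    threshold: float = 0.2,
    remove_small: int = 0,
) -> RoiMask:
    """Band-math ROI mask: ``band(high_nm) - band(low_nm) > threshold``.

    The threshold is interpreted on the fractional (0-1) reflectance scale;
    a percent-scale cube is divided by 100 before comparison.  Nearest bands
    are used for the two requested wavelengths.  ``remove_small`` optionally
    drops connected components with fewer pixels than the given count.
    """
    i_low = nearest_band(cube.wavelengths, low_nm)
    i_high = nearest_band(cube.wavelengths, high_nm)
    diff = cube.data[:, :, i_high].astype(float) - cube.data[:, :, i_low]
    if cube.kind == "reflectance":
        diff = diff / 100.0
    mask = diff > threshold
    if remove_small > 0:
        from scipy import ndimage

        labels, n = ndimage.label(mask)
        if n:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            for lab in np.flatnonzero(sizes < remove_small) + 1:
                mask[labels == lab] = False
    return RoiMask(mask)


def mean_spectrum(cube: Hypercube, mask: RoiMask) -> np.ndarray:
    """Arithmetic mean spectrum over the masked pixels, per band."""
    if mask.mask.shape != cube.data.shape[:2]:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match cube spatial shape "
            f"{cube.data.shape[:2]}"
        )
    if mask.n_pixels < 1:
        raise ValueError("cannot extract a mean spectrum from an empty mask")
    return cube.data[mask.mask].mean(axis=0)
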