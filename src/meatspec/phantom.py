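"""Synthetic "meat phantom" hypercubes for exercising the whole pipeline.

The generator emulates visible/near-infrared (400-1000 nm, 284 bands)
reflectance imaging of a disk of minced meat in a Petri dish on a dark
background.  Two endmember spectra stand in for pure minced pork and pure
minced jowl meat: a smooth sigmoid baseline minus Gaussian absorption dips
at the haemoglobin Soret band (411 nm), deoxy-/oxymyoglobin (543/570 nm),
the third and second O-H water overtones (759/975 nm) and an aliphatic C-H
band (842 nm).  Jowl meat sits at a lower overall reflectance with deeper
myoglobin, water and fat dips, so pork has the slightly higher reflective
intensity.

Each pixel inside the disk mixes the endmembers linearly at a local jowl
fraction c, then receives a per-pixel multiplicative gain (scatter), an
additive baseline offset, and per-band noise:

    r(lambda) = g * [(1 - c) * pork + c * jowl] + b + eps

Sample-to-sample realism comes from two concentration noise terms: a
between-sample composition error (``level_sd``, the realized mean level of
a sample around its nominal level) and within-sample spatial jitter
(``jitter_sd``).  Background pixels are flat low reflectance so that the
890 nm - 450 nm band-math mask excludes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hsi_io import Hypercube, ReferencePair

__all__ = [
    "FEATURE_BANDS",
    "Endmembers",
    "PhantomConfig",
    "DesignSpec",
    "SampleCube",
    "make_endmembers",
    "wavelength_grid",
    "simulate_sample_cube",
    "simulate_control_cube",
    "simulate_dataset",
    "plan_dataset",
    "simulate_references",
    "uncalibrate",
]

# Absorption features: centre nm -> (width nm, pork dip depth, jowl depth factor)
FEATURE_BANDS: dict[float, tuple[float, float, float]] = {
    411.0: (12.0, 0.060, 1.3),  # Soret band, haemoglobin
    543.0: (8.0, 0.050, 1.6),   # deoxymyoglobin
    570.0: (8.0, 0.050, 1.6),   # oxymyoglobin
    759.0: (10.0, 0.020, 1.5),  # O-H 3rd overtone, water
    842.0: (12.0, 0.015, 1.8),  # C-H, aliphatic fat
    975.0: (20.0, 0.040, 1.5),  # O-H 2nd overtone, water
}


@dataclass
class Endmembers:
    """Pure-component reflectance spectra on a shared wavelength grid.

    Reflectance is fractional (0-1).  Pork has the higher mean reflectance.
    """

    wavelengths: np.ndarray
    pork: np.ndarray
    jowl: np.ndarray

    def __post_init__(self) -> None:
        for name in ("pork", "jowl"):
            s = getattr(self, name)
            if len(s) != len(self.wavelengths):
                raise ValueError(f"{name} spectrum length mismatch")
            if np.any(s <= 0) or np.any(s >= 1):
                raise ValueError(f"{name} spectrum must lie strictly inside (0, 1)")
        if self.pork.mean() <= self.jowl.mean():
            raise ValueError("pork mean reflectance must exceed jowl mean reflectance")

    def mix(self, c: np.ndarray | float) -> np.ndarray:
        """Linear mixture ``(1 - c) * pork + c * jowl`` for jowl fraction c."""
        c = np.asarray(c, dtype=float)
        return (1.0 - c)[..., None] * self.pork + c[..., None] * self.jowl


@dataclass
class PhantomConfig:
    """Geometry and noise settings for one synthetic sample cube.

    Noise defaults are the study conditions used throughout: multiplicative
    scatter SD 5 %, additive offset SD 0.01, per-band noise SD 0.004 (all on
    the fractional reflectance scale), within-sample concentration jitter SD
    2 %-points, and between-sample composition error SD 7 %-points.
    """

    rows: int = 64
    cols: int = 64
    bands: int = 284
    wavelength_range: tuple[float, float] = (400.0, 1000.0)
    disk_center: tuple[float, float] | None = None  # (row, col); None = frame centre
    disk_radius: float = 24.0
    gain_sd: float = 0.05
    baseline_sd: float = 0.01
    noise_sd: float = 0.004
    jitter_sd: float = 2.0
    level_sd: float = 7.0
    background_reflectance: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bands < 2:
            raise ValueError("need at least 2 spectral bands")
        for name in ("gain_sd", "baseline_sd", "noise_sd", "jitter_sd", "level_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        cy, cx = self.center
        r = self.disk_radius
        if r < 0:
            raise ValueError("disk_radius must be >= 0")
        if cy - r < -0.5 or cx - r < -0.5 or cy + r > self.rows - 0.5 or cx + r > self.cols - 0.5:
            raise ValueError("disk does not fit inside the frame")

    @property
    def center(self) -> tuple[float, float]:
        if self.disk_center is not None:
            return self.disk_center
        return ((self.rows - 1) / 2.0, (self.cols - 1) / 2.0)

    def wavelengths(self) -> np.ndarray:
        return wavelength_grid(self.bands, self.wavelength_range)


@dataclass
class DesignSpec:
    """Sampling design: adulteration levels, replication and the split.

    Defaults mirror the study layout: 11 levels (0-100 % in 10 % steps) with
    16 replicates each, 12 of which go to calibration -> 176 cubes, 132/44.
    """

    levels: tuple[float, ...] = tuple(float(v) for v in range(0, 101, 10))
    replicates_per_level: int = 16
    calibration_per_level: int = 12

    def __post_init__(self) -> None:
        if any(not 0 <= lv <= 100 for lv in self.levels):
            raise ValueError("levels must lie in [0, 100] % w/w")
        if not 0 <= self.calibration_per_level <= self.replicates_per_level:
            raise ValueError("calibration_per_level must be <= replicates_per_level")

    @property
    def n_samples(self) -> int:
        return len(self.levels) * self.replicates_per_level


@dataclass
class SampleCube:
    """One simulated sample: cube, ground truth and bookkeeping."""

    sample_id: str
    level: float
    split: str
    seed: int
    cube: Hypercube
    true_map: np.ndarray = field(repr=False)


def wavelength_grid(bands: int, wavelength_range: tuple[float, float] = (400.0, 1000.0)) -> np.ndarray:
    return np.linspace(wavelength_range[0], wavelength_range[1], bands)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_endmembers(wavelengths: np.ndarray, seed: int = 0) -> Endmembers:
    """Build pork/jowl endmember spectra on the given wavelength grid.

    The seed perturbs dip depths and widths by ~10 % so repeated studies see
    slightly different, but physically equivalent, endmember pairs.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or len(wl) < 2 or not np.all(np.diff(wl) > 0):
        raise ValueError("wavelengths must be a strictly increasing 1-D grid")
    if wl[-1] < 400.0 or wl[0] > 1000.0:
        feats = ", ".join(f"{c:.0f} nm" for c in FEATURE_BANDS)
        raise ValueError(
            f"wavelength grid [{wl[0]:.0f}, {wl[-1]:.0f}] nm covers none of the "
            f"absorption features ({feats})"
        )
    rng = np.random.default_rng(seed)

    baseline = 0.15 + 0.45 * _sigmoid((wl - 560.0) / 80.0)
    jowl_scale = 0.92 + rng.normal(0.0, 0.01)
    pork = baseline.copy()
    jowl = jowl_scale * baseline
    for centre, (width, depth, jowl_factor) in FEATURE_BANDS.items():
        w = width * rng.uniform(0.9, 1.1)
        d = depth * rng.uniform(0.9, 1.1)
        dip = np.exp(-0.5 * ((wl - centre) / w) ** 2)
        pork = pork - d * dip
        jowl = jowl - d * jowl_factor * dip
    pork = np.clip(pork, 1e-3, 1 - 1e-3)
    jowl = np.clip(jowl, 1e-3, 1 - 1e-3)
    return Endmembers(wl, pork, jowl)


def _disk_mask(config: PhantomConfig) -> np.ndarray:
    cy, cx = config.center
    yy, xx = np.mgrid[0 : config.rows, 0 : config.cols]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= config.disk_radius**2


def _render_cube(
    c_map: np.ndarray,
    in_disk: np.ndarray,
    config: PhantomConfig,
    endmembers: Endmembers,
    rng: np.random.Generator,
) -> Hypercube:
    """Render a reflectance cube from a per-pixel jowl-fraction map (0-1)."""
    rows, cols = config.rows, config.cols
    bands = len(endmembers.wavelengths)
    refl = np.full((rows, cols, bands), config.background_reflectance, dtype=np.float64)
    refl[in_disk] = endmembers.mix(c_map[in_disk])
    gain = rng.normal(1.0, config.gain_sd, size=(rows, cols, 1))
    offset = rng.normal(0.0, config.baseline_sd, size=(rows, cols, 1))
    noise = rng.normal(0.0, config.noise_sd, size=(rows, cols, bands)) if config.noise_sd else 0.0
    refl = gain * refl + offset + noise
    np.clip(refl, 0.0, 1.1, out=refl)
    return Hypercube(refl * 100.0, endmembers.wavelengths, kind="reflectance")


def simulate_sample_cube(
    config: PhantomConfig,
    level: float,
    seed: int,
    endmembers: Endmembers | None = None,
) -> tuple[Hypercube, np.ndarray]:
    """Simulate one adulterated-sample cube at a nominal level (% w/w).

    Returns the reflectance cube (percent scale) and the true per-pixel
    adulteration map (%, NaN outside the disk).  The sample's realized mean
    level is ``level + N(0, level_sd)`` and each pixel adds jitter
    ``N(0, jitter_sd)``, both clipped to [0, 100].
    """
    if not 0 <= level <= 100:
        raise ValueError(f"adulteration level must be in [0, 100] %, got {level}")
    if endmembers is None:
        endmembers = make_endmembers(config.wavelengths(), config.seed)
    rng = np.random.default_rng(seed)
    in_disk = _disk_mask(config)
    if not in_disk.any():
        warnings.warn("disk radius produced an empty ROI", stacklevel=2)

    realized = float(np.clip(level + rng.normal(0.0, config.level_sd), 0.0, 100.0)) \
        if config.level_sd else float(level)
    levels_map = np.full((config.rows, config.cols), np.nan)
    jitter = rng.normal(0.0, config.jitter_sd, size=in_disk.sum()) if config.jitter_sd else 0.0
    levels_map[in_disk] = np.clip(realized + jitter, 0.0, 100.0)

    cube = _render_cube(levels_map / 100.0, in_disk, config, endmembers, rng)
    return cube, levels_map


CONTROL_PATTERNS = ("quadrants", "halves")


def simulate_control_cube(
    pattern: str,
    config: PhantomConfig,
    seed: int,
    endmembers: Endmembers | None = None,
) -> tuple[Hypercube, np.ndarray]:
    """Simulate a control sample with a known spatial layout.

    ``"quadrants"``: four fan-shaped sectors at 100/80/40/20 % (one per
    quarter turn).  ``"halves"``: two semicircles at 0 % and 50 %.  The true
    map holds the exact nominal level of each region (no composition noise
    or jitter -- these samples exist to verify the visualization), while the
    rendered spectra still carry gain/offset/band noise.
    """
    if pattern not in CONTROL_PATTERNS:
        raise ValueError(f"unknown control pattern {pattern!r}; choose from {CONTROL_PATTERNS}")
    if endmembers is None:
        endmembers = make_endmembers(config.wavelengths(), config.seed)
    rng = np.random.default_rng(seed)
    in_disk = _disk_mask(config)
    if not in_disk.any():
        warnings.warn("disk radius produced an empty ROI", stacklevel=2)

    cy, cx = config.center
    yy, xx = np.mgrid[0 : config.rows, 0 : config.cols]
    levels_map = np.full((config.rows, config.cols), np.nan)
    if pattern == "quadrants":
        theta = np.arctan2(yy - cy, xx - cx)  # (-pi, pi]
        sector = ((theta + np.pi) / (np.pi / 2)).astype(int) % 4
        sector_levels = np.array([100.0, 80.0, 40.0, 20.0])
        levels_map[in_disk] = sector_levels[sector[in_disk]]
    else:
        levels_map[in_disk] = np.where(yy[in_disk] < cy, 0.0, 50.0)

    cube = _render_cube(np.nan_to_num(levels_map) / 100.0, in_disk, config, endmembers, rng)
    return cube, levels_map


def plan_dataset(design: DesignSpec, seed: int) -> pd.DataFrame:
    """Deterministic sampling manifest: sample_id, level, split, per-cube seed.

    Per level, ``calibration_per_level`` replicates are assigned to the
    calibration set at random under the seed; the rest go to prediction.
    """
    rng = np.random.default_rng(seed)
    records = []
    for level in design.levels:
        order = rng.permutation(design.replicates_per_level)
        for rep in range(design.replicates_per_level):
            split = "calibration" if order[rep] < design.calibration_per_level else "prediction"
            records.append(
                {
                    "sample_id": f"L{level:05.1f}_R{rep:02d}",
                    "level_percent": float(level),
                    "split": split,
                    "seed": int(rng.integers(0, 2**31 - 1)),
                }
            )
    return pd.DataFrame.from_records(records)


def simulate_dataset(design: DesignSpec, config: PhantomConfig, seed: int):
    """Yield :class:`SampleCube` records for the full design, lazily.

    Cubes are generated on demand (a full default design holds 176 cubes,
    which would be wasteful to keep in memory at once).  Deterministic given
    ``(design, config, seed)``.
    """
    manifest = plan_dataset(design, seed)
    endmembers = make_endmembers(config.wavelengths(), config.seed)
    for rec in manifest.itertuples(index=False):
        cube, true_map = simulate_sample_cube(
            config, rec.level_percent, int(rec.seed), endmembers=endmembers
        )
        yield SampleCube(rec.sample_id, rec.level_percent, rec.split, int(rec.seed), cube, true_map)


# ---------------------------------------------------------------------------
# Raw-count synthesis (to exercise reflectance calibration end-to-end)
# ---------------------------------------------------------------------------


def simulate_references(
    config: PhantomConfig,
    seed: int,
    white_counts: float = 3600.0,
    dark_counts: float = 120.0,
    ref_noise_sd: float = 8.0,
) -> ReferencePair:
    """Synthesize white/dark reference cubes with a lamp-shaped count profile."""
    rng = np.random.default_rng(seed)
    wl = config.wavelengths()
    # tungsten-halogen-ish envelope: weak in blue, peaking toward the NIR
    envelope = 0.35 + 0.65 * _sigmoid((wl - 520.0) / 110.0)
    shape = (config.rows, config.cols, config.bands)
    white = dark_counts + (white_counts - dark_counts) * envelope + rng.normal(0, ref_noise_sd, shape)
    dark = dark_counts + rng.normal(0, ref_noise_sd, shape)
    return ReferencePair(
        white=Hypercube(white.astype(np.float32), wl, kind="raw"),
        dark=Hypercube(dark.astype(np.float32), wl, kind="raw"),
    )


def uncalibrate(cube: Hypercube, refs: ReferencePair) -> Hypercube:
    """Invert the reflectance equation: percent reflectance -> raw counts.

    Uses the spatially averaged reference spectra, so a subsequent
    :func:`meatspec.hsi_io.calibrate` recovers the reflectance cube up to
    reference noise.
    """
    if cube.kind != "reflectance":
        raise ValueError("uncalibrate expects a reflectance cube")
    w, d = refs.mean_spectra()
    counts = cube.data / 100.0 * (w - d) + d
    return Hypercube(counts.astype(np.float32), cube.wavelengths, kind="raw")
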