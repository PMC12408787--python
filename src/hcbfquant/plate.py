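"""Plate and well geometry for high-contrast brightfield (HCBF) imaging.

Microplate wells imaged in brightfield suffer from the liquid-meniscus
effect: the curved liquid surface distorts illumination near the well
edge, so only a central circular fraction of the well -- the *analytical
area* -- is usable for quantification.  This module holds the plate
formats, the empirically calibrated meniscus lookup, circular plugin-ROI
masks, and montage (tiling) arithmetic for different objectives.

Conventions: image origin top-left, x rightward, y downward, pixel
centers at half-integer coordinates; all physical quantities in µm/µm².
Wells are addressed letter-row + 1-based column ("A1").
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlateFormat",
    "AnalyticalRegion",
    "MeniscusCalibration",
    "ObjectivePreset",
    "P96",
    "P384",
    "OBJ_4X",
    "OBJ_10X",
    "DEFAULT_MENISCUS",
    "PlateConfigError",
    "analytical_fraction",
    "analytical_area_um2",
    "region_mask",
    "montage_plan",
    "well_ids",
    "analyzable_wells",
]


class PlateConfigError(ValueError):
    """Raised for unknown formats or inconsistent plate configuration."""


@dataclass(frozen=True)
class PlateFormat:
    """A microplate format (96- or 384-well).

    ``well_diameter_um`` is the diameter of the circular growth area;
    ``edge_rows_excluded`` is how many outer rows/columns are dropped
    from analysis by default (edge wells evaporate in long live assays
    and are filled with liquid instead of samples).
    """

    name: str
    rows: int
    cols: int
    well_diameter_um: float
    edge_rows_excluded: int = 0

    def __post_init__(self) -> None:
        if self.rows * self.cols not in (96, 384):
            raise PlateConfigError(
                f"rows*cols must be 96 or 384, got {self.rows * self.cols}"
            )
        if self.well_diameter_um <= 0:
            raise PlateConfigError("well_diameter_um must be positive")

    @property
    def full_well_area_um2(self) -> float:
        return math.pi * (self.well_diameter_um / 2.0) ** 2

    @property
    def n_wells(self) -> int:
        return self.rows * self.cols


# Well diameters chosen so the circular growth areas match the measured
# analytical areas (47% of a 96-well at 150 µL = 1.3e7 µm²; 80% of a
# 384-well at 70 µL = 7.13e6 µm²).
P96 = PlateFormat("P96", rows=8, cols=12, well_diameter_um=5934.0, edge_rows_excluded=1)
P384 = PlateFormat("P384", rows=16, cols=24, well_diameter_um=3369.0, edge_rows_excluded=2)

_FORMATS = {"P96": P96, "P384": P384}


def get_format(name: str) -> PlateFormat:
    try:
        return _FORMATS[name]
    except KeyError:
        raise PlateConfigError(f"unknown plate format {name!r}; known: {sorted(_FORMATS)}")


def well_ids(fmt: PlateFormat) -> list[str]:
    """All well addresses of the plate in row-major order (A1, A2, ...)."""
    letters = string.ascii_uppercase
    return [f"{letters[r]}{c + 1}" for r in range(fmt.rows) for c in range(fmt.cols)]


def analyzable_wells(fmt: PlateFormat, edge_rows_excluded: int | None = None) -> list[str]:
    """Well addresses with the outer ``edge_rows_excluded`` rows/columns removed.

    With the default exclusions this yields 60 wells for a 96-well plate
    and 240 wells for a 384-well plate.
    """
    k = fmt.edge_rows_excluded if edge_rows_excluded is None else edge_rows_excluded
    letters = string.ascii_uppercase
    return [
        f"{letters[r]}{c + 1}"
        for r in range(k, fmt.rows - k)
        for c in range(k, fmt.cols - k)
    ]


@dataclass(frozen=True)
class AnalyticalRegion:
    """Circular plugin ROI to which all quantification is restricted.

    ``offset_x_um``/``offset_y_um`` shift the ROI center relative to the
    image center (plate displacement between runs is compensated by a
    per-experiment offset; there is no automatic estimator).
    """

    diameter_um: float
    offset_x_um: float = 0.0
    offset_y_um: float = 0.0
    shape: str = "circle"

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise PlateConfigError("ROI diameter must be positive")
        if self.shape != "circle":
            raise PlateConfigError(f"unsupported ROI shape {self.shape!r}")


#: Plugin ROI used for 96-well quantification (circular, 4700 µm across).
ROI_96 = AnalyticalRegion(diameter_um=4700.0)
#: Default 384-well ROI, sized to sit inside the 70 µL analytical area.
ROI_384 = AnalyticalRegion(diameter_um=3000.0)

DEFAULT_ROI = {"P96": ROI_96, "P384": ROI_384}


@dataclass(frozen=True)
class MeniscusCalibration:
    """Empirical (volume µL -> analytical fraction) anchors per format.

    The meniscus is measured, not modeled: anchors come from imaging
    wells at known fill volumes.  Between anchors the fraction is
    linearly interpolated; outside the anchor range it is clamped.
    """

    anchors: dict[str, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: {
            "P96": ((150.0, 0.47),),
            "P384": ((50.0, 0.60), (70.0, 0.80)),
        }
    )

    def __post_init__(self) -> None:
        for name, pairs in self.anchors.items():
            vols = [v for v, _ in pairs]
            fracs = [f for _, f in pairs]
            if not pairs:
                raise PlateConfigError(f"no anchors for format {name}")
            if any(not (0.0 < f <= 1.0) for f in fracs):
                raise PlateConfigError(f"fractions for {name} must be in (0, 1]")
            if sorted(vols) != list(vols):
                raise PlateConfigError(f"anchors for {name} must be sorted by volume")
            if sorted(fracs) != list(fracs):
                raise PlateConfigError(
                    f"analytical fraction must be non-decreasing in volume for {name}"
                )


DEFAULT_MENISCUS = MeniscusCalibration()


def analytical_fraction(
    fmt: PlateFormat,
    volume_ul: float,
    cal: MeniscusCalibration = DEFAULT_MENISCUS,
) -> float:
    """Usable fraction of the well area at the given fill volume.

    Piecewise-linear interpolation between calibration anchors, clamped
    to [lowest anchor fraction, 1.0]; monotone non-decreasing in volume.
    """
    if volume_ul <= 0:
        raise ValueError(f"volume must be positive, got {volume_ul} µL")
    if fmt.name not in cal.anchors:
        raise PlateConfigError(f"no meniscus calibration for format {fmt.name!r}")
    pairs = cal.anchors[fmt.name]
    vols = np.array([v for v, _ in pairs])
    fracs = np.array([f for _, f in pairs])
    # np.interp clamps to the terminal anchor values on both sides
    frac = float(np.interp(volume_ul, vols, fracs))
    return min(frac, 1.0)


def analytical_area_um2(
    fmt: PlateFormat,
    volume_ul: float,
    cal: MeniscusCalibration = DEFAULT_MENISCUS,
) -> float:
    """Analytical (meniscus-limited) area in µm² at the given volume."""
    return analytical_fraction(fmt, volume_ul, cal) * fmt.full_well_area_um2


def region_mask(
    region: AnalyticalRegion,
    image_shape: tuple[int, int],
    um_per_px: float,
) -> np.ndarray:
    """Boolean mask of the circular ROI on an image grid.

    The ROI is centered at the image center plus the region offset.
    Pixels outside the mask are excluded from all downstream
    quantification.  Raises if the ROI does not fit the image, naming
    the overflow in µm.
    """
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    ny, nx = image_shape
    r_um = region.diameter_um / 2.0
    cx = nx * um_per_px / 2.0 + region.offset_x_um
    cy = ny * um_per_px / 2.0 + region.offset_y_um
    for label, c, extent in (("x", cx, nx * um_per_px), ("y", cy, ny * um_per_px)):
        lo, hi = c - r_um, c + r_um
        if lo < -1e-9 or hi > extent + 1e-9:
            over = max(-lo, hi - extent)
            raise ValueError(
                f"ROI exceeds image bounds along {label} by {over:.1f} µm "
                f"(diameter {region.diameter_um} µm, offset "
                f"({region.offset_x_um}, {region.offset_y_um}) µm)"
            )
    x = (np.arange(nx) + 0.5) * um_per_px
    y = (np.arange(ny) + 0.5) * um_per_px
    dx = x[np.newaxis, :] - cx
    dy = y[:, np.newaxis] - cy
    return dx * dx + dy * dy <= r_um * r_um


@dataclass(frozen=True)
class ObjectivePreset:
    """Objective magnification preset for montage imaging.

    ``tile_px`` is the camera crop (x, y) in pixels.  The defaults
    reproduce the standard montage grids: 5x4 tiles per 96-well with the
    4x objective and 12x10 tiles with the 10x objective, at 10% stitch
    overlap.
    """

    name: str
    um_per_px: float
    tile_px: tuple[int, int] = (904, 1024)
    overlap_fraction: float = 0.10

    @property
    def tile_fov_um(self) -> tuple[float, float]:
        return (self.tile_px[0] * self.um_per_px, self.tile_px[1] * self.um_per_px)


OBJ_4X = ObjectivePreset("4x", um_per_px=1.6)
OBJ_10X = ObjectivePreset("10x", um_per_px=0.65)


def _tiles_along(extent_um: float, fov_um: float, overlap: float) -> int:
    # stitched extent of n tiles: fov * (1 + (n-1)*(1-overlap))
    if fov_um >= extent_um:
        return 1
    step = 1.0 - overlap
    n = 1 + math.ceil((extent_um / fov_um - 1.0) / step - 1e-9)
    return max(1, n)


def montage_plan(
    fmt: PlateFormat,
    tile_fov_um: tuple[float, float],
    target: str = "full_well",
    overlap_fraction: float = 0.10,
    roi: AnalyticalRegion | None = None,
) -> tuple[int, int]:
    """Smallest (n_x, n_y) tile grid whose stitched extent covers the target.

    ``target`` is ``"full_well"`` (bounding square of the well circle)
    or ``"analytical_roi"`` (bounding square of the plugin ROI).  A tile
    at least as large as the target in both axes gives (1, 1).
    """
    if tile_fov_um[0] <= 0 or tile_fov_um[1] <= 0:
        raise ValueError("tile field of view must be positive")
    if not (0.0 <= overlap_fraction < 0.5):
        raise ValueError("overlap_fraction must be in [0, 0.5)")
    if target == "full_well":
        extent = fmt.well_diameter_um
    elif target == "analytical_roi":
        extent = (roi or DEFAULT_ROI[fmt.name]).diameter_um
    else:
        raise ValueError(f"unknown montage target {target!r}")
    nx = _tiles_along(extent, tile_fov_um[0], overlap_fraction)
    ny = _tiles_along(extent, tile_fov_um[1], overlap_fraction)
    return nx, ny
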