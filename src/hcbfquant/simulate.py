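"""Seeded synthetic generator of ground-truthed HCBF well images and
multi-day live-assay time-courses.

The renderer emulates the *appearance* of defocused brightfield
imaging, not its optics: single cells act as lenses and show up as
bright isotropic Gaussian spots on the cell-count channel, while the
extra-defocused channel highlights the large elongated myotubes as
bright ridges and attenuates single cells.  A noisy background with a
radial vignette and a bright meniscus ring near the well edge completes
the frame.  Every object is recorded in a :class:`SceneTruth` so each
downstream measurement has an exact oracle.

The time-course simulator is phenomenological: lagged logistic growth
to a carrying capacity, density-triggered differentiation in which
cells fuse into myotubes (count falls, area rises), stochastic
detachment of plateaued myotubes, and an optional second wave of
myotube reformation from the freed surface area.

All randomness flows from one explicit seed through spawned
``numpy.random.Generator`` instances; no global state is touched.

Intensity scale (16-bit counts): background 8000; cell spots 12000;
myotube ridges 3000; nuclei 20000 over a near-zero (200) fluorescence
background.  Cross-channel bleed: myotubes render at 30 % of their
amplitude on the cell channel, single cells at 25 % of theirs on the
myotube channel.  These amplitudes are set so that the standard recipe
thresholds (3000 cell / 1000 myotube / 4000 nuclei counts above the
flattened baseline) are meaningful defaults after the full
rolling-ball + smoothing preprocessing chain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .frames import DEFOCUS_Z_UM, Channel, ImageFrame
from .plate import P96, P384, PlateFormat, analyzable_wells

logger = logging.getLogger(__name__)

__all__ = [
    "CellSpot",
    "Myotube",
    "SceneTruth",
    "AcquisitionModel",
    "GrowthParams",
    "TimePoint",
    "random_scene",
    "render_frame",
    "seed_clonal_plate",
    "simulate_timecourse",
    "simulate_clonal_screen",
    "two_wave_params",
    "density_ladder",
    "CELL_SPOT_AMPLITUDE",
    "MYO_RIDGE_AMPLITUDE",
    "CELL_FOOTPRINT_LEVEL",
    "MYO_FOOTPRINT_LEVEL",
    "mean_cell_footprint_um2",
]

# Default object amplitudes (counts over background)
CELL_SPOT_AMPLITUDE = 12000.0
MYO_RIDGE_AMPLITUDE = 3000.0
NUCLEUS_AMPLITUDE = 20000.0
NUCLEUS_FWHM_UM = 12.0
NUCLEI_BACKGROUND = 200.0
MYO_BLEED_IN_CELL_CHANNEL = 0.30
CELL_BLEED_IN_MYO_CHANNEL = 0.25

# Iso-intensity levels (counts) at which object footprints are defined.
# They equal the default analysis thresholds so that ground-truth areas
# and measured areas refer to the same contour of the rendered object.
CELL_FOOTPRINT_LEVEL = 3000.0
MYO_FOOTPRINT_LEVEL = 1000.0

MENISCUS_RING_SIGMA_UM = 60.0

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548


@dataclass
class CellSpot:
    """One cell: position, rendered spot diameter (FWHM) and amplitude."""

    x_um: float
    y_um: float
    spot_diameter_um: float
    amplitude: float = CELL_SPOT_AMPLITUDE

    @property
    def sigma_um(self) -> float:
        return self.spot_diameter_um / _FWHM

    def footprint_um2(self, level: float = CELL_FOOTPRINT_LEVEL) -> float:
        """Analytic area enclosed by the given iso-intensity contour."""
        if self.amplitude <= level:
            return 0.0
        r = self.sigma_um * math.sqrt(2.0 * math.log(self.amplitude / level))
        return math.pi * r * r


@dataclass
class Myotube:
    """One myotube: polyline control points (µm), ridge width (FWHM), amplitude."""

    points: np.ndarray  # (n, 2) x/y in µm relative to the well center
    width_um: float
    amplitude: float = MYO_RIDGE_AMPLITUDE

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)

    @property
    def sigma_um(self) -> float:
        return self.width_um / _FWHM

    @property
    def length_um(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    def footprint_um2(self, level: float = MYO_FOOTPRINT_LEVEL) -> float:
        """Analytic ridge footprint (rounded-rectangle) at the given level."""
        if self.amplitude <= level:
            return 0.0
        half = self.sigma_um * math.sqrt(2.0 * math.log(self.amplitude / level))
        return self.length_um * 2.0 * half + math.pi * half * half


@dataclass
class SceneTruth:
    """Ground truth of one well at one timepoint.

    Coordinates are µm relative to the well center.  The rasterized
    myotube area is filled in by the renderer (``None`` until a frame
    has been rendered); the analytic footprint sum is always available
    via :meth:`analytic_myotube_area_um2`.
    """

    cells: list[CellSpot] = field(default_factory=list)
    myotubes: list[Myotube] = field(default_factory=list)
    well_diameter_um: float = P384.well_diameter_um
    true_myotube_area_um2: float | None = None

    @property
    def true_cell_count(self) -> int:
        return len(self.cells)

    def analytic_myotube_area_um2(self, level: float = MYO_FOOTPRINT_LEVEL) -> float:
        return sum(m.footprint_um2(level) for m in self.myotubes)

    def analytic_cell_coverage_um2(self, level: float = CELL_FOOTPRINT_LEVEL) -> float:
        return sum(c.footprint_um2(level) for c in self.cells)

    def cells_within_radius(self, radius_um: float) -> int:
        return sum(1 for c in self.cells if math.hypot(c.x_um, c.y_um) <= radius_um)

    def shifted(self, dx_um: float, dy_um: float) -> "SceneTruth":
        return SceneTruth(
            cells=[replace(c, x_um=c.x_um + dx_um, y_um=c.y_um + dy_um) for c in self.cells],
            myotubes=[
                Myotube(m.points + np.array([dx_um, dy_um]), m.width_um, m.amplitude)
                for m in self.myotubes
            ],
            well_diameter_um=self.well_diameter_um,
        )


@dataclass(frozen=True)
class AcquisitionModel:
    """Rendering/acquisition settings for one channel.

    ``meniscus_ring`` is ``(inner_radius_fraction, amplitude)``: a
    bright Gaussian ring at that fraction of the well radius, emulating
    the meniscus-distorted rim that makes the outer well unusable.
    ``defocus_z_um`` is metadata only.
    """

    um_per_px: float = 3.2
    bit_depth: int = 16
    background_level: float = 8000.0
    vignette_strength: float = 0.05
    meniscus_ring: tuple[float, float] = (0.88, 12000.0)
    read_noise_sd: float = 100.0
    shot_noise: bool = True
    channel: Channel = Channel.CELL_DEFOCUS
    defocus_z_um: float = 2400.0

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.bit_depth != 16:
            raise ValueError("only 16-bit rendering is supported")

    def for_channel(self, channel: Channel, fmt: PlateFormat = P96) -> "AcquisitionModel":
        z = DEFOCUS_Z_UM.get((fmt.name, Channel(channel)), 0.0)
        return replace(self, channel=Channel(channel), defocus_z_um=z)


def random_scene(
    n_cells: int,
    rng: np.random.Generator,
    well_diameter_um: float = P384.well_diameter_um,
    placement_diameter_um: float | None = None,
    spot_diameter_range_um: tuple[float, float] = (20.0, 32.0),
    amplitude: float = CELL_SPOT_AMPLITUDE,
    min_separation_um: float | None = None,
    n_myotubes: int = 0,
    myotube_width_range_um: tuple[float, float] = (15.0, 40.0),
    myotube_length_range_um: tuple[float, float] = (150.0, 1500.0),
) -> SceneTruth:
    """Random ground-truth scene with cells (and optionally myotubes).

    Cells are placed uniformly inside the circle of
    ``placement_diameter_um`` (default: the whole well); with
    ``min_separation_um`` set, positions are drawn by dart throwing so
    spots stay disjoint.
    """
    r_max = (placement_diameter_um or well_diameter_um) / 2.0
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n_cells:
        rr = r_max * math.sqrt(rng.uniform())
        th = rng.uniform(0.0, 2.0 * math.pi)
        x, y = rr * math.cos(th), rr * math.sin(th)
        if min_separation_um is not None and any(
            math.hypot(x - px, y - py) < min_separation_um for px, py in pts
        ):
            tries += 1
            if tries > 200 * max(n_cells, 1):
                raise RuntimeError(
                    f"could not place {n_cells} cells with "
                    f"{min_separation_um} µm separation in a "
                    f"{2 * r_max:.0f} µm circle"
                )
            continue
        pts.append((x, y))
    lo, hi = spot_diameter_range_um
    cells = [
        CellSpot(x, y, float(rng.uniform(lo, hi)), amplitude) for x, y in pts
    ]
    myotubes = [
        _random_myotube(rng, r_max, myotube_width_range_um, myotube_length_range_um)
        for _ in range(n_myotubes)
    ]
    return SceneTruth(cells=cells, myotubes=myotubes, well_diameter_um=well_diameter_um)


def _random_myotube(
    rng: np.random.Generator,
    r_max: float,
    width_range: tuple[float, float],
    length_range: tuple[float, float],
    length_um: float | None = None,
) -> Myotube:
    """Gently curved polyline inside the circle of radius ``r_max``."""
    width = float(rng.uniform(*width_range))
    length = float(length_um if length_um is not None else rng.uniform(*length_range))
    n_seg = max(2, int(length // 150) + 1)
    seg = length / n_seg
    for _ in range(200):
        rr = (r_max - length / 2.0 - width) * math.sqrt(rng.uniform())
        th = rng.uniform(0.0, 2.0 * math.pi)
        x, y = max(rr, 0.0) * math.cos(th), max(rr, 0.0) * math.sin(th)
        ang = rng.uniform(0.0, 2.0 * math.pi)
        pts = [(x, y)]
        ok = True
        for _k in range(n_seg):
            ang += rng.normal(0.0, 0.25)
            x, y = x + seg * math.cos(ang), y + seg * math.sin(ang)
            if math.hypot(x, y) > r_max - width:
                ok = False
                break
            pts.append((x, y))
        if ok:
            return Myotube(np.array(pts), width, MYO_RIDGE_AMPLITUDE)
    # fall back to a straight chord through the center
    half = min(length / 2.0, r_max - width)
    return Myotube(np.array([(-half, 0.0), (half, 0.0)]), width, MYO_RIDGE_AMPLITUDE)


def _spot_patch(shape, cx_px, cy_px, sigma_px, amp):
    """(sy, sx, patch) of a Gaussian spot clipped to the image."""
    ny, nx = shape
    m = int(math.ceil(4.0 * sigma_px)) + 1
    x0, x1 = max(0, int(cx_px) - m), min(nx, int(cx_px) + m + 1)
    y0, y1 = max(0, int(cy_px) - m), min(ny, int(cy_px) + m + 1)
    if x0 >= x1 or y0 >= y1:
        return None
    xs = np.arange(x0, x1) + 0.5 - cx_px
    ys = np.arange(y0, y1) + 0.5 - cy_px
    patch = amp * np.exp(
        -(xs[np.newaxis, :] ** 2 + ys[:, np.newaxis] ** 2) / (2.0 * sigma_px**2)
    )
    return slice(y0, y1), slice(x0, x1), patch


def _ridge_patch(shape, pts_px, sigma_px, amp):
    """(sy, sx, patch) of a Gaussian-profile ridge along a polyline.

    Intensity is ``amp * exp(-d^2 / 2 sigma^2)`` with ``d`` the distance
    to the polyline (max-composited over segments, so joints do not
    double-brighten); end caps are round.
    """
    ny, nx = shape
    m = 4.0 * sigma_px + 1.0
    x0 = max(0, int(pts_px[:, 0].min() - m))
    x1 = min(nx, int(pts_px[:, 0].max() + m) + 1)
    y0 = max(0, int(pts_px[:, 1].min() - m))
    y1 = min(ny, int(pts_px[:, 1].max() + m) + 1)
    if x0 >= x1 or y0 >= y1:
        return None
    xs = np.arange(x0, x1) + 0.5
    ys = np.arange(y0, y1) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    d2 = np.full(gx.shape, np.inf)
    for (ax, ay), (bx, by) in zip(pts_px[:-1], pts_px[1:]):
        vx, vy = bx - ax, by - ay
        vv = vx * vx + vy * vy
        if vv == 0:
            t = np.zeros_like(gx)
        else:
            t = np.clip(((gx - ax) * vx + (gy - ay) * vy) / vv, 0.0, 1.0)
        dx = gx - (ax + t * vx)
        dy = gy - (ay + t * vy)
        d2 = np.minimum(d2, dx * dx + dy * dy)
    patch = amp * np.exp(-d2 / (2.0 * sigma_px**2))
    return slice(y0, y1), slice(x0, x1), patch


def default_image_px(well_diameter_um: float, um_per_px: float) -> int:
    """Image side length: the well bounding square, rounded up to 32 px."""
    n = int(math.ceil(well_diameter_um / um_per_px))
    return ((n + 31) // 32) * 32


def render_frame(
    truth: SceneTruth,
    acq: AcquisitionModel,
    image_px: int | None = None,
    rng: np.random.Generator | None = None,
    well_id: str = "",
    t_h: float = 0.0,
) -> ImageFrame:
    """Render one 16-bit well frame for the acquisition's channel.

    Also rasterizes each myotube's footprint (pixels above
    ``MYO_FOOTPRINT_LEVEL`` in its own noiseless layer) and stores the
    sum back on ``truth.true_myotube_area_um2``.
    """
    upp = acq.um_per_px
    n = image_px or default_image_px(truth.well_diameter_um, upp)
    shape = (n, n)
    half_um = n * upp / 2.0

    def to_px(x_um, y_um):
        return (x_um + half_um) / upp, (y_um + half_um) / upp

    channel = Channel(acq.channel)
    # --- background, vignette, meniscus ring -------------------------------
    xs = (np.arange(n) + 0.5) * upp - half_um
    r_um = np.hypot(xs[np.newaxis, :], xs[:, np.newaxis])
    if channel is Channel.NUCLEI_FLUOR:
        img = np.full(shape, NUCLEI_BACKGROUND, dtype=np.float64)
    else:
        r_corner = half_um * math.sqrt(2.0)
        img = acq.background_level * (
            1.0 - acq.vignette_strength * (r_um / r_corner) ** 2
        )
        ring_frac, ring_amp = acq.meniscus_ring
        if ring_amp > 0:
            ring_r = ring_frac * truth.well_diameter_um / 2.0
            img += ring_amp * np.exp(
                -((r_um - ring_r) ** 2) / (2.0 * MENISCUS_RING_SIGMA_UM**2)
            )

    # --- objects -----------------------------------------------------------
    if channel is Channel.CELL_DEFOCUS:
        cell_scale, myo_scale = 1.0, MYO_BLEED_IN_CELL_CHANNEL
    elif channel is Channel.MYO_DEFOCUS:
        cell_scale, myo_scale = CELL_BLEED_IN_MYO_CHANNEL, 1.0
    else:
        cell_scale, myo_scale = 0.0, 0.0

    if cell_scale > 0:
        for c in truth.cells:
            cx, cy = to_px(c.x_um, c.y_um)
            res = _spot_patch(shape, cx, cy, c.sigma_um / upp, c.amplitude * cell_scale)
            if res is not None:
                sy, sx, patch = res
                img[sy, sx] += patch
    if channel is Channel.NUCLEI_FLUOR:
        for c in truth.cells:
            cx, cy = to_px(c.x_um, c.y_um)
            res = _spot_patch(shape, cx, cy, NUCLEUS_FWHM_UM / _FWHM / upp, NUCLEUS_AMPLITUDE)
            if res is not None:
                sy, sx, patch = res
                img[sy, sx] += patch

    raster_area = 0.0
    for m in truth.myotubes:
        pts_px = np.column_stack(to_px(m.points[:, 0], m.points[:, 1]))
        res = _ridge_patch(shape, pts_px, m.sigma_um / upp, m.amplitude)
        if res is None:
            continue
        sy, sx, patch = res
        raster_area += float((patch >= MYO_FOOTPRINT_LEVEL).sum()) * upp * upp
        if myo_scale > 0:
            img[sy, sx] += patch * myo_scale
    truth.true_myotube_area_um2 = raster_area

    # --- noise, clip, quantize ---------------------------------------------
    if acq.shot_noise or acq.read_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        if acq.shot_noise:
            img = rng.poisson(np.maximum(img, 0.0)).astype(np.float64)
        if acq.read_noise_sd > 0:
            img += rng.normal(0.0, acq.read_noise_sd, size=shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return ImageFrame(
        pixels=img,
        um_per_px=upp,
        channel=channel,
        defocus_z_um=acq.defocus_z_um,
        well_id=well_id,
        t_h=t_h,
    )


def seed_clonal_plate(
    lam: float,
    fmt: PlateFormat = P384,
    rng_seed: int = 0,
    wells: list[str] | None = None,
) -> pd.Series:
    """Poisson(λ) initial cell counts, one draw per analyzable well.

    Limiting-dilution seeding: at λ cells/well the number of founder
    cells per well is Poisson-distributed, so a fraction exp(-λ) of
    wells stays empty.
    """
    if lam < 0:
        raise ValueError(f"seeding density must be >= 0, got {lam}")
    ids = wells if wells is not None else analyzable_wells(fmt)
    rng = np.random.default_rng(rng_seed)
    counts = rng.poisson(lam, size=len(ids))
    return pd.Series(counts, index=pd.Index(ids, name="well_id"), name="n_cells")


@dataclass(frozen=True)
class GrowthParams:
    """Phenomenological growth/differentiation parameters for one well.

    Units: cells per well, hours, h⁻¹.  ``K`` is the surface carrying
    capacity in cell-equivalents, shared between attached cells and the
    surface already covered by myotubes.  Once the total occupancy
    (cells plus myotube area in cell-equivalents) reaches
    ``diff_onset_density_fraction * K``, differentiation switches on
    and cells fuse into myotubes at ``fusion_rate`` (count falls, area
    rises).  After the area plateaus, detachment events fire at
    ``detachment_hazard`` per hour, each removing
    ``detachment_drop_fraction`` of the area.  With ``reformation`` the
    freed surface re-enters the growth/fusion loop, producing a second
    area wave; without it the lost surface stays unavailable.
    """

    n0: float = 1000.0
    r: float = 0.06
    K: float = 12000.0
    lag_h: float = 12.0
    diff_onset_density_fraction: float = 0.85
    fusion_rate: float = 0.05
    detachment_hazard: float = 0.02
    detachment_drop_fraction: float = 0.5
    reformation: bool = True
    interval_h: float = 4.0
    duration_h: float = 216.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n0 <= self.K):
            raise ValueError("require 0 < n0 <= K")
        if self.r <= 0:
            raise ValueError("growth rate must be positive")
        if self.interval_h <= 0:
            raise ValueError("interval_h must be positive")
        for name in ("diff_onset_density_fraction", "detachment_drop_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


def mean_cell_footprint_um2(
    diameter_range_um: tuple[float, float] = (20.0, 32.0),
    amplitude: float = CELL_SPOT_AMPLITUDE,
    level: float = CELL_FOOTPRINT_LEVEL,
) -> float:
    """Expected per-cell footprint area for uniformly drawn spot diameters."""
    lo, hi = diameter_range_um
    e_d2 = (lo * lo + lo * hi + hi * hi) / 3.0
    k = math.sqrt(2.0 * math.log(amplitude / level)) / _FWHM
    return math.pi * k * k * e_d2


@dataclass
class TimePoint:
    """One timepoint of a simulated live assay."""

    t_h: float
    truth: SceneTruth
    frames: dict[Channel, ImageFrame]
    n_cells: float
    myo_area_um2: float
    detachment_event: bool = False
    cum_fused_cells: float = 0.0


def _logistic_step(n: float, r: float, K: float, dt: float) -> float:
    """Exact logistic update over one interval."""
    if n <= 0:
        return 0.0
    e = math.exp(r * dt)
    return K * n * e / (K + n * (e - 1.0))


def simulate_timecourse(
    gp: GrowthParams,
    acq: AcquisitionModel | None = None,
    fmt: PlateFormat = P96,
    render_channels: tuple[Channel, ...] = (),
    image_px: int | None = None,
    well_id: str = "",
    spot_diameter_range_um: tuple[float, float] = (20.0, 32.0),
    myotube_width_range_um: tuple[float, float] = (15.0, 40.0),
) -> list[TimePoint]:
    """Simulate one well's live assay at the read interval of ``gp``.

    Pass ``render_channels`` to get rendered frames per timepoint;
    leave it empty for a fast truth-only kinetic series.
    """
    if gp.duration_h < gp.interval_h:
        logger.warning(
            "duration %.1f h is shorter than one %.1f h interval; "
            "returning a single timepoint",
            gp.duration_h,
            gp.interval_h,
        )
    acq = acq or AcquisitionModel()
    rng = np.random.default_rng(gp.rng_seed)
    rng_place, rng_fuse, rng_detach, rng_noise = rng.spawn(4)

    well_d = fmt.well_diameter_um
    r_place = 0.95 * well_d / 2.0  # keep objects clear of the rim
    dt = gp.interval_h

    def new_cell() -> CellSpot:
        rr = r_place * math.sqrt(rng_place.uniform())
        th = rng_place.uniform(0.0, 2.0 * math.pi)
        d = float(rng_place.uniform(*spot_diameter_range_um))
        return CellSpot(rr * math.cos(th), rr * math.sin(th), d)

    cells: list[CellSpot] = [new_cell() for _ in range(int(round(gp.n0)))]
    myotubes: list[Myotube] = []
    tube_areas: list[float] = []  # analytic footprint per tube, µm²

    n = float(gp.n0)
    frac_cells = 0.0  # fractional cells not yet materialized as spots
    pending_area = 0.0  # fused footprint waiting to become a tube
    diff_active = False
    prev_area = 0.0
    peak_area = 0.0
    lost_capacity = 0.0  # cell-equivalents permanently lost to detachment
    cum_fused = 0.0  # total cells that have fused into myotubes
    foot = mean_cell_footprint_um2(spot_diameter_range_um)
    points: list[TimePoint] = []

    def sync_cells(target: float) -> None:
        """Keep the discrete spot list tracking the continuous count."""
        nonlocal frac_cells
        want = int(round(target + frac_cells)) - len(cells)
        if want > 0:
            cells.extend(new_cell() for _ in range(want))
        elif want < 0:
            for _ in range(-want):
                if cells:
                    cells.pop(int(rng_place.integers(len(cells))))

    n_steps = max(1, int(math.floor(gp.duration_h / dt)) + 1)
    t = 0.0
    for _step in range(n_steps):
        area = float(sum(tube_areas))
        detach_now = False

        if points:  # advance state from the previous timepoint
            # growth: lagged logistic on the cell pool.  The carrying
            # capacity is surface area expressed in cell-equivalents, so
            # the capacity left for cells shrinks by the area already
            # occupied by myotubes (and, without reformation, by the
            # surface rendered useless by detached tubes).
            if t - dt >= gp.lag_h:
                k_eff = gp.K - area / foot - lost_capacity
                if k_eff > 0:
                    n = _logistic_step(n, gp.r, k_eff, dt)
            # density-triggered differentiation with hysteresis: fusion
            # switches on at the onset density and off only when a
            # detachment has freed a substantial part of the surface,
            # letting the culture regrow before a second wave
            occupancy = n + area / foot
            onset_occ = gp.diff_onset_density_fraction * gp.K
            if not diff_active and occupancy >= onset_occ:
                diff_active = True
            elif diff_active and occupancy < 0.7 * onset_occ:
                diff_active = False
            # fusion: cells convert to myotube area
            if diff_active and gp.fusion_rate > 0:
                n_fuse = n * (1.0 - math.exp(-gp.fusion_rate * dt))
                n -= n_fuse
                cum_fused += n_fuse
                take = int(round(n_fuse))
                for _ in range(take):
                    if cells:
                        c = cells.pop(int(rng_fuse.integers(len(cells))))
                        pending_area += c.footprint_um2()
                pending_area += (n_fuse - take) * foot
                # materialize pending area as new tubes
                while pending_area >= 2.0 * foot:
                    width = float(rng_fuse.uniform(*myotube_width_range_um))
                    sigma = width / _FWHM
                    half = sigma * math.sqrt(
                        2.0 * math.log(MYO_RIDGE_AMPLITUDE / MYO_FOOTPRINT_LEVEL)
                    )
                    cap = math.pi * half * half
                    l_max = 1500.0
                    target = min(pending_area, l_max * 2.0 * half + cap)
                    length = max((target - cap) / (2.0 * half), 150.0)
                    tube = _random_myotube(
                        rng_fuse,
                        r_place,
                        (width, width),
                        (length, length),
                        length_um=length,
                    )
                    a = tube.footprint_um2()
                    myotubes.append(tube)
                    tube_areas.append(a)
                    pending_area -= a
                    if pending_area < 0:
                        pending_area = 0.0
            area = float(sum(tube_areas))
            peak_area = max(peak_area, area)
            # the hazard is armed while the area has plateaued near its
            # historical peak: relative growth below 1 % per interval and
            # at least 80 % of the largest area seen (a reformation wave
            # must rebuild before it can detach again)
            plateaued = (
                diff_active
                and area > 0
                and prev_area > 0
                and (area - prev_area) < 0.01 * area
                and area >= 0.8 * peak_area
            )
            # stochastic detachment of plateaued myotubes
            if plateaued and gp.detachment_hazard > 0 and myotubes:
                p_event = 1.0 - math.exp(-gp.detachment_hazard * dt)
                if rng_detach.uniform() < p_event:
                    detach_now = True
                    goal = gp.detachment_drop_fraction * area
                    removed = 0.0
                    order = rng_detach.permutation(len(myotubes))
                    for idx in sorted(order.tolist(), reverse=True):
                        if removed >= goal:
                            break
                        removed += tube_areas[idx]
                        del tube_areas[idx]
                        del myotubes[idx]
                    if not gp.reformation:
                        # the vacated surface stays unavailable
                        lost_capacity += removed / foot
                    area = float(sum(tube_areas))
            prev_area = area
            sync_cells(n)
        else:
            prev_area = area

        truth = SceneTruth(
            cells=list(cells),
            myotubes=list(myotubes),
            well_diameter_um=well_d,
        )
        frames: dict[Channel, ImageFrame] = {}
        for ch in render_channels:
            frames[Channel(ch)] = render_frame(
                truth,
                acq.for_channel(ch, fmt),
                image_px=image_px,
                rng=rng_noise,
                well_id=well_id,
                t_h=t,
            )
        points.append(
            TimePoint(
                t_h=t,
                truth=truth,
                frames=frames,
                n_cells=n,
                myo_area_um2=area,
                detachment_event=detach_now,
                cum_fused_cells=cum_fused,
            )
        )
        t += dt
    return points


def simulate_clonal_screen(
    lam: float = 0.85,
    fmt: PlateFormat = P384,
    days: tuple[int, ...] = (7, 8),
    rng_seed: int = 0,
    growth_rate_mean: float = 0.065,
    growth_rate_cv: float = 0.0,
    lag_h: float = 24.0,
    K: float = 8000.0,
    fusion_rate: float = 0.08,
    diff_onset_density_fraction: float = 0.85,
) -> pd.DataFrame:
    """Limiting-dilution screen: per-well truth counts/areas at read days.

    Seeds every analyzable well with Poisson(λ) founder cells and grows
    each clone with the live-assay state equations (lagged logistic to
    the surface capacity ``K``, then density-triggered fusion; no
    detachment on this short timescale).  ``growth_rate_cv`` adds
    log-normal clone-to-clone variation in the growth rate, emulating
    the heterogeneity of freshly isolated satellite-cell populations;
    zero means every clone is equally fast.

    Returns a table with one row per well and day: ``well_id, day,
    n_founders, cell_count, myo_area_um2``.
    """
    founders = seed_clonal_plate(lam, fmt, rng_seed)
    rng = np.random.default_rng(rng_seed + 1)
    duration = 24.0 * max(days)
    rows = []
    for well_id, k in founders.items():
        seed_w = int(rng.integers(2**31 - 1))
        r = growth_rate_mean
        if growth_rate_cv > 0:
            sigma = math.sqrt(math.log(1.0 + growth_rate_cv**2))
            r = growth_rate_mean * float(
                np.exp(rng.normal(-0.5 * sigma**2, sigma))
            )
        if k == 0:
            for day in days:
                rows.append(
                    {
                        "well_id": well_id,
                        "day": day,
                        "n_founders": 0,
                        "cell_count": 0.0,
                        "myo_area_um2": 0.0,
                    }
                )
            continue
        gp = GrowthParams(
            n0=float(k),
            r=r,
            K=K,
            lag_h=lag_h,
            diff_onset_density_fraction=diff_onset_density_fraction,
            fusion_rate=fusion_rate,
            detachment_hazard=0.0,
            duration_h=duration,
            rng_seed=seed_w,
        )
        points = simulate_timecourse(gp, fmt=fmt)
        by_t = {p.t_h: p for p in points}
        for day in days:
            p = by_t[24.0 * day]
            rows.append(
                {
                    "well_id": well_id,
                    "day": day,
                    "n_founders": int(k),
                    "cell_count": p.n_cells,
                    "myo_area_um2": p.myo_area_um2,
                }
            )
    return pd.DataFrame(rows)


def two_wave_params(rng_seed: int = 0) -> GrowthParams:
    """Forced early-detachment scenario with one full reformation wave.

    A dense, fast-fusing culture plateaus early; a near-certain hazard
    detaches 85 % of the myotube area right after the plateau, the
    freed surface is recolonized, and the assay ends at the rebuilt
    second maximum -- the two-peak trace characteristic of myotube
    detachment followed by reformation (one detachment event, two area
    peaks of similar height).
    """
    return GrowthParams(
        n0=2000.0,
        r=0.08,
        K=12000.0,
        lag_h=8.0,
        diff_onset_density_fraction=0.8,
        fusion_rate=0.12,
        detachment_hazard=2.0,
        detachment_drop_fraction=0.85,
        reformation=True,
        duration_h=184.0,
        rng_seed=rng_seed,
    )


def density_ladder(
    densities: tuple[int, ...] = (50, 100, 200, 400, 800, 1600),
    n_replicates: int = 4,
    acq: AcquisitionModel | None = None,
    fmt: PlateFormat = P384,
    rng_seed: int = 0,
    image_px: int | None = None,
) -> list[tuple[int, int, SceneTruth, ImageFrame]]:
    """Seeded density ladder for method-agreement validation.

    Renders ``n_replicates`` cell-channel wells at each seeding density
    from sparse to sub-confluent and returns
    ``(density, replicate, truth, frame)`` tuples.
    """
    acq = acq or AcquisitionModel()
    acq = acq.for_channel(Channel.CELL_DEFOCUS, fmt)
    rng = np.random.default_rng(rng_seed)
    out = []
    for density in densities:
        for rep in range(n_replicates):
            scene_rng, noise_rng = rng.spawn(2)
            truth = random_scene(
                density,
                scene_rng,
                well_diameter_um=fmt.well_diameter_um,
                min_separation_um=30.0,
            )
            frame = render_frame(
                truth,
                acq,
                image_px=image_px,
                rng=noise_rng,
                well_id=f"D{density}R{rep}",
            )
            out.append((density, rep, truth, frame))
    return out
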