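"""Limiting-dilution clonal myogenicity screen.

Seeding a 384-well plate at λ < 1 cells/well makes the per-well founder
count Poisson-distributed, so single-cell clones can be screened
without sorting: at the λ = 0.85 used for the screen, ~43 % of wells
stay empty, ~36 % receive exactly one cell and under ~5 % receive
three or more.  After a week of culture each analyzable well is called
*cell-positive* (enough cells to rule out debris) and/or
*myo-positive* (enough myotube area to rule out dense non-myogenic
clusters), and the plate is summarized as the percentage of
cell-positive wells out of all tested wells and of myo-positive wells
out of the cell-positive ones.

In screening mode both analyses run on the same extra-defocused
(myotube) frame: counting on that channel is slightly less precise but
halves imaging time and data volume, and calls inherit a
``reduced_precision`` flag to record it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .frames import Channel, ImageFrame
from .quant import CELL_COUNT_HCBF, MYO_QUANT_HCBF, AnalysisParams, cell_count, myo_quant

__all__ = [
    "ScreenThresholds",
    "CloneCall",
    "poisson_occupancy",
    "classify_well",
    "screen_summary",
    "screen_frames",
    "occupancy_gof",
]


@dataclass(frozen=True)
class ScreenThresholds:
    """Per-well positivity thresholds.

    Defaults: 120 cells (below that, debris and plate artefacts can
    fake a positive) and 60 000 µm² of myotube area (below that, dense
    non-myogenic clusters can).
    """

    cell_positive_min: float = 120.0
    myo_positive_min_area: float = 60_000.0

    def __post_init__(self) -> None:
        if self.cell_positive_min <= 0 or self.myo_positive_min_area <= 0:
            raise ValueError("screen thresholds must be positive")


@dataclass
class CloneCall:
    """Per-well screening verdict with the measurements behind it."""

    well_id: str
    day: int
    cell_count: float
    myo_area_um2: float
    cell_positive: bool
    myo_positive: bool
    flags: tuple[str, ...] = ()


def poisson_occupancy(lam: float, k_max: int = 4) -> tuple[np.ndarray, float]:
    """P(0..k_max) founder cells per well plus the tail P(> k_max).

    P(k) = λᵏ e^(−λ) / k!; the tail is the exact complement, so the
    probabilities and the tail sum to 1.
    """
    if lam < 0:
        raise ValueError(f"seeding density must be >= 0, got {lam}")
    k = np.arange(k_max + 1)
    probs = stats.poisson.pmf(k, lam)
    tail = float(max(0.0, 1.0 - probs.sum()))
    return probs, tail


def classify_well(
    well_id: str,
    cell_count: float,
    myo_area_um2: float,
    thr: ScreenThresholds = ScreenThresholds(),
    day: int = 0,
    flags: tuple[str, ...] = (),
) -> CloneCall:
    """Binary positivity call for one well.

    A well is myo-positive when its myotube area reaches the area
    threshold.  A well is cell-positive when its count reaches the
    count threshold *or* it is myo-positive: a fully fused well may
    have few countable cells left, yet must stay in the cell-positive
    denominator used for the myo-positive percentage.
    """
    if cell_count < 0 or myo_area_um2 < 0:
        raise ValueError("counts and areas must be non-negative")
    myo_pos = myo_area_um2 >= thr.myo_positive_min_area
    cell_pos = cell_count >= thr.cell_positive_min or myo_pos
    return CloneCall(
        well_id=well_id,
        day=day,
        cell_count=cell_count,
        myo_area_um2=myo_area_um2,
        cell_positive=cell_pos,
        myo_positive=myo_pos,
        flags=flags,
    )


def screen_summary(calls: list[CloneCall]) -> pd.DataFrame:
    """Plate summary with explicit denominators, one row per day.

    Columns: ``n_wells, n_cell_positive, n_myo_positive,
    pct_cell_positive`` (of all wells) and ``pct_myo_positive`` (of the
    cell-positive wells; 0 of 0 is reported as 0).  With two days the
    day-over-day deltas can be read directly across rows.
    """
    if not calls:
        raise ValueError("no clone calls supplied")
    rows = []
    for day in sorted({c.day for c in calls}):
        sub = [c for c in calls if c.day == day]
        n = len(sub)
        ncp = sum(c.cell_positive for c in sub)
        nmp = sum(c.myo_positive for c in sub)
        rows.append(
            {
                "day": day,
                "n_wells": n,
                "n_cell_positive": ncp,
                "n_myo_positive": nmp,
                "pct_cell_positive": 100.0 * ncp / n,
                "pct_myo_positive": (100.0 * nmp / ncp) if ncp else 0.0,
            }
        )
    return pd.DataFrame(rows)


def screen_frames(
    frames: dict[str, ImageFrame],
    thr: ScreenThresholds = ScreenThresholds(),
    day: int = 0,
    count_params: AnalysisParams = CELL_COUNT_HCBF,
    myo_params: AnalysisParams = MYO_QUANT_HCBF,
) -> list[CloneCall]:
    """Classify wells from single-channel screening frames.

    Each well contributes one extra-defocused frame on which both the
    cell count and the myo-quant are evaluated (single-channel mode);
    counts made on the myotube channel carry a ``reduced_precision``
    flag.
    """
    calls = []
    for well_id, frame in sorted(frames.items()):
        flags: tuple[str, ...] = ()
        if Channel(frame.channel) is Channel.MYO_DEFOCUS:
            flags = ("reduced_precision",)
        n = cell_count(frame, count_params)
        a = myo_quant(frame, myo_params)
        calls.append(classify_well(well_id, n, a, thr, day=day, flags=flags))
    return calls


def occupancy_gof(observed_counts: np.ndarray, lam: float, k_max: int = 4):
    """Chi-square goodness of fit of empirical occupancy to Poisson(λ).

    Bins 0..k_max plus a pooled tail; returns the scipy chisquare
    result.  Used to check that simulated limiting-dilution plates
    actually follow the occupancy model.
    """
    observed_counts = np.asarray(observed_counts)
    n = observed_counts.size
    probs, tail = poisson_occupancy(lam, k_max)
    expected = np.append(probs, tail) * n
    obs_hist = np.array(
        [(observed_counts == k).sum() for k in range(k_max + 1)]
        + [(observed_counts > k_max).sum()]
    )
    # pool sparse tail bins so the chi-square approximation holds
    while len(expected) > 2 and expected[-1] < 5:
        expected[-2] += expected[-1]
        obs_hist[-2] += obs_hist[-1]
        expected = expected[:-1]
        obs_hist = obs_hist[:-1]
    return stats.chisquare(obs_hist, expected)
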