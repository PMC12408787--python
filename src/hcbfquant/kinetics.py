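"""Per-well kinetic series and live-assay feature extraction.

A live assay reads every well on a uniform grid (nominally every 4 h)
on two channels, giving a cell-count series and a myotube-area series
per well.  The features read off those curves are: the growth plateau
(maximum and its timing), the differentiation onset (the drop in cell
count from its plateau coinciding with the myotube-area rise), myotube
detachment events (abrupt sustained drops in area from the running
peak), and the number of area peaks (detachment followed by reformation
gives two).

Event thresholds (25 % sustained drop for detachment; 10 % count drop
plus 5 % area rise for onset) are operational defaults for events that
are conventionally identified by eye; all are keyword-exposed.  Series
are median-filtered (window 3) before feature extraction, which is
robust to single-frame segmentation glitches without shifting event
timing by more than one interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, medfilt

__all__ = [
    "KineticSeries",
    "KineticFeatures",
    "aggregate",
    "plateau",
    "differentiation_onset",
    "detect_detachment",
    "count_peaks",
    "fit_logistic",
    "extract_features",
]


@dataclass
class KineticSeries:
    """One well's time-series of a single metric (counts or µm²)."""

    well_id: str
    channel: str
    times: np.ndarray
    values: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D and the same length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class KineticFeatures:
    """Derived features of one well's kinetic pair."""

    lag_h: float | None
    max_value: float
    t_max_h: float
    growth_rate: float | None
    onset_h: float | None
    detachment_events: list[tuple[float, float]]
    n_peaks: int


def _medfilt3(values: np.ndarray) -> np.ndarray:
    if len(values) < 3:
        return np.asarray(values, dtype=np.float64)
    return medfilt(np.asarray(values, dtype=np.float64), kernel_size=3)


def aggregate(replicates: list[KineticSeries]) -> pd.DataFrame:
    """Per-timepoint mean, SD and SEM (= SD/sqrt(n)) over replicate wells.

    Requires identical time grids; raises listing the offending wells
    otherwise.  NaN values (missing reads) are tolerated and lower the
    per-timepoint ``n``; a timepoint with n = 1 has undefined SD/SEM
    (reported NaN) and is flagged.
    """
    if not replicates:
        raise ValueError("no replicate series supplied")
    ref = replicates[0].times
    bad = [s.well_id for s in replicates if not np.array_equal(s.times, ref)]
    if bad:
        raise ValueError(f"replicates have mismatched time grids: wells {bad}")
    mat = np.vstack([s.values for s in replicates])
    n = np.sum(~np.isnan(mat), axis=0)
    mean = np.nanmean(mat, axis=0)
    with np.errstate(invalid="ignore"):
        sd = np.where(n > 1, np.nanstd(mat, axis=0, ddof=1), np.nan)
    sem = sd / np.sqrt(np.maximum(n, 1))
    return pd.DataFrame(
        {
            "t_h": ref,
            "mean": mean,
            "sd": sd,
            "sem": sem,
            "n": n,
            "flag_single_replicate": n <= 1,
        }
    )


def plateau(series: KineticSeries, rel_tol: float = 0.02) -> tuple[float, float, bool]:
    """(t_max_h, max_value, plateau_reached) of a median-filtered series.

    The plateau is considered reached when the pre-maximum slope over
    the last three intervals is below ``rel_tol * max`` per interval.
    """
    if len(series) < 5:
        raise ValueError("plateau needs at least 5 timepoints")
    sm = _medfilt3(series.values)
    i = int(np.argmax(sm))
    m = float(sm[i])
    t_max = float(series.times[i])
    back = min(3, i)
    slope = 0.0 if back == 0 else (sm[i] - sm[i - back]) / back
    return t_max, m, bool(slope < rel_tol * m)


def differentiation_onset(
    count_series: KineticSeries,
    myo_series: KineticSeries,
    count_drop_fraction: float = 0.10,
    sustain_intervals: int = 2,
    myo_rise_fraction: float = 0.05,
) -> float | None:
    """Earliest time at which differentiation is under way, or ``None``.

    Requires both signatures simultaneously: the cell count has dropped
    at least ``count_drop_fraction`` below its running maximum and stays
    there for ``sustain_intervals`` reads, and the myotube area exceeds
    ``myo_rise_fraction`` of its eventual maximum.
    """
    if not np.array_equal(count_series.times, myo_series.times):
        raise ValueError("count and myo series must share one time grid")
    counts = _medfilt3(count_series.values)
    myo = _medfilt3(myo_series.values)
    myo_max = float(np.max(myo)) if len(myo) else 0.0
    if myo_max <= 0:
        return None
    runmax = np.maximum.accumulate(counts)
    dropped = counts <= (1.0 - count_drop_fraction) * runmax
    nt = len(counts)
    for i in range(nt):
        j = min(nt, i + sustain_intervals)
        if j - i < sustain_intervals:
            break
        if np.all(dropped[i:j]) and myo[i] >= myo_rise_fraction * myo_max:
            return float(count_series.times[i])
    return None


def detect_detachment(
    myo_series: KineticSeries,
    drop_fraction_min: float = 0.25,
    sustain_intervals: int = 2,
) -> list[tuple[float, float]]:
    """Myotube detachment events as ``(t_h, drop_fraction)`` tuples.

    An event fires when the (median-filtered) area falls at least
    ``drop_fraction_min`` below the running peak and stays below for
    ``sustain_intervals`` reads.  The running peak resets after each
    event, so a reformation wave and its later detachment are detected
    as separate events.
    """
    if len(myo_series) < 5:
        raise ValueError("detect_detachment needs at least 5 timepoints")
    v = _medfilt3(myo_series.values)
    t = myo_series.times
    events: list[tuple[float, float]] = []
    peak = v[0]
    i = 1
    nt = len(v)
    while i < nt:
        peak = max(peak, v[i])
        j_end = i + sustain_intervals
        if (
            peak > 0
            and v[i] <= (1.0 - drop_fraction_min) * peak
            and j_end <= nt
            and np.all(v[i:j_end] <= (1.0 - drop_fraction_min) * peak)
        ):
            events.append((float(t[i]), float(1.0 - v[i] / peak)))
            peak = v[i]  # reset for second-wave detection
            i = j_end
        else:
            i += 1
    return events


def count_peaks(myo_series: KineticSeries, prominence_fraction: float = 0.2) -> int:
    """Number of prominent local maxima of the median-filtered series.

    Prominence threshold is ``prominence_fraction`` of the global
    maximum; boundary maxima count (a monotone rise has one peak, at
    the end).  An everywhere-constant series has none.
    """
    v = _medfilt3(myo_series.values)
    vmax = float(np.max(v)) if len(v) else 0.0
    if vmax <= 0 or np.ptp(v) == 0:
        return 0
    pad = float(np.min(v)) - vmax  # low enough to expose boundary peaks
    padded = np.concatenate([[pad], v, [pad]])
    peaks, _ = find_peaks(padded, prominence=prominence_fraction * vmax)
    return int(len(peaks))


def _lagged_logistic(t, n0, r, K, lag):
    tt = np.maximum(t - lag, 0.0)
    return K * n0 * np.exp(r * tt) / (K + n0 * (np.exp(r * tt) - 1.0))


def fit_logistic(
    series: KineticSeries, relative_sigma: float | None = None
) -> dict[str, float]:
    """Least-squares fit of a lagged logistic; returns n0, r, K, lag_h.

    Initialisation: K from the series maximum, n0 from the first value,
    r from the log-slope over the early rise.  ``relative_sigma``
    enables weighted least squares with per-point sigma proportional to
    the value (floored at one count) -- the right weighting when the
    measurement error scales with the count, as it does for cell
    counting.
    """
    t = series.times
    v = series.values
    if len(t) < 5:
        raise ValueError("fit_logistic needs at least 5 timepoints")
    k0 = max(float(np.max(v)), 1e-9)
    early = v[: max(3, len(v) // 4)]
    pos = early[early > 0]
    r_est = 0.05
    if len(pos) >= 2:
        dt = t[1] - t[0]
        r_est = max(1e-4, float(np.polyfit(np.arange(len(pos)) * dt, np.log(pos), 1)[0]))
    # n0 and the lag trade off against each other in noisy data, so a
    # single start can settle in a degenerate minimum; take the best of
    # several starts by residual
    n0_first = min(max(float(v[0]), k0 / 1000.0), k0)
    starts = [
        (n0_first, r_est, k0, 0.0),
        (n0_first, 0.05, k0, 0.0),
        (k0 / 30.0, r_est, k0, 0.0),
        (k0 / 30.0, 0.03, k0, float(t[len(t) // 8])),
    ]
    bounds = (
        [1e-9, 1e-5, 1e-9, 0.0],
        [np.inf, 5.0, np.inf, max(float(t[-1]), 1.0)],
    )
    sigma = None
    if relative_sigma is not None:
        sigma = np.maximum(np.abs(v) * relative_sigma, 1.0)
    best: tuple[float, np.ndarray] | None = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                _lagged_logistic, t, v, p0=p0, bounds=bounds, sigma=sigma,
                maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = v - _lagged_logistic(t, *popt)
        if sigma is not None:
            resid = resid / sigma
        sse = float(np.sum(resid**2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError("logistic fit failed to converge from any start")
    popt = best[1]
    return {"n0": popt[0], "r": popt[1], "K": popt[2], "lag_h": popt[3]}


def extract_features(
    count_series: KineticSeries,
    myo_series: KineticSeries | None = None,
    fit_growth: bool = False,
) -> KineticFeatures:
    """Bundle the standard feature set for one well."""
    t_max, max_v, _ = plateau(count_series)
    growth_rate = None
    lag = None
    if fit_growth:
        fit = fit_logistic(count_series)
        growth_rate = float(fit["r"])
        lag = float(fit["lag_h"])
    onset = None
    events: list[tuple[float, float]] = []
    n_peaks = 0
    if myo_series is not None:
        onset = differentiation_onset(count_series, myo_series)
        events = detect_detachment(myo_series)
        n_peaks = count_peaks(myo_series)
    return KineticFeatures(
        lag_h=lag,
        max_value=max_v,
        t_max_h=t_max,
        growth_rate=growth_rate,
        onset_h=onset,
        detachment_events=events,
        n_peaks=n_peaks,
    )


def series_from_results(
    df: pd.DataFrame,
    metric: str,
    well_id: str,
    group: str = "",
) -> KineticSeries:
    """Build a KineticSeries from a long-format results table.

    Expects columns ``well_id, t_h, metric, value``; missing timepoints
    (NaN) are linearly interpolated for feature extraction.
    """
    sel = df[(df["well_id"] == well_id) & (df["metric"] == metric)].sort_values("t_h")
    t = sel["t_h"].to_numpy(dtype=float)
    v = sel["value"].to_numpy(dtype=float)
    if np.any(np.isnan(v)):
        good = ~np.isnan(v)
        v = np.interp(t, t[good], v[good])
    return KineticSeries(well_id=well_id, channel=metric, times=t, values=v, group=group)
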