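"""Per-pixel detection of abrupt bursts of motion ("cellular paroxysms").

During UV-induced cell death the temporal interference trace of a pixel can
switch, within a single frame, from quiescent fluctuation to large-amplitude
motion.  Localizing that switch per pixel turns a whole-acquisition movie
into an event-timing map with single-exposure temporal resolution, from
which onset histograms and synchrony statistics follow.

Detection is an exhaustive single-changepoint scan minimizing the summed
Gaussian negative log-likelihood of the two segments with segment-wise mean
*and* variance (observed bursts shift both the baseline and the fluctuation
amplitude), accepted when the improvement over the no-change model exceeds
a BIC-like penalty ``c * ln(n)`` (three extra parameters: second mean,
second variance, change location).  The scan is O(n) per pixel via running
sums and fully vectorized across pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .cubes import TemporalCube

__all__ = [
    "EventTimingMap",
    "SynchronyReport",
    "detect_changepoint",
    "event_timing_map",
    "onset_histogram",
    "required_diffusion_rate",
    "synchrony_report",
    "default_penalty",
]

MIN_SEGMENT = 3
#: penalty multiplier on the 2x log-likelihood scale, chosen by null
#: calibration so that pure stationary noise triggers in < 5% of traces
PENALTY_COEFF = 1.3


def default_penalty(n: int) -> float:
    """BIC-like penalty ``PENALTY_COEFF * 3 * ln(n)`` (3 extra parameters)."""
    return PENALTY_COEFF * 3.0 * math.log(n)


def _changepoint_scan(traces: np.ndarray, penalty: float | None):
    """Vectorized single-changepoint scan over columns of ``traces`` (n, P).

    Returns (onset, score): onset frame index (-1 where no change is
    supported) and the penalized improvement of the best split.
    """
    n, p = traces.shape
    if n < 2 * MIN_SEGMENT:
        raise ValueError(f"trace length must be >= {2 * MIN_SEGMENT}")
    if penalty is None:
        penalty = default_penalty(n)

    s1 = np.vstack([np.zeros(p), np.cumsum(traces, axis=0)])
    s2 = np.vstack([np.zeros(p), np.cumsum(traces**2, axis=0)])
    total_var = s2[n] / n - (s1[n] / n) ** 2
    floor = np.maximum(np.max(total_var), 1e-300) * 1e-12

    ts = np.arange(MIN_SEGMENT, n - MIN_SEGMENT + 1)
    tl = ts[:, None].astype(np.float64)
    tr = n - tl
    var_l = s2[ts] / tl - (s1[ts] / tl) ** 2
    var_r = (s2[n] - s2[ts]) / tr - ((s1[n] - s1[ts]) / tr) ** 2
    cost = tl * np.log(np.maximum(var_l, floor)) + tr * np.log(np.maximum(var_r, floor))
    best = np.argmin(cost, axis=0)
    cols = np.arange(p)
    null_cost = n * np.log(np.maximum(total_var, floor))
    score = null_cost - cost[best, cols]      # 2x log-likelihood improvement
    onset = np.where(score > penalty, ts[best], -1)
    return onset, score


def detect_changepoint(trace: np.ndarray, penalty: float | None = None,
                       statistic: str = "meanvar"):
    """Most likely single changepoint of one trace, or ``None``.

    The returned index is the first frame of the post-change regime.
    ``penalty`` defaults to :func:`default_penalty`; a constant trace
    yields ``None`` (no error).
    """
    if statistic != "meanvar":
        raise ValueError(f"unknown statistic {statistic!r}")
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1 or trace.size < 16:
        raise ValueError("trace must be 1-D with length >= 16")
    if np.ptp(trace) == 0:
        return None
    onset, _ = _changepoint_scan(trace[:, None], penalty)
    return int(onset[0]) if onset[0] >= 0 else None


@dataclass
class EventTimingMap:
    """Per-pixel changepoint frame index (or -1), time, and score."""

    onset_frame: np.ndarray          # int, -1 where no event
    score: np.ndarray
    frame_interval: float
    valid_mask: np.ndarray = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.valid_mask is None:
            self.valid_mask = self.onset_frame >= 0

    @property
    def onset_time(self) -> np.ndarray:
        """Onset in seconds (nan where no event)."""
        return np.where(self.valid_mask,
                        self.onset_frame * self.frame_interval, np.nan)

    @property
    def n_events(self) -> int:
        return int(self.valid_mask.sum())


def event_timing_map(cube: TemporalCube, penalty: float | None = None) -> EventTimingMap:
    """Apply the changepoint scan to every pixel of a temporal cube."""
    n = cube.n_frames
    ny, nx = cube.spatial_shape
    traces = cube.intensities.reshape(n, ny * nx)
    onset, score = _changepoint_scan(traces, penalty)
    used = penalty if penalty is not None else default_penalty(n)
    return EventTimingMap(
        onset_frame=onset.reshape(ny, nx), score=score.reshape(ny, nx),
        frame_interval=cube.meta.frame_interval,
        provenance={"penalty": used, "statistic": "meanvar",
                    "min_segment": MIN_SEGMENT})


def onset_histogram(timing_map: EventTimingMap):
    """Fraction of event pixels per frame offset from the earliest onset.

    Returns ``(offsets, fractions, cumulative)``; offsets are integer frame
    counts after the first onset, fractions sum to one over event pixels.
    """
    onsets = timing_map.onset_frame[timing_map.valid_mask]
    if onsets.size == 0:
        raise ValueError("timing map contains no events")
    rel = onsets - onsets.min()
    offsets = np.arange(rel.max() + 1)
    fractions = np.bincount(rel) / rel.size
    return offsets, fractions, np.cumsum(fractions)


_MSD_DIMS = {"1d": 1, "2d": 2, "3d": 3, "planar": 2}


def required_diffusion_rate(distance_um: float, time_s: float,
                            msd_convention: str = "2d") -> float:
    """Diffusion coefficient needed to cover ``distance`` in ``time``.

    From the mean-squared displacement ``<r^2> = 2 d D t``:
    ``D = L^2 / (2 d t)`` with dimensionality ``d`` per ``msd_convention``
    (default planar, d = 2).
    """
    if time_s <= 0:
        raise ValueError("time must be positive")
    if distance_um < 0:
        raise ValueError("distance must be >= 0")
    d = _MSD_DIMS.get(str(msd_convention).lower())
    if d is None:
        raise ValueError(f"unknown MSD convention {msd_convention!r}")
    return distance_um**2 / (2.0 * d * time_s)


@dataclass
class SynchronyReport:
    """Spatial synchrony of the earliest-onset pixels."""

    offsets: np.ndarray
    fractions: np.ndarray
    cumulative: np.ndarray
    max_distance_first_frame_um: float
    required_regulator_D: float      # um^2/s
    msd_convention: str
    n_event_pixels: int


def _max_pairwise_distance(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 64:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (collinear) inputs
            pass
    return float(pdist(points).max())


def synchrony_report(timing_map: EventTimingMap, pixel_size_um: float,
                     msd_convention: str = "2d") -> SynchronyReport:
    """Maximum extent of simultaneous (first-frame) onsets and the diffusion
    rate a molecular regulator would need to span it in one frame interval.
    """
    if timing_map.n_events < 2:
        raise ValueError("synchrony analysis requires >= 2 event pixels")
    offsets, fractions, cumulative = onset_histogram(timing_map)
    first = timing_map.onset_frame[timing_map.valid_mask].min()
    ys, xs = np.nonzero(timing_map.valid_mask & (timing_map.onset_frame == first))
    pts = np.column_stack([xs, ys]).astype(np.float64) * pixel_size_um
    dist = _max_pairwise_distance(pts)
    req = required_diffusion_rate(dist, timing_map.frame_interval, msd_convention)
    return SynchronyReport(
        offsets=offsets, fractions=fractions, cumulative=cumulative,
        max_distance_first_frame_um=dist, required_regulator_D=req,
        msd_convention=str(msd_convention), n_event_pixels=timing_map.n_events)
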