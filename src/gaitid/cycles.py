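"""Gait-cycle extraction from 3D joint sequences.

The extractor works on the Euclidean distance between the two ankles
(H3.6M joints 3 and 8): its local maxima are the instants of maximal foot
separation — initial contact and terminal stance — so a full gait cycle
(two steps) spans the pattern maximum, minimum, maximum, minimum, maximum.

Pipeline: cubic-spline interpolate the joint tracks (pose data is sampled
at 20-25 fps, too coarse to hit the critical instants), recompute the ankle
distance, smooth it with a moving average, detect extrema with a sliding
slope-sign window, and segment cycles. Eight phase timestamps t_a..t_h are
assigned per cycle: t_a, t_d, t_h are separation maxima, t_c, t_f the
intervening minima, and t_b, t_e, t_g the temporal midpoints of their
flanking events (the data fix only the extrema; midpoints are a documented
convention).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .skeleton import JointSequence3D

__all__ = [
    "DistanceSeries",
    "GaitCycle",
    "PHASE_NAMES",
    "ankle_distance",
    "interpolate",
    "smooth",
    "find_extrema",
    "prune_extrema",
    "segment_cycles",
    "extract_cycles",
    "cycles_to_manifest",
]

logger = logging.getLogger(__name__)

PHASE_NAMES = ("ta", "tb", "tc", "td", "te", "tf", "tg", "th")

DEFAULT_INTERP_FACTOR = 5   # four extra samples per original gap
DEFAULT_SMOOTH_M = 12       # moving-average filter length
DEFAULT_WINDOW_N = 7        # extrema detection window


class Provenance(enum.Enum):
    RAW = "raw"
    INTERPOLATED = "interpolated"
    SMOOTHED = "smoothed"


@dataclass
class DistanceSeries:
    """Per-frame ankle-separation signal with its effective frame rate.

    ``edge_invalid`` counts samples at each end whose smoothed value averaged
    zero-padding; they are never eligible as extrema centers.
    """

    values: np.ndarray
    fps_effective: float
    provenance: Provenance = Provenance.RAW
    edge_invalid: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.isfinite(self.values).all():
            raise ValueError("distance values must be finite")
        if (self.values < 0).any():
            raise ValueError("distances cannot be negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class GaitCycle:
    """One full gait cycle (two steps) within an interpolated sequence.

    ``phase_times`` maps the eight phase labels to fractional frame indices
    on the interpolated timeline; ``source`` is the interpolated sequence
    the indices refer to.
    """

    source: JointSequence3D
    phase_times: dict[str, float]
    cycle_index: int

    def __post_init__(self) -> None:
        if tuple(sorted(self.phase_times, key=PHASE_NAMES.index)) != PHASE_NAMES:
            raise ValueError(f"phase_times must contain exactly {PHASE_NAMES}")
        ts = [self.phase_times[p] for p in PHASE_NAMES]
        if not all(a < b for a, b in zip(ts, ts[1:])):
            raise ValueError("phase timestamps must be strictly increasing")

    @property
    def ta(self) -> float:
        return self.phase_times["ta"]

    @property
    def th(self) -> float:
        return self.phase_times["th"]

    def duration_seconds(self) -> float:
        return (self.th - self.ta) / self.source.fps  # source fps is already effective


def ankle_distance(seq: JointSequence3D) -> DistanceSeries:
    """Per-frame Euclidean distance between right (3) and left (8) ankles."""
    diff = seq.joint(3) - seq.joint(8)
    return DistanceSeries(
        values=np.linalg.norm(diff, axis=1),
        fps_effective=seq.fps,
        provenance=Provenance.RAW,
    )


def interpolate(seq: JointSequence3D, factor: int = DEFAULT_INTERP_FACTOR) -> JointSequence3D:
    """Cubic-spline upsample of every joint track.

    Each original inter-frame gap receives ``factor - 1`` new samples
    (default 4), the original frames are reproduced exactly at the knots,
    and the effective frame rate scales by ``factor``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return seq.with_positions(seq.positions.copy())
    T = seq.n_frames
    if T < 4:
        raise ValueError(
            f"cubic-spline interpolation needs at least 4 frames (got {T}); skip interpolation"
        )
    t = np.arange(T, dtype=float)
    t_new = np.arange((T - 1) * factor + 1, dtype=float) / factor
    flat = seq.positions.reshape(T, -1)
    spline = CubicSpline(t, flat, axis=0)
    new = spline(t_new).reshape(len(t_new), *seq.positions.shape[1:])
    # knots must be bit-faithful to the originals
    new[::factor] = seq.positions
    return seq.with_positions(new, fps=seq.fps * factor)


def smooth(d: DistanceSeries, M: int = DEFAULT_SMOOTH_M) -> DistanceSeries:
    """Moving-average smoothing by discrete linear convolution.

    A length-``M`` uniform filter (weights 1/M) is convolved with the signal
    in "same" alignment, so the output has the input's length; the first and
    last few samples average zero-padding and are excluded from extrema
    eligibility downstream.
    """
    if M < 1:
        raise ValueError("filter size M must be >= 1")
    if len(d) < M:
        raise ValueError(f"series of length {len(d)} is shorter than filter size {M}")
    if M == 1:
        out = d.values.copy()
    else:
        out = np.convolve(d.values, np.full(M, 1.0 / M), mode="same")
        # zero-padded edge averages are clamped back into the input's range so
        # smoothing can never manufacture out-of-range values
        out = np.clip(out, d.values.min(), d.values.max())
    return DistanceSeries(
        values=out,
        fps_effective=d.fps_effective,
        provenance=Provenance.SMOOTHED,
        # zero-padding plus the range clamp distorts shapes up to a full
        # filter length from each end; extrema there are untrustworthy
        edge_invalid=M if M > 1 else 0,
    )


def find_extrema(d: DistanceSeries, N: int = DEFAULT_WINDOW_N) -> tuple[list[int], list[int]]:
    """Sliding-window extrema detection by slope signs.

    For each eligible center, slopes are taken from the center to each of
    the floor(N/2) points on either side. All left slopes positive and all
    right slopes negative marks a local maximum; the mirrored condition a
    minimum. Centers are restricted to positions whose window lies fully in
    range and outside any smoothing-contaminated edge region. Same-type
    extrema closer than ``N`` samples are merged, keeping the larger maximum
    / smaller minimum (ties keep the earlier index).
    """
    if N < 3 or N % 2 == 0:
        raise ValueError("window size N must be odd and >= 3")
    v = d.values
    if len(v) < N:
        raise ValueError(f"series of length {len(v)} is shorter than window size {N}")
    h = N // 2
    lo = max(h, d.edge_invalid)
    maxima: list[int] = []
    minima: list[int] = []
    for i in range(lo, len(v) - lo):
        c = v[i]
        left = v[i - h : i]
        right = v[i + 1 : i + 1 + h]
        # slope from left point j to center is positive iff v[j] < c
        if (left < c).all() and (right < c).all():
            maxima.append(i)
        elif (left > c).all() and (right > c).all():
            minima.append(i)
    return _dedupe(maxima, v, N, keep="max"), _dedupe(minima, v, N, keep="min")


def _dedupe(idx: list[int], v: np.ndarray, N: int, keep: str) -> list[int]:
    """Collapse same-type extrema within N samples of one another."""
    better = (lambda a, b: v[a] > v[b]) if keep == "max" else (lambda a, b: v[a] < v[b])
    out: list[int] = []
    for i in idx:
        if out and i - out[-1] < N:
            if better(i, out[-1]):
                out[-1] = i
        else:
            out.append(i)
    return out


def prune_extrema(
    d: DistanceSeries,
    maxima: list[int],
    minima: list[int],
    min_fraction: float = 0.2,
) -> tuple[list[int], list[int]]:
    """Remove low-persistence extrema left by residual estimator jitter.

    Noisy ankle-distance signals carry shallow max-min wiggles riding the
    true peaks (the motivation for smoothing in the first place); those that
    survive smoothing and the same-type merge appear as adjacent
    opposite-type event pairs whose value difference is far below a real
    swing. Pairs whose drop is under ``min_fraction`` of the median adjacent
    drop are cancelled (smallest first); adjacent same-type events exposed
    by a cancellation merge onto the better one.
    """
    v = d.values
    events: list[tuple[int, str]] = sorted(
        [(i, "max") for i in maxima] + [(i, "min") for i in minima]
    )
    drops = [
        abs(v[a] - v[b])
        for (a, ka), (b, kb) in zip(events, events[1:])
        if ka != kb
    ]
    if not drops:
        return list(maxima), list(minima)
    thr = min_fraction * float(np.median(drops))

    changed = True
    while changed and len(events) > 1:
        changed = False
        # merge adjacent same-type events (keep the larger max / smaller min)
        for k in range(len(events) - 1):
            (a, ka), (b, kb) = events[k], events[k + 1]
            if ka == kb:
                better = (ka == "max") == (v[a] >= v[b])
                del events[k + 1 if better else k]
                changed = True
                break
        if changed:
            continue
        # cancel the shallowest opposite-type pair below threshold
        best_k, best_d = -1, thr
        for k in range(len(events) - 1):
            dmag = abs(v[events[k][0]] - v[events[k + 1][0]])
            if dmag < best_d:
                best_k, best_d = k, dmag
        if best_k >= 0:
            del events[best_k : best_k + 2]
            changed = True

    return (
        [i for i, k in events if k == "max"],
        [i for i, k in events if k == "min"],
    )


def segment_cycles(
    seq: JointSequence3D, maxima: list[int], minima: list[int]
) -> list[GaitCycle]:
    """Assemble full gait cycles from alternating ankle-separation extrema.

    A cycle is a maximal run max-min-max-min-max: t_a, t_c, t_d, t_f, t_h in
    order, with t_b, t_e, t_g the midpoints of (t_a,t_c), (t_d,t_f), (t_f,t_h).
    Consecutive cycles share their boundary maximum. Fewer than three maxima
    yield no complete cycle (logged, not an error).
    """
    events = sorted([(i, "max") for i in maxima] + [(i, "min") for i in minima])
    cycles: list[GaitCycle] = []
    k = 0
    n = len(events)
    if len(maxima) < 3:
        logger.info("only %d maxima: no complete gait cycle", len(maxima))
        return cycles
    while k + 4 < n:
        kinds = [events[k + j][1] for j in range(5)]
        if kinds == ["max", "min", "max", "min", "max"]:
            ta, tc, td, tf, th = (float(events[k + j][0]) for j in range(5))
            cycles.append(
                GaitCycle(
                    source=seq,
                    phase_times={
                        "ta": ta,
                        "tb": (ta + tc) / 2.0,
                        "tc": tc,
                        "td": td,
                        "te": (td + tf) / 2.0,
                        "tf": tf,
                        "tg": (tf + th) / 2.0,
                        "th": th,
                    },
                    cycle_index=len(cycles),
                )
            )
            k += 4  # share the boundary maximum with the next cycle
        else:
            k += 1
    return cycles


def extract_cycles(
    seq: JointSequence3D,
    interp_factor: int = DEFAULT_INTERP_FACTOR,
    smooth_M: int = DEFAULT_SMOOTH_M,
    window_N: int = DEFAULT_WINDOW_N,
) -> list[GaitCycle]:
    """Full extraction pipeline: interpolate, measure, smooth, detect, segment.

    Interpolation is applied to the joint positions (the distance signal is
    recomputed from them) so that every phase timestamp indexes an actual
    pose for feature extraction. Returns cycles on the interpolated timeline.
    """
    dense = interpolate(seq, factor=interp_factor)
    d = ankle_distance(dense)
    ds = smooth(d, M=smooth_M)
    maxima, minima = find_extrema(ds, N=window_N)
    maxima, minima = prune_extrema(ds, maxima, minima)
    return segment_cycles(dense, maxima, minima)


def cycles_to_manifest(cycles: list[GaitCycle]) -> pd.DataFrame:
    """Tabulate cycles as a manifest: subject, bout, index, phases, fps."""
    rows = []
    for c in cycles:
        row = {
            "subject": c.source.subject_id,
            "bout": c.source.bout_id,
            "cycle_index": c.cycle_index,
        }
        row.update({p: c.phase_times[p] for p in PHASE_NAMES})
        row["fps_effective"] = c.source.fps
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject", "bout", "cycle_index", *PHASE_NAMES, "fps_effective"])
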