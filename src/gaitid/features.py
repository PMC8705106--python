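"""Per-cycle gait features: joint angles, relative segment lengths, strides, periods.

All features are computed on the interpolated pose timeline of a
:class:`~gaitid.cycles.GaitCycle`. Angles are vertex angles in degrees;
leg-inclination angles measure a shank against the world-vertical ray
obtained by lifting the ankle along +z (the ground is the x-y plane, so the
vertical reference is viewpoint-independent for any camera rotation about
z). Segment lengths are averaged over the cycle and expressed relative to
the upper-body length, since lifted 3D coordinates carry no physical unit.

Feature catalogue (26 values per cycle), using H3.6M joint ids
(1/2/3 right hip/knee/ankle, 6/7/8 left hip/knee/ankle, 0 hip center,
12 spine, 13 thorax):

========================================  =======================================
max_Rdegree / min_Rdegree                 extrema over the cycle of the right
                                          knee vertex angle ang(3, 2, 1)
max_Ldegree / min_Ldegree                 extrema of the left knee vertex angle
                                          ang(6, 7, 8)
initial_contact_hip_extension             ang(7, 6, 3) at t_a
initial_contact_left_knee_extension       ang(6, 7, 8) at t_a
initial_contact_left_leg_inclination      ang(7, 8, lift(8)) at t_a
initial_swing_knee_flextion               ang(6, 7, 8) at t_f
mid_stance_knee_flextion                  ang(6, 7, 8) at t_c
terminal_stance_hip_extension             ang(7, 6, 2) at t_d
terminal_stance_right_knee_flextion       ang(1, 2, 3) at t_d
terminal_stance_right_leg_inclination     ang(2, 3, lift(3)) at t_d
terminal_stance_left_leg_inclination      ang(7, 8, lift(8)) at t_d
terminal_swing_hip_extension              ang(2, 1, 7) at t_h
terminal_swing_right_leg_inclination      ang(2, 3, lift(3)) at t_h
upper_body                                mean of D(0,12) + D(12,13)
right/left_lower/upper_leg                mean segment lengths / upper_body
left_stride                               D(left ankle at t_a, left ankle at t_d)
right_stride                              D(right ankle at t_d, right ankle at t_h)
period                                    frames in [t_a, t_h]
RFoot_period / LFoot_period               frames with the right/left foot ahead
                                          along the walking direction
main_foot                                 1 if RFoot_period >= LFoot_period
========================================  =======================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cycles import GaitCycle

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "FeatureTable",
    "angle",
    "lift",
    "compute_features",
    "feature_table",
]

#: Fixed column order of the feature catalogue.
FEATURE_NAMES: tuple[str, ...] = (
    "max_Rdegree",
    "max_Ldegree",
    "min_Rdegree",
    "min_Ldegree",
    "initial_contact_hip_extension",
    "initial_contact_left_knee_extension",
    "initial_contact_left_leg_inclination",
    "initial_swing_knee_flextion",
    "mid_stance_knee_flextion",
    "terminal_stance_hip_extension",
    "terminal_stance_right_knee_flextion",
    "terminal_stance_right_leg_inclination",
    "terminal_stance_left_leg_inclination",
    "terminal_swing_hip_extension",
    "terminal_swing_right_leg_inclination",
    "upper_body",
    "right_lower_leg",
    "right_upper_leg",
    "left_lower_leg",
    "left_upper_leg",
    "left_stride",
    "right_stride",
    "RFoot_period",
    "LFoot_period",
    "period",
    "main_foot",
)

#: Vertical-lift constant for the inclination reference ray; any positive
#: value yields the same ray direction, so it is fixed at 1.
LIFT_H = 1.0


class FeatureError(ValueError):
    """Raised when a feature cannot be computed (degenerate geometry, missing joint)."""


@dataclass
class FeatureVector:
    """Named gait features for one cycle, in the fixed catalogue order."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            missing = set(FEATURE_NAMES) - set(self.values)
            extra = set(self.values) - set(FEATURE_NAMES)
            raise ValueError(f"feature names mismatch (missing {missing}, extra {extra})")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES])


class FeatureTable:
    """Rows of (subject_id, cycle_index, features), one per extracted cycle.

    Thin wrapper over a DataFrame with a fixed, documented column order:
    ``subject_id, cycle_index`` then :data:`FEATURE_NAMES`. Round-trips
    losslessly through CSV.
    """

    ID_COLUMNS = ("subject_id", "cycle_index")

    def __init__(self, df: pd.DataFrame):
        expected = [*self.ID_COLUMNS, *FEATURE_NAMES]
        if list(df.columns) != expected:
            raise ValueError(f"FeatureTable columns must be exactly {expected}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_rows(cls, rows: list[tuple[str, int, FeatureVector]]) -> "FeatureTable":
        recs = [
            {"subject_id": s, "cycle_index": i, **fv.values} for s, i, fv in rows
        ]
        return cls(pd.DataFrame(recs, columns=[*cls.ID_COLUMNS, *FEATURE_NAMES]))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path))

    @property
    def labels(self) -> np.ndarray:
        return self.df["subject_id"].to_numpy()

    @property
    def matrix(self) -> np.ndarray:
        return self.df[list(FEATURE_NAMES)].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)


def angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Vertex angle at ``p2`` between rays p2->p1 and p2->p3, in degrees [0, 180]."""
    u = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    v = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0:
        raise FeatureError("zero-length ray p2->p1 in vertex angle")
    if nv == 0.0:
        raise FeatureError("zero-length ray p2->p3 in vertex angle")
    c = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def lift(p: np.ndarray, H: float = LIFT_H) -> np.ndarray:
    """Raise a point along the vertical (+z) axis by ``H`` (> 0)."""
    if not H > 0:
        raise ValueError("H must be positive")
    q = np.asarray(p, dtype=float).copy()
    q[2] += H
    return q


def _nearest_frame(t: float, n: int) -> int:
    """Nearest integer frame to a fractional timestamp; ties break earlier."""
    i = int(math.ceil(t - 0.5))
    return min(max(i, 0), n - 1)


def compute_features(cycle: GaitCycle) -> FeatureVector:
    """Compute the full feature catalogue for one gait cycle.

    Knee-flexion extremes scan every interpolated frame in [t_a, t_h];
    phase-anchored angles use the pose at the frame nearest the fractional
    phase timestamp. The walking direction used for the foot-ahead periods
    is the root joint's ground-plane displacement from t_a to t_h.
    """
    seq = cycle.source
    n = seq.n_frames
    pt = cycle.phase_times
    pose = {p: seq.positions[_nearest_frame(pt[p], n)] for p in pt}

    def J(ph: str, joint_id: int) -> np.ndarray:
        from .skeleton import h36m_column

        return pose[ph][h36m_column(joint_id)]

    lo = int(math.ceil(pt["ta"]))
    hi = int(math.floor(pt["th"]))
    if hi < lo:
        raise FeatureError("cycle spans no whole frame")
    window = seq.positions[lo : hi + 1]

    from .skeleton import h36m_column as col

    def track(j: int) -> np.ndarray:
        return window[:, col(j), :]

    def vertex_angles(a: int, b: int, c: int) -> np.ndarray:
        u = track(a) - track(b)
        v = track(c) - track(b)
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        if (nu == 0).any() or (nv == 0).any():
            raise FeatureError(f"degenerate knee geometry in window for angle({a},{b},{c})")
        cs = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
        return np.degrees(np.arccos(cs))

    r_knee = vertex_angles(3, 2, 1)
    l_knee = vertex_angles(6, 7, 8)

    f: dict[str, float] = {}
    f["max_Rdegree"] = float(r_knee.max())
    f["max_Ldegree"] = float(l_knee.max())
    f["min_Rdegree"] = float(r_knee.min())
    f["min_Ldegree"] = float(l_knee.min())

    f["initial_contact_hip_extension"] = angle(J("ta", 7), J("ta", 6), J("ta", 3))
    f["initial_contact_left_knee_extension"] = angle(J("ta", 6), J("ta", 7), J("ta", 8))
    f["initial_contact_left_leg_inclination"] = angle(J("ta", 7), J("ta", 8), lift(J("ta", 8)))
    f["initial_swing_knee_flextion"] = angle(J("tf", 6), J("tf", 7), J("tf", 8))
    f["mid_stance_knee_flextion"] = angle(J("tc", 6), J("tc", 7), J("tc", 8))
    f["terminal_stance_hip_extension"] = angle(J("td", 7), J("td", 6), J("td", 2))
    f["terminal_stance_right_knee_flextion"] = angle(J("td", 1), J("td", 2), J("td", 3))
    f["terminal_stance_right_leg_inclination"] = angle(J("td", 2), J("td", 3), lift(J("td", 3)))
    f["terminal_stance_left_leg_inclination"] = angle(J("td", 7), J("td", 8), lift(J("td", 8)))
    f["terminal_swing_hip_extension"] = angle(J("th", 2), J("th", 1), J("th", 7))
    f["terminal_swing_right_leg_inclination"] = angle(J("th", 2), J("th", 3), lift(J("th", 3)))

    def seg_mean(a: int, b: int) -> float:
        return float(np.linalg.norm(track(a) - track(b), axis=1).mean())

    ub = seg_mean(0, 12) + seg_mean(12, 13)
    if ub == 0:
        raise FeatureError("upper-body length is zero; cannot form length ratios")
    f["upper_body"] = ub
    f["right_lower_leg"] = seg_mean(3, 2) / ub
    f["right_upper_leg"] = seg_mean(2, 1) / ub
    f["left_lower_leg"] = seg_mean(8, 7) / ub
    f["left_upper_leg"] = seg_mean(7, 6) / ub

    f["left_stride"] = float(np.linalg.norm(J("ta", 8) - J("td", 8)))
    f["right_stride"] = float(np.linalg.norm(J("td", 3) - J("th", 3)))

    period = hi - lo + 1
    # walking direction: root ground-plane displacement over the cycle
    disp = (J("th", 0) - J("ta", 0))[:2]
    nd = np.linalg.norm(disp)
    if nd == 0:
        direction = np.array([1.0, 0.0])  # stationary walker: arbitrary but fixed
    else:
        direction = disp / nd
    ahead = (track(3)[:, :2] - track(8)[:, :2]) @ direction
    rfoot = int((ahead >= 0).sum())
    f["RFoot_period"] = float(rfoot)
    f["LFoot_period"] = float(period - rfoot)
    f["period"] = float(period)
    f["main_foot"] = 1.0 if rfoot >= period - rfoot else 0.0

    return FeatureVector(values=f)


def feature_table(cycles_by_subject: list[tuple[str, list[GaitCycle]]]) -> FeatureTable:
    """Build a FeatureTable from per-subject cycle lists."""
    rows: list[tuple[str, int, FeatureVector]] = []
    for subject, cycles in cycles_by_subject:
        for c in cycles:
            rows.append((subject, c.cycle_index, compute_features(c)))
    return FeatureTable.from_rows(rows)
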