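"""Parametric multi-subject 3D gait generator.

Emulates the output of a 2D-to-3D pose-lifting estimator for a walking
person: unitless coordinates, z-up, ground in the x-y plane, sampled at
20-25 frames/s, with additive Gaussian jitter standing in for pose-estimator
error. Subjects differ in limb proportions, stride length, cadence,
knee-flexion amplitude and waveform timing — enough identity signal for the
downstream feature and sequence classifiers without pretending to be a
biomechanically detailed model.

Kinematic model (sagittal-plane pendulum limbs):

* the pelvis advances along +x at ``stride_len * cadence`` with a small
  vertical bob; hips sit a fixed half-width off the midline in y;
* each thigh swings about its hip with angle ``A * sin(psi)`` from vertical,
  the two legs half a cycle apart (``psi = 2*pi*cadence*(t - t_off)``);
* the knee flexes by ``knee_amp * cos(psi)**4`` (modulated per subject),
  which vanishes with flat fourth-order contact at the instants of maximal
  foot separation, so at those instants the legs are straight;
* the hip swing amplitude defaults to ``asin(stride_len / (4 * leg_len))``,
  which makes the distance a swinging ankle covers between consecutive
  maximal-separation events exactly ``stride_len``.

One "stride" here is one full gait cycle (two steps); the ankle-separation
signal peaks twice per stride. The generator also returns the closed-form
event times of those peaks as ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .skeleton import H36M_JOINTS, JointSequence3D, h36m_column

__all__ = [
    "WalkerParams",
    "CohortSpec",
    "WalkEvents",
    "sample_subject",
    "generate_walk",
    "generate_cohort",
    "openpose_json_frames",
    "DEFAULT_MEANS",
    "DEFAULT_BETWEEN_SUBJECT_SD",
]

#: Population means for subject parameters (unitless lengths, strides/s, degrees).
DEFAULT_MEANS: dict[str, float] = {
    "thigh_len": 0.45,
    "shank_len": 0.42,
    "torso_len": 0.50,
    "stride_len": 1.10,
    "cadence": 1.00,
    "knee_amp": 55.0,
    "asymmetry": 1.00,
}

#: Between-subject standard deviations used by cohort sampling.
DEFAULT_BETWEEN_SUBJECT_SD: dict[str, float] = {
    "thigh_len": 0.030,
    "shank_len": 0.030,
    "torso_len": 0.040,
    "stride_len": 0.100,
    "cadence": 0.100,
    "knee_amp": 6.0,
    "asymmetry": 0.030,
}

# phase offset (in stride periods) of the first maximal-separation event;
# keeps every analytic event comfortably inside the sampled window. The odd
# value avoids degenerate alignment of separation peaks with the sample grid
# (an exactly grid-centered peak yields two tied samples, which the strict
# slope predicate of the extrema detector rightly rejects)
_T_OFF_STRIDES = 0.313


@dataclass
class WalkerParams:
    """Subject-specific generative parameters.

    ``hip_amp`` (degrees) defaults to the value derived from stride length
    and leg length (see module docstring); set it explicitly to decouple the
    swing amplitude from the stride. ``phase_offset`` (radians) shifts the
    subject's knee-waveform modulation, not the gait events. ``asymmetry``
    is the left-to-right stride ratio contribution in [0.8, 1.2].
    """

    thigh_len: float = DEFAULT_MEANS["thigh_len"]
    shank_len: float = DEFAULT_MEANS["shank_len"]
    torso_len: float = DEFAULT_MEANS["torso_len"]
    stride_len: float = DEFAULT_MEANS["stride_len"]
    cadence: float = DEFAULT_MEANS["cadence"]
    hip_amp: float | None = None
    knee_amp: float = DEFAULT_MEANS["knee_amp"]
    phase_offset: float = 0.0
    asymmetry: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("thigh_len", "shank_len", "torso_len", "stride_len", "cadence"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.8 <= self.asymmetry <= 1.2:
            raise ValueError("asymmetry must lie in [0.8, 1.2]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def leg_len(self) -> float:
        return self.thigh_len + self.shank_len

    def swing_amplitudes(self) -> tuple[float, float]:
        """(left, right) hip swing amplitudes in radians."""
        if self.hip_amp is not None:
            base = math.radians(self.hip_amp)
            return base * self.asymmetry, base * (2.0 - self.asymmetry)
        ratio = self.stride_len / (4.0 * self.leg_len)
        if ratio >= 1.0:
            raise ValueError("stride_len too large for the leg length")
        return (
            math.asin(min(0.999, ratio * self.asymmetry)),
            math.asin(min(0.999, ratio * (2.0 - self.asymmetry))),
        )


@dataclass
class CohortSpec:
    """Shape and population statistics of a synthetic cohort."""

    n_subjects: int = 20
    cycles_per_subject: int = 12
    fps: float = 25.0
    between_subject_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_SUBJECT_SD)
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if self.cycles_per_subject < 1:
            raise ValueError("cycles_per_subject must be >= 1")
        if not self.fps > 0:
            raise ValueError("fps must be positive")


@dataclass
class WalkEvents:
    """Closed-form ground truth for one generated bout."""

    max_times: np.ndarray      # seconds; instants of maximal ankle separation
    contact_foot: list[str]    # which foot is forward at each maximum
    n_cycles: int              # full gait cycles the bout is built to contain
    stride_period: float       # seconds per full cycle


def sample_subject(spec: CohortSpec, rng: np.random.Generator) -> WalkerParams:
    """Draw one subject's parameters from the cohort's population model.

    Normal draws per parameter, truncated to the type invariants
    (positive lengths and rates; asymmetry in [0.8, 1.2]).
    """
    sd = spec.between_subject_sd

    def draw(name: str, lo: float, hi: float | None = None) -> float:
        v = rng.normal(DEFAULT_MEANS[name], sd.get(name, 0.0))
        if hi is not None:
            v = min(v, hi)
        return max(v, lo)

    return WalkerParams(
        thigh_len=draw("thigh_len", 0.2),
        shank_len=draw("shank_len", 0.2),
        torso_len=draw("torso_len", 0.25),
        stride_len=draw("stride_len", 0.4),
        cadence=draw("cadence", 0.4),
        knee_amp=draw("knee_amp", 20.0),
        phase_offset=float(rng.uniform(-math.pi, math.pi)),
        asymmetry=draw("asymmetry", 0.8, 1.2),
        noise_sd=spec.noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_walk(
    p: WalkerParams, n_strides: int, fps: float
) -> tuple[JointSequence3D, WalkEvents]:
    """Simulate one walking bout containing ``n_strides`` full gait cycles.

    Returns the joint sequence (H3.6M layout, z-up, noise added if
    ``p.noise_sd > 0``) together with the closed-form gait-event ground
    truth. The bout carries margin before the first and after the last
    usable event so that every requested cycle is recoverable.
    """
    if n_strides < 2:
        raise ValueError("n_strides must be >= 2")
    if fps < 4.0 * p.cadence:
        raise ValueError(
            f"fps {fps} cannot resolve cadence {p.cadence} strides/s (need fps >= 4*cadence)"
        )
    c = p.cadence
    t_off = _T_OFF_STRIDES / c
    duration = (n_strides + 1.0) / c
    n_frames = int(round(duration * fps)) + 1
    t = np.arange(n_frames) / fps

    A_L, A_R = p.swing_amplitudes()
    psi_L = 2.0 * math.pi * c * (t - t_off) - math.pi / 2.0
    psi_R = psi_L + math.pi

    theta_L = A_L * np.sin(psi_L)
    theta_R = A_R * np.sin(psi_R)
    knee_amp = math.radians(p.knee_amp)
    # quartic-in-cos flexion: zero (flat to 4th order) at maximal separation
    mod_L = 1.0 + 0.3 * np.sin(psi_L + p.phase_offset)
    mod_R = 1.0 + 0.3 * np.sin(psi_R + p.phase_offset)
    beta_L = knee_amp * np.cos(psi_L) ** 4 * mod_L
    beta_R = knee_amp * np.cos(psi_R) ** 4 * mod_R

    leg = p.leg_len
    hip_w = 0.22 * leg
    pelvis_h = 0.98 * leg
    v = p.stride_len * c
    root = np.stack(
        [v * t, np.zeros_like(t), pelvis_h + 0.01 * leg * np.cos(2.0 * (psi_L + math.pi / 2))],
        axis=1,
    )

    def leg_chain(theta: np.ndarray, beta: np.ndarray, y: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        hip = root + np.array([0.0, y, 0.0])
        knee = hip + p.thigh_len * np.stack(
            [np.sin(theta), np.zeros_like(t), -np.cos(theta)], axis=1
        )
        ankle = knee + p.shank_len * np.stack(
            [np.sin(theta - beta), np.zeros_like(t), -np.cos(theta - beta)], axis=1
        )
        return hip, knee, ankle

    hip_R, knee_R, ankle_R = leg_chain(theta_R, beta_R, -hip_w / 2.0)
    hip_L, knee_L, ankle_L = leg_chain(theta_L, beta_L, +hip_w / 2.0)

    torso = p.torso_len
    up = np.array([0.0, 0.0, 1.0])
    spine = root + 0.5 * torso * up
    thorax = root + torso * up
    necknose = thorax + 0.12 * torso * up + np.array([0.05 * torso, 0.0, 0.0])
    head = thorax + 0.25 * torso * up
    sh_w = 0.45 * torso
    sho_L = thorax + np.array([0.0, +sh_w / 2.0, 0.0])
    sho_R = thorax + np.array([0.0, -sh_w / 2.0, 0.0])
    # arms swing gently in antiphase with the same-side leg
    arm = 0.10 * torso
    swing_L = arm * np.sin(psi_R)
    swing_R = arm * np.sin(psi_L)
    elb_L = sho_L + np.stack([swing_L, np.zeros_like(t), np.full_like(t, -0.35 * torso)], axis=1)
    elb_R = sho_R + np.stack([swing_R, np.zeros_like(t), np.full_like(t, -0.35 * torso)], axis=1)
    wri_L = sho_L + np.stack([2.0 * swing_L, np.zeros_like(t), np.full_like(t, -0.65 * torso)], axis=1)
    wri_R = sho_R + np.stack([2.0 * swing_R, np.zeros_like(t), np.full_like(t, -0.65 * torso)], axis=1)

    def bc(a: np.ndarray) -> np.ndarray:
        return np.broadcast_to(a, (n_frames, 3))

    by_id = {
        0: root, 1: hip_R, 2: knee_R, 3: ankle_R,
        6: hip_L, 7: knee_L, 8: ankle_L,
        12: bc(spine) if spine.ndim == 1 else spine,
        13: bc(thorax) if thorax.ndim == 1 else thorax,
        14: bc(necknose) if necknose.ndim == 1 else necknose,
        15: bc(head) if head.ndim == 1 else head,
        17: bc(sho_L) if sho_L.ndim == 1 else sho_L,
        18: elb_L, 19: wri_L,
        25: bc(sho_R) if sho_R.ndim == 1 else sho_R,
        26: elb_R, 27: wri_R,
    }
    pos = np.empty((n_frames, len(H36M_JOINTS), 3))
    for j in H36M_JOINTS:
        pos[:, h36m_column(j), :] = by_id[j]

    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        pos = pos + rng.normal(0.0, p.noise_sd, size=pos.shape)

    seq = JointSequence3D(positions=pos, fps=fps, subject_id=None, bout_id=None)

    # maximal-separation events: half-stride apart, starting with the left
    # foot at the back (right foot forward)
    k = np.arange(int(math.floor((duration - t_off) * 2.0 * c)) + 1)
    max_times = t_off + k / (2.0 * c)
    contact_foot = ["right" if i % 2 == 0 else "left" for i in k]
    events = WalkEvents(
        max_times=max_times,
        contact_foot=contact_foot,
        n_cycles=n_strides,
        stride_period=1.0 / c,
    )
    return seq, events


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[JointSequence3D], pd.DataFrame]:
    """Generate one bout per subject plus a ground-truth table.

    The table has one row per subject with the drawn parameters, the bout's
    analytic event times (JSON-encoded) and the number of full cycles the
    bout contains.
    """
    rng = np.random.default_rng(spec.seed)
    seqs: list[JointSequence3D] = []
    rows: list[dict] = []
    for s in range(spec.n_subjects):
        params = sample_subject(spec, rng)
        seq, events = generate_walk(params, spec.cycles_per_subject, spec.fps)
        sid = f"S{s:03d}"
        seq.subject_id = sid
        seq.bout_id = f"{sid}_b0"
        seqs.append(seq)
        rows.append(
            {
                "subject_id": sid,
                "thigh_len": params.thigh_len,
                "shank_len": params.shank_len,
                "torso_len": params.torso_len,
                "stride_len": params.stride_len,
                "cadence": params.cadence,
                "knee_amp": params.knee_amp,
                "phase_offset": params.phase_offset,
                "asymmetry": params.asymmetry,
                "noise_sd": params.noise_sd,
                "seed": params.seed,
                "n_cycles": events.n_cycles,
                "stride_period": events.stride_period,
                "event_times": json.dumps(np.round(events.max_times, 6).tolist()),
            }
        )
    return seqs, pd.DataFrame(rows)


# COCO index <- H3.6M id for the joints that project directly
_COCO_FROM_H36M = {
    0: 14, 1: 13, 2: 25, 3: 26, 4: 27, 5: 17, 6: 18, 7: 19,
    8: 1, 9: 2, 10: 3, 11: 6, 12: 7, 13: 8,
}


def openpose_json_frames(
    seq: JointSequence3D, scale: float = 100.0, origin: tuple[float, float] = (300.0, 500.0)
) -> list[str]:
    """Project a 3D bout to OpenPose-style 2D JSON documents (one per frame).

    The sagittal x-z plane is projected to image pixels with the image
    y-axis pointing down (v = origin_y - scale * z). Face keypoints absent
    from the H3.6M set (eyes, ears) are placed at small offsets around the
    head position. All confidences are 1. Intended for converter testing.
    """
    docs: list[str] = []
    for f in range(seq.n_frames):
        kp = np.zeros((18, 3))
        for c_idx, h_id in _COCO_FROM_H36M.items():
            pnt = seq.positions[f, h36m_column(h_id), :]
            kp[c_idx] = [origin[0] + scale * pnt[0], origin[1] - scale * pnt[2], 1.0]
        head = seq.positions[f, h36m_column(15), :]
        hu, hv = origin[0] + scale * head[0], origin[1] - scale * head[2]
        for c_idx, (du, dv) in ((14, (2.0, -1.0)), (15, (-2.0, -1.0)), (16, (4.0, 0.0)), (17, (-4.0, 0.0))):
            kp[c_idx] = [hu + du, hv + dv, 1.0]
        docs.append(
            json.dumps(
                {
                    "version": 1.3,
                    "frame_index": f,
                    "people": [{"pose_keypoints_2d": kp.ravel().tolist()}],
                }
            )
        )
    return docs
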