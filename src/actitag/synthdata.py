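"""Synthetic lumbar-accelerometer sessions with ground-truth activity tags.

The clinical recordings this package targets (an activity circuit performed
by rheumatoid-arthritis patients and healthy controls wearing a single
tri-axial accelerometer at L5) are not publicly available, so this module
generates surrogate sessions that reproduce the phenomenology the method
relies on:

* static postures are gravity-dominated with a constant device orientation;
* walking adds a periodic body-acceleration component at the step frequency;
* postural transitions are smooth (sigmoid) rotations of the gravity vector
  between posture orientations;
* patient signals differ from healthy ones by a tremor component in a
  4-6 Hz band, slowed transitions with optional mid-transition pauses, and
  a constant hunched baseline tilt.

The synthesis model is deliberately simple: a single orientation angle in
the device x-z plane drives a rotated unit gravity vector; tag-specific
deterministic body-acceleration kernels and white Gaussian noise are added
on top.  It is not a biomechanical gait simulation.

All randomness flows from integer seeds through ``numpy.random.SeedSequence``
so identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .logicfilter import default_adjacency, is_feasible_sequence
from .preprocess import (
    OVERLAP_S_DEFAULT,
    WIN_S_DEFAULT,
    write_labels_csv,
    write_signal_csv,
)
from .tags import ActivityTag, TRANSITION_ENDPOINTS, TRANSITION_TAGS, as_tag

__all__ = [
    "FS_DEFAULT",
    "SubjectProfile",
    "healthy_profile",
    "patient_profile",
    "Session",
    "Cohort",
    "default_circuit",
    "generate_segment",
    "generate_session",
    "generate_cohort",
    "ground_truth_window_tags",
]

FS_DEFAULT = 100.0

#: Device-frame tilt angle (deg) of the gravity vector per posture:
#: 0 = upright (gravity along +z), 90 = lying (gravity along +x).
_POSTURE_TILT_DEG = {
    ActivityTag.STAND: 0.0,
    ActivityTag.WALK: 0.0,
    ActivityTag.SIT: 20.0,
    ActivityTag.LIE: 90.0,
}

_TREMOR_AMP_MAX_G = 0.15  # tremor amplitude cap; scales linearly with severity


@dataclass(frozen=True)
class SubjectProfile:
    """Signal-generation parameters of one simulated subject.

    ``severity`` in [0, 1] scales every impairment; healthy profiles have
    severity 0 and pause_prob 0.  ``transition_slowdown`` multiplies the
    scripted duration of every transition; ``pause_prob`` is the chance a
    transition contains a mid-movement static pause; ``hunch_tilt_deg`` is
    a constant baseline rotation added to the posture orientation.
    """

    group: str = "healthy"
    severity: float = 0.0
    tremor_band_hz: tuple[float, float] = (4.0, 6.0)
    transition_slowdown: float = 1.0
    pause_prob: float = 0.0
    hunch_tilt_deg: float = 0.0
    step_freq_hz: float = 1.8
    noise_sd_g: float = 0.02

    def __post_init__(self) -> None:
        if self.group not in ("healthy", "patient"):
            raise ValueError(f"group must be 'healthy' or 'patient', got {self.group!r}")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must be in [0, 1]")
        if not 0.0 <= self.pause_prob <= 1.0:
            raise ValueError("pause_prob must be in [0, 1]")
        if self.transition_slowdown < 1.0:
            raise ValueError("transition_slowdown must be >= 1")
        if self.hunch_tilt_deg < 0.0:
            raise ValueError("hunch_tilt_deg must be >= 0")
        if self.noise_sd_g <= 0.0:
            raise ValueError("noise_sd_g must be > 0")
        if self.tremor_band_hz[0] >= self.tremor_band_hz[1] or self.tremor_band_hz[0] <= 0:
            raise ValueError("tremor_band_hz must be an increasing positive interval")
        if self.group == "healthy" and (self.severity != 0.0 or self.pause_prob != 0.0):
            raise ValueError("healthy profiles require severity = 0 and pause_prob = 0")


def healthy_profile(**overrides) -> SubjectProfile:
    return SubjectProfile(group="healthy", **overrides)


def patient_profile(severity: float = 0.6, **overrides) -> SubjectProfile:
    """A patient profile whose impairments scale with ``severity``."""
    defaults = dict(
        group="patient",
        severity=severity,
        transition_slowdown=1.0 + severity,
        pause_prob=0.3 * severity,
        hunch_tilt_deg=10.0 * severity,
        step_freq_hz=1.6,
    )
    defaults.update(overrides)
    return SubjectProfile(**defaults)


# ---------------------------------------------------------------------------
# Segment synthesis
# ---------------------------------------------------------------------------

def _gravity(theta_deg: np.ndarray) -> np.ndarray:
    """Unit gravity vector rotated by theta in the device x-z plane."""
    th = np.radians(theta_deg)
    return np.column_stack([np.sin(th), np.zeros_like(th), np.cos(th)])


def _sigmoid_fraction(u: np.ndarray, steepness: float = 8.0) -> np.ndarray:
    """Normalized logistic ramp: 0 at u=0, 1 at u=1, smooth in between."""
    lo = 1.0 / (1.0 + np.exp(steepness / 2.0))
    hi = 1.0 / (1.0 + np.exp(-steepness / 2.0))
    s = 1.0 / (1.0 + np.exp(-steepness * (u - 0.5)))
    return (s - lo) / (hi - lo)


def _transition_theta(
    tag: ActivityTag, n: int, profile: SubjectProfile, rng: np.random.Generator
) -> np.ndarray:
    src, dst = TRANSITION_ENDPOINTS[tag]
    th0 = _POSTURE_TILT_DEG[src]
    th1 = _POSTURE_TILT_DEG[dst]
    u = np.linspace(0.0, 1.0, n)
    if profile.pause_prob > 0 and rng.random() < profile.pause_prob:
        # hold the mid-transition posture for ~30% of the duration
        u = np.interp(u, [0.0, 0.35, 0.65, 1.0], [0.0, 0.5, 0.5, 1.0])
    return th0 + (th1 - th0) * _sigmoid_fraction(u)


def generate_segment(
    tag: "ActivityTag | str",
    duration_s: float,
    profile: SubjectProfile,
    rng_seed: "int | np.random.Generator",
    fs: float = FS_DEFAULT,
) -> np.ndarray:
    """Synthesize one activity segment; returns (n, 3) acceleration in g.

    Static tags give a constant rotated gravity vector plus noise; walking
    adds a periodic body component at ``profile.step_freq_hz``; transitions
    rotate the gravity vector smoothly between the two posture orientations.
    Patient profiles (severity > 0) add a tremor component in
    ``profile.tremor_band_hz`` and the constant hunch baseline rotation.
    """
    tag = as_tag(tag)
    if duration_s < 0.5:
        raise ValueError("segment duration must be >= 0.5 s")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    if tag in TRANSITION_TAGS:
        theta = _transition_theta(tag, n, profile, rng)
    else:
        theta = np.full(n, _POSTURE_TILT_DEG[tag])
    theta = theta + profile.hunch_tilt_deg

    acc = _gravity(theta)

    if tag is ActivityTag.WALK:
        f = profile.step_freq_hz
        phase = rng.uniform(0, 2 * np.pi)
        acc[:, 2] += 0.30 * np.sin(2 * np.pi * f * t + phase)
        acc[:, 0] += 0.12 * np.sin(2 * np.pi * 2 * f * t + phase)
        acc[:, 1] += 0.08 * np.sin(2 * np.pi * f * t + phase + np.pi / 3)
    elif tag in TRANSITION_TAGS:
        # movement effort: body acceleration proportional to angular velocity
        dtheta = np.gradient(theta) * fs  # deg/s
        acc[:, 0] += 0.003 * dtheta
        acc[:, 2] += -0.002 * dtheta

    if profile.severity > 0:
        amp = min(_TREMOR_AMP_MAX_G, _TREMOR_AMP_MAX_G * profile.severity)
        f_tremor = rng.uniform(*profile.tremor_band_hz)
        phase = rng.uniform(0, 2 * np.pi)
        acc[:, 0] += amp * np.sin(2 * np.pi * f_tremor * t + phase)
        acc[:, 2] += 0.5 * amp * np.sin(2 * np.pi * f_tremor * t + phase + np.pi / 4)

    acc += rng.normal(0.0, profile.noise_sd_g, size=acc.shape)
    return acc


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------

ActivityScript = Sequence[tuple["ActivityTag | str", float]]


def default_circuit() -> list[tuple[ActivityTag, float]]:
    """The default activity circuit: walking, seated/lying stations with
    repeated transitions, closing with a lying rest.  Feasible under the
    default adjacency matrix."""
    T = ActivityTag
    return [
        (T.WALK, 10.0),
        (T.STAND, 4.0),
        (T.STAND2SIT, 2.0), (T.SIT, 5.0), (T.SIT2STAND, 2.0), (T.STAND, 4.0),
        (T.STAND2SIT, 2.0), (T.SIT, 5.0), (T.SIT2STAND, 2.0), (T.STAND, 4.0),
        (T.STAND2LIE, 2.5), (T.LIE, 5.0), (T.LIE2SIT, 2.5), (T.SIT, 5.0),
        (T.SIT2LIE, 2.5), (T.LIE, 5.0), (T.LIE2STAND, 2.5), (T.STAND, 4.0),
        (T.STAND2LIE, 2.5), (T.LIE, 6.0),
    ]


@dataclass
class Session:
    """One generated recording: raw signal, label intervals, window truth."""

    time: np.ndarray
    acc: np.ndarray
    fs: float
    intervals: list[tuple[float, float, ActivityTag]]
    window_tags: list[ActivityTag]
    window_starts: np.ndarray
    profile: SubjectProfile
    subject_id: str = ""

    def write_csv(self, signal_path, labels_path) -> None:
        write_signal_csv(signal_path, self.time, self.acc)
        write_labels_csv(labels_path, self.intervals)


def ground_truth_window_tags(
    intervals: Sequence[tuple[float, float, ActivityTag]],
    n_samples: int,
    fs: float,
    win_s: float = WIN_S_DEFAULT,
    overlap_s: float = OVERLAP_S_DEFAULT,
) -> tuple[list[ActivityTag], np.ndarray]:
    """Assign one tag per sliding window by majority time coverage.

    Ties are broken toward the transition tag, so that few-second
    transitions are not swallowed by the surrounding static bouts.
    """
    n_win = int(round(win_s * fs))
    hop = int(round((win_s - overlap_s) * fs))
    count = (n_samples - n_win) // hop + 1
    if count < 1:
        raise ValueError("session shorter than one window")
    starts = np.arange(count) * hop / fs
    tags: list[ActivityTag] = []
    for w0 in starts:
        w1 = w0 + win_s
        cover: dict[ActivityTag, float] = {}
        for a, b, tag in intervals:
            ov = min(b, w1) - max(a, w0)
            if ov > 0:
                cover[tag] = cover.get(tag, 0.0) + ov
        best = max(cover.values())
        candidates = [t for t, c in cover.items() if np.isclose(c, best)]
        trans = [t for t in candidates if t in TRANSITION_TAGS]
        tags.append(trans[0] if trans else candidates[0])
    return tags, starts


def generate_session(
    script: ActivityScript,
    profile: SubjectProfile,
    rng_seed: "int | np.random.SeedSequence",
    fs: float = FS_DEFAULT,
    subject_id: str = "",
) -> Session:
    """Concatenate scripted segments into a session with window ground truth.

    The script must be feasible under the default adjacency matrix.
    Transition durations are stretched by ``profile.transition_slowdown``.
    Orientation is continuous at joins because each transition connects the
    two posture orientations it is named for.
    """
    script = [(as_tag(tag), float(d)) for tag, d in script]
    if not script:
        raise ValueError("script must be non-empty")
    if not is_feasible_sequence([t for t, _ in script], default_adjacency()):
        raise ValueError("script is not feasible under the default adjacency matrix")
    ss = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    children = ss.spawn(len(script))
    chunks = []
    intervals = []
    t0 = 0.0
    for (tag, dur), child in zip(script, children):
        if tag in TRANSITION_TAGS:
            dur = dur * profile.transition_slowdown
        seg = generate_segment(tag, dur, profile, np.random.default_rng(child), fs=fs)
        chunks.append(seg)
        intervals.append((t0, t0 + len(seg) / fs, tag))
        t0 += len(seg) / fs
    acc = np.vstack(chunks)
    time = np.arange(len(acc)) / fs
    window_tags, starts = ground_truth_window_tags(intervals, len(acc), fs)
    return Session(
        time=time,
        acc=acc,
        fs=fs,
        intervals=intervals,
        window_tags=window_tags,
        window_starts=starts,
        profile=profile,
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    sessions: list[Session] = field(default_factory=list)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.sessions]

    def __iter__(self):
        return iter(self.sessions)

    def __len__(self) -> int:
        return len(self.sessions)


def _jitter_script(
    script: list[tuple[ActivityTag, float]], rng: np.random.Generator, frac: float = 0.1
) -> list[tuple[ActivityTag, float]]:
    return [(t, d * rng.uniform(1 - frac, 1 + frac)) for t, d in script]


def generate_cohort(
    n_patients: int,
    n_controls: int,
    master_seed: int,
    fs: float = FS_DEFAULT,
) -> Cohort:
    """Generate a labelled multi-subject dataset, reproducible from one seed.

    Patients draw severity uniformly in (0.2, 1] (a moderate-to-severe
    cohort); their transition slowdown, pause probability and hunch tilt all
    scale with severity.  Every subject performs a duration-jittered copy of
    the default circuit.
    """
    if n_patients < 1 or n_controls < 1:
        raise ValueError("need at least one patient and one control")
    ss = np.random.SeedSequence(master_seed)
    subject_seeds = ss.spawn(n_patients + n_controls)
    sessions = []
    base = default_circuit()
    for i, sseed in enumerate(subject_seeds):
        profile_seed, script_seed, session_seed = sseed.spawn(3)
        rng = np.random.default_rng(profile_seed)
        if i < n_patients:
            sid = f"P{i + 1:02d}"
            severity = rng.uniform(0.2, 1.0)
            profile = patient_profile(
                severity=severity,
                step_freq_hz=rng.normal(1.6, 0.1),
                noise_sd_g=rng.uniform(0.015, 0.03),
            )
        else:
            sid = f"H{i - n_patients + 1:02d}"
            profile = healthy_profile(
                step_freq_hz=rng.normal(1.8, 0.1),
                noise_sd_g=rng.uniform(0.015, 0.03),
            )
        script = _jitter_script(base, np.random.default_rng(script_seed))
        sessions.append(
            generate_session(script, profile, session_seed, fs=fs, subject_id=sid)
        )
    return Cohort(sessions=sessions)
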