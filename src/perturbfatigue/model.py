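"""Domain model for perturbed-stance sessions.

A *session* is one subject performing one protocol (FAT: continuous
perturbations until exhaustion; CON: volume-matched, rest-interleaved) on a
translating platform. Each *trial* is a single surface translation in one of
eight directions with a bundle of synchronously recorded channels: surface
EMG of seven leg muscles (1 kHz, mV), three sagittal joint angles (1 kHz,
deg), the anterior-posterior centre-of-pressure trace (100 Hz, mm) and, on
stimulation trials, a peripheral-nerve stimulation marker.

Conventions fixed here and relied on everywhere else:

* one clock per trial, in seconds; the perturbation onset ``onset_s`` is on
  that clock and all analysis windows are expressed relative to it;
* sample ``k`` of a channel covers the half-open interval
  ``[k/rate, (k+1)/rate)``; every analysis window is half-open;
* the COP channel is anterior-positive (a posterior platform translation
  produces a positive COP excursion); angles are flexion/dorsiflexion
  positive.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "MuscleLabel",
    "JointLabel",
    "Direction",
    "Quarter",
    "Protocol",
    "TimeSeriesChannel",
    "TrialOutcome",
    "Trial",
    "Session",
    "COP_CHANNEL",
    "STIM_CHANNEL",
    "angle_channel",
    "validate_session",
    "sessions_equal",
]


class MuscleLabel(str, enum.Enum):
    """The seven muscles carrying surface EMG electrodes (right leg)."""

    SOL = "SOL"  # soleus
    MG = "MG"    # medial gastrocnemius
    TA = "TA"    # tibialis anterior
    RF = "RF"    # rectus femoris
    BF = "BF"    # biceps femoris
    VM = "VM"    # vastus medialis
    GM = "GM"    # gluteus maximus


class JointLabel(str, enum.Enum):
    ANKLE = "ankle"
    KNEE = "knee"
    HIP = "hip"


class Direction(str, enum.Enum):
    """The eight platform translation directions."""

    ANTERIOR = "anterior"
    POSTERIOR = "posterior"
    MEDIAL = "medial"
    LATERAL = "lateral"
    ANTEROMEDIAL = "anteromedial"
    ANTEROLATERAL = "anterolateral"
    POSTEROMEDIAL = "posteromedial"
    POSTEROLATERAL = "posterolateral"


class Quarter(enum.IntEnum):
    """Four consecutive quarters of a session's trial sequence."""

    T1 = 1
    T2 = 2
    T3 = 3
    T4 = 4


class Protocol(str, enum.Enum):
    FAT = "FAT"
    CON = "CON"


COP_CHANNEL = "cop_ap"
STIM_CHANNEL = "stim"


def angle_channel(joint: JointLabel) -> str:
    return f"angle_{JointLabel(joint).value}"


@dataclass
class TimeSeriesChannel:
    """A uniformly sampled signal.

    Parameters
    ----------
    label : channel name ("SOL", "cop_ap", "angle_knee", ...).
    samples : ordered sample values; stored as a float64 array.
    rate : sampling rate in Hz, > 0.
    units : physical unit string ("mV", "deg", "mm", "N", "").
    """

    label: str
    samples: np.ndarray
    rate: float
    units: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"channel {self.label!r}: rate must be > 0, got {self.rate}")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError(f"channel {self.label!r}: samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"channel {self.label!r}: non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    def times(self) -> np.ndarray:
        """Sample start times (sample k covers [k/rate, (k+1)/rate))."""
        return np.arange(self.samples.size) / self.rate


# Failure criteria, in the precedence order used when several flags are set.
FAILURE_FRAME_TOUCH = "frame_touch"
FAILURE_FOOT_LIFTOFF = "foot_liftoff"
FAILURE_NONE = "none"

MAX_RESTABILIZE_S = 2.0


@dataclass
class TrialOutcome:
    """Adjudicated outcome of one perturbation trial.

    ``status`` is "failed" iff a failure criterion applies (safety-frame
    touch or lift-off of the unsupported foot). A successful trial must have
    re-stabilized within 2 s of the surface translation.
    """

    status: str  # "success" | "failed"
    failure_criterion: str = FAILURE_NONE
    restabilize_time: Optional[float] = None

    @property
    def failed(self) -> bool:
        return self.status == "failed"


@dataclass
class Trial:
    """One perturbation: direction, onset, raw event flags and channels.

    ``frame_touch`` / ``foot_liftoff`` are the raw event flags recorded
    during the trial; :func:`perturbfatigue.pipeline.classify_outcome`
    derives the :class:`TrialOutcome` from them.
    """

    index: int  # 1-based position in the session
    direction: Direction
    onset_s: float
    outcome: TrialOutcome
    channels: dict[str, TimeSeriesChannel] = field(default_factory=dict)
    frame_touch: bool = False
    foot_liftoff: bool = False
    restabilize_time: Optional[float] = None
    start_time_s: float = 0.0  # trial start on the session clock (metadata)

    @property
    def is_posterior(self) -> bool:
        return self.direction == Direction.POSTERIOR


@dataclass
class Session:
    """Ordered trials for one subject under one protocol, plus MVC references.

    ``mvc`` maps each muscle to its maximal-voluntary-contraction reference
    amplitude in mV (the normalisation denominator for %MVC).
    ``stimulation_trials`` lists the 1-based indices of posterior trials that
    carried peripheral-nerve stimulation (H-reflex/M-wave trials).
    """

    subject_id: str
    protocol: Protocol
    trials: list[Trial]
    mvc: dict[MuscleLabel, float]
    stimulation_trials: list[int] = field(default_factory=list)
    date: str = ""

    def __len__(self) -> int:
        return len(self.trials)


# channels a posterior trial must carry to be analysable
def required_posterior_channels() -> list[str]:
    names = [m.value for m in MuscleLabel]
    names += [angle_channel(j) for j in JointLabel]
    names.append(COP_CHANNEL)
    return names


def validate_session(session: Session) -> list[str]:
    """Check every domain invariant; return a list of violation descriptions.

    Total: reports problems instead of raising, so it can run on arbitrary
    well-typed input (e.g. a session freshly read from disk).
    """
    v: list[str] = []
    try:
        Protocol(session.protocol)
    except ValueError:
        v.append(f"unknown protocol {session.protocol!r}")
    for muscle, ref in session.mvc.items():
        try:
            MuscleLabel(muscle)
        except ValueError:
            v.append(f"MVC entry for unknown muscle {muscle!r}")
            continue
        if not (isinstance(ref, (int, float)) and math.isfinite(ref) and ref > 0):
            v.append(f"MVC reference for {MuscleLabel(muscle).value} must be a positive finite number")

    for pos, trial in enumerate(session.trials, start=1):
        tag = f"trial {trial.index}"
        if trial.index != pos:
            v.append(f"{tag}: index not contiguous (expected {pos})")
        if trial.onset_s < 0.1:
            v.append(f"{tag}: PRE window precedes recording (onset_s={trial.onset_s} < 0.1 s)")
        out = trial.outcome
        if out.status not in ("success", "failed"):
            v.append(f"{tag}: unknown outcome status {out.status!r}")
        if out.failed and out.failure_criterion == FAILURE_NONE:
            v.append(f"{tag}: failed trial without a failure criterion")
        if not out.failed and out.failure_criterion != FAILURE_NONE:
            v.append(f"{tag}: successful trial carries failure criterion {out.failure_criterion!r}")
        if (
            not out.failed
            and out.restabilize_time is not None
            and out.restabilize_time > MAX_RESTABILIZE_S
        ):
            v.append(f"{tag}: successful trial with restabilize_time > {MAX_RESTABILIZE_S} s")
        for name, ch in trial.channels.items():
            if name != ch.label:
                v.append(f"{tag}: channel stored under {name!r} but labelled {ch.label!r}")
        if trial.is_posterior:
            missing = [n for n in required_posterior_channels() if n not in trial.channels]
            if missing:
                v.append(f"{tag}: posterior trial missing channels {missing}")

    bad_stim = [i for i in session.stimulation_trials if not (1 <= i <= len(session.trials))]
    if bad_stim:
        v.append(f"stimulation_trials out of range: {bad_stim}")
    else:
        non_post = [
            i for i in session.stimulation_trials if not session.trials[i - 1].is_posterior
        ]
        if non_post:
            v.append(f"stimulation_trials not posterior: {non_post}")
    return v


def sessions_equal(a: Session, b: Session, rtol: float = 0.0, atol: float = 0.0) -> bool:
    """Field-for-field equality of two sessions (sample arrays to tolerance)."""
    if (
        a.subject_id != b.subject_id
        or Protocol(a.protocol) != Protocol(b.protocol)
        or a.date != b.date
        or len(a.trials) != len(b.trials)
        or list(a.stimulation_trials) != list(b.stimulation_trials)
    ):
        return False
    mvc_a = {MuscleLabel(k): v for k, v in a.mvc.items()}
    mvc_b = {MuscleLabel(k): v for k, v in b.mvc.items()}
    if mvc_a.keys() != mvc_b.keys():
        return False
    if not all(np.isclose(mvc_a[k], mvc_b[k], rtol=rtol, atol=atol) for k in mvc_a):
        return False
    for ta, tb in zip(a.trials, b.trials):
        if (
            ta.index != tb.index
            or Direction(ta.direction) != Direction(tb.direction)
            or not np.isclose(ta.onset_s, tb.onset_s, rtol=rtol, atol=atol)
            or ta.outcome.status != tb.outcome.status
            or ta.outcome.failure_criterion != tb.outcome.failure_criterion
            or ta.frame_touch != tb.frame_touch
            or ta.foot_liftoff != tb.foot_liftoff
        ):
            return False
        for x, y in ((ta.outcome.restabilize_time, tb.outcome.restabilize_time),
                     (ta.restabilize_time, tb.restabilize_time)):
            if (x is None) != (y is None):
                return False
            if x is not None and not np.isclose(x, y, rtol=rtol, atol=atol):
                return False
        if ta.channels.keys() != tb.channels.keys():
            return False
        for name in ta.channels:
            ca, cb = ta.channels[name], tb.channels[name]
            if ca.units != cb.units or ca.rate != cb.rate or ca.samples.size != cb.samples.size:
                return False
            if not np.allclose(ca.samples, cb.samples, rtol=rtol, atol=atol):
                return False
    return True
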