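"""Centre-of-pressure, joint-kinematic and jump-force measures.

All perturbation measures use the 400 ms post-onset search window. The COP
peak search runs over the anterior (positive) direction only — a posterior
platform translation shifts the COP anteriorly — and the displacement is
reported as an absolute value. Joint excursion uses the absolute angle
change so goniometer mounting conventions cannot flip its sign. Ties break
to the first (earliest) maximum everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import JointLabel, TimeSeriesChannel

__all__ = [
    "CopMeasures",
    "JointExcursion",
    "JumpMeasures",
    "cop_displacement",
    "joint_excursion",
    "jump_measures",
    "mean_of_jumps",
    "SEARCH_WINDOW_S",
    "CONTACT_THRESHOLD_N",
]

SEARCH_WINDOW_S = 0.4
CONTACT_THRESHOLD_N = 3.0


@dataclass(frozen=True)
class CopMeasures:
    cop_d_mm: float   # anterior peak displacement, onset-referenced
    t_peak_ms: float  # onset -> first COP peak; NaN for a flat trace
    cop_v: float      # cop_d_mm / t_peak_ms (mm/ms); NaN when t_peak is NaN


@dataclass(frozen=True)
class JointExcursion:
    joint: JointLabel
    excursion_deg: float


@dataclass(frozen=True)
class JumpMeasures:
    peak_grf_n: float
    rfd_kn_s: float  # peak GRF (kN) / time from ground contact to peak (s)


def _onset_index(channel: TimeSeriesChannel, onset_s: float) -> int:
    # onset snapped to the nearest earlier sample of this channel's grid
    i = int(np.floor(onset_s * channel.rate + 1e-9))
    if not 0 <= i < channel.samples.size:
        raise ValueError(f"onset {onset_s} s outside channel {channel.label!r}")
    return i


def _window_end_index(channel: TimeSeriesChannel, onset_s: float) -> int:
    hi = int(np.ceil((onset_s + SEARCH_WINDOW_S) * channel.rate - 1e-9))
    if hi > channel.samples.size:
        raise ValueError(
            f"400 ms search window outside recording of channel {channel.label!r}"
        )
    return hi


def cop_displacement(cop_ap: TimeSeriesChannel, onset_s: float) -> CopMeasures:
    """Anterior COP peak displacement, its latency and the derived velocity.

    peak = max over [onset, onset+400 ms) of x(t) - x(onset) on the
    anterior-positive channel; COP_D = |peak|; t is the time from onset to
    the first maximum; COP_V = COP_D / t. A perfectly flat trace has zero
    displacement and no defined peak time.
    """
    i0 = _onset_index(cop_ap, onset_s)
    hi = _window_end_index(cop_ap, onset_s)
    d = cop_ap.samples[i0:hi] - cop_ap.samples[i0]
    k = int(np.argmax(d))
    peak = float(d[k])
    cop_d = abs(peak)
    if k == 0:
        return CopMeasures(cop_d, float("nan"), float("nan"))
    t_peak_ms = k / cop_ap.rate * 1000.0
    return CopMeasures(cop_d, t_peak_ms, cop_d / t_peak_ms)


def joint_excursion(angle: TimeSeriesChannel, onset_s: float) -> JointExcursion:
    """Peak absolute angle change from the onset position within 400 ms."""
    joint = JointLabel(angle.label.removeprefix("angle_"))
    i0 = _onset_index(angle, onset_s)
    hi = _window_end_index(angle, onset_s)
    d = np.abs(angle.samples[i0:hi] - angle.samples[i0])
    return JointExcursion(joint, float(np.max(d)))


def jump_measures(force: TimeSeriesChannel) -> JumpMeasures:
    """Peak vertical GRF and rate of force development of one jump.

    Ground contact is the first upward crossing of the 3 N threshold
    (linearly interpolated between samples); the peak is the global maximum
    after contact; RFD = peak (kN) / (t_peak - t_contact).
    """
    x = force.samples
    thr = CONTACT_THRESHOLD_N
    above = x > thr
    if not above.any() or above[0]:
        raise ValueError(
            f"no upward crossing of {thr} N in channel {force.label!r}"
        )
    k = int(np.argmax(above))  # first sample above threshold
    # interpolate the crossing inside [k-1, k]
    x0, x1 = x[k - 1], x[k]
    frac = (thr - x0) / (x1 - x0)
    t_contact = (k - 1 + frac) / force.rate
    kp = k + int(np.argmax(x[k:]))
    t_peak = kp / force.rate
    peak = float(x[kp])
    dt = t_peak - t_contact
    if dt <= 0:
        raise ValueError("force peak precedes ground contact")
    return JumpMeasures(peak, peak / 1000.0 / dt)


def mean_of_jumps(measures: Sequence[JumpMeasures], expected_count: int = 10) -> JumpMeasures:
    """Field-wise arithmetic mean of a block of jumps (default 10)."""
    if len(measures) != expected_count:
        raise ValueError(f"expected {expected_count} jumps, got {len(measures)}")
    return JumpMeasures(
        float(np.mean([m.peak_grf_n for m in measures])),
        float(np.mean([m.rfd_kn_s for m in measures])),
    )
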