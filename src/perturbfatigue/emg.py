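"""EMG-derived measures.

Phase windows relative to perturbation onset (half-open, ms):

======  ==============  ==========================================
name    window          meaning
======  ==============  ==========================================
PRE     [-100, 0)       pre-activation
SLR     [30, 60)        short-latency reflex response
MLR     [60, 85)        medium-latency reflex response
LLR     [85, 120)       long-latency reflex response
RP      [30, 120)       entire reflex phase (co-contraction window)
======  ==============  ==========================================

iEMG is the rectangle-rule integral of the rectified signal over a window
(mV*s); its time-normalised value is the mean rectified amplitude over the
window (mV), reported as %MVC after division by the muscle's MVC reference.

The co-contraction index (CCI) of an antagonistic pair is the per-sample
quantity ``(lower/higher) * (lower + higher)`` computed on rectified,
MVC-normalised signals and averaged over the window samples. The underlying
sum over samples and this mean differ by the fixed window sample count, a
factor that cancels under T1 normalisation; the mean is reported because it
is invariant to the sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MuscleLabel, TimeSeriesChannel

__all__ = [
    "PhaseWindow",
    "PHASES",
    "IEMG_PHASES",
    "PhaseIEMG",
    "CCI_PAIRS",
    "rectify",
    "window_slice",
    "integrate_window",
    "phase_iemg",
    "mvc_reference",
    "cci",
    "cci_from_channels",
    "peak_to_peak",
    "slr_peak_time",
]


@dataclass(frozen=True)
class PhaseWindow:
    name: str
    start_ms: float
    end_ms: float

    @property
    def duration_s(self) -> float:
        return (self.end_ms - self.start_ms) / 1000.0


PRE = PhaseWindow("PRE", -100.0, 0.0)
SLR = PhaseWindow("SLR", 30.0, 60.0)
MLR = PhaseWindow("MLR", 60.0, 85.0)
LLR = PhaseWindow("LLR", 85.0, 120.0)
RP = PhaseWindow("RP", 30.0, 120.0)

PHASES: dict[str, PhaseWindow] = {w.name: w for w in (PRE, SLR, MLR, LLR, RP)}
IEMG_PHASES = (PRE, SLR, MLR, LLR)

# antagonistic pairs (agonist, antagonist) per joint: ankle, knee, hip
CCI_PAIRS: dict[str, tuple[MuscleLabel, MuscleLabel]] = {
    "SOL_TA": (MuscleLabel.SOL, MuscleLabel.TA),
    "VM_BF": (MuscleLabel.VM, MuscleLabel.BF),
    "GM_RF": (MuscleLabel.GM, MuscleLabel.RF),
}


@dataclass(frozen=True)
class PhaseIEMG:
    muscle: MuscleLabel
    phase: str
    iemg_mvs: float  # integrated rectified value, mV*s
    mean_mv: float   # iemg / window duration, mV
    pct_mvc: float   # mean_mv / MVC reference * 100


def rectify(channel: TimeSeriesChannel) -> TimeSeriesChannel:
    """Element-wise absolute value; rate and units preserved. Idempotent."""
    return TimeSeriesChannel(channel.label, np.abs(channel.samples), channel.rate, channel.units)


def window_slice(channel: TimeSeriesChannel, onset_s: float, window: PhaseWindow) -> slice:
    """Sample indices whose time lies in [onset+start, onset+end).

    Sample k covers [k/rate, (k+1)/rate); it belongs to the window iff its
    start time does. Raises if the window is not fully inside the recording.
    """
    t0 = onset_s + window.start_ms / 1000.0
    t1 = onset_s + window.end_ms / 1000.0
    rate = channel.rate
    lo = int(np.ceil(t0 * rate - 1e-9))
    hi = int(np.ceil(t1 * rate - 1e-9))
    if lo < 0 or hi > channel.samples.size or lo >= hi:
        raise ValueError(
            f"window {window.name} [{t0:.3f}, {t1:.3f}) s outside recording of "
            f"channel {channel.label!r} (duration {channel.duration_s:.3f} s)"
        )
    return slice(lo, hi)


def integrate_window(channel: TimeSeriesChannel, onset_s: float, window: PhaseWindow) -> float:
    """Rectified rectangle-rule integral over the window, in mV*s."""
    sl = window_slice(channel, onset_s, window)
    return float(np.sum(np.abs(channel.samples[sl])) / channel.rate)


def phase_iemg(
    channel: TimeSeriesChannel,
    onset_s: float,
    mvc_ref_mv: float,
    phases: tuple[PhaseWindow, ...] = IEMG_PHASES,
) -> dict[str, PhaseIEMG]:
    """iEMG, mean amplitude and %MVC for each analysis phase."""
    if not mvc_ref_mv > 0:
        raise ValueError(f"MVC reference must be positive, got {mvc_ref_mv}")
    muscle = MuscleLabel(channel.label)
    out = {}
    for w in phases:
        iemg = integrate_window(channel, onset_s, w)
        mean_mv = iemg / w.duration_s
        out[w.name] = PhaseIEMG(muscle, w.name, iemg, mean_mv, 100.0 * mean_mv / mvc_ref_mv)
    return out


def mvc_reference(channel: TimeSeriesChannel, avg_window_s: float = 0.5) -> float:
    """MVC reference amplitude: peak of the moving average of the rectified
    recording (default 500 ms window). Requires a recording of at least one
    averaging window."""
    n = int(round(avg_window_s * channel.rate))
    x = np.abs(channel.samples)
    if x.size < n or n < 1:
        raise ValueError(
            f"MVC recording too short: {x.size} samples < {n} ({avg_window_s} s at {channel.rate} Hz)"
        )
    kernel = np.full(n, 1.0 / n)
    return float(np.max(np.convolve(x, kernel, mode="valid")))


def cci(a: np.ndarray, b: np.ndarray) -> float:
    """Co-contraction index of two rectified, MVC-normalised sample series.

    Per sample: ``(min/max) * (min + max)``, defined as 0 where both are 0;
    returned as the mean over samples. Symmetric in its arguments and
    degree-1 homogeneous (``cci(c*a, c*b) == c * cci(a, b)``).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"inputs must be 1-D and equal length, got {a.shape} and {b.shape}")
    if a.size == 0:
        raise ValueError("empty input")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("inputs must be rectified (non-negative)")
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    terms = np.where(hi > 0, lo / np.where(hi > 0, hi, 1.0) * (lo + hi), 0.0)
    return float(np.mean(terms))


def cci_from_channels(
    ch_a: TimeSeriesChannel,
    ch_b: TimeSeriesChannel,
    mvc_a: float,
    mvc_b: float,
    onset_s: float,
    window: PhaseWindow,
) -> float:
    """CCI over a phase window from two raw EMG channels and MVC references."""
    if not (mvc_a > 0 and mvc_b > 0):
        raise ValueError("MVC references must be positive")
    sa = window_slice(ch_a, onset_s, window)
    sb = window_slice(ch_b, onset_s, window)
    return cci(np.abs(ch_a.samples[sa]) / mvc_a, np.abs(ch_b.samples[sb]) / mvc_b)


def peak_to_peak(channel: TimeSeriesChannel, start_s: float, end_s: float) -> float:
    """max - min of the raw (unrectified) signal in [start_s, end_s)."""
    rate = channel.rate
    lo = int(np.ceil(start_s * rate - 1e-9))
    hi = int(np.ceil(end_s * rate - 1e-9))
    if lo < 0 or hi > channel.samples.size or lo >= hi:
        raise ValueError(f"empty or out-of-range window [{start_s}, {end_s}) s")
    seg = channel.samples[lo:hi]
    return float(np.max(seg) - np.min(seg))


def slr_peak_time(sol_channel: TimeSeriesChannel, onset_s: float) -> float:
    """Time (s, on the channel clock) of the peak rectified sample within the
    short-latency window; the earlier sample wins ties."""
    sl = window_slice(sol_channel, onset_s, SLR)
    seg = np.abs(sol_channel.samples[sl])
    k = sl.start + int(np.argmax(seg))  # argmax returns the first maximum
    return k / sol_channel.rate
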