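"""Calibrated synthetic FAT/CON session generator.

No raw recordings accompany the study this package reimplements, so every
downstream stage is exercised on synthetic cohorts whose *expected* extracted
features equal configurable per-quarter targets. The shipped
:func:`paper_preset` sets those targets to the printed grand means (and
between-subject SDs) of the study's summary tables: per-quarter failed-attempt
probabilities, anterior COP displacement, joint excursions, per-muscle
per-phase iEMG drift, antagonist co-contraction drift, and SOL H-reflex drift,
for 24 subjects.

Signal model (statistical, deliberately not biomechanical):

* raw EMG: x(t) = n(t) * e(t) * sqrt(pi/2), n(t) standard normal, so
  E|x(t)| = e(t) exactly; the envelope e(t) is a background level plus
  truncated-Gaussian reflex bursts centred in the SLR/MLR/LLR windows, each
  phase piece scaled by that muscle's subject-quarter multiplier so the
  T1-normalised phase iEMG recovers the configured multiplier exactly;
* within each antagonistic pair the two noise processes share a per-sample
  correlation calibrated (see ``_cci_expect``) so the pair's expected
  windowed co-contraction index follows the configured CCI drift without
  disturbing single-muscle activation;
* COP: baseline random walk plus, on posterior trials, an anterior
  raised-cosine excursion peaking ``t_peak_ms`` after onset; joint angles
  analogous;
* stimulation trials carry a stimulus marker at the SOL short-latency peak
  and biphasic M/H waveforms whose peak-to-peak amplitudes follow the
  configured drift; the natural SOL reflex bursts are suppressed after the
  stimulus (the electrical volley occupies the motoneuron pool).

Each subject's FAT session length (time to exhaustion) is drawn first and
outcomes are Bernoulli per quarter of that realized length, which keeps the
recovered per-quarter failure rates calibrated; the 50%-in-four stop rule is
available as :func:`apply_stop_criterion` and truncates sessions when
``truncate_at_stop`` is enabled (the paper preset disables it — see the
methods note for why truncating at the printed failure rates would distort
the very rates the preset is calibrated to).

Determinism: a cohort is a pure function of (config, seed); per-subject and
per-trial generators are spawned from one ``numpy`` SeedSequence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _cci_expect
from .emg import CCI_PAIRS, IEMG_PHASES, PHASES
from .model import (
    COP_CHANNEL,
    STIM_CHANNEL,
    Direction,
    JointLabel,
    MuscleLabel,
    Protocol,
    Quarter,
    Session,
    TimeSeriesChannel,
    Trial,
    TrialOutcome,
    angle_channel,
)
from .pipeline import quarter_bins

__all__ = [
    "GeneratorConfig",
    "SubjectParams",
    "paper_preset",
    "generate_emg_channel",
    "generate_trial",
    "generate_cohort",
    "apply_stop_criterion",
    "generate_jump_trace",
    "draw_subject_params",
]

_SQ = np.sqrt(np.pi / 2)
_Q = list(Quarter)
PHASE_NAMES = ("PRE", "SLR", "MLR", "LLR")


def _qt(means: Sequence[float], sds: Sequence[float]) -> dict:
    """Per-quarter target: mean and between-subject SD for T1..T4."""
    m, s = np.asarray(means, float), np.asarray(sds, float)
    if m.shape != (4,) or s.shape != (4,):
        raise ValueError("quarter targets need 4 means and 4 sds")
    if np.any(m <= 0) or np.any(s < 0):
        raise ValueError("target means must be positive, sds non-negative")
    return {"mean": m, "sd": s}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Targets are nested mappings keyed by protocol name ("FAT"/"CON") and,
    where applicable, muscle/phase/pair/joint names; each leaf is a
    ``{"mean": (4,), "sd": (4,)}`` per-quarter table. Multiplier targets
    (EMG, CCI, H-reflex) are relative to the subject's own T1 and must have
    mean 1, sd 0 at T1.
    """

    n_subjects: int = 24
    trials_per_set: int = 8
    min_sets: int = 10
    max_sets: int = 16
    gap_s: tuple[float, float] = (4.0, 6.0)

    emg_rate: float = 1000.0
    cop_rate: float = 100.0
    trial_duration_s: float = 0.6
    onset_s: float = 0.15

    mvc_mean_mv: dict = field(default_factory=dict)   # muscle -> mV
    mvc_cv: float = 0.25
    baseline_emg: dict = field(default_factory=dict)  # muscle -> phase -> %MVC at T1
    baseline_cv: float = 0.2

    emg_targets: dict = field(default_factory=dict)       # proto -> muscle -> phase -> qt
    cci_targets: dict = field(default_factory=dict)       # proto -> pair -> PRE|RP -> qt
    cop_targets: dict = field(default_factory=dict)       # proto -> qt (mm)
    excursion_targets: dict = field(default_factory=dict)  # proto -> joint -> qt (deg)
    hreflex_targets: dict = field(default_factory=dict)   # proto -> qt (relative)
    mwave_rel: float = 1.0
    failure_prob: dict = field(default_factory=dict)      # proto -> qt (fraction)

    burst_centers_ms: tuple[float, float, float] = (45.0, 72.0, 102.0)
    burst_widths_ms: tuple[float, float, float] = (8.0, 8.0, 10.0)
    rho_baseline: float = 0.45
    antagonist_lag_ms: float = 5.0      # baseline burst lag of the antagonist
    antagonist_lag_max_ms: float = 12.0  # keeps every lagged burst inside its window

    t_peak_ms: float = 150.0
    cop_pulse_s: float = 0.3
    cop_walk_step_mm: float = 0.05
    angle_noise_sd_deg: float = 0.05
    angle_baseline_deg: dict = field(default_factory=dict)  # joint -> deg

    trial_cv_cop: float = 0.15
    trial_cv_excursion: float = 0.10
    trial_cv_h: float = 0.10
    # fraction of the smallest quarter's log-variance carried by a subject's
    # persistent individual level (0 = independent draws per quarter)
    subject_persistence: float = 0.7

    h_amp_mean_mv: float = 3.0
    h_amp_cv: float = 0.25
    m_amp_mean_mv: float = 1.5
    m_center_ms: float = 14.0
    m_period_ms: float = 10.0
    h_center_ms: float = 40.0
    h_period_ms: float = 14.0

    stim_every: int = 2
    truncate_at_stop: bool = True

    n_jumps: int = 10
    jump_targets: dict = field(default_factory=dict)  # proto -> pre|post -> dict

    def validate(self) -> None:
        for proto, qt in self.failure_prob.items():
            if np.any(qt["mean"] < 0) or np.any(qt["mean"] > 1):
                raise ValueError(f"failure probabilities for {proto} outside [0, 1]")
        for proto, table in self.emg_targets.items():
            for mus, phases in table.items():
                for ph, qt in phases.items():
                    if not (qt["mean"][0] == 1.0 and qt["sd"][0] == 0.0):
                        raise ValueError(
                            f"T1 multiplier for {proto}/{mus}/{ph} must be 1.0 +- 0"
                        )
        if not 1 <= self.min_sets <= self.max_sets:
            raise ValueError("need 1 <= min_sets <= max_sets")


# Printed grand means and SDs: activation drift (T1-normalised iEMG
# multipliers) per muscle and phase, fatigue protocol, quarters T1..T4.
_FAT_EMG = {
    "GM": {
        "PRE": ([1.00, 1.04, 1.08, 1.12], [0, 0.12, 0.19, 0.16]),
        "SLR": ([1.00, 1.32, 1.35, 1.41], [0, 0.23, 0.27, 0.28]),
        "MLR": ([1.00, 1.37, 1.47, 1.46], [0, 0.32, 0.38, 0.33]),
        "LLR": ([1.00, 1.36, 1.40, 1.57], [0, 0.30, 0.36, 0.55]),
    },
    "RF": {
        "PRE": ([1.00, 1.05, 1.12, 1.16], [0, 0.20, 0.36, 0.41]),
        "SLR": ([1.00, 1.00, 1.34, 1.48], [0, 0.15, 0.46, 0.47]),
        "MLR": ([1.00, 1.00, 1.36, 1.49], [0, 0.13, 0.37, 0.40]),
        "LLR": ([1.00, 1.05, 1.51, 1.60], [0, 0.17, 0.71, 0.60]),
    },
    "VM": {
        "PRE": ([1.00, 1.04, 1.23, 1.28], [0, 0.10, 0.35, 0.51]),
        "SLR": ([1.00, 1.04, 1.49, 1.48], [0, 0.14, 0.33, 0.40]),
        "MLR": ([1.00, 1.03, 1.38, 1.62], [0, 0.17, 0.46, 0.64]),
        "LLR": ([1.00, 1.04, 1.35, 1.45], [0, 0.11, 0.30, 0.52]),
    },
    "BF": {
        "PRE": ([1.00, 1.21, 1.22, 1.25], [0, 0.34, 0.31, 0.37]),
        "SLR": ([1.00, 1.66, 1.87, 2.13], [0, 0.53, 0.57, 0.77]),
        "MLR": ([1.00, 1.73, 1.86, 2.11], [0, 0.34, 0.53, 0.92]),
        "LLR": ([1.00, 1.67, 1.90, 2.07], [0, 0.53, 0.71, 1.07]),
    },
    "SOL": {
        "PRE": ([1.00, 1.16, 1.21, 1.23], [0, 0.09, 0.13, 0.19]),
        "SLR": ([1.00, 1.12, 1.23, 1.33], [0, 0.17, 0.24, 0.31]),
        "MLR": ([1.00, 1.26, 1.34, 1.49], [0, 0.24, 0.36, 0.44]),
        "LLR": ([1.00, 1.24, 1.32, 1.46], [0, 0.23, 0.27, 0.33]),
    },
    "TA": {
        "PRE": ([1.00, 1.34, 1.42, 1.57], [0, 0.33, 0.41, 0.53]),
        "SLR": ([1.00, 1.42, 1.50, 1.53], [0, 0.43, 0.53, 0.49]),
        "MLR": ([1.00, 1.41, 1.35, 1.47], [0, 0.48, 0.42, 0.34]),
        "LLR": ([1.00, 1.38, 1.40, 1.34], [0, 0.33, 0.42, 0.36]),
    },
    # MG is recorded but carries no published drift; held flat.
    "MG": {ph: ([1.0] * 4, [0, 0.10, 0.10, 0.10]) for ph in PHASE_NAMES},
}

_FAT_CCI = {
    "GM_RF": {"PRE": ([1.00, 1.07, 1.11, 1.11], [0, 0.25, 0.62, 0.38]),
              "RP": ([1.00, 1.08, 1.30, 1.76], [0, 0.21, 0.37, 0.65])},
    "VM_BF": {"PRE": ([1.00, 1.01, 1.15, 1.15], [0, 0.20, 0.31, 0.36]),
              "RP": ([1.00, 1.03, 1.16, 1.40], [0, 0.13, 0.14, 0.33])},
    "SOL_TA": {"PRE": ([1.00, 1.12, 1.17, 1.15], [0, 0.34, 0.48, 0.21]),
               "RP": ([1.00, 1.28, 1.41, 1.64], [0, 0.19, 0.24, 0.43])},
}


def paper_preset() -> GeneratorConfig:
    """The study conditions: 24 subjects, targets from the printed tables.

    FAT quarter targets equal the printed FAT grand means; CON targets are
    constant across quarters at the T1 baseline, with representative
    between-subject SDs from the printed CON columns.
    """
    con_emg_sd = 0.15
    con_cci_sd = 0.15
    cfg = GeneratorConfig(
        n_subjects=24,
        mvc_mean_mv={
            "SOL": 0.50, "MG": 0.45, "TA": 0.40, "RF": 0.35,
            "BF": 0.35, "VM": 0.40, "GM": 0.30,
        },
        baseline_emg={
            # %MVC at T1 per phase; tonic plantarflexor activity dominates
            # unipedal stance, reflex bursts reach tens of %MVC.
            "SOL": {"PRE": 8, "SLR": 45, "MLR": 40, "LLR": 35},
            "MG": {"PRE": 7, "SLR": 40, "MLR": 35, "LLR": 30},
            "TA": {"PRE": 6, "SLR": 35, "MLR": 32, "LLR": 30},
            "RF": {"PRE": 4, "SLR": 15, "MLR": 18, "LLR": 20},
            "VM": {"PRE": 4, "SLR": 15, "MLR": 18, "LLR": 20},
            "BF": {"PRE": 4, "SLR": 12, "MLR": 15, "LLR": 18},
            "GM": {"PRE": 3, "SLR": 10, "MLR": 12, "LLR": 15},
        },
        emg_targets={
            "FAT": {m: {ph: _qt(*t) for ph, t in table.items()} for m, table in _FAT_EMG.items()},
            "CON": {m: {ph: _qt([1.0] * 4, [0, con_emg_sd, con_emg_sd, con_emg_sd])
                        for ph in PHASE_NAMES} for m in _FAT_EMG},
        },
        cci_targets={
            "FAT": {p: {w: _qt(*t) for w, t in table.items()} for p, table in _FAT_CCI.items()},
            "CON": {p: {w: _qt([1.0] * 4, [0, con_cci_sd, con_cci_sd, con_cci_sd])
                        for w in ("PRE", "RP")} for p in _FAT_CCI},
        },
        cop_targets={
            "FAT": _qt([17.0, 16.9, 14.0, 12.2], [10.5, 10.2, 8.7, 8.9]),
            "CON": _qt([17.0] * 4, [11.0] * 4),
        },
        excursion_targets={
            "FAT": {
                "hip": _qt([2.2, 5.0, 1.2, 1.0], [1.3, 1.8, 0.7, 0.61]),
                "knee": _qt([2.9, 3.7, 1.6, 1.2], [2.1, 3.2, 1.0, 0.9]),
                "ankle": _qt([6.2, 5.5, 5.3, 5.1], [1.1, 1.2, 0.9, 1.1]),
            },
            "CON": {
                "hip": _qt([2.2] * 4, [1.4] * 4),
                "knee": _qt([2.9] * 4, [2.1] * 4),
                "ankle": _qt([6.2] * 4, [0.55] * 4),
            },
        },
        hreflex_targets={
            "FAT": _qt([1.00, 0.97, 0.92, 0.86], [0, 0.22, 0.17, 0.18]),
            "CON": _qt([1.0] * 4, [0, 0.20, 0.20, 0.20]),
        },
        failure_prob={
            "FAT": _qt(np.array([0.5, 0.8, 9.3, 15.9]) / 100,
                       np.array([0.3, 0.3, 12.2, 13.5]) / 100),
            "CON": _qt([0.006] * 4, [0.003] * 4),
        },
        angle_baseline_deg={"ankle": 10.0, "knee": 15.0, "hip": 5.0},
        jump_targets={
            # pre protocol ~21 kN/s at ~2.08 kN peak; FAT halves the peak
            "FAT": {"pre": {"peak_n": 2084.0, "sd_n": 401.0, "rfd_kn_s": 21.0},
                    "post": {"peak_n": 1042.0, "sd_n": 401.0, "rfd_kn_s": 13.0}},
            "CON": {"pre": {"peak_n": 2069.0, "sd_n": 444.0, "rfd_kn_s": 21.0},
                    "post": {"peak_n": 2069.0, "sd_n": 444.0, "rfd_kn_s": 21.0}},
        },
        truncate_at_stop=False,
    )
    cfg.validate()
    return cfg


def _lognormal(rng: np.random.Generator, mean, sd, size=None):
    """Lognormal draws with *exact* first moment ``mean`` and SD ``sd``.

    sd = 0 degenerates to the mean itself, so a target with zero spread is
    reproduced deterministically.
    """
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    if np.any(mean <= 0):
        raise ValueError("lognormal mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def apply_stop_criterion(failed_flags: Sequence[bool]) -> Optional[int]:
    """First 1-based index i >= 4 with >= 2 failures among trials i-3..i.

    The exhaustion stop rule — half of any four consecutive perturbations
    failed — read as a sliding window of four trials.
    Returns None if it never fires.
    """
    flags = np.asarray(failed_flags, dtype=bool)
    if flags.size < 4:
        return None
    counts = np.convolve(flags.astype(int), np.ones(4, dtype=int), mode="valid")
    hits = np.nonzero(counts >= 2)[0]
    return int(hits[0]) + 4 if hits.size else None


def generate_emg_channel(
    envelope: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    label: str = "emg",
    noise: Optional[np.ndarray] = None,
) -> TimeSeriesChannel:
    """Raw EMG with a prescribed expected rectified value.

    x_k = n_k * e_k * sqrt(pi/2) with n_k standard normal, so E|x_k| = e_k.
    ``noise`` lets the caller supply (possibly correlated) standard-normal
    draws; by default they come from ``rng``.
    """
    e = np.asarray(envelope, dtype=float)
    if np.any(e < 0):
        raise ValueError("envelope must be non-negative")
    n = rng.standard_normal(e.size) if noise is None else np.asarray(noise, float)
    return TimeSeriesChannel(label, n * e * _SQ, rate, "mV")


@dataclass
class SubjectParams:
    """One subject's drawn characteristics and per-quarter schedules."""

    subject_id: str
    mvc: dict                 # muscle -> mV
    baseline_pct: dict        # muscle -> phase -> %MVC
    angle_base: dict          # joint -> deg
    h_base_mv: float
    m_base_mv: float
    emg_mult: dict            # proto -> muscle -> phase -> (4,)
    cop_amp: dict             # proto -> (4,) mm
    exc_amp: dict             # proto -> joint -> (4,) deg
    h_mult: dict              # proto -> (4,)
    cci_dials: dict           # proto -> pair -> PRE|RP -> {"rho": (4,), "lag_ms": (4,)}
    failure_p: dict           # proto -> (4,)


def _phase_region(cfg: GeneratorConfig, t_rel: np.ndarray) -> dict[str, np.ndarray]:
    """Boolean masks of the analysis phases on the trial-relative time grid."""
    masks = {}
    for name in PHASE_NAMES:
        w = PHASES[name]
        masks[name] = (t_rel >= w.start_ms / 1000.0) & (t_rel < w.end_ms / 1000.0)
    return masks


def _envelope(
    cfg: GeneratorConfig,
    sub: SubjectParams,
    muscle: str,
    mult: np.ndarray,  # multipliers for PRE, SLR, MLR, LLR (this quarter)
    t_rel: np.ndarray,
    posterior: bool,
    mask_after_s: Optional[float] = None,
    burst_lag_ms: float = 0.0,
) -> np.ndarray:
    """Expected rectified amplitude (mV) on the trial grid.

    Background at the PRE level everywhere; on posterior trials each reflex
    window is replaced by its own scaled piece (background + truncated
    Gaussian burst) whose *discrete mean* equals that phase's target
    amplitude exactly, so T1-normalised phase iEMG recovers the multipliers
    with no leakage between phases. ``burst_lag_ms`` shifts the burst
    centres within their windows (the per-window renormalisation keeps the
    phase mean exact regardless), which desynchronises an antagonist's
    bursts from its partner's without touching either muscle's iEMG.
    """
    mvc = sub.mvc[muscle]
    b = {ph: sub.baseline_pct[muscle][ph] / 100.0 * mvc for ph in PHASE_NAMES}
    m = dict(zip(PHASE_NAMES, mult))
    env = np.full(t_rel.size, b["PRE"] * m["PRE"])
    if posterior:
        masks = _phase_region(cfg, t_rel)
        for iph, ph in enumerate(("SLR", "MLR", "LLR")):
            sel = masks[ph]
            if not sel.any():
                continue
            c = (cfg.burst_centers_ms[iph] + burst_lag_ms) / 1000.0
            w = cfg.burst_widths_ms[iph] / 1000.0
            shape = np.exp(-0.5 * ((t_rel[sel] - c) / w) ** 2)
            mean_shape = shape.mean()
            amp = (b[ph] - b["PRE"]) / mean_shape if mean_shape > 0 else 0.0
            env[sel] = m[ph] * (b["PRE"] + amp * shape)
    if mask_after_s is not None:
        env[t_rel >= mask_after_s] = b["PRE"]
    return env


def _biphasic_wave(t_rel: np.ndarray, center_s: float, period_s: float, pp: float) -> np.ndarray:
    """One full sine cycle of peak-to-peak amplitude ``pp`` centred at ``center_s``."""
    out = np.zeros(t_rel.size)
    sel = np.abs(t_rel - center_s) <= period_s / 2
    out[sel] = pp / 2 * np.sin(2 * np.pi * (t_rel[sel] - center_s) / period_s)
    return out


def _raised_cosine(t_rel: np.ndarray, amp: float, peak_s: float, duration_s: float) -> np.ndarray:
    out = np.zeros(t_rel.size)
    t0 = peak_s - duration_s / 2
    sel = (t_rel >= t0) & (t_rel <= t0 + duration_s)
    out[sel] = amp * 0.5 * (1 - np.cos(2 * np.pi * (t_rel[sel] - t0) / duration_s))
    return out


def generate_trial(
    cfg: GeneratorConfig,
    sub: SubjectParams,
    protocol: Protocol | str,
    quarter: Quarter | int,
    direction: Direction | str,
    rng: np.random.Generator,
    *,
    index: int = 1,
    start_time_s: float = 0.0,
    stimulated: bool = False,
    failed: Optional[bool] = None,
) -> Trial:
    """Generate one perturbation trial with all channels and its outcome.

    ``failed=None`` draws the outcome Bernoulli(failure_prob[quarter]); a
    bool forces it. Failed trials pick one of the two failure criteria with
    equal probability.
    """
    proto = Protocol(protocol).value
    qi = int(quarter) - 1
    direction = Direction(direction)
    posterior = direction == Direction.POSTERIOR
    rate = cfg.emg_rate
    n = int(round(cfg.trial_duration_s * rate))
    t_rel = np.arange(n) / rate - cfg.onset_s
    channels: dict[str, TimeSeriesChannel] = {}

    stim_time_rel = cfg.burst_centers_ms[0] / 1000.0  # SOL SLR peak
    dials = sub.cci_dials[proto]

    # EMG: noise drawn jointly for the three antagonist pairs, plus MG alone
    drawn: dict[str, np.ndarray] = {}
    lag_of: dict[str, float] = {}
    for pair, (mus_a, mus_b) in CCI_PAIRS.items():
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        rho = np.where(
            t_rel < PHASES["RP"].start_ms / 1000.0,
            dials[pair]["PRE"]["rho"][qi],
            dials[pair]["RP"]["rho"][qi],
        )
        drawn[mus_a.value] = z1
        drawn[mus_b.value] = rho * z1 + np.sqrt(1 - rho**2) * z2
        lag_of[mus_b.value] = float(dials[pair]["RP"]["lag_ms"][qi])
    drawn[MuscleLabel.MG.value] = rng.standard_normal(n)

    for mus in MuscleLabel:
        mult = np.array([sub.emg_mult[proto][mus.value][ph][qi] for ph in PHASE_NAMES])
        mask_after = stim_time_rel if (stimulated and mus == MuscleLabel.SOL) else None
        env = _envelope(cfg, sub, mus.value, mult, t_rel, posterior, mask_after,
                        burst_lag_ms=lag_of.get(mus.value, 0.0))
        ch = generate_emg_channel(env, rate, rng, label=mus.value, noise=drawn[mus.value])
        if stimulated and mus == MuscleLabel.SOL:
            h_pp = sub.h_base_mv * sub.h_mult[proto][qi] * _lognormal(rng, 1.0, cfg.trial_cv_h)
            m_pp = sub.m_base_mv * cfg.mwave_rel * _lognormal(rng, 1.0, cfg.trial_cv_h)
            wave = _biphasic_wave(t_rel, stim_time_rel + cfg.m_center_ms / 1000.0,
                                  cfg.m_period_ms / 1000.0, m_pp)
            wave += _biphasic_wave(t_rel, stim_time_rel + cfg.h_center_ms / 1000.0,
                                   cfg.h_period_ms / 1000.0, h_pp)
            ch = TimeSeriesChannel(ch.label, ch.samples + wave, rate, "mV")
        channels[mus.value] = ch

    # stimulus marker
    stim = np.zeros(n)
    if stimulated:
        stim[int(round((cfg.onset_s + stim_time_rel) * rate))] = 1.0
    channels[STIM_CHANNEL] = TimeSeriesChannel(STIM_CHANNEL, stim, rate, "")

    # COP at its own (coarser) rate: baseline random walk + anterior pulse
    n_cop = int(round(cfg.trial_duration_s * cfg.cop_rate))
    t_cop = np.arange(n_cop) / cfg.cop_rate - cfg.onset_s
    cop = np.cumsum(rng.standard_normal(n_cop) * cfg.cop_walk_step_mm)
    if posterior:
        amp = sub.cop_amp[proto][qi] * _lognormal(rng, 1.0, cfg.trial_cv_cop)
        cop = cop + _raised_cosine(t_cop, amp, cfg.t_peak_ms / 1000.0, cfg.cop_pulse_s)
    channels[COP_CHANNEL] = TimeSeriesChannel(COP_CHANNEL, cop, cfg.cop_rate, "mm")

    for joint in JointLabel:
        base = sub.angle_base[joint.value]
        ang = base + rng.standard_normal(n) * cfg.angle_noise_sd_deg
        if posterior:
            amp = sub.exc_amp[proto][joint.value][qi] * _lognormal(rng, 1.0, cfg.trial_cv_excursion)
            ang = ang + _raised_cosine(t_rel, amp, cfg.t_peak_ms / 1000.0, cfg.cop_pulse_s)
        channels[angle_channel(joint)] = TimeSeriesChannel(angle_channel(joint), ang, rate, "deg")

    if failed is None:
        failed = bool(rng.random() < sub.failure_p[proto][qi])
    if failed:
        criterion = "frame_touch" if rng.random() < 0.5 else "foot_liftoff"
        outcome = TrialOutcome("failed", criterion, None)
        frame_touch = criterion == "frame_touch"
        foot_liftoff = criterion == "foot_liftoff"
        restab = None
    else:
        restab = float(rng.uniform(0.5, 2.0))
        outcome = TrialOutcome("success", "none", restab)
        frame_touch = foot_liftoff = False

    return Trial(
        index=index,
        direction=direction,
        onset_s=cfg.onset_s,
        outcome=outcome,
        channels=channels,
        frame_touch=frame_touch,
        foot_liftoff=foot_liftoff,
        restabilize_time=restab,
        start_time_s=start_time_s,
    )


def _stratified_lognormal(
    rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray, n: int
) -> np.ndarray:
    """(n, 4) exact-mean lognormal draws, Latin-hypercube stratified over the
    cohort: each quarter's n draws occupy one random quantile stratum each,
    so the cohort mean concentrates at the target while the marginal
    distribution (and its SD) is unchanged."""
    from scipy.special import ndtri

    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    out = np.empty((n, 4))
    for q in range(4):
        if sd[q] == 0:
            out[:, q] = mean[q]
            continue
        u = (rng.permutation(n) + rng.random(n)) / n
        sigma2 = np.log1p((sd[q] / mean[q]) ** 2)
        mu = np.log(mean[q]) - sigma2 / 2
        out[:, q] = np.exp(mu + np.sqrt(sigma2) * ndtri(u))
    return out


def _persistent_quarter_draws(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: np.ndarray,
    n: int,
    frac: float,
) -> np.ndarray:
    """(n, 4) target draws with a persistent subject factor.

    A subject keeps an individual level across quarters (real cohorts do),
    so each quarter's value is a shared subject factor times a
    quarter-specific residual, both stratified exact-mean lognormals. The
    log-variance split is exact: the per-quarter marginal keeps mean and SD
    at the configured values, while the fraction ``frac`` of the smallest
    quarter's log-variance is carried by the persistent factor.
    """
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    cv = np.divide(sd, mean, out=np.zeros_like(sd), where=mean > 0)
    pos = cv[cv > 0]
    if pos.size == 0 or frac <= 0:
        return _stratified_lognormal(rng, mean, sd, n)
    logvar_s = frac * np.min(np.log1p(pos**2))
    cv_s = np.sqrt(np.expm1(logvar_s))
    factor = _stratified_lognormal(rng, np.full(4, 1.0), np.full(4, cv_s), n)[:, 0]
    out = np.empty((n, 4))
    for q in range(4):
        if cv[q] == 0:
            out[:, q] = mean[q]
            continue
        logvar_res = np.log1p(cv[q] ** 2) - logvar_s
        cv_res = np.sqrt(np.expm1(logvar_res))
        res = _stratified_lognormal(
            rng, np.full(4, 1.0), np.full(4, cv_res), n
        )[:, 0]
        out[:, q] = mean[q] * factor * res
    return out


def _cohort_target_draws(cfg: GeneratorConfig, n: int, rng: np.random.Generator) -> dict:
    """Per-quarter target draws for a whole cohort (leading axis = subject)."""
    frac = cfg.subject_persistence
    draw = lambda qt: _persistent_quarter_draws(rng, qt["mean"], qt["sd"], n, frac)
    draws: dict = {}
    for proto in ("FAT", "CON"):
        draws[proto] = {
            "emg": {
                mus: {ph: draw(qt) for ph, qt in table.items()}
                for mus, table in cfg.emg_targets[proto].items()
            },
            "cop": draw(cfg.cop_targets[proto]),
            "exc": {j: draw(qt) for j, qt in cfg.excursion_targets[proto].items()},
            "h": draw(cfg.hreflex_targets[proto]),
            "fail": draw(cfg.failure_prob[proto]),
            "cci": {
                pair: {w: draw(qt) for w, qt in table.items()}
                for pair, table in cfg.cci_targets[proto].items()
            },
        }
    return draws


def _subject_slice(cohort_draws: dict, i: int) -> dict:
    def take(x):
        if isinstance(x, dict):
            return {k: take(v) for k, v in x.items()}
        return np.asarray(x[i], float)

    return take(cohort_draws)


def draw_subject_params(
    cfg: GeneratorConfig,
    subject_id: str,
    rng: np.random.Generator,
    predrawn: Optional[dict] = None,
) -> SubjectParams:
    """Draw one subject: anthropometric-like baselines shared between
    protocols, per-quarter target draws per protocol, and the calibrated
    within-pair co-contraction dials.

    ``predrawn`` supplies this subject's slice of cohort-level stratified
    target draws (see :func:`_cohort_target_draws`); without it the targets
    are drawn independently from ``rng``.
    """
    mvc = {m: float(_lognormal(rng, cfg.mvc_mean_mv[m], cfg.mvc_cv * cfg.mvc_mean_mv[m]))
           for m in cfg.mvc_mean_mv}
    baseline = {
        mus: {ph: float(_lognormal(rng, pct, cfg.baseline_cv * pct))
              for ph, pct in table.items()}
        for mus, table in cfg.baseline_emg.items()
    }
    angle_base = {j: float(rng.normal(v, 2.0)) for j, v in cfg.angle_baseline_deg.items()}
    h_base = float(_lognormal(rng, cfg.h_amp_mean_mv, cfg.h_amp_cv * cfg.h_amp_mean_mv))
    m_base = float(_lognormal(rng, cfg.m_amp_mean_mv, cfg.h_amp_cv * cfg.m_amp_mean_mv))

    emg_mult, cop_amp, exc_amp, h_mult, failure_p, cci_targets = {}, {}, {}, {}, {}, {}
    for proto in ("FAT", "CON"):
        if predrawn is not None:
            d = predrawn[proto]
            emg_mult[proto] = d["emg"]
            cop_amp[proto] = d["cop"]
            exc_amp[proto] = d["exc"]
            h_mult[proto] = d["h"]
            failure_p[proto] = np.clip(d["fail"], 0.0, 1.0)
            cci_targets[proto] = d["cci"]
            continue
        emg_mult[proto] = {
            mus: {ph: np.asarray(_lognormal(rng, qt["mean"], qt["sd"]), float)
                  for ph, qt in table.items()}
            for mus, table in cfg.emg_targets[proto].items()
        }
        cop_amp[proto] = np.asarray(
            _lognormal(rng, cfg.cop_targets[proto]["mean"], cfg.cop_targets[proto]["sd"]), float
        )
        exc_amp[proto] = {
            j: np.asarray(_lognormal(rng, qt["mean"], qt["sd"]), float)
            for j, qt in cfg.excursion_targets[proto].items()
        }
        h_mult[proto] = np.asarray(
            _lognormal(rng, cfg.hreflex_targets[proto]["mean"], cfg.hreflex_targets[proto]["sd"]),
            float,
        )
        failure_p[proto] = np.clip(
            np.asarray(
                _lognormal(rng, cfg.failure_prob[proto]["mean"], cfg.failure_prob[proto]["sd"]),
                float,
            ),
            0.0,
            1.0,
        )
        cci_targets[proto] = {
            pair: {w: np.asarray(_lognormal(rng, qt["mean"], qt["sd"]), float)
                   for w, qt in table.items()}
            for pair, table in cfg.cci_targets[proto].items()
        }

    sub = SubjectParams(
        subject_id=subject_id,
        mvc=mvc,
        baseline_pct=baseline,
        angle_base=angle_base,
        h_base_mv=h_base,
        m_base_mv=m_base,
        emg_mult=emg_mult,
        cop_amp=cop_amp,
        exc_amp=exc_amp,
        h_mult=h_mult,
        cci_dials={},
        failure_p=failure_p,
    )
    sub.cci_dials = _calibrate_subject_cci(cfg, sub, cci_targets)
    return sub


def _calibrate_subject_cci(
    cfg: GeneratorConfig, sub: SubjectParams, cci_targets: dict
) -> dict:
    """Per pair, window and quarter: the two co-contraction dials.

    The drawn CCI multiplier (relative to T1 at the baseline dials) is hit
    by adjusting, in order: the within-pair noise correlation rho (raises
    co-contraction above envelope-driven independence), and the antagonist
    burst lag (temporal desynchronisation, the only way to push
    co-contraction below it). Values outside the attainable range are
    clamped to the nearest endpoint — a documented limitation for targets
    far below the joint activation drift (pre-activation CCI cells).
    """
    from scipy.optimize import brentq

    rate = cfg.emg_rate
    n = int(round(cfg.trial_duration_s * rate))
    t_rel = np.arange(n) / rate - cfg.onset_s
    windows = {
        "PRE": (t_rel >= -0.1) & (t_rel < 0.0),
        "RP": (t_rel >= PHASES["RP"].start_ms / 1000.0) & (t_rel < PHASES["RP"].end_ms / 1000.0),
    }
    lag0 = cfg.antagonist_lag_ms
    lag_max = cfg.antagonist_lag_max_ms
    rho_max = _cci_expect.RHO_MAX
    out: dict = {}
    for proto in ("FAT", "CON"):
        out[proto] = {}
        for pair, (mus_a, mus_b) in CCI_PAIRS.items():
            out[proto][pair] = {}
            targets = cci_targets[proto][pair]

            def env_pair(qi: int, lag_ms: float, sel: np.ndarray):
                env = {}
                for mus, lag in ((mus_a.value, 0.0), (mus_b.value, lag_ms)):
                    mult = np.array([sub.emg_mult[proto][mus][ph][qi] for ph in PHASE_NAMES])
                    env[mus] = (
                        _envelope(cfg, sub, mus, mult, t_rel, posterior=True,
                                  burst_lag_ms=lag)[sel] / sub.mvc[mus]
                    )
                a, b = env[mus_a.value], env[mus_b.value]
                return np.maximum(a, b), np.minimum(a, b)

            for w, sel in windows.items():
                rho_q = np.empty(4)
                lag_q = np.empty(4)
                rho_q[0], lag_q[0] = cfg.rho_baseline, lag0

                def f(rho: float, lag: float, qi: int) -> float:
                    hi, lo = env_pair(qi, lag, sel)
                    return _cci_expect.expected_cci(hi, lo, rho)

                base_cci = f(cfg.rho_baseline, lag0, 0)
                for qi in range(1, 4):
                    goal = targets[w][qi] * base_cci
                    v_min = f(0.0, lag0, qi)
                    v_max = f(rho_max, lag0, qi)
                    if v_min <= goal <= v_max:
                        rho_q[qi] = brentq(lambda r: f(r, lag0, qi) - goal, 0.0, rho_max, xtol=1e-5)
                        lag_q[qi] = lag0
                    elif goal < v_min:
                        rho_q[qi] = 0.0
                        if f(0.0, lag_max, qi) >= goal:
                            lag_q[qi] = lag_max  # clamp: desynchronisation exhausted
                        else:
                            lag_q[qi] = brentq(
                                lambda L: f(0.0, L, qi) - goal, lag0, lag_max, xtol=1e-4
                            )
                    else:
                        rho_q[qi] = rho_max
                        if f(rho_max, 0.0, qi) <= goal:
                            lag_q[qi] = 0.0  # clamp: full synchrony exhausted
                        else:
                            lag_q[qi] = brentq(
                                lambda L: f(rho_max, L, qi) - goal, 0.0, lag0, xtol=1e-4
                            )
                out[proto][pair][w] = {"rho": rho_q, "lag_ms": lag_q}
    return out


def _direction_schedule(cfg: GeneratorConfig, rng: np.random.Generator) -> list[Direction]:
    """max_sets sets, each a random permutation of the 8 directions (so one
    posterior trial per set); shared between the FAT and CON sessions."""
    dirs = list(Direction)
    sched: list[Direction] = []
    for _ in range(cfg.max_sets):
        sched.extend(dirs[i] for i in rng.permutation(len(dirs)))
    return sched


def _generate_session(
    cfg: GeneratorConfig,
    sub: SubjectParams,
    proto: str,
    schedule: list[Direction],
    n_trials: int,
    trial_seeds: list[np.random.SeedSequence],
    rng: np.random.Generator,
) -> Session:
    quarters = quarter_bins(n_trials)
    # outcomes first: Bernoulli per realized quarter, optional stop truncation
    fails = rng.random(n_trials) < sub.failure_p[proto][np.asarray(quarters) - 1]
    if cfg.truncate_at_stop:
        k = apply_stop_criterion(fails)
        if k is not None:
            n_trials = k
            fails = fails[:k]
            quarters = quarter_bins(n_trials)

    posterior_count = 0
    trials: list[Trial] = []
    t_clock = 0.0
    stim_idx: list[int] = []
    for i in range(n_trials):
        direction = schedule[i]
        stimulated = False
        if direction == Direction.POSTERIOR:
            stimulated = posterior_count % cfg.stim_every == 1 if cfg.stim_every > 1 else True
            posterior_count += 1
        trng = np.random.default_rng(trial_seeds[i])
        trial = generate_trial(
            cfg, sub, proto, int(quarters[i]), direction, trng,
            index=i + 1, start_time_s=t_clock, stimulated=stimulated,
            failed=bool(fails[i]),
        )
        if stimulated:
            stim_idx.append(i + 1)
        trials.append(trial)
        t_clock += cfg.trial_duration_s + float(rng.uniform(*cfg.gap_s))
    return Session(
        subject_id=sub.subject_id,
        protocol=Protocol(proto),
        trials=trials,
        mvc={MuscleLabel(m): v for m, v in sub.mvc.items()},
        stimulation_trials=stim_idx,
        date="synthetic",
    )


def generate_cohort(
    cfg: GeneratorConfig, seed: int, n_subjects: Optional[int] = None
) -> list[tuple[Session, Session]]:
    """Generate ``n_subjects`` matched (FAT, CON) session pairs.

    Per subject: the FAT session length is the subject's drawn time to
    exhaustion (uniform min_sets..max_sets sets; truncated earlier by the
    stop rule when ``truncate_at_stop``); the CON session runs the full
    ``max_sets`` so it can later be volume-matched by truncation. Both share
    one direction schedule, so the i-th trial of CON equals the i-th of FAT
    in direction and stimulation status.
    """
    cfg.validate()
    n_sub = cfg.n_subjects if n_subjects is None else n_subjects
    root = np.random.SeedSequence(seed)
    cohort_ss, *subject_ss = root.spawn(n_sub + 1)
    # between-subject target draws are stratified across the cohort
    cohort_draws = _cohort_target_draws(cfg, n_sub, np.random.default_rng(cohort_ss))
    cohort: list[tuple[Session, Session]] = []
    for s, sub_ss in enumerate(subject_ss, start=1):
        ss_params, ss_fat, ss_con, ss_trials = sub_ss.spawn(4)
        rng = np.random.default_rng(ss_params)
        sub = draw_subject_params(
            cfg, f"S{s:02d}", rng, predrawn=_subject_slice(cohort_draws, s - 1)
        )
        schedule = _direction_schedule(cfg, rng)
        n_fat = int(rng.integers(cfg.min_sets, cfg.max_sets + 1)) * cfg.trials_per_set
        n_con = cfg.max_sets * cfg.trials_per_set
        trial_seeds = ss_trials.spawn(2 * n_con)
        fat = _generate_session(
            cfg, sub, "FAT", schedule, n_fat, trial_seeds[:n_con], np.random.default_rng(ss_fat)
        )
        con = _generate_session(
            cfg, sub, "CON", schedule, n_con, trial_seeds[n_con:], np.random.default_rng(ss_con)
        )
        cohort.append((fat, con))
    return cohort


def generate_jump_trace(
    peak_target_n: float,
    time_to_peak_s: float,
    rng: Optional[np.random.Generator] = None,
    rate: float = 1000.0,
    flight_s: float = 0.1,
    decay_s: float = 0.3,
    noise_sd_n: float = 0.0,
) -> TimeSeriesChannel:
    """Vertical force trace of one maximal jump landing/push-off.

    Zero during flight, linear rise to ``peak_target_n`` over
    ``time_to_peak_s`` after contact, raised-cosine decay back to zero.
    Supports peak-GRF and RFD extraction: with a noiseless trace the
    extracted peak equals the target exactly and RFD differs from
    peak/time_to_peak only by the 3 N threshold offset.
    """
    if peak_target_n <= 3.0:
        raise ValueError("peak force must exceed the 3 N contact threshold")
    if time_to_peak_s <= 0:
        raise ValueError("time_to_peak_s must be positive")
    dt = 1.0 / rate
    t_rise = np.arange(dt, time_to_peak_s + dt / 2, dt)
    rise = peak_target_n * t_rise / time_to_peak_s
    t_decay = np.arange(dt, decay_s + dt / 2, dt)
    decay = peak_target_n * 0.5 * (1 + np.cos(np.pi * t_decay / decay_s))
    x = np.concatenate([
        np.zeros(int(round(flight_s * rate))),
        [0.0],  # contact sample, below threshold
        rise,
        decay,
        np.zeros(int(round(0.05 * rate))),
    ])
    if noise_sd_n > 0:
        if rng is None:
            raise ValueError("need a generator for noisy traces")
        contact = x > 0
        x = x + contact * rng.standard_normal(x.size) * noise_sd_n
    return TimeSeriesChannel("grf_z", x, rate, "N")


def config_to_dict(cfg: GeneratorConfig) -> dict:
    """Plain-dict form of a config (JSON/YAML-serialisable)."""
    d = dataclasses.asdict(cfg)

    def conv(x):
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, np.ndarray):
            return [float(v) for v in x]
        if isinstance(x, tuple):
            return [conv(v) for v in x]
        return x

    return conv(d)


def config_from_dict(d: dict) -> GeneratorConfig:
    kwargs = dict(d)
    for key in ("gap_s", "burst_centers_ms", "burst_widths_ms"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])

    def restore(x):
        if isinstance(x, dict):
            if set(x) == {"mean", "sd"}:
                return _qt(x["mean"], x["sd"])
            return {k: restore(v) for k, v in x.items()}
        return x

    cfg = GeneratorConfig(**{k: restore(v) for k, v in kwargs.items()})
    cfg.validate()
    return cfg
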