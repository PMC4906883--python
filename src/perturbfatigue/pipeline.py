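"""From sessions to the quarter-level analysis tables.

The analysis unit is the subject: each session's trials are binned into four
contiguous quarters (T1-T4), features are extracted from successful
posterior trials only, averaged per subject x quarter, EMG/CCI/H-reflex
parameters are normalised to the subject's own T1, and grand means are taken
across subjects (every subject weight 1, mirroring the within-subject
statistics). Failed trials contribute to the failure rate and to nothing
else. Stimulation trials provide H-reflex/M-wave amplitudes and the
mechanical measures, but are excluded from iEMG/CCI extraction because the
electrically evoked response replaces the natural reflex burst.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import emg as emg_mod
from . import mech as mech_mod
from . import stats as stats_mod
from .emg import CCI_PAIRS, IEMG_PHASES, PHASES
from .model import (
    COP_CHANNEL,
    STIM_CHANNEL,
    JointLabel,
    MuscleLabel,
    Protocol,
    Quarter,
    Session,
    Trial,
    TrialOutcome,
    angle_channel,
)

__all__ = [
    "classify_outcome",
    "quarter_bins",
    "failed_rate",
    "match_control",
    "extract_features",
    "quarter_means",
    "normalize_to_t1",
    "grand_means",
    "run_pipeline",
    "PipelineResult",
    "NORMALIZED_PREFIXES",
    "M_WINDOW_MS",
    "H_WINDOW_MS",
]

log = logging.getLogger(__name__)

# peak-to-peak search windows after the stimulus artifact (conventional SOL
# latencies; only the extraction rule is under test, not the physiology)
M_WINDOW_MS = (5.0, 25.0)
H_WINDOW_MS = (25.0, 60.0)

NORMALIZED_PREFIXES = ("iemg_", "cci_", "h_amp", "m_amp")


def is_normalized_parameter(name: str) -> bool:
    return name.startswith(NORMALIZED_PREFIXES)


def classify_outcome(trial: Trial) -> TrialOutcome:
    """Adjudicate a trial from its raw event flags.

    Failure iff the safety frame was touched or the unsupported foot lifted
    off (frame touch takes precedence when both are flagged); success
    requires re-stabilisation within 2 s. Struggling/swaying does not fail a
    trial. A trial with no failure flag but a re-stabilisation time above
    2 s is inconsistent and raises.
    """
    if trial.frame_touch:
        return TrialOutcome("failed", "frame_touch", None)
    if trial.foot_liftoff:
        return TrialOutcome("failed", "foot_liftoff", None)
    rt = trial.restabilize_time
    if rt is not None and rt > 2.0:
        raise ValueError(
            f"trial {trial.index}: no failure flag but restabilize_time {rt} s > 2 s"
        )
    return TrialOutcome("success", "none", rt)


def quarter_bins(n_trials: int) -> np.ndarray:
    """Quarter index (1..4) per trial: contiguous blocks of nearly equal
    size, the larger blocks first when n is not divisible by 4."""
    if n_trials < 4:
        raise ValueError(f"need at least 4 trials to form quarters, got {n_trials}")
    base, rem = divmod(n_trials, 4)
    sizes = [base + 1] * rem + [base] * (4 - rem)
    return np.repeat(np.arange(1, 5), sizes)


def failed_rate(session: Session, assignment: Optional[np.ndarray] = None) -> dict[Quarter, float]:
    """Percentage of failed attempts per quarter, over all directions."""
    if assignment is None:
        assignment = quarter_bins(len(session.trials))
    assignment = np.asarray(assignment)
    flags = np.array([classify_outcome(t).failed for t in session.trials])
    out = {}
    for q in Quarter:
        sel = assignment == int(q)
        if not sel.any():
            raise ValueError(f"empty quarter {q.name}")
        out[q] = float(100.0 * flags[sel].mean())
    return out


def match_control(fat: Session, con: Session) -> Session:
    """Truncate the CON session to the FAT trial count (order preserved)."""
    n = len(fat.trials)
    if len(con.trials) < n:
        raise ValueError(
            f"CON session has {len(con.trials)} trials, fewer than FAT's {n}"
        )
    return Session(
        subject_id=con.subject_id,
        protocol=con.protocol,
        trials=con.trials[:n],
        mvc=con.mvc,
        stimulation_trials=[i for i in con.stimulation_trials if i <= n],
        date=con.date,
    )


def _stim_time_s(trial: Trial) -> float:
    stim = trial.channels[STIM_CHANNEL]
    hits = np.nonzero(stim.samples > 0.5)[0]
    if hits.size == 0:
        raise ValueError(f"trial {trial.index}: stimulation trial without stimulus marker")
    return hits[0] / stim.rate


def extract_features(session: Session, assignment: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-trial features of the successful posterior trials.

    Returns a tidy frame (subject, protocol, trial, quarter, parameter,
    value). Mechanical measures (COP, excursions) come from every successful
    posterior trial; iEMG and CCI only from non-stimulation ones; H/M
    peak-to-peak amplitudes only from stimulation ones. Failed trials are
    excluded from everything (they feed :func:`failed_rate` alone).
    """
    if assignment is None:
        assignment = quarter_bins(len(session.trials))
    assignment = np.asarray(assignment)
    stim_set = set(session.stimulation_trials)
    rows: list[tuple] = []
    n_posterior = n_success = 0
    for trial, q in zip(session.trials, assignment):
        if not trial.is_posterior:
            continue
        n_posterior += 1
        if classify_outcome(trial).failed:
            continue
        n_success += 1
        feats: dict[str, float] = {}

        cop = mech_mod.cop_displacement(trial.channels[COP_CHANNEL], trial.onset_s)
        feats["cop_d"] = cop.cop_d_mm
        if np.isfinite(cop.cop_v):
            feats["cop_v"] = cop.cop_v
        for joint in JointLabel:
            exc = mech_mod.joint_excursion(trial.channels[angle_channel(joint)], trial.onset_s)
            feats[f"excursion_{joint.value}"] = exc.excursion_deg

        if trial.index in stim_set:
            sol = trial.channels[MuscleLabel.SOL.value]
            t0 = _stim_time_s(trial)
            feats["m_amp"] = emg_mod.peak_to_peak(
                sol, t0 + M_WINDOW_MS[0] / 1000.0, t0 + M_WINDOW_MS[1] / 1000.0
            )
            feats["h_amp"] = emg_mod.peak_to_peak(
                sol, t0 + H_WINDOW_MS[0] / 1000.0, t0 + H_WINDOW_MS[1] / 1000.0
            )
        else:
            for mus in MuscleLabel:
                ch = trial.channels[mus.value]
                phases = emg_mod.phase_iemg(ch, trial.onset_s, session.mvc[mus])
                for w in IEMG_PHASES:
                    feats[f"iemg_{mus.value}_{w.name}"] = phases[w.name].pct_mvc
            for pair, (mus_a, mus_b) in CCI_PAIRS.items():
                for wname in ("PRE", "RP"):
                    feats[f"cci_{pair}_{wname}"] = emg_mod.cci_from_channels(
                        trial.channels[mus_a.value],
                        trial.channels[mus_b.value],
                        session.mvc[mus_a],
                        session.mvc[mus_b],
                        trial.onset_s,
                        PHASES[wname],
                    )
        for name, value in feats.items():
            rows.append(
                (session.subject_id, Protocol(session.protocol).value, trial.index, int(q), name, value)
            )
    log.info(
        "extract %s/%s: %d trials, %d posterior, %d successful posterior",
        session.subject_id, Protocol(session.protocol).value,
        len(session.trials), n_posterior, n_success,
    )
    return pd.DataFrame(
        rows, columns=["subject", "protocol", "trial", "quarter", "parameter", "value"]
    )


def quarter_means(features: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean per subject x protocol x quarter x parameter."""
    return (
        features.groupby(["subject", "protocol", "quarter", "parameter"], as_index=False)["value"]
        .mean()
    )


def normalize_to_t1(qtable: pd.DataFrame, on_missing: str = "raise") -> pd.DataFrame:
    """Divide EMG/CCI/H-reflex/M-wave quarter means by the subject's T1.

    COP, kinematics and failure rates stay in physical units and are passed
    through unchanged. FAT and CON are normalised independently. A missing
    or non-positive T1 cell raises, or yields NaN with ``on_missing="nan"``.
    """
    if on_missing not in ("raise", "nan"):
        raise ValueError("on_missing must be 'raise' or 'nan'")
    out = qtable.copy()
    norm_mask = out["parameter"].map(is_normalized_parameter)
    norm = out[norm_mask]
    t1 = (
        norm[norm["quarter"] == 1]
        .set_index(["subject", "protocol", "parameter"])["value"]
    )
    keys = list(zip(norm["subject"], norm["protocol"], norm["parameter"]))
    denom = np.array([t1.get(k, np.nan) for k in keys])
    bad = ~np.isfinite(denom) | (denom <= 0)
    if bad.any() and on_missing == "raise":
        missing = sorted({keys[i] for i in np.nonzero(bad)[0]})[:5]
        raise ValueError(f"missing or non-positive T1 reference for {missing} ...")
    values = norm["value"].to_numpy() / np.where(bad, np.nan, denom)
    out.loc[norm_mask, "value"] = values
    return out


def grand_means(qtable: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD across subjects per protocol x quarter x parameter.

    Each subject enters with weight one (mean of subject means, not a
    pooled-trial mean); NaN cells (subjects without a valid value) are
    dropped casewise per cell.
    """
    g = qtable.groupby(["parameter", "protocol", "quarter"])["value"]
    res = g.agg(mean="mean", sd="std", n="count").reset_index()
    return res


@dataclass
class PipelineResult:
    features: pd.DataFrame      # per-trial feature rows (all sessions)
    quarter_raw: pd.DataFrame   # subject x quarter means, physical units
    quarter_norm: pd.DataFrame  # same, EMG/CCI/H/M divided by subject T1
    grand: pd.DataFrame         # grand means +- SD of the analysis values
    stats: dict = field(default_factory=dict)


def _analysis_table(quarter_raw: pd.DataFrame, quarter_norm: pd.DataFrame) -> pd.DataFrame:
    """Normalised values for EMG/CCI/H/M parameters, raw for the rest."""
    norm_mask = quarter_norm["parameter"].map(is_normalized_parameter)
    return pd.concat(
        [quarter_raw[~quarter_raw["parameter"].map(is_normalized_parameter)],
         quarter_norm[norm_mask]],
        ignore_index=True,
    )


def run_pipeline(
    cohort: Sequence[tuple[Session, Session]],
    with_stats: bool = True,
) -> PipelineResult:
    """Full analysis of a cohort of matched (FAT, CON) session pairs.

    Volume-matches each pair, bins trials into quarters, extracts features,
    forms subject quarter means (plus the per-quarter failure rate),
    T1-normalises, and reports grand means and the within-subject test
    battery. Deterministic given the cohort.
    """
    all_feats = []
    fail_rows = []
    for fat, con in cohort:
        con = match_control(fat, con)
        for session in (fat, con):
            assignment = quarter_bins(len(session.trials))
            all_feats.append(extract_features(session, assignment))
            for q, pct in failed_rate(session, assignment).items():
                fail_rows.append(
                    (session.subject_id, Protocol(session.protocol).value, int(q), "failed_pct", pct)
                )
    features = pd.concat(all_feats, ignore_index=True)
    qmeans = quarter_means(features)
    failed = pd.DataFrame(
        fail_rows, columns=["subject", "protocol", "quarter", "parameter", "value"]
    )
    quarter_raw = pd.concat([qmeans.drop(columns="trial", errors="ignore"), failed], ignore_index=True)
    quarter_norm = normalize_to_t1(quarter_raw, on_missing="nan")
    analysis = _analysis_table(quarter_raw, quarter_norm)
    grand = grand_means(analysis)
    stats_report = compute_stats(analysis, features) if with_stats else {}
    return PipelineResult(features, quarter_raw, quarter_norm, grand, stats_report)


# ---------------------------------------------------------------------------
# inferential battery


def _cube(analysis: pd.DataFrame, parameter: str) -> Optional[stats_mod.WithinDesignCube]:
    df = analysis[analysis["parameter"] == parameter]
    if df.empty:
        return None
    try:
        return stats_mod.WithinDesignCube.from_long(
            df, subject="subject", factors=["quarter", "protocol"], value="value"
        )
    except ValueError:
        return None


def _effect_dict(e: stats_mod.AnovaEffect) -> dict:
    return {
        "effect": e.name,
        "F": e.F,
        "df": [e.df, e.error_df],
        "epsilon_gg": e.epsilon_gg,
        "mauchly_w": e.mauchly_w,
        "mauchly_p": e.mauchly_p,
        "p_uncorrected": e.p_uncorrected,
        "p_gg": e.p_gg,
        "sphericity_applied": e.sphericity_applied,
        "p": e.p,
    }


def compute_stats(analysis: pd.DataFrame, features: pd.DataFrame) -> dict:
    """Time x protocol rmANOVA per parameter (Bonferroni within each results
    family), the three-factor interactions (phase, segmentation, muscle
    pair), and the failed-attempts correlation battery with BHY control."""
    params = sorted(analysis["parameter"].unique())
    families = {
        "balance": [p for p in params if p in
                    ("failed_pct", "cop_d", "cop_v",
                     "excursion_ankle", "excursion_knee", "excursion_hip")],
        "iemg": [p for p in params if p.startswith("iemg_")],
        "cci_hm": [p for p in params if p.startswith("cci_") or p in ("h_amp", "m_amp")],
    }
    anova: dict[str, dict] = {}
    for family, members in families.items():
        raw_p = []
        effects_by_param = {}
        for p in members:
            cube = _cube(analysis, p)
            if cube is None:
                continue
            effects = stats_mod.rm_anova(cube)
            inter = next(e for e in effects if e.name == "quarter:protocol")
            effects_by_param[p] = {
                "main_effects": [
                    {"effect": e.name, "F": round(e.F, 4), "p": round(e.p, 6)}
                    for e in effects if e.name != "quarter:protocol"
                ],
                "time_x_protocol": _effect_dict(inter),
            }
            raw_p.append((p, inter.p))
        adj = stats_mod.bonferroni([x[1] for x in raw_p])
        for (p, _), pa in zip(raw_p, adj):
            effects_by_param[p]["time_x_protocol"]["p_bonferroni"] = pa
            effects_by_param[p]["family"] = family
            effects_by_param[p]["n_tests"] = len(raw_p)
        anova.update(effects_by_param)

    three_way = {}
    # time x protocol x phase per muscle (reflex phases only)
    for mus in MuscleLabel:
        sub = analysis[analysis["parameter"].isin(
            [f"iemg_{mus.value}_{ph}" for ph in ("SLR", "MLR", "LLR")]
        )].copy()
        if sub.empty:
            continue
        sub["phase"] = sub["parameter"].str.rsplit("_", n=1).str[-1]
        try:
            cube = stats_mod.WithinDesignCube.from_long(
                sub, "subject", ["quarter", "protocol", "phase"], "value"
            )
        except ValueError:
            continue
        effects = stats_mod.rm_anova(cube)
        inter = next(e for e in effects if e.name == "quarter:protocol:phase")
        three_way[f"iemg_{mus.value}_x_phase"] = _effect_dict(inter)
    # time x protocol x segmentation (joints)
    sub = analysis[analysis["parameter"].str.startswith("excursion_")].copy()
    if not sub.empty:
        sub["joint"] = sub["parameter"].str.removeprefix("excursion_")
        try:
            cube = stats_mod.WithinDesignCube.from_long(
                sub, "subject", ["quarter", "protocol", "joint"], "value"
            )
            inter = next(
                e for e in stats_mod.rm_anova(cube) if e.name == "quarter:protocol:joint"
            )
            three_way["excursion_x_segmentation"] = _effect_dict(inter)
        except ValueError:
            pass
    # time x protocol x muscle pair for the reflex-phase CCI
    sub = analysis[analysis["parameter"].str.match(r"cci_.*_RP")].copy()
    if not sub.empty:
        sub["pair"] = sub["parameter"].str.removeprefix("cci_").str.removesuffix("_RP")
        try:
            cube = stats_mod.WithinDesignCube.from_long(
                sub, "subject", ["quarter", "protocol", "pair"], "value"
            )
            inter = next(
                e for e in stats_mod.rm_anova(cube) if e.name == "quarter:protocol:pair"
            )
            three_way["cci_rp_x_pair"] = _effect_dict(inter)
        except ValueError:
            pass

    correlations = _correlation_battery(analysis)
    return {"anova": anova, "three_way": three_way, "correlations": correlations}


def _correlation_battery(analysis: pd.DataFrame) -> dict:
    """Failed attempts (subject FAT mean %) against reflex-phase iEMG, RP
    co-contraction and joint excursions at T4, BHY-adjusted."""
    fat = analysis[analysis["protocol"] == "FAT"]
    failed = (
        fat[fat["parameter"] == "failed_pct"].groupby("subject")["value"].mean()
    )
    battery = (
        [f"iemg_{m.value}_{ph}" for m in MuscleLabel for ph in ("SLR", "MLR", "LLR")]
        + [f"cci_{p}_RP" for p in CCI_PAIRS]
        + [f"excursion_{j.value}" for j in JointLabel]
    )
    results = []
    for param in battery:
        y = (
            fat[(fat["parameter"] == param) & (fat["quarter"] == 4)]
            .set_index("subject")["value"]
        )
        common = failed.index.intersection(y.index)
        sub_y = y.loc[common].dropna()
        common = sub_y.index
        if len(common) < 3:
            continue
        try:
            res = stats_mod.pearson(failed.loc[common], sub_y)
        except ValueError:
            continue
        results.append((param, res))
    adjusted, reject = stats_mod.bhy_fdr([r.p_two_tailed for _, r in results])
    return {
        param: {
            "r": res.r,
            "n": res.n,
            "p": res.p_two_tailed,
            "p_bhy": pa,
            "significant": bool(rej),
        }
        for (param, res), pa, rej in zip(results, adjusted, reject)
    }
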