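"""Plain-text session storage.

Layout of a session directory::

    session.json     subject, protocol, MVC mapping, per-trial metadata
    trial_001.tsv    one table per trial: first column time_s, one column
    trial_002.tsv    per channel; header cell "label[units]@rateHz"
    ...

Channels of different rates share one table: rows follow the finest rate in
the trial and a slower channel fills only the rows whose time coincides with
one of its own sample starts (its rate must divide the finest rate). All
numbers are written with 9 significant digits, so writing the same session
twice is byte-identical and a read-back reproduces every field to that
precision.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path

import numpy as np

from .model import (
    Direction,
    MuscleLabel,
    Protocol,
    Session,
    TimeSeriesChannel,
    Trial,
    TrialOutcome,
    validate_session,
)

__all__ = ["read_session", "write_session"]

_FMT = "%.9g"
_HEADER_RE = re.compile(r"^(?P<label>.+)\[(?P<units>[^\]]*)\]@(?P<rate>[0-9.eE+-]+)Hz$")


def _trial_filename(index: int) -> str:
    return f"trial_{index:03d}.tsv"


def _num(x: float) -> str:
    return _FMT % x


def write_session(session: Session, path: str | Path) -> None:
    """Write ``session`` to directory ``path`` (created if needed).

    Deterministic: trials are written in index order, channels in sorted
    name order, JSON keys sorted; two writes of the same session produce
    byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    meta = {
        "subject_id": session.subject_id,
        "protocol": Protocol(session.protocol).value,
        "date": session.date,
        "mvc": {MuscleLabel(k).value: float(v) for k, v in session.mvc.items()},
        "stimulation_trials": [int(i) for i in session.stimulation_trials],
        "trials": [
            {
                "index": t.index,
                "direction": Direction(t.direction).value,
                "onset_s": float(t.onset_s),
                "start_time_s": float(t.start_time_s),
                "frame_touch": bool(t.frame_touch),
                "foot_liftoff": bool(t.foot_liftoff),
                "restabilize_time": t.restabilize_time,
                "outcome": {
                    "status": t.outcome.status,
                    "failure_criterion": t.outcome.failure_criterion,
                    "restabilize_time": t.outcome.restabilize_time,
                },
            }
            for t in session.trials
        ],
    }
    (path / "session.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )

    for trial in session.trials:
        _write_trial_table(path / _trial_filename(trial.index), trial)


def _write_trial_table(file: Path, trial: Trial) -> None:
    names = sorted(trial.channels)
    if not names:
        file.write_text("time_s\n", encoding="utf-8")
        return
    chans = [trial.channels[n] for n in names]
    base_rate = max(c.rate for c in chans)
    steps = []
    for c in chans:
        step = base_rate / c.rate
        if abs(step - round(step)) > 1e-9:
            raise ValueError(
                f"{file.name}: rate {c.rate} of channel {c.label!r} does not divide "
                f"the trial base rate {base_rate}"
            )
        steps.append(int(round(step)))
    n_rows = max(c.samples.size * s for c, s in zip(chans, steps))

    header = "time_s\t" + "\t".join(
        f"{c.label}[{c.units}]@{_num(c.rate)}Hz" for c in chans
    )
    lines = [header]
    for row in range(n_rows):
        cells = [_num(row / base_rate)]
        for c, s in zip(chans, steps):
            if row % s == 0 and row // s < c.samples.size:
                cells.append(_num(c.samples[row // s]))
            else:
                cells.append("")
        lines.append("\t".join(cells))
    file.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_session(path: str | Path) -> Session:
    """Read a session directory written by :func:`write_session`.

    Raises ``FileNotFoundError``/``ValueError`` naming the offending file and
    field on malformed input; the returned session has passed
    :func:`perturbfatigue.model.validate_session`.
    """
    path = Path(path)
    meta_file = path / "session.json"
    if not meta_file.is_file():
        raise FileNotFoundError(f"{meta_file}: missing session metadata file")
    try:
        meta = json.loads(meta_file.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValueError(f"{meta_file}: malformed JSON ({exc})") from None

    for key in ("subject_id", "protocol", "mvc", "trials"):
        if key not in meta:
            raise ValueError(f"{meta_file}: missing field {key!r}")
    try:
        protocol = Protocol(meta["protocol"])
    except ValueError:
        raise ValueError(f"{meta_file}: unknown protocol {meta['protocol']!r}") from None
    try:
        mvc = {MuscleLabel(k): float(v) for k, v in meta["mvc"].items()}
    except ValueError as exc:
        raise ValueError(f"{meta_file}: bad mvc mapping ({exc})") from None

    trials: list[Trial] = []
    for tm in meta["trials"]:
        idx = int(tm["index"])
        tsv = path / _trial_filename(idx)
        if not tsv.is_file():
            raise FileNotFoundError(f"{tsv}: missing trial table for trial {idx}")
        channels = _read_trial_table(tsv)
        out = tm.get("outcome", {})
        trials.append(
            Trial(
                index=idx,
                direction=Direction(tm["direction"]),
                onset_s=float(tm["onset_s"]),
                outcome=TrialOutcome(
                    status=out.get("status", "success"),
                    failure_criterion=out.get("failure_criterion", "none"),
                    restabilize_time=out.get("restabilize_time"),
                ),
                channels=channels,
                frame_touch=bool(tm.get("frame_touch", False)),
                foot_liftoff=bool(tm.get("foot_liftoff", False)),
                restabilize_time=tm.get("restabilize_time"),
                start_time_s=float(tm.get("start_time_s", 0.0)),
            )
        )

    session = Session(
        subject_id=str(meta["subject_id"]),
        protocol=protocol,
        trials=trials,
        mvc=mvc,
        stimulation_trials=[int(i) for i in meta.get("stimulation_trials", [])],
        date=str(meta.get("date", "")),
    )
    problems = validate_session(session)
    if problems:
        raise ValueError(f"{path}: invalid session: " + "; ".join(problems))
    return session


def _read_trial_table(file: Path) -> dict[str, TimeSeriesChannel]:
    with file.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "time_s":
            raise ValueError(f"{file}: first column must be time_s")
        specs = []
        for cell in header[1:]:
            m = _HEADER_RE.match(cell)
            if m is None:
                raise ValueError(f"{file}: malformed channel header {cell!r}")
            specs.append((m.group("label"), m.group("units"), float(m.group("rate"))))
        columns: list[list[float]] = [[] for _ in specs]
        for ln, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(specs) + 1:
                raise ValueError(f"{file}:{ln}: expected {len(specs) + 1} columns, got {len(cells)}")
            for col, cell in zip(columns, cells[1:]):
                if cell != "":
                    try:
                        col.append(float(cell))
                    except ValueError:
                        raise ValueError(f"{file}:{ln}: malformed number {cell!r}") from None

    channels: dict[str, TimeSeriesChannel] = {}
    for (label, units, rate), col in zip(specs, columns):
        if not col:
            raise ValueError(f"{file}: channel {label!r} has no samples")
        if not all(math.isfinite(x) for x in col):
            raise ValueError(f"{file}: channel {label!r} has non-finite samples")
        channels[label] = TimeSeriesChannel(label, np.asarray(col), rate, units)
    return channels
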