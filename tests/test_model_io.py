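"""Domain model invariants and plain-text session round-tripping."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from perturbfatigue import io as io_mod
from perturbfatigue import model as m


def _hash_dir(path: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(path.rglob("*")):
        if f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()


class TestChannel:
    def test_rejects_bad_rate_and_empty_and_nonfinite(self):
        with pytest.raises(ValueError, match="rate"):
            m.TimeSeriesChannel("x", [1.0], 0.0, "mV")
        with pytest.raises(ValueError, match="non-empty"):
            m.TimeSeriesChannel("x", [], 1000.0, "mV")
        with pytest.raises(ValueError, match="non-finite"):
            m.TimeSeriesChannel("x", [1.0, np.nan], 1000.0, "mV")

    def test_enumerations_are_closed(self):
        assert len(m.MuscleLabel) == 7
        assert len(m.JointLabel) == 3
        assert len(m.Direction) == 8
        assert [q.name for q in m.Quarter] == ["T1", "T2", "T3", "T4"]


class TestValidate:
    def test_generated_session_is_valid(self, tiny_session):
        assert m.validate_session(tiny_session) == []

    def test_early_onset_reported_as_pre_window_violation(self, tiny_session):
        trial = tiny_session.trials[0]
        bad = m.Trial(
            index=1, direction=trial.direction, onset_s=0.05,
            outcome=trial.outcome, channels=trial.channels,
        )
        session = m.Session(
            "s", m.Protocol.FAT, [bad], tiny_session.mvc, [],
        )
        problems = m.validate_session(session)
        assert any("PRE window" in p for p in problems)

    def test_failed_without_criterion_is_a_violation(self, tiny_session):
        trial = tiny_session.trials[0]
        bad = m.Trial(
            index=1, direction=m.Direction.POSTERIOR, onset_s=0.15,
            outcome=m.TrialOutcome("failed", "none", None),
            channels=trial.channels,
        )
        session = m.Session("s", m.Protocol.FAT, [bad], tiny_session.mvc, [])
        assert any("failure criterion" in p for p in m.validate_session(session))

    def test_total_on_odd_input(self):
        # never raises, whatever the (well-typed) session content
        session = m.Session("s", m.Protocol.CON, [], {}, [99])
        problems = m.validate_session(session)
        assert isinstance(problems, list) and problems


class TestRoundTrip:
    def test_write_read_identity(self, tiny_session, tmp_path):
        io_mod.write_session(tiny_session, tmp_path / "s")
        back = io_mod.read_session(tmp_path / "s")
        assert m.sessions_equal(tiny_session, back, rtol=1e-8, atol=1e-12)

    def test_two_writes_byte_identical(self, tiny_session, tmp_path):
        io_mod.write_session(tiny_session, tmp_path / "a")
        io_mod.write_session(tiny_session, tmp_path / "b")
        assert _hash_dir(tmp_path / "a") == _hash_dir(tmp_path / "b")

    def test_empty_session_writes_metadata_only(self, tmp_path):
        session = m.Session("s", m.Protocol.FAT, [], {m.MuscleLabel.SOL: 0.5}, [])
        io_mod.write_session(session, tmp_path / "e")
        assert [p.name for p in (tmp_path / "e").iterdir()] == ["session.json"]

    def test_missing_sol_channel_error_names_sol(self, tiny_session, tmp_path):
        io_mod.write_session(tiny_session, tmp_path / "s")
        post_idx = next(t.index for t in tiny_session.trials if t.is_posterior)
        tsv = tmp_path / "s" / f"trial_{post_idx:03d}.tsv"
        lines = tsv.read_text().splitlines()
        header = lines[0].split("\t")
        col = next(i for i, h in enumerate(header) if h.startswith("SOL["))
        stripped = [
            "\t".join(c for i, c in enumerate(line.split("\t")) if i != col)
            for line in lines
        ]
        tsv.write_text("\n".join(stripped) + "\n")
        with pytest.raises(ValueError, match="SOL"):
            io_mod.read_session(tmp_path / "s")

    def test_malformed_metadata_names_file_and_field(self, tiny_session, tmp_path):
        io_mod.write_session(tiny_session, tmp_path / "s")
        meta = tmp_path / "s" / "session.json"
        meta.write_text(meta.read_text().replace('"protocol": "FAT"', '"protocol": "XXX"'))
        with pytest.raises(ValueError, match="protocol"):
            io_mod.read_session(tmp_path / "s")

    def test_mixed_rates_preserved(self, tiny_session, tmp_path):
        io_mod.write_session(tiny_session, tmp_path / "s")
        back = io_mod.read_session(tmp_path / "s")
        trial = back.trials[0]
        assert trial.channels["cop_ap"].rate == 100.0
        assert trial.channels["SOL"].rate == 1000.0
        n_emg = trial.channels["SOL"].samples.size
        assert trial.channels["cop_ap"].samples.size == n_emg // 10
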