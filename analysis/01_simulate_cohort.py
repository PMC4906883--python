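#!/usr/bin/env python
"""Generate a small demonstration cohort and write it as session directories.

Two subjects under the study conditions (eight-direction perturbations in
sets of eight, individually drawn time to exhaustion for the fatigue
protocol, volume-matched control protocol), written in the plain-text
session layout under scratch/demo_cohort/ so the extract/aggregate stages
can be exercised from disk. The full 24-subject analyses (scripts 03/04)
generate their cohorts in memory instead.
"""

from pathlib import Path

from perturbfatigue import io as io_mod
from perturbfatigue import synthetic as syn
from perturbfatigue.model import Protocol, validate_session

OUT = Path(__file__).resolve().parent.parent / "scratch" / "demo_cohort"


def main() -> None:
    cfg = syn.paper_preset()
    cohort = syn.generate_cohort(cfg, seed=100, n_subjects=2)
    for fat, con in cohort:
        for session in (fat, con):
            problems = validate_session(session)
            assert not problems, problems
            io_mod.write_session(
                session, OUT / session.subject_id / Protocol(session.protocol).value
            )
            n_post = sum(t.is_posterior for t in session.trials)
            print(
                f"{session.subject_id}/{Protocol(session.protocol).value}: "
                f"{len(session.trials)} trials, {n_post} posterior, "
                f"{len(session.stimulation_trials)} stimulated"
            )
    print(f"wrote session directories under {OUT}")


if __name__ == "__main__":
    main()
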