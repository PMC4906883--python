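#!/usr/bin/env python
"""Extract per-trial features from the demonstration cohort on disk.

Reads the session directories written by 01_simulate_cohort.py,
volume-matches each control session to its fatigue session, and extracts
the per-trial measures (COP displacement/velocity, joint excursions, phase
iEMG in %MVC, co-contraction indices, H/M peak-to-peak amplitudes) from
successful posterior trials. Writes the tidy feature table to
results/demo_features.tsv and prints exclusion counts.
"""

from pathlib import Path

import pandas as pd

from perturbfatigue import io as io_mod
from perturbfatigue import pipeline as pl

ROOT = Path(__file__).resolve().parent.parent
IN = ROOT / "scratch" / "demo_cohort"
OUT = ROOT / "results" / "demo_features.tsv"


def main() -> None:
    frames = []
    for subj_dir in sorted(IN.iterdir()):
        fat = io_mod.read_session(subj_dir / "FAT")
        con = pl.match_control(fat, io_mod.read_session(subj_dir / "CON"))
        for session in (fat, con):
            feats = pl.extract_features(session)
            n_post = sum(t.is_posterior for t in session.trials)
            n_failed = sum(pl.classify_outcome(t).failed for t in session.trials)
            print(
                f"{session.subject_id}/{session.protocol.value}: {len(session.trials)} trials, "
                f"{n_failed} failed (excluded), {n_post} posterior, "
                f"{feats['trial'].nunique()} analysed"
            )
            frames.append(feats)
    table = pd.concat(frames, ignore_index=True)
    OUT.parent.mkdir(exist_ok=True)
    table.to_csv(OUT, sep="\t", index=False, float_format="%.6g")
    print(f"{len(table)} feature rows -> {OUT}")


if __name__ == "__main__":
    main()
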