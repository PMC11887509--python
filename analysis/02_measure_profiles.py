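#!/usr/bin/env python
"""Measure and classify the synthetic landmark profiles.

Reads the TPS files written by 01_simulate_cohort.py, runs the full
geometry pipeline (construction lines, heights, inclinations), classifies
each profile against the default normative model, and prints advisory
suggestions for the disharmonious ones.  Writes a per-subject table to
results/profile_measurements.csv.
"""

from pathlib import Path

import pandas as pd

from faceharmony.config import PipelineConfig
from faceharmony.io import analyse_subject, read_landmarks

ROOT = Path(__file__).resolve().parents[1] / "results"
ANGLE_CLASS = {
    "harmonious": "I",
    "class2_retrognathic": "II",
    "class3_longface": "III",
    "protrusive_maxilla": "II",
}


def main() -> None:
    cfg = PipelineConfig()
    rows = []
    for tps in sorted((ROOT / "synthetic").glob("*.tps")):
        ls = read_landmarks(tps)[0]
        res = analyse_subject(ls, cfg, angle_class=ANGLE_CLASS.get(ls.subject_id))
        row = {"subject": res.subject_id, **res.measurements.as_dict(),
               **{f"cat_{k}": v for k, v in res.classification.as_dict().items()}}
        rows.append(row)
        print(f"{res.subject_id}: {res.classification.as_dict()}")
        for r in res.recommendations:
            print(f"  {r}")
    df = pd.DataFrame(rows).round(3)
    out = ROOT / "profile_measurements.csv"
    df.to_csv(out, index=False)
    print(f"\nwrote {out}")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
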