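#!/usr/bin/env python
"""Generate the synthetic study inputs: a calibrated cohort and noisy profiles.

Writes a 160-patient cohort CSV whose demographic margins and harmony
rates follow the bundled reference-cohort margins, plus a handful of
deformed, noisy landmark files (TPS and CSV) for the geometry pipeline.
"""

from pathlib import Path

from faceharmony.cohort import write_cohort_csv
from faceharmony.io import write_landmarks_csv, write_tps
from faceharmony.synth import (
    Deformation,
    generate_cohort,
    generate_profile,
    profile_template,
    table_calibrated_spec,
)

SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"

PHENOTYPES = {
    "harmonious": Deformation(),
    "class2_retrognathic": Deformation(mandible_shift_mm=-4.0),
    "class3_longface": Deformation(mandible_shift_mm=3.0, elongation=0.25),
    "protrusive_maxilla": Deformation(maxilla_shift_mm=7.0),
}
NOISE_SD = 0.25  # mm tracing error; small against the band halfwidths


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(table_calibrated_spec(), seed=SEED)
    write_cohort_csv(cohort, OUT / "cohort.csv")
    print(f"wrote {OUT / 'cohort.csv'}: {len(cohort)} synthetic patients")
    for i, (name, d) in enumerate(PHENOTYPES.items()):
        ls = generate_profile(profile_template(name), d, noise_sd=NOISE_SD, seed=SEED + i)
        write_tps(ls, OUT / f"{name}.tps")
        write_landmarks_csv(ls, OUT / f"{name}.csv")
    print(f"wrote {len(PHENOTYPES)} landmark profiles (TPS + CSV) under {OUT}")


if __name__ == "__main__":
    main()
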