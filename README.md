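# faceharmony

Soft-tissue facial profile analysis for orthognathic-surgery planning
and outcome audit: landmark-based construction lines, golden-section
normative bands, per-dimension harmony classification, and the cohort
statistics used to ask *which patients actually reach facial harmony
after surgery*.

## Who this is for

Clinician-researchers and morphometricians working with lateral
profile photographs (or tracings) of orthognathic-surgery patients, who
want a reproducible, scriptable implementation of a classical
soft-tissue profile analysis plus the statistical toolkit for pre/post
outcome cohorts: exact r×c tests, logistic regression with AIC model
selection, and Fisher-test power simulation.

## The analysis

From nine named 2D landmarks (G, N, Prn, Sn, Ls, St, Li, Pg, Me; x
anterior-positive, y superior-positive) the package constructs

* the **nasofrontal line (NFL)** through glabella and nasion, and
* the **vertical analysis line (VAL)** — the NFL rotated 15° caudally
  about nasion so its lower end moves posteriorly,

and measures seven quantities: three facial heights as projections onto
the VAL, **NasFH** (N–Sn), **MaxFH** (Sn–St), **MandFH** (St–Me) in mm,
and four inclinations as signed angles against the VAL, **NRI** (nasal
bridge, N–Prn), **OLI** (upper lip, Sn–Ls), **ULI** (lower lip, St–Li),
**MI** (chin, St–Pg) in degrees, ventral positive.

The vertical norm is the golden section of the lower face:
MandFH_opt = φ·MaxFH (φ ≈ 1.618) with a ±10 % normal range; shorter is
a short-face (SF), longer a long-face (LF) configuration. Each sagittal
angle has a normal band centred on an affine function of NRI. **Facial
harmony** holds when all four dimensions are within their bands, and
per-dimension surgical **success** means the post-operative value is in
range. All normative constants are configuration keys (see
`docs/methods.md` — the sagittal defaults are placeholders to be
overridden with calibrated norms).

On the cohort side the package provides prevalence/improvement tables,
the **Freeman–Halton exact test** of independence for r×c tables
(exhaustive enumeration of the multivariate hypergeometric), logistic
regression by IRLS with Wald inference and quasi-separation flagging,
forward-backward **AIC stepwise selection**, and Monte-Carlo **power**
of the two-sided Fisher exact test at a fixed odds ratio.

## Worked example

```python
from faceharmony import (classify_profile, measure_profile,
                         recommend_procedures, profile_template,
                         generate_profile, Deformation)

# a synthetic Class II phenotype: chin and lower lip set back 4 mm
subject = generate_profile(profile_template("demo"),
                           Deformation(mandible_shift_mm=-4.0),
                           noise_sd=0.25, seed=2027)
m = measure_profile(subject)
print({k: round(v, 2) for k, v in m.as_dict().items()})
c = classify_profile(m)
print(c.as_dict())
for advice in recommend_procedures(c, angle_class="II"):
    print(advice)
```

prints

```
{'NasFH': 29.01, 'MaxFH': 20.9, 'MandFH': 35.56, 'NRI': 54.76, 'OLI': 26.94, 'ULI': -1.85, 'MI': 18.63}
{'vertical': 'NF', 'OLI': 'N', 'ULI': 'L', 'MI': 'L', 'overall_harmony': False}
ADVISORY (non-normative, not a clinical directive): [genioplasty-advancement] Class II with low (dorsal) mandibular inclination: consider chin advancement / augmentation genioplasty, or a bimaxillary advancement if chin retrusion is severe.
```

The 4 mm setback leaves the heights inside the golden-section band
(MandFH 35.6 against an optimum of φ·20.9 ≈ 33.8, band ≈ 30.4–37.2)
but drops the chin inclination to 18.6° and the lower lip to −1.9°,
both below their NRI-dependent bands (≈ 22.4–32.4° at NRI 54.8) — a
dorsal, Class II-type disharmony, which triggers the genioplasty
advisory rule.

For a cohort, `faceharmony simulate --seed 3 --outdir sim` writes a
calibrated synthetic cohort CSV and `faceharmony cohort sim/cohort.csv`
prints the prevalence table and the exact tests of harmony by Angle
class. The numbered scripts under `analysis/` run the full study
narrative (simulation → measurement → outcome tables → regression →
power) and write their tables under `results/`.

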