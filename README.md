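# octinl

Measurement and analysis chain for paramacular retinal layer changes after
optic neuritis (ON), built around spectral-domain OCT radial macular scans.

In MS-related ON, retrograde degeneration thins the retinal nerve fiber
layer (RNFL) and the combined ganglion cell / inner plexiform layer
(GCL/IPL), while the inner nuclear layer (INL) *thickens* — in a minority
of eyes visibly, as hyporeflective microcysts confined to the INL. This
package implements the full measurement chain needed to study that
relationship, and a synthetic-OCT generator with known ground truth to
validate every stage:

1. **Synthetic radial OCT scan sets** (`octinl.phantom`, `octinl.render`,
   `octinl.cohort`): layered retina phantoms with a foveal pit,
   partial-volume rendering, axial PSF blur, multiplicative gamma speckle,
   vessel shadows, INL microcysts (elongated perpendicular to the layers,
   nasal, 0.75–2.0 mm from the fovea), and paired-eye cohorts drawn from
   truncated multivariate normals with configurable means, SDs and
   inter-layer correlations.
2. **Automated layer segmentation** (`octinl.segmentation`): scan quality
   gate (SNR > 25 dB, centration, brightness uniformity), vessel shadow
   detection and removal, multiple-size median filtering, Canny edge
   detection with quantile hysteresis thresholds, and conversion of the
   edge/gradient field into four ordered non-crossing boundaries (ILM,
   RNFL/GCL-IPL, GCL-IPL/INL, INL/OPL) by per-boundary dynamic-programming
   shortest paths.
3. **36-point paramacular thickness grid** (`octinl.sampling`): 12 radial
   lines (30° apart, 4.5 mm slices) × 3 eccentricities (0.75 / 1.5 /
   2.25 mm), central points excluded; left eyes mirrored to a right-eye
   template so nasal/temporal semantics are stable.
4. **Microcyst detection** (`octinl.microcysts`): well-circumscribed
   hyporeflective regions strictly inside the INL band, found against a
   rolling local INL median, filtered by size, axial elongation and rim
   contrast; cohort prevalence and quadrant topography.
5. **Cohort statistics** (`octinl.stats`): pooled-variance Student t
   group comparisons, Pearson correlations among layer means, the
   affected-minus-fellow-eye asymmetry analysis, duration covariates,
   cyst-subgroup comparisons with exclusion re-runs, and the 36-point
   topographic deviation map with its cross-layer coupling.

The numbered scripts under `analysis/` run the study-scale experiments and
write their tables under `results/`; `octinl.pipeline` / the `octinl` CLI
orchestrate the same chain over scan directories on disk.

## Worked example

Simulate 36 affected eyes in which the generator places INL microcysts in
exactly 5 eyes, then segment every eye and detect cysts blind to the
ground truth:

```python
from octinl.experiments import microcyst_prevalence_experiment

exp = microcyst_prevalence_experiment(seed=7, n_eyes=36)
print(exp.summary.prevalence_pct)   # 14   (5 of 36 eyes, nearest percent)
print(exp.summary.quadrant_counts)  # {'supero-nasal': 10, 'infero-nasal': 12,
                                    #  'supero-temporal': 0, 'infero-temporal': 0}
print(exp.cysts.eccentricity_um.agg(["min", "max"]).round())
# min     814.0
# max    1963.0
```

Every detected cyst lies on a nasal radial line between 0.75 and 2.0 mm
from the fovea — the topography the generator imposed — and the detected
prevalence reproduces the 5/36 ≈ 14 % injection rate.

Segmentation accuracy against generator truth
(`analysis/02_segmentation_accuracy.py`, 20 phantoms spanning healthy to
severely thinned anatomy): per-boundary mean absolute error ≤ 0.05 px
noise-free and ≤ 0.16 px at the default speckle level, with a 36-point
thickness RMS error of 0.3 µm (noise-free) / 1.1 µm (speckle).

## Layout

    src/octinl/       library (phantoms, rendering, cohorts, segmentation,
                      sampling, microcysts, statistics, pipeline, CLI)
    analysis/         numbered narrative drivers writing results/
    tests/            pytest suite (unit, property and end-to-end checks)
    scripts/          acceptance.py
    docs/methods.md   model, parameters, numerical choices, limitations
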