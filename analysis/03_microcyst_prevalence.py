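#!/usr/bin/env python
"""Reproduce the microcyst prevalence and topography on a synthetic cohort.

Simulates 36 affected eyes with INL microcysts injected into exactly 5,
runs segmentation + detection blind to the ground truth, and reports the
detected prevalence (expected: 14 %), the quadrant histogram (expected:
nasal only) and the eccentricity range of the detections (expected: within
0.75-2.0 mm of the fovea).
"""

import json
from pathlib import Path

from octinl.experiments import microcyst_prevalence_experiment

OUT = Path(__file__).resolve().parents[1] / "results" / "03_microcysts"
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    exp = microcyst_prevalence_experiment(seed=SEED, n_eyes=36)
    s = exp.summary
    report = {
        "n_eyes": s.n_eyes,
        "truth_positive_eyes": exp.n_truth_positive,
        "detected_positive_eyes": s.n_eyes_with_cysts,
        "prevalence_pct": s.prevalence_pct,
        "quadrant_counts": s.quadrant_counts,
        "mean_axial_um": round(s.mean_axial_um, 1),
        "mean_lateral_um": round(s.mean_lateral_um, 1),
        "eccentricity_min_um": round(float(exp.cysts.eccentricity_um.min()), 0),
        "eccentricity_max_um": round(float(exp.cysts.eccentricity_um.max()), 0),
    }
    exp.cysts.to_csv(OUT / "detected_cysts.csv", index=False)
    (OUT / "summary.json").write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
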