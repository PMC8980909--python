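#!/usr/bin/env python
"""Earliest statistically detectable ages for the fitted divergence models.

Reads the stage-2 fits, scans each measure for the youngest age at which
the high-score (95th percentile) vs low-score (5th percentile) difference
is detectable with a one-sided two-sample t test at P <= .05, and writes
results/detection_report.tsv plus a text arrow summary contrasting each
measure's divergence age with its detection age.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS, build_simulation_config, ensure_dirs

from divage import DetectionSpec, earliest_detectable_age, simulate_cohort
from divage.detection import arrow_summary, detection_report_frame
from divage.divergence import fit_from_dict


def main() -> None:
    ensure_dirs()
    fits_path = RESULTS / "divergence_fits.json"
    if not fits_path.exists():
        sys.exit("run 04_divergence_model.py first (no divergence_fits.json)")
    fits = [fit_from_dict(d) for d in json.loads(fits_path.read_text())]
    cohort = simulate_cohort(build_simulation_config())

    results = [
        earliest_detectable_age(fit, cohort, DetectionSpec(alpha=0.05))
        for fit in fits
    ]
    detection_report_frame(results).to_csv(
        RESULTS / "detection_report.tsv", sep="\t", index=False
    )
    summary = arrow_summary(results)
    (RESULTS / "detection_summary.txt").write_text(summary + "\n")
    print(summary)
    print(f"\nwrote {RESULTS / 'detection_report.tsv'} and "
          f"{RESULTS / 'detection_summary.txt'}")


if __name__ == "__main__":
    main()
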