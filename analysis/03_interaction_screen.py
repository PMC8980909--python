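#!/usr/bin/env python
"""Stage 1: screen every cognitive measure for an age x risk-score interaction.

Fits the interaction model per measure on complete cases (directions
harmonized so higher always means better), applies the Bonferroni rule at
alpha/m, and ranks measures by the percent-of-age-slope effect size.
Writes results/screen_report.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import ALPHA, COVARIATES, RESULTS, build_simulation_config, ensure_dirs

from divage import ScreenModelSpec, screen_all, simulate_cohort
from divage.screen import screen_report_frame


def run_screen():
    config = build_simulation_config()
    cohort = simulate_cohort(config)
    specs = [
        ScreenModelSpec(
            phenotype=s.name,
            link="logit" if s.scale == "binary" else "identity",
            covariates=COVARIATES + (("practice",) if "practice" in s.covariate_effects else ()),
            direction=s.direction,
        )
        for s in config.phenotype_specs
    ]
    return cohort, config, screen_all(cohort, specs, alpha=ALPHA)


def main() -> None:
    ensure_dirs()
    _, config, outcome = run_screen()
    report = screen_report_frame(outcome)
    report.to_csv(RESULTS / "screen_report.tsv", sep="\t", index=False)

    truly_divergent = {
        s.name for s in config.phenotype_specs if s.true_threshold_age is not None
    }
    print(f"screened m={outcome.m} measures at Bonferroni threshold "
          f"{outcome.threshold:.2e}")
    print(f"selected {len(outcome.selected)}: {outcome.selected}")
    print(f"truly divergent in the generator: {sorted(truly_divergent)}")
    missed = truly_divergent - set(outcome.selected)
    false_pos = set(outcome.selected) - truly_divergent
    if missed:
        print(f"missed (underpowered at this n/missingness): {sorted(missed)}")
    if false_pos:
        print(f"false positives: {sorted(false_pos)}")
    print(report.round(4).to_string(index=False))
    print(f"\nwrote {RESULTS / 'screen_report.tsv'}")


if __name__ == "__main__":
    main()
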