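#!/usr/bin/env python
"""Does the second regression stage help?

For each seeded cohort (one subject, 3 trials), fit the two-stage GRNN
pipeline on two trials, test on the held-out one, and compare the final
(stage-2) mean R^2 against the single-stage (stage-1) baseline from the
same fit.  A sign test across cohorts summarizes whether stacking wins
more often than chance.  Writes results/stacking_gain.csv.
"""

from pathlib import Path

import pandas as pd
from scipy.stats import binomtest

from fmgforce import (
    BandLayout,
    CaseConfig,
    CouplingModel,
    ProtocolConfig,
    TuningPlan,
    cross_trial_evaluate,
    generate_subject,
)
from fmgforce.evaluation import mean_r2

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_COHORTS = 20
PLAN = TuningPlan(grids={"grnn": [{"sigma": s} for s in (0.1, 0.3, 1.0)]})


def main() -> None:
    layout = BandLayout()
    case = CaseConfig.case2("grnn")
    rows = []
    for seed in range(N_COHORTS):
        cfg = ProtocolConfig(n_trials=3)
        coupling = CouplingModel.default(layout, seed=seed * 7 + 1)
        ds = generate_subject(cfg, coupling, layout, seed=seed * 7)
        df = cross_trial_evaluate(ds, case, plan=PLAN, seed=seed, holdout_trials=[0])
        rows.append(
            {
                "cohort": seed,
                "single_stage_r2": mean_r2(df, stage=1),
                "two_stage_r2": mean_r2(df, stage=2),
            }
        )
        print(f"cohort {seed}: {rows[-1]['single_stage_r2']:.3f} -> {rows[-1]['two_stage_r2']:.3f}")
    table = pd.DataFrame(rows)
    table["gain"] = table["two_stage_r2"] - table["single_stage_r2"]
    wins = int((table["gain"] > 0).sum())
    p = binomtest(wins, len(table), 0.5, alternative="greater").pvalue
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "stacking_gain.csv", index=False)
    print(
        f"\nstacking wins {wins}/{len(table)} cohorts "
        f"(sign test p = {p:.4f}); mean gain {table['gain'].mean():+.3f} R^2"
    )
    print(f"wrote {RESULTS / 'stacking_gain.csv'}")


if __name__ == "__main__":
    main()
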