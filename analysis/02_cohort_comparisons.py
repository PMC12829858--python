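#!/usr/bin/env python
"""Per-analyte case-control comparisons in each cohort.

For the human cohort: Shapiro-Wilk normality screening per group, the
normality-gated test per analyte (Welch t or Mann-Whitney), and the same
comparisons after sex adjustment by pooled linear-model residualization.
For each mouse model: the treated-vs-control comparisons.  Also computes the
behavioral endpoints (immobility, sucrose preference) per model.  Tables go
to results/tables/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from ffaconcord.io import read_concentration_table
from ffaconcord.stats import (ComparisonPolicy, adjust_for_covariates,
                              compare_all_analytes, compare_two_groups,
                              sucrose_preference)

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--out", type=Path,
                        default=ROOT / "results" / "tables")
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    truth = json.loads((args.data / "truth.json").read_text())
    policy = ComparisonPolicy()

    human = read_concentration_table(args.data / "human.csv")
    human_cmp = compare_all_analytes(human, "alMDD", "HC", policy)
    human_cmp.to_csv(out / "human_comparisons.csv", index=False)
    adjusted = {a: adjust_for_covariates(human, ["sex"], a)[0]
                for a in human.analytes}
    human_adj = compare_all_analytes(human, "alMDD", "HC", policy,
                                     adjusted_values=adjusted)
    human_adj.to_csv(out / "human_comparisons_sex_adjusted.csv", index=False)
    n_sig = int(human_cmp["significant"].sum())
    n_down = int((human_cmp["significant"]
                  & (human_cmp["direction"] == "down")).sum())
    print(f"human alMDD vs HC: {n_sig}/{len(human_cmp)} analytes "
          f"significant, {n_down} decreased "
          f"({int(human_adj['significant'].sum())} significant after sex "
          f"adjustment)")

    for name, (control, case) in sorted(truth["group_labels"].items()):
        mouse = read_concentration_table(args.data / f"mouse_{name}.csv")
        cmp_df = compare_all_analytes(mouse, case, control, policy)
        cmp_df.to_csv(out / f"comparisons_{name}.csv", index=False)
        down = cmp_df["significant"] & (cmp_df["direction"] == "down")
        print(f"{name} mice ({case} vs {control}): "
              f"{int(down.sum())} analytes significantly decreased of "
              f"{len(cmp_df)}")

        behav = pd.read_csv(args.data / f"behavior_{name}.csv")
        rows = []
        for endpoint in ("immobility_s", "interaction_zone_s"):
            res = compare_two_groups(
                behav.loc[behav["group"] == case, endpoint],
                behav.loc[behav["group"] == control, endpoint],
                policy, analyte_id=endpoint)
            rows.append(vars(res))
        spt = behav.assign(spt=[sucrose_preference(s, w) for s, w in
                                zip(behav["sucrose_intake_g"],
                                    behav["water_intake_g"])])
        res = compare_two_groups(spt.loc[spt["group"] == case, "spt"],
                                 spt.loc[spt["group"] == control, "spt"],
                                 policy, analyte_id="sucrose_preference_pct")
        rows.append(vars(res))
        pd.DataFrame(rows).to_csv(out / f"behavior_tests_{name}.csv",
                                  index=False)


if __name__ == "__main__":
    main()
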