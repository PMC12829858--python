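#!/usr/bin/env python
"""Concordance scoring: z-scores, S-scores, and per-animal AERC.

Standardizes the human cohort against HC and each mouse cohort against its
own control group, locates every treated animal within the patient z-score
distribution (S-score), and summarizes each animal's whole-panel deviation
as the area enclosed by its |s| radar polygon (AERC).  Emits score tables
and plot-ready radar vertex coordinates under results/tables/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from ffaconcord.concordance import (aerc, compare_model_sscores,
                                    radar_vertices, sscore, zscore_reference)
from ffaconcord.io import harmonize_panels, read_concentration_table

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--out", type=Path,
                        default=ROOT / "results" / "tables")
    parser.add_argument("--radius-transform", default="abs",
                        choices=["abs", "shift_min", "clip_zero"])
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    truth = json.loads((args.data / "truth.json").read_text())

    human = read_concentration_table(args.data / "human.csv")
    sscores, aercs = {}, {}
    for name, (control, case) in sorted(truth["group_labels"].items()):
        mouse = read_concentration_table(args.data / f"mouse_{name}.csv")
        _, human_h, mouse_h = harmonize_panels(human, mouse)
        human_z = zscore_reference(human_h, "HC")
        mouse_z = zscore_reference(mouse_h, control)
        s = sscore(mouse_z, human_z, "alMDD")
        s.s.to_csv(out / f"sscores_{name}.csv", index=False)
        sscores[name] = s

        case_s = type(s)(s.s[s.s["group"] == case].copy(), list(s.analytes),
                         s.patient_group, s.patient_stats, list(s.dropped))
        res = aerc(case_s, radius_transform=args.radius_transform)
        aercs[name] = res
        res.per_animal.to_csv(out / f"aerc_{name}.csv", index=False)
        mean_radii = case_s.values()[res.panel_order].abs().mean()
        radar_vertices(mean_radii.to_numpy(), res.panel_order).to_csv(
            out / f"radar_vertices_{name}.csv", index=False)
        g = res.group_summary.loc[case]
        print(f"{name}: mean AERC {g['mean']:.3f} +/- {g['sem']:.3f} SEM "
              f"(n={int(g['n'])}), mean |s| {s.mean_abs(case):.3f}")

    names = sorted(sscores)
    if len(names) == 2:
        table, overall = compare_model_sscores(sscores[names[0]],
                                               sscores[names[1]],
                                               names[0], names[1])
        table.to_csv(out / "model_sscore_comparison.csv", index=False)
        closer = table["closer_model"].value_counts().to_dict()
        print(f"per-analyte closer-to-patient counts: {closer}")

    human_z = zscore_reference(human, "HC")
    human_z.z.to_csv(out / "zscores_human.csv", index=False)


if __name__ == "__main__":
    main()
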