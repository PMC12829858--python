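"""End-to-end pipeline: load/simulate -> compare -> standardize -> rank.

The driver wires the stages together in the order the analysis needs them:

1. load (or simulate) the human cohort and one table per animal model;
2. harmonize analyte panels across species;
3. per-analyte normality screening and case-vs-control comparisons
   (humans additionally covariate-adjusted);
4. z-score every cohort against its own control group;
5. S-score each animal model against the patient z-score distribution;
6. AERC per animal and per-group summaries; model-vs-model s-score tests;
7. rank models by concordance.

All stage outputs land in the output directory as CSV/JSON together with a
run manifest (config hash, seed, package version) and a warnings log, so a
run can be reproduced exactly from the manifest.  Identical config + seed
give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .concordance import (aerc, compare_model_sscores, radar_vertices,
                          rank_models, sscore, zscore_reference)
from .io import SampleTable, harmonize_panels, read_concentration_table
from .stats import (ComparisonPolicy, adjust_for_covariates,
                    assess_normality, compare_all_analytes)
from .synthetic import (SimulationConfig, default_human_covariates,
                        default_human_panel, default_mouse_panel,
                        simulate_behavior, simulate_concordance_scenario)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_demo"]


class PipelineError(RuntimeError):
    """Raised with a stage-named message when any pipeline stage fails."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of (input paths, scenario).

    `human_groups` / model group pairs are (control, case) label pairs; the
    human case group is the patient cohort that the S-scores reference.
    """

    human_table: str | None = None
    model_tables: dict[str, str] = field(default_factory=dict)
    scenario: dict | None = None
    human_groups: tuple[str, str] = ("HC", "alMDD")
    model_groups: dict[str, tuple[str, str]] = field(default_factory=dict)
    alpha: float = 0.05
    parametric: str = "welch"
    covariates: list[str] = field(default_factory=lambda: ["sex"])
    radius_transform: str = "abs"
    panel_order: list[str] | None = None
    ranking_policy: str = "mean_aerc"
    seed: int = 0
    output_dir: str = "ffaconcord_out"

    def __post_init__(self) -> None:
        has_paths = self.human_table is not None or bool(self.model_tables)
        has_scenario = self.scenario is not None
        if has_paths == has_scenario:
            raise ValueError("provide exactly one of input paths or a "
                             "synthetic scenario spec")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "human_groups" in raw:
            raw["human_groups"] = tuple(raw["human_groups"])
        if "model_groups" in raw:
            raw["model_groups"] = {k: tuple(v)
                                   for k, v in raw["model_groups"].items()}
        return cls(**raw)

    def canonical_json(self) -> str:
        d = asdict(self)
        d["human_groups"] = list(d["human_groups"])
        d["model_groups"] = {k: list(v) for k, v in d["model_groups"].items()}
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _scenario_from_spec(spec: dict, seed: int):
    """Build the simulation bundle described by a scenario spec dict."""
    panel = default_human_panel(seed=spec.get("panel_seed", 0))
    cov_model, cov_effects = default_human_covariates()
    human_cfg = SimulationConfig(
        panel=panel,
        n_control=spec.get("n_control", 88),
        n_case=spec.get("n_case", 116),
        covariate_model=cov_model, covariate_effects=cov_effects,
        seed=seed, species="human")
    mouse_panel = default_mouse_panel(panel)
    n_mice = spec.get("n_mice_per_group", 6)
    fidelity = dict(spec.get("fidelity", {"LPS": 0.8, "CSDS": 0.3}))
    model_cfgs = {name: SimulationConfig(panel=mouse_panel, n_control=n_mice,
                                         n_case=n_mice, seed=seed,
                                         species="mouse")
                  for name in fidelity}
    return simulate_concordance_scenario(human_cfg, model_cfgs, fidelity,
                                         seed=seed)


def _load_inputs(config: PipelineConfig):
    """Stage 1: read or simulate all cohort tables."""
    if config.scenario is not None:
        bundle = _scenario_from_spec(config.scenario, config.seed)
        model_groups = dict(bundle.group_labels)
        return bundle.human, bundle.models, config.human_groups, model_groups
    if config.human_table is None or not config.model_tables:
        raise ValueError("need both a human table and at least one model table")
    human = read_concentration_table(config.human_table)
    models = {name: read_concentration_table(path)
              for name, path in config.model_tables.items()}
    model_groups = dict(config.model_groups)
    for name, table in models.items():
        if name not in model_groups:
            groups = table.groups
            if len(groups) != 2:
                raise ValueError(f"cannot infer (control, case) groups for "
                                 f"model {name!r}; found {groups}")
            model_groups[name] = (groups[0], groups[1])
    return human, models, config.human_groups, model_groups


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a summary dict and writes outputs."""

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    collected: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        human, models, human_groups, model_groups = stage(
            "load", _load_inputs, config)
        hc_group, patient_group = human_groups

        # panel harmonization: every model against the human panel
        def _harmonize():
            out = {}
            human_r = human
            for name, table in models.items():
                _, human_r, out[name] = harmonize_panels(human_r, table)
            # second pass restricts every model to the final shared panel
            return human_r, {n: t.restrict(human_r.analytes)
                             for n, t in out.items()}
        human_h, models_h = stage("harmonize", _harmonize)

        policy = ComparisonPolicy(alpha=config.alpha,
                                  parametric=config.parametric)

        def _normality():
            rows = []
            for analyte in human_h.analytes:
                rep = assess_normality(
                    {g: human_h.concentrations(analyte, g).to_numpy()
                     for g in human_groups},
                    alpha=policy.normality_alpha, analyte_id=analyte,
                    with_qq=False)
                for g in rep.groups:
                    rows.append({"analyte_id": analyte, "group": g.group,
                                 "n": g.n, "W": g.W, "p": g.p,
                                 "status": g.status, "verdict": rep.verdict})
            return pd.DataFrame(rows)
        normality = stage("normality", _normality)

        human_cmp = stage("human_comparisons", compare_all_analytes,
                          human_h, patient_group, hc_group, policy)

        def _adjusted():
            usable = [c for c in config.covariates
                      if c in human_h.data.columns
                      and human_h.data[c].notna().all()]
            if not usable:
                return None, None
            adj = {a: adjust_for_covariates(human_h, usable, a)[0]
                   for a in human_h.analytes}
            cmp_adj = compare_all_analytes(human_h, patient_group, hc_group,
                                           policy, adjusted_values=adj)
            return usable, cmp_adj
        used_covariates, human_cmp_adj = stage("covariate_adjustment", _adjusted)

        model_cmp = {name: stage(f"{name}_comparisons", compare_all_analytes,
                                 table, model_groups[name][1],
                                 model_groups[name][0], policy)
                     for name, table in models_h.items()}

        human_z = stage("zscore_human", zscore_reference, human_h, hc_group)
        model_z = {name: stage(f"zscore_{name}", zscore_reference,
                               table, model_groups[name][0])
                   for name, table in models_h.items()}
        model_s = {name: stage(f"sscore_{name}", sscore, z, human_z,
                               patient_group)
                   for name, z in model_z.items()}

        def _aerc_case(name):
            s = model_s[name]
            case_label = model_groups[name][1]
            case_s = type(s)(s.s[s.s["group"] == case_label].copy(),
                             list(s.analytes), s.patient_group,
                             s.patient_stats, list(s.dropped))
            order = config.panel_order or None
            if order is not None:
                order = [a for a in order if a in s.analytes]
            return aerc(case_s, panel_order=order,
                        radius_transform=config.radius_transform)
        model_aerc = {name: stage(f"aerc_{name}", _aerc_case, name)
                      for name in model_s}

        pairwise, overall_abs_s = (None, None)
        if len(model_s) == 2:
            a, b = sorted(model_s)
            pairwise, overall_abs_s = stage(
                "model_comparison", compare_model_sscores,
                model_s[a], model_s[b], a, b)

        ranking = stage("ranking", rank_models, model_aerc, model_s,
                        config.ranking_policy)

        collected = [str(w.message) for w in wrec]

    # ---- write outputs --------------------------------------------------
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    normality.to_csv(outdir / "normality_human.csv", index=False)
    human_cmp.to_csv(outdir / "human_comparisons.csv", index=False)
    if human_cmp_adj is not None:
        human_cmp_adj.to_csv(outdir / "human_comparisons_adjusted.csv",
                             index=False)
    for name, df in model_cmp.items():
        df.to_csv(outdir / f"comparisons_{name}.csv", index=False)
    human_z.z.to_csv(outdir / "zscores_human.csv", index=False)
    for name, z in model_z.items():
        z.z.to_csv(outdir / f"zscores_{name}.csv", index=False)
    for name, s in model_s.items():
        s.s.to_csv(outdir / f"sscores_{name}.csv", index=False)

    aerc_rows, vert_rows = [], []
    for name, res in model_aerc.items():
        df = res.per_animal.copy()
        df.insert(0, "model", name)
        aerc_rows.append(df)
        mean_radii = (model_s[name].values(model_groups[name][1])
                      [res.panel_order].abs().mean())
        v = radar_vertices(mean_radii.to_numpy(), res.panel_order)
        v.insert(0, "model", name)
        vert_rows.append(v)
    pd.concat(aerc_rows).to_csv(outdir / "aerc_per_animal.csv", index=False)
    pd.concat([r.group_summary.assign(model=n).reset_index()
               for n, r in model_aerc.items()]
              ).to_csv(outdir / "aerc_summary.csv", index=False)
    pd.concat(vert_rows).to_csv(outdir / "radar_vertices.csv", index=False)
    if pairwise is not None:
        pairwise.to_csv(outdir / "model_sscore_comparison.csv", index=False)

    ranking.to_csv(outdir / "ranking.csv", index=False)
    ranking_payload = {
        "policy": config.ranking_policy,
        "radius_transform": config.radius_transform,
        "panel_order": model_aerc[ranking["model"].iloc[0]].panel_order,
        "ranking": ranking.to_dict(orient="records"),
        "overall_mean_abs_s": overall_abs_s,
    }
    (outdir / "ranking.json").write_text(
        json.dumps(ranking_payload, indent=2, sort_keys=True))

    manifest = {
        "config": json.loads(config.canonical_json()),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "covariates_used": used_covariates,
        "n_warnings": len(collected),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "warnings.log").write_text("\n".join(collected) + ("\n" if collected else ""))

    best = ranking.iloc[0]
    summary_lines = [
        f"samples: human n={human_h.n_samples}, models: "
        + ", ".join(f"{n} n={t.n_samples}" for n, t in models_h.items()),
        f"shared panel: {len(human_h.analytes)} analytes",
        "significant human analytes (unadjusted p < "
        f"{config.alpha:g}): {int(human_cmp['significant'].sum())}"
        f" of {len(human_cmp)}",
        *(f"significant analytes in {n}: {int(df['significant'].sum())}"
          f" of {len(df)}" for n, df in model_cmp.items()),
        *(f"mean AERC {n} ({model_groups[n][1]}): "
          f"{res.per_animal['area'].mean():.3f}"
          for n, res in model_aerc.items()),
        f"most concordant model by {config.ranking_policy}: {best['model']} "
        f"(mean AERC {best['mean_aerc']:.3f}, mean |s| {best['mean_abs_s']:.3f})",
    ]
    (outdir / "summary.txt").write_text("\n".join(summary_lines) + "\n")

    return {
        "ranking": ranking,
        "model_aerc": model_aerc,
        "model_sscores": model_s,
        "human_comparisons": human_cmp,
        "human_comparisons_adjusted": human_cmp_adj,
        "model_comparisons": model_cmp,
        "warnings": collected,
        "output_dir": str(outdir),
    }


def make_demo(output_dir, seed: int = 0) -> Path:
    """Write a small, documented demo dataset plus a ready-to-run config.

    30 HC / 40 patients, two 6+6-mouse models (one high-, one low-fidelity),
    behavioral endpoint tables, generating-parameter sidecars, and a
    `config.yaml` whose pipeline run completes in seconds.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    panel = default_human_panel(seed=0)
    cov_model, cov_effects = default_human_covariates()
    human_cfg = SimulationConfig(panel=panel, n_control=30, n_case=40,
                                 covariate_model=cov_model,
                                 covariate_effects=cov_effects,
                                 seed=seed, species="human")
    mouse_panel = default_mouse_panel(panel)
    fidelity = {"LPS": 0.8, "CSDS": 0.3}
    model_cfgs = {name: SimulationConfig(panel=mouse_panel, n_control=6,
                                         n_case=6, seed=seed, species="mouse")
                  for name in fidelity}
    bundle = simulate_concordance_scenario(human_cfg, model_cfgs, fidelity,
                                           seed=seed)

    bundle.human.to_wide_csv(outdir / "human.csv")
    (outdir / "human_params.json").write_text(human_cfg.params_json())
    model_tables = {}
    for idx, (name, table) in enumerate(sorted(bundle.models.items())):
        path = outdir / f"mouse_{name}.csv"
        table.to_wide_csv(path)
        model_tables[name] = str(path)
        behav = simulate_behavior(6, effect=1.5, seed=seed * 7 + idx + 1,
                                  group_labels=bundle.group_labels[name])
        behav.to_csv(outdir / f"behavior_{name}.csv", index=False)
    (outdir / "truth.json").write_text(json.dumps(
        {"fidelity": bundle.fidelity,
         "human_fold_changes": bundle.human_fold_changes.round(6).to_dict(),
         "model_fold_changes": {n: s.round(6).to_dict()
                                for n, s in bundle.true_fold_changes.items()}},
        indent=2, sort_keys=True))

    cfg = {
        "human_table": str(outdir / "human.csv"),
        "model_tables": model_tables,
        "human_groups": ["HC", "alMDD"],
        "model_groups": {n: list(bundle.group_labels[n]) for n in fidelity},
        "alpha": 0.05,
        "covariates": ["sex"],
        "radius_transform": "abs",
        "seed": seed,
        "output_dir": str(outdir / "results"),
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return outdir
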