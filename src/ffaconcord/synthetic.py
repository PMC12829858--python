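"""Synthetic FFA cohorts with the statistical structure the analysis assumes.

Concentrations are log-normal per analyte: positive, spanning roughly three
orders of magnitude across a 26-analyte panel, as serum free fatty acid GC-MS
tables do.  The case-group effect acts multiplicatively on the median
(additively on the log scale) so "fold change 0.6" means the case median is
60% of the control median regardless of the analyte's absolute level.
Covariates (sex, age, years of education) enter additively on the log scale,
which lets the covariate-adjustment stage be exercised and its coefficients
recovered.

A single integer seed drives everything; sub-streams for the human cohort,
each animal model, the inherited-effect selection, and behavioral endpoints
are spawned from it with ``numpy.random.SeedSequence``, so identical configs
and seeds give bit-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import SampleTable, META_COLUMNS

__all__ = [
    "EffectProfile",
    "SimulationConfig",
    "ScenarioBundle",
    "simulate_cohort",
    "simulate_concordance_scenario",
    "simulate_behavior",
    "default_human_panel",
    "default_mouse_panel",
    "default_human_covariates",
]


@dataclass(frozen=True)
class EffectProfile:
    """Generating parameters of one analyte.

    log_mean/log_sd parameterize the control group's log-normal concentration
    (natural log of µg/mL); case_fold_change multiplies the case-group median
    (1 = no effect, < 1 = down-regulated in cases).
    """

    analyte_id: str
    log_mean: float
    log_sd: float
    case_fold_change: float = 1.0

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ValueError(f"{self.analyte_id}: log_sd must be > 0")
        if self.case_fold_change <= 0:
            raise ValueError(f"{self.analyte_id}: case_fold_change must be > 0")


@dataclass
class SimulationConfig:
    """One cohort: analyte panel, group sizes, covariate model, seed.

    covariate_model maps covariate name to a distribution spec:
    ``("bernoulli", p)`` for sex (drawn as female with probability p) or
    ``("normal", mean, sd)`` for age / education_years.  covariate_effects
    maps covariate name to a per-analyte vector of additive log-scale
    coefficients (sex effects multiply the female indicator).
    """

    panel: list[EffectProfile]
    n_control: int
    n_case: int
    covariate_model: dict[str, tuple] = field(default_factory=dict)
    covariate_effects: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0
    species: str = "human"

    def __post_init__(self) -> None:
        if not self.panel:
            raise ValueError("panel must not be empty")
        ids = [p.analyte_id for p in self.panel]
        if len(set(ids)) != len(ids):
            raise ValueError("analyte ids must be unique within a panel")
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need n >= 2 per group so SDs are computable")
        for cov, vec in self.covariate_effects.items():
            if len(np.asarray(vec)) != len(self.panel):
                raise ValueError(
                    f"covariate effect vector for {cov!r} has length "
                    f"{len(np.asarray(vec))}, panel has {len(self.panel)}")

    @property
    def analyte_ids(self) -> list[str]:
        return [p.analyte_id for p in self.panel]

    def with_fold_changes(self, folds) -> "SimulationConfig":
        """Copy of this config with a replaced fold-change vector."""
        folds = np.asarray(folds, dtype=float)
        panel = [EffectProfile(p.analyte_id, p.log_mean, p.log_sd, float(f))
                 for p, f in zip(self.panel, folds)]
        return SimulationConfig(panel, self.n_control, self.n_case,
                                dict(self.covariate_model),
                                dict(self.covariate_effects),
                                self.seed, self.species)

    def params_json(self) -> str:
        """Generating parameters as a JSON sidecar string."""
        payload = {
            "species": self.species,
            "n_control": self.n_control,
            "n_case": self.n_case,
            "seed": self.seed,
            "covariate_model": {k: list(v) for k, v in self.covariate_model.items()},
            "covariate_effects": {k: list(map(float, v))
                                  for k, v in self.covariate_effects.items()},
            "panel": [asdict(p) for p in self.panel],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _sub_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2 ** 31))


def _draw_covariates(rng: np.random.Generator, model: dict[str, tuple],
                     n: int) -> dict[str, np.ndarray]:
    """Draw covariate columns in a fixed order for reproducibility."""
    out: dict[str, np.ndarray] = {}
    for cov in sorted(model):
        spec = model[cov]
        kind = spec[0]
        if kind == "bernoulli":
            out[cov] = rng.binomial(1, spec[1], size=n).astype(float)
        elif kind == "normal":
            out[cov] = rng.normal(spec[1], spec[2], size=n)
        else:
            raise ValueError(f"unknown covariate distribution {kind!r}")
    return out


def simulate_cohort(config: SimulationConfig,
                    group_labels: tuple[str, str] = ("control", "case")
                    ) -> SampleTable:
    """Draw one cohort: n_control + n_case samples over the config's panel.

    Concentration of analyte a in subject i is
    ``exp(log_mean_a + covariate terms + eps)``, ``eps ~ N(0, log_sd_a)``,
    times ``case_fold_change_a`` iff the subject is a case.  All
    concentrations are strictly positive; identical config + seed reproduce
    the table bit-for-bit.
    """
    control_label, case_label = group_labels
    rng = np.random.default_rng(config.seed)
    n = config.n_control + config.n_case
    is_case = np.zeros(n, dtype=bool)
    is_case[config.n_control:] = True

    covs = _draw_covariates(rng, config.covariate_model, n)
    k = len(config.panel)
    log_mean = np.array([p.log_mean for p in config.panel])
    log_sd = np.array([p.log_sd for p in config.panel])
    log_fold = np.log([p.case_fold_change for p in config.panel])

    log_conc = log_mean[None, :] + rng.standard_normal((n, k)) * log_sd[None, :]
    for cov, beta in sorted(config.covariate_effects.items()):
        if cov in covs:
            log_conc += np.outer(covs[cov], np.asarray(beta, dtype=float))
    log_conc[is_case] += log_fold[None, :]

    groups = np.where(is_case, case_label, control_label)
    data = {
        "sample_id": [f"{config.species}_{g}_{i:04d}"
                      for i, g in enumerate(groups)],
        "species": config.species,
        "group": groups,
    }
    if "sex" in covs:
        data["sex"] = np.where(covs["sex"] > 0, "female", "male")
    if "age" in covs:
        data["age"] = covs["age"]
    if "education_years" in covs:
        data["education_years"] = covs["education_years"]
    df = pd.DataFrame(data)
    conc = pd.DataFrame(np.exp(log_conc), columns=config.analyte_ids)
    return SampleTable(pd.concat([df, conc], axis=1), config.analyte_ids)


@dataclass
class ScenarioBundle:
    """Human table, one table per animal model, and the generating truth."""

    human: SampleTable
    models: dict[str, SampleTable]
    human_fold_changes: pd.Series
    true_fold_changes: dict[str, pd.Series]
    fidelity: dict[str, float]
    group_labels: dict[str, tuple[str, str]]


def simulate_concordance_scenario(human_config: SimulationConfig,
                                  model_configs: dict[str, SimulationConfig],
                                  fidelity: dict[str, float],
                                  seed: int | None = None,
                                  human_groups: tuple[str, str] = ("HC", "alMDD"),
                                  ) -> ScenarioBundle:
    """Generate a human cohort plus animal models of known fidelity.

    For each model, a fraction ``fidelity[name]`` of analytes (chosen at
    random, recorded in the result) inherits the human case fold change; the
    rest get fold change 1.  A model with fidelity 1 therefore shares the
    full human effect vector, and fidelity 0 is a null model — this gives the
    downstream ranking a recoverable ground truth.
    """
    if set(model_configs) != set(fidelity):
        raise ValueError("model_configs and fidelity must name the same models")
    human_ids = human_config.analyte_ids
    for name, cfg in model_configs.items():
        if set(cfg.analyte_ids) != set(human_ids):
            raise ValueError(f"model {name!r} panel does not match the human panel")
    for name, f in fidelity.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fidelity for {name!r} must lie in [0, 1]")

    root = np.random.SeedSequence(human_config.seed if seed is None else seed)
    names = sorted(model_configs)
    streams = root.spawn(1 + 2 * len(names))
    human_seed = _sub_seed(streams[0])

    human_cfg = SimulationConfig(human_config.panel, human_config.n_control,
                                 human_config.n_case,
                                 dict(human_config.covariate_model),
                                 dict(human_config.covariate_effects),
                                 human_seed, human_config.species)
    human = simulate_cohort(human_cfg, human_groups)
    human_folds = pd.Series({p.analyte_id: p.case_fold_change
                             for p in human_config.panel})

    models: dict[str, SampleTable] = {}
    truth: dict[str, pd.Series] = {}
    labels: dict[str, tuple[str, str]] = {}
    for idx, name in enumerate(names):
        select_rng = np.random.default_rng(_sub_seed(streams[1 + 2 * idx]))
        cfg = model_configs[name]
        k = len(cfg.panel)
        n_inherit = int(round(fidelity[name] * k))
        chosen = select_rng.choice(k, size=n_inherit, replace=False)
        folds = np.ones(k)
        # model panels may order analytes differently; inherit by id
        human_by_id = human_folds.to_dict()
        for j in chosen:
            folds[j] = human_by_id[cfg.analyte_ids[j]]
        model_cfg = cfg.with_fold_changes(folds)
        model_cfg.seed = _sub_seed(streams[2 + 2 * idx])
        glabels = (f"{name}_control", name)
        models[name] = simulate_cohort(model_cfg, glabels)
        truth[name] = pd.Series(folds, index=cfg.analyte_ids)
        labels[name] = glabels
    return ScenarioBundle(human, models, human_folds, truth,
                          dict(fidelity), labels)


def simulate_behavior(n_per_group: int, effect: float, seed: int,
                      group_labels: tuple[str, str] = ("control", "case")
                      ) -> pd.DataFrame:
    """Behavioral endpoints for a two-group mouse experiment.

    Case animals are shifted by `effect` control SDs in the depressive
    direction on each latent scale: immobility up, sucrose intake down,
    social-interaction-zone time down.  Immobility is clipped to the 0–240 s
    scoring window of a 4-minute forced swim test; intakes are log-normal and
    therefore strictly positive.
    """
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    group = np.array([group_labels[0]] * n_per_group
                     + [group_labels[1]] * n_per_group)
    case = group == group_labels[1]

    immobility = rng.normal(100.0, 25.0, n) + np.where(case, effect * 25.0, 0.0)
    immobility = np.clip(immobility, 0.0, 240.0)
    sucrose = np.exp(rng.normal(np.log(3.0), 0.25, n)
                     - np.where(case, effect * 0.25, 0.0))
    water = np.exp(rng.normal(np.log(1.5), 0.25, n))
    interaction = np.exp(rng.normal(np.log(80.0), 0.3, n)
                         - np.where(case, effect * 0.3, 0.0))
    return pd.DataFrame({
        "sample_id": [f"mouse_{g}_{i:03d}" for i, g in enumerate(group)],
        "group": group,
        "immobility_s": immobility,
        "sucrose_intake_g": sucrose,
        "water_intake_g": water,
        "interaction_zone_s": interaction,
    })


# --- study-condition defaults -------------------------------------------

def default_human_panel(seed: int = 0) -> list[EffectProfile]:
    """26-analyte FFA panel with a general case down-regulation.

    Log-means span roughly three orders of magnitude of µg/mL; fold changes
    sit in [0.55, 0.85] (down-regulated) for most analytes, near 1 for a few,
    mirroring a panel where the case group is broadly but unevenly reduced.
    """
    ids = ["C6:0", "C8:0", "C9:0", "C10:0", "C11:0", "C12:0", "C13:0",
           "C14:0", "C15:0", "C16:0", "C16:1", "C17:0", "C17:1", "C18:0",
           "C18:1n9c", "C18:1n9t", "C18:2n6c", "C18:3n3", "C19:0", "C20:0",
           "C20:1", "C20:4n6", "C21:0", "C22:0", "C22:6n3", "C24:0"]
    rng = np.random.default_rng(seed)
    # abundances from ~0.05 to ~150 µg/mL; long-chain saturates most abundant
    log_means = rng.uniform(np.log(0.05), np.log(150.0), len(ids))
    log_sds = rng.uniform(0.35, 0.7, len(ids))
    folds = rng.uniform(0.55, 0.85, len(ids))
    folds[rng.choice(len(ids), size=4, replace=False)] = 1.0  # a few unaffected
    return [EffectProfile(a, float(m), float(s), float(f))
            for a, m, s, f in zip(ids, log_means, log_sds, folds)]


def default_mouse_panel(human_panel: list[EffectProfile]) -> list[EffectProfile]:
    """Mouse control panel over the same analytes, no effects.

    Mouse baseline abundances differ from human ones (units and physiology
    do not transfer); the concordance statistics must cancel this, so the
    generator deliberately shifts and reshapes the log-scale parameters.
    """
    return [EffectProfile(p.analyte_id, p.log_mean - 0.7,
                          p.log_sd * 0.9, 1.0) for p in human_panel]


def default_human_covariates() -> tuple[dict[str, tuple], dict[str, np.ndarray]]:
    """Covariate model for the human cohort.

    Sex ~ Bernoulli (female-skewed as adolescent depression cohorts are),
    age ~ Normal(14.7, 1.9) years, education ~ Normal(8.9, 1.9) years.  Sex
    carries a modest log-scale effect on every analyte; age and education
    carry none by default, so their adjustment is a no-op that the covariate
    stage must leave intact.
    """
    model = {
        "sex": ("bernoulli", 0.62),
        "age": ("normal", 14.7, 1.9),
        "education_years": ("normal", 8.9, 1.9),
    }
    effects = {"sex": np.full(26, 0.12)}
    return model, effects
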