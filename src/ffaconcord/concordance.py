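"""Cross-species concordance scoring: z-scores, S-scores, and AERC.

The chain of statistics used to ask "which animal model best reproduces the
patient FFA signature?":

1.  **z-score** — every subject's concentration of each analyte is
    standardized against a named reference (control) population:
    ``z = (x - mean_ref) / sd_ref`` with the sample SD (ddof=1).  By
    construction the reference cohort's z-scores have mean 0 and SD 1 per
    analyte.

2.  **S-score** — an animal's standardized value is located within the
    patient cohort's z-score distribution:
    ``s = (z_animal - mean(z_patients)) / sd(z_patients)``.
    s = 0 means the animal sits exactly at the patient mean; larger |s|
    means greater divergence from the patient profile.  Because the two
    standardizations cancel measurement units within each species, s is
    invariant to affine rescaling of raw concentrations applied consistently
    within a species.

3.  **AERC** — the area enclosed by the radar chart: with k analytes on
    equally spaced axes (angle step 2*pi/k) and non-negative radii r_1..r_k,
    the polygon area is ``0.5 * sin(2*pi/k) * sum_i r_i * r_{i+1}`` (cyclic).
    Radii are a non-negative transform of the s-scores (|s| by default, so
    AERC summarizes whole-panel distance from the patient profile per
    animal).  The area depends on axis order, so the order used is always
    carried in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import META_COLUMNS, SampleTable
from .panels import AnalytePanel

__all__ = [
    "ZScoreTable",
    "SScoreTable",
    "AERCResult",
    "zscore_reference",
    "sscore",
    "polygon_area",
    "radar_vertices",
    "aerc",
    "compare_model_sscores",
    "rank_models",
]

RADIUS_TRANSFORMS = ("abs", "shift_min", "clip_zero")


@dataclass
class ZScoreTable:
    """Per-sample, per-analyte z-scores against a named reference group."""

    z: pd.DataFrame                  # metadata columns + one column per analyte
    analytes: list[str]
    reference_group: str
    reference_stats: pd.DataFrame    # index analyte_id; columns mean, sd, n
    dropped: list[str] = field(default_factory=list)

    def values(self, group: str | None = None) -> pd.DataFrame:
        df = self.z
        if group is not None:
            df = df[df["group"] == group]
        return df.set_index("sample_id")[self.analytes]


@dataclass
class SScoreTable:
    """Per-animal deviation from the patient cohort's z-score distribution."""

    s: pd.DataFrame                  # metadata columns + one column per analyte
    analytes: list[str]
    patient_group: str
    patient_stats: pd.DataFrame      # index analyte_id; columns mean_z, sd_z, n
    dropped: list[str] = field(default_factory=list)

    def values(self, group: str | None = None) -> pd.DataFrame:
        df = self.s
        if group is not None:
            df = df[df["group"] == group]
        return df.set_index("sample_id")[self.analytes]

    def mean_abs(self, group: str | None = None) -> float:
        """Mean |s| over animals and analytes (smaller = closer to patients)."""
        return float(self.values(group).abs().mean().mean())


@dataclass
class AERCResult:
    """Per-animal radar polygon areas plus group summaries."""

    per_animal: pd.DataFrame         # sample_id, group, area
    group_summary: pd.DataFrame      # index group; columns mean, sem, n
    panel_order: list[str]
    radius_transform: str


def zscore_reference(table: SampleTable, reference_group: str) -> ZScoreTable:
    """Standardize every sample per analyte against the reference group.

    Reference mean and SD (ddof=1) are computed from non-missing reference
    values; analytes whose reference SD is zero (or with fewer than two
    reference values) are dropped with a warning.
    """
    if reference_group not in set(table.data["group"]):
        raise ValueError(f"reference group {reference_group!r} absent from table")
    ref = table.data[table.data["group"] == reference_group]
    if len(ref) < 2:
        raise ValueError("reference group needs at least 2 samples")

    stats_rows, dropped, kept = [], [], []
    for analyte in table.analytes:
        vals = ref[analyte].dropna()
        if len(vals) < 2 or float(vals.std(ddof=1)) == 0.0:
            dropped.append(analyte)
            continue
        kept.append(analyte)
        stats_rows.append({"analyte_id": analyte, "mean": float(vals.mean()),
                           "sd": float(vals.std(ddof=1)), "n": len(vals)})
    if dropped:
        warnings.warn(f"dropped {len(dropped)} analyte(s) with zero/undefined "
                      f"reference SD: {dropped}")
    if not kept:
        raise ValueError("no analyte has a usable reference SD")

    ref_stats = pd.DataFrame(stats_rows).set_index("analyte_id")
    meta = [c for c in META_COLUMNS if c in table.data.columns]
    z = table.data[meta].copy()
    for analyte in kept:
        mu, sd = ref_stats.loc[analyte, "mean"], ref_stats.loc[analyte, "sd"]
        z[analyte] = (table.data[analyte] - mu) / sd
    return ZScoreTable(z, kept, reference_group, ref_stats, dropped)


def sscore(animal_z: ZScoreTable, patient_z: ZScoreTable, patient_group: str,
           animal_values: str = "standardized") -> SScoreTable:
    """S-score each animal against the patient cohort's z-score distribution.

    ``s = (v_animal - mean(z_patient)) / sd(z_patient)`` per analyte, where
    ``v_animal`` is the animal's z-score against its own species' control
    group (``animal_values="standardized"``, the default, which makes the two
    species commensurable) or — for auditability — the raw concentration
    (``animal_values="raw"`` requires `animal_z.z` to carry raw values).
    Analytes with zero patient z SD are dropped with a warning.
    """
    if animal_values not in {"standardized", "raw"}:
        raise ValueError("animal_values must be 'standardized' or 'raw'")
    patients = patient_z.z[patient_z.z["group"] == patient_group]
    if len(patients) < 2:
        raise ValueError(f"patient group {patient_group!r} needs >= 2 samples")

    shared = [a for a in AnalytePanel.canonical(
        set(animal_z.analytes) & set(patient_z.analytes))]
    if not shared:
        raise ValueError("no shared analytes between animal and patient panels")

    stats_rows, kept, dropped = [], [], []
    for analyte in shared:
        zp = patients[analyte].dropna()
        sd = float(zp.std(ddof=1)) if len(zp) >= 2 else 0.0
        if sd == 0.0:
            dropped.append(analyte)
            continue
        kept.append(analyte)
        stats_rows.append({"analyte_id": analyte, "mean_z": float(zp.mean()),
                           "sd_z": sd, "n": len(zp)})
    if dropped:
        warnings.warn(f"dropped {len(dropped)} analyte(s) with zero patient "
                      f"z-score SD: {dropped}")
    if not kept:
        raise ValueError("no analyte has a usable patient z-score SD")

    pstats = pd.DataFrame(stats_rows).set_index("analyte_id")
    meta = [c for c in META_COLUMNS if c in animal_z.z.columns]
    s = animal_z.z[meta].copy()
    for analyte in kept:
        m, sd = pstats.loc[analyte, "mean_z"], pstats.loc[analyte, "sd_z"]
        s[analyte] = (animal_z.z[analyte] - m) / sd
    return SScoreTable(s, kept, patient_group, pstats, dropped)


def _transform_radii(svals: np.ndarray, transform: str) -> np.ndarray:
    if transform == "abs":
        return np.abs(svals)
    if transform == "shift_min":
        return svals - svals.min(axis=-1, keepdims=True)
    if transform == "clip_zero":
        return np.clip(svals, 0.0, None)
    raise ValueError(f"unknown radius transform {transform!r}; "
                     f"choose one of {RADIUS_TRANSFORMS}")


def polygon_area(radii) -> float:
    """Area of a radar polygon with vertices at equal angular spacing.

    With k radii and angle step theta = 2*pi/k the enclosed area is
    0.5 * sum_i r_i * r_{i+1} * sin(theta), indices cyclic.
    """
    r = np.asarray(radii, dtype=float)
    if r.ndim != 1 or len(r) < 3:
        raise ValueError("a radar polygon needs at least 3 radii")
    if (r < 0).any():
        raise ValueError("radii must be non-negative")
    theta = 2.0 * np.pi / len(r)
    return float(0.5 * np.sin(theta) * np.sum(r * np.roll(r, -1)))


def radar_vertices(radii, analyte_ids=None) -> pd.DataFrame:
    """Polar vertex coordinates (angle, radius, x, y) for external plotting."""
    r = np.asarray(radii, dtype=float)
    k = len(r)
    angles = 2.0 * np.pi * np.arange(k) / k
    out = pd.DataFrame({"angle": angles, "radius": r,
                        "x": r * np.cos(angles), "y": r * np.sin(angles)})
    if analyte_ids is not None:
        out.insert(0, "analyte_id", list(analyte_ids))
    return out


def aerc(s_table: SScoreTable, panel_order=None,
         radius_transform: str = "abs") -> AERCResult:
    """Radar polygon area per animal over the analyte panel.

    `panel_order` defaults to the s-table's (canonical) analyte order; it is
    recorded in the result because the area is not ordering-invariant.
    """
    order = list(panel_order) if panel_order is not None else list(s_table.analytes)
    missing = [a for a in order if a not in s_table.analytes]
    if missing:
        raise ValueError(f"panel order names analytes absent from the s-table: {missing}")
    if len(order) < 3:
        raise ValueError("AERC needs a panel of at least 3 analytes")

    svals = s_table.values()[order]
    if svals.isna().any().any():
        raise ValueError("missing s-scores; complete the panel before AERC")
    radii = _transform_radii(svals.to_numpy(), radius_transform)
    if (radii < 0).any():
        raise AssertionError("radius transform produced negative radii")
    theta = 2.0 * np.pi / len(order)
    areas = 0.5 * np.sin(theta) * np.sum(radii * np.roll(radii, -1, axis=1), axis=1)

    per_animal = pd.DataFrame({
        "sample_id": svals.index,
        "group": s_table.s.set_index("sample_id").loc[svals.index, "group"].to_numpy(),
        "area": areas,
    })
    summary = per_animal.groupby("group")["area"].agg(
        mean="mean", sem=lambda v: sps.sem(v, ddof=1), n="count")
    return AERCResult(per_animal, summary, order, radius_transform)


def compare_model_sscores(s_a: SScoreTable, s_b: SScoreTable,
                          name_a: str = "A", name_b: str = "B"
                          ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-analyte two-sample t-test of s-scores between two models.

    Also reports which model's mean |s| is smaller (closer to the patient
    profile) per analyte and overall.  Returns (per-analyte table,
    {model: overall mean |s|}).
    """
    shared = [a for a in s_a.analytes if a in set(s_b.analytes)]
    if not shared:
        raise ValueError("the two s-score tables share no analytes")
    va, vb = s_a.values()[shared], s_b.values()[shared]
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("each model needs >= 2 animals")

    rows = []
    for analyte in shared:
        a, b = va[analyte].dropna().to_numpy(), vb[analyte].dropna().to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=False)
        ma, mb = float(np.mean(np.abs(a))), float(np.mean(np.abs(b)))
        closer = "tie" if ma == mb else (name_a if ma < mb else name_b)
        rows.append({"analyte_id": analyte, "t_statistic": float(stat),
                     "p_value": float(p),
                     f"mean_abs_s_{name_a}": ma, f"mean_abs_s_{name_b}": mb,
                     "closer_model": closer})
    overall = {name_a: s_a.mean_abs(), name_b: s_b.mean_abs()}
    return pd.DataFrame(rows), overall


def rank_models(aerc_by_model: dict[str, AERCResult] | dict[str, float],
                s_by_model: dict[str, SScoreTable] | dict[str, float],
                policy: str = "mean_aerc") -> pd.DataFrame:
    """Order models by concordance with the patient profile (smaller = closer).

    `policy` picks the primary summary ("mean_aerc" over case animals, or
    "mean_abs_s"); ties break on the other summary, then on the model name.
    Both summaries are reported.
    """
    if policy not in {"mean_aerc", "mean_abs_s"}:
        raise ValueError("policy must be 'mean_aerc' or 'mean_abs_s'")
    if not aerc_by_model or not s_by_model:
        raise ValueError("need at least one model to rank")

    def _aerc_mean(v) -> float:
        return float(v.per_animal["area"].mean()) if isinstance(v, AERCResult) else float(v)

    def _abs_s(v) -> float:
        return v.mean_abs() if isinstance(v, SScoreTable) else float(v)

    names = sorted(aerc_by_model)
    rows = [{"model": m, "mean_aerc": _aerc_mean(aerc_by_model[m]),
             "mean_abs_s": _abs_s(s_by_model[m])} for m in names]
    df = pd.DataFrame(rows)
    secondary = "mean_abs_s" if policy == "mean_aerc" else "mean_aerc"
    df = df.sort_values([policy, secondary, "model"]).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
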