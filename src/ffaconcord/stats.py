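"""Group-comparison statistics for concentration panels.

The comparison policy mirrors common practice for small targeted-metabolomics
panels: each analyte is screened for normality per group (Shapiro-Wilk plus
exported Q-Q coordinates); analytes passing in every group get an unpaired
t-test (Welch by default), the rest a two-sided Mann-Whitney U — exact
enumeration when both groups are small and tie-free, otherwise the
tie-corrected normal approximation.  No multiple-testing correction is applied
by default; Benjamini-Hochberg adjusted p-values can be reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonPolicy",
    "ComparisonResult",
    "NormalityReport",
    "assess_normality",
    "compare_two_groups",
    "compare_all_analytes",
    "chi_square_contingency",
    "contingency_consistency",
    "kruskal_wallis",
    "one_way_anova",
    "adjust_for_covariates",
    "sucrose_preference",
    "significance_stars",
]


@dataclass(frozen=True)
class ComparisonPolicy:
    """Configuration of the normality-gated two-group test selection."""

    alpha: float = 0.05              # significance threshold for flags/stars
    normality_alpha: float = 0.05    # per-group Shapiro-Wilk gate
    parametric: str = "welch"        # "welch" or "student"
    force: str | None = None         # None | "t_test" | "mann_whitney"
    exact_max_n: int = 8             # exact Mann-Whitney when both n <= this
    multiple_testing: str | None = None  # None or "benjamini_hochberg"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.parametric not in {"welch", "student"}:
            raise ValueError("parametric must be 'welch' or 'student'")
        if self.force not in {None, "t_test", "mann_whitney"}:
            raise ValueError("force must be None, 't_test' or 'mann_whitney'")


@dataclass
class GroupNormality:
    group: str
    n: int
    W: float | None
    p: float | None
    status: str                      # "normal" | "non_normal" | "untestable"
    qq: pd.DataFrame | None = None   # theoretical vs sample quantiles


@dataclass
class NormalityReport:
    analyte_id: str
    groups: list[GroupNormality]
    verdict: str                     # "normal" | "non_normal" | "untestable"


@dataclass
class ComparisonResult:
    analyte_id: str
    test_used: str                   # "t_test" | "mann_whitney" | "kruskal_wallis"
    statistic: float
    p_value: float
    direction: str                   # "up" | "down" | "none" (case vs control)
    significant: bool
    n_case: int = 0
    n_control: int = 0
    mean_case: float = float("nan")
    mean_control: float = float("nan")
    p_adjusted: float | None = None


def _qq_coordinates(values: np.ndarray) -> pd.DataFrame:
    (theo, ordered), _ = sps.probplot(values, dist="norm")
    return pd.DataFrame({"theoretical": theo, "sample": ordered})


def assess_normality(values_by_group: dict[str, np.ndarray],
                     alpha: float = 0.05,
                     analyte_id: str = "",
                     with_qq: bool = True) -> NormalityReport:
    """Shapiro-Wilk screen per group with Q-Q coordinates for inspection.

    Verdict is "normal" only if every group is testable (n >= 3, non-constant)
    and passes at `alpha`; any untestable group makes the whole verdict
    "untestable", which downstream routes to the nonparametric branch.
    """
    groups: list[GroupNormality] = []
    statuses: list[str] = []
    for name, raw in values_by_group.items():
        vals = np.asarray(raw, dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 3 or np.ptp(vals) == 0:
            groups.append(GroupNormality(name, len(vals), None, None, "untestable"))
            statuses.append("untestable")
            continue
        W, p = sps.shapiro(vals)
        status = "normal" if p > alpha else "non_normal"
        qq = _qq_coordinates(vals) if with_qq else None
        groups.append(GroupNormality(name, len(vals), float(W), float(p), status, qq))
        statuses.append(status)
    if "untestable" in statuses:
        verdict = "untestable"
    elif all(s == "normal" for s in statuses):
        verdict = "normal"
    else:
        verdict = "non_normal"
    return NormalityReport(analyte_id, groups, verdict)


def _direction(mean_case: float, mean_control: float) -> str:
    if mean_case > mean_control:
        return "up"
    if mean_case < mean_control:
        return "down"
    return "none"


def compare_two_groups(case, control,
                       policy: ComparisonPolicy = ComparisonPolicy(),
                       analyte_id: str = "") -> ComparisonResult:
    """Normality-gated two-group comparison of one analyte.

    Both groups normal (Shapiro-Wilk p > normality gate) -> two-sided unpaired
    t-test (Welch unless the policy selects the pooled-variance variant);
    otherwise two-sided Mann-Whitney U, exact when both n <= 8 with no ties,
    else the tie-corrected normal approximation.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    case = case[~np.isnan(case)]
    control = control[~np.isnan(control)]
    if len(case) < 2 or len(control) < 2:
        raise ValueError("each group needs at least 2 non-missing values")

    mean_case, mean_control = float(np.mean(case)), float(np.mean(control))
    combined = np.concatenate([case, control])

    if np.ptp(combined) == 0:
        return ComparisonResult(analyte_id, "mann_whitney",
                                statistic=len(case) * len(control) / 2.0,
                                p_value=1.0, direction="none", significant=False,
                                n_case=len(case), n_control=len(control),
                                mean_case=mean_case, mean_control=mean_control)

    if policy.force == "t_test":
        use_t = True
    elif policy.force == "mann_whitney":
        use_t = False
    else:
        report = assess_normality({"case": case, "control": control},
                                  alpha=policy.normality_alpha, with_qq=False)
        use_t = report.verdict == "normal"

    if use_t:
        stat, p = sps.ttest_ind(case, control,
                                equal_var=(policy.parametric == "student"))
        test_used = "t_test"
    else:
        ties = len(np.unique(combined)) < len(combined)
        small = len(case) <= policy.exact_max_n and len(control) <= policy.exact_max_n
        if small and not ties:
            res = sps.mannwhitneyu(case, control, alternative="two-sided",
                                   method="exact")
        else:
            # tie-corrected normal approximation, no continuity correction
            res = sps.mannwhitneyu(case, control, alternative="two-sided",
                                   method="asymptotic", use_continuity=False)
        stat, p = res.statistic, res.pvalue
        test_used = "mann_whitney"

    p = float(min(p, 1.0))
    return ComparisonResult(analyte_id, test_used, float(stat), p,
                            _direction(mean_case, mean_control),
                            significant=p < policy.alpha,
                            n_case=len(case), n_control=len(control),
                            mean_case=mean_case, mean_control=mean_control)


def compare_all_analytes(table, case_group: str, control_group: str,
                         policy: ComparisonPolicy = ComparisonPolicy(),
                         adjusted_values: dict[str, pd.Series] | None = None
                         ) -> pd.DataFrame:
    """Run the two-group comparison over every analyte of a SampleTable.

    `adjusted_values` optionally substitutes covariate-adjusted series
    (indexed by sample_id) for the raw concentrations.
    """
    rows = []
    sample_group = table.data.set_index("sample_id")["group"]
    for analyte in table.analytes:
        if adjusted_values is not None and analyte in adjusted_values:
            series = adjusted_values[analyte]
            grp = sample_group.reindex(series.index)
            case_vals = series[grp == case_group].to_numpy()
            ctrl_vals = series[grp == control_group].to_numpy()
        else:
            case_vals = table.concentrations(analyte, case_group).to_numpy()
            ctrl_vals = table.concentrations(analyte, control_group).to_numpy()
        try:
            res = compare_two_groups(case_vals, ctrl_vals, policy, analyte)
        except ValueError as exc:
            warnings.warn(f"skipping analyte {analyte}: {exc}")
            continue
        rows.append(vars(res).copy())
    out = pd.DataFrame(rows)
    if policy.multiple_testing == "benjamini_hochberg" and len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    if len(out):
        out["stars"] = out["p_value"].map(significance_stars)
    return out


def chi_square_contingency(counts, correction: bool = False
                           ) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c table, without continuity correction
    by default.  Returns (statistic, df, p)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("every row and column marginal must be positive")
    stat, p, df, _ = sps.chi2_contingency(counts, correction=correction)
    return float(stat), int(df), float(p)


def contingency_consistency(counts, row_totals=None, col_totals=None) -> list[str]:
    """Flag mismatches between a printed contingency table and its stated
    marginals (e.g. a cell count inconsistent with the reported group n)."""
    counts = np.asarray(counts, dtype=float)
    flags: list[str] = []
    if row_totals is not None:
        for i, (got, want) in enumerate(zip(counts.sum(axis=1), row_totals)):
            if got != want:
                flags.append(f"row {i} sums to {got:g}, stated total is {want:g}")
    if col_totals is not None:
        for j, (got, want) in enumerate(zip(counts.sum(axis=0), col_totals)):
            if got != want:
                flags.append(f"column {j} sums to {got:g}, stated total is {want:g}")
    return flags


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if len(arrays) < 2 or any(len(a) < 1 for a in arrays):
        raise ValueError("need >= 2 groups with >= 1 value each")
    total_n = sum(len(a) for a in arrays)
    if total_n < 3:
        raise ValueError("need >= 3 values in total")
    df = len(arrays) - 1
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, df, 1.0
    H, p = sps.kruskal(*arrays)
    return float(H), df, float(p)


def one_way_anova(groups) -> tuple[float, int, int, float]:
    """One-way ANOVA F test; returns (F, df_between, df_within, p).

    Provided for completeness alongside the nonparametric tests; the
    reference analysis pipeline does not route any comparison through it.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    F, p = sps.f_oneway(*arrays)
    df_b = len(arrays) - 1
    df_w = sum(len(a) for a in arrays) - len(arrays)
    return float(F), df_b, df_w, float(p)


def adjust_for_covariates(table, covariates: list[str], analyte_id: str
                          ) -> tuple[pd.Series, pd.Series]:
    """Residualize one analyte's concentrations on covariates (pooled OLS).

    Fits concentration ~ covariates over the pooled sample, and returns the
    residuals re-centered at the pooled mean (indexed by sample_id) together
    with the fitted coefficients.  Sex is coded female=1/male=0 when given as
    strings.  A rank-deficient design raises, naming the collinear columns.
    """
    df = table.data.set_index("sample_id")
    y = pd.to_numeric(df[analyte_id], errors="coerce")
    X = pd.DataFrame(index=df.index)
    for cov in covariates:
        if cov not in df.columns:
            raise ValueError(f"covariate {cov!r} not present in the table")
        col = df[cov]
        if col.dtype == object:
            if cov == "sex":
                col = col.map({"female": 1.0, "male": 0.0})
            else:
                col = pd.to_numeric(col, errors="coerce")
        X[cov] = col.astype(float)
    mask = y.notna() & X.notna().all(axis=1)
    if mask.sum() < len(covariates) + 2:
        raise ValueError("too few complete cases to fit the covariate model")
    Xm = sm.add_constant(X[mask], has_constant="add")
    rank = np.linalg.matrix_rank(Xm.to_numpy())
    if rank < Xm.shape[1]:
        corr = X[mask].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax() if len(covariates) > 1 else (covariates[0],)
        raise ValueError(f"rank-deficient design; collinear columns: {sorted(set(worst))}")
    fit = sm.OLS(y[mask], Xm).fit()
    adjusted = fit.resid + y[mask].mean()
    adjusted.name = analyte_id
    return adjusted, fit.params


def sucrose_preference(sucrose_intake: float, water_intake: float) -> float:
    """Sucrose preference as sucrose / (sucrose + water) x 100, in percent."""
    if sucrose_intake < 0 or water_intake < 0:
        raise ValueError("intakes must be non-negative")
    total = sucrose_intake + water_intake
    if total <= 0:
        raise ValueError("total intake must be positive")
    return 100.0 * sucrose_intake / total


def significance_stars(p: float) -> str:
    """Render the conventional significance stars (* p<0.05, ** p<0.01)."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
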