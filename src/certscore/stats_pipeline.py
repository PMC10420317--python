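"""Nonparametric cohort statistics: group tests, regressions, rank ANCOVA.

The battery mirrors a cross-sectional three-group study design:

* per-variable Kruskal-Wallis omnibus tests with Dunn's pairwise post-hoc
  z-tests (Bonferroni-adjusted by default),
* multiple linear regressions of ceramide endpoints and the CERT1 score on
  clinical surrogates (waist circumference, blood pressure, HOMA-IR,
  HDL-C, triglycerides, CRP),
* covariate-adjusted group comparisons by rank-transform ANCOVA
  (Conover-Iman style; Quade's residual-rank variant available),
* Spearman association plus a descriptive least-squares line,
* a group-by-risk-category contingency test (Pearson chi-square, with a
  seeded Monte Carlo exact fallback when expected counts are small).

:func:`run_full_analysis` chains all stages into one
:class:`AnalysisReport` that serializes losslessly to JSON.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from certscore.ceramide_scoring import (
    RiskCategory,
    add_ratio_columns,
    fit_quartile_reference,
    score_cohort,
)
from certscore.clinical_scores import frs_2008, homa_ir, vascular_age
from certscore.core_model import CohortFrame, Group

__all__ = [
    "AnalysisConfig",
    "GroupTestResult",
    "RegressionResult",
    "AncovaResult",
    "AssociationResult",
    "ContingencyResult",
    "AnalysisReport",
    "kruskal_dunn",
    "ols_multiple_regression",
    "rank_ancova",
    "spearman_with_linfit",
    "risk_category_contingency",
    "run_full_analysis",
    "derive_analysis_frame",
]

_CATEGORY_ORDER = [c.value for c in RiskCategory]


def _clean(value: Any) -> Any:
    """Make a value JSON-native; NaN becomes None so round-trips are exact."""
    if isinstance(value, (np.floating, float)):
        v = float(value)
        return None if math.isnan(v) else v
    if isinstance(value, (np.integer, int)):
        return int(value)
    if isinstance(value, (np.bool_, bool)):
        return bool(value)
    if isinstance(value, dict):
        return {str(k): _clean(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_clean(v) for v in value]
    return value


@dataclass
class AnalysisConfig:
    """Knobs of the full analysis battery.

    ``adjustment`` applies to Dunn's pairwise tests (``"bonferroni"``,
    ``"holm"`` or ``"none"``); ``ancova_method`` selects the rank-ANCOVA
    flavor; ``contingency_exact`` switches the small-expected-count
    fallback (``"auto"`` triggers a seeded Monte Carlo test when any
    expected cell drops below ``expected_min``).
    """

    alpha: float = 0.05
    adjustment: str = "bonferroni"
    reference_group: str = Group.NW.value
    ancova_method: str = "rank_linear"  # or "quade"
    contingency_exact: str = "auto"  # "auto", "never", "always"
    expected_min: float = 5.0
    mc_permutations: int = 4999
    mc_seed: int = 0
    group_test_variables: tuple[str, ...] = (
        "age",
        "bmi",
        "wc",
        "sbp",
        "dbp",
        "glucose",
        "insulin",
        "homa_ir",
        "tc",
        "hdl",
        "ldl",
        "tg",
        "crp",
        "cer16",
        "cer18",
        "cer241",
        "cer240",
        "r16_240",
        "r18_240",
        "r241_240",
        "frs",
        "va",
    )
    regression_outcomes: tuple[str, ...] = (
        "cer16",
        "cer18",
        "cer241",
        "cer240",
        "r16_240",
        "r18_240",
        "r241_240",
        "cert1",
    )
    regression_predictors: tuple[str, ...] = (
        "wc",
        "sbp",
        "dbp",
        "homa_ir",
        "hdl",
        "tg",
        "crp",
    )
    ancova_covariate_sets: tuple[tuple[str, ...], ...] = (
        ("wc",),
        ("homa_ir", "crp"),
        ("wc", "homa_ir"),
        ("wc", "crp"),
    )
    run_group_tests: bool = True
    run_regressions: bool = True
    run_ancova: bool = True
    run_associations: bool = True
    run_contingency: bool = True

    def to_dict(self) -> dict[str, Any]:
        return _clean(
            {
                "alpha": self.alpha,
                "adjustment": self.adjustment,
                "reference_group": self.reference_group,
                "ancova_method": self.ancova_method,
                "contingency_exact": self.contingency_exact,
                "expected_min": self.expected_min,
                "mc_permutations": self.mc_permutations,
                "mc_seed": self.mc_seed,
                "group_test_variables": list(self.group_test_variables),
                "regression_outcomes": list(self.regression_outcomes),
                "regression_predictors": list(self.regression_predictors),
                "ancova_covariate_sets": [list(s) for s in self.ancova_covariate_sets],
                "run_group_tests": self.run_group_tests,
                "run_regressions": self.run_regressions,
                "run_ancova": self.run_ancova,
                "run_associations": self.run_associations,
                "run_contingency": self.run_contingency,
            }
        )


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    variable: str
    summaries: dict[str, dict[str, float | int]]  # group -> {n, q25, median, q75}
    statistic: float
    df: int
    p_value: float
    pairwise: list[dict[str, Any]]  # {group_a, group_b, z, p_raw, p_adjusted}
    degenerate: bool = False

    def to_dict(self) -> dict[str, Any]:
        return _clean(vars(self))


@dataclass
class RegressionResult:
    outcome: str
    predictors: list[str]
    n: int
    r_squared: float
    coefficients: dict[str, dict[str, float]]  # term -> {coef, se, p}

    def to_dict(self) -> dict[str, Any]:
        return _clean(vars(self))


@dataclass
class AncovaResult:
    outcome: str
    covariates: list[str]
    method: str
    reference_group: str
    n: int
    contrasts: dict[str, dict[str, float]]  # group -> {estimate, se, p}

    def to_dict(self) -> dict[str, Any]:
        return _clean(vars(self))


@dataclass
class AssociationResult:
    x: str
    y: str
    n: int
    rho: float | None
    rho_p: float | None
    slope: float
    intercept: float
    slope_p: float
    constant_input: bool = False

    def to_dict(self) -> dict[str, Any]:
        return _clean(vars(self))


@dataclass
class ContingencyResult:
    groups: list[str]
    categories: list[str]
    table: list[list[int]]
    statistic: float
    df: int
    p_value: float
    method: str
    min_expected: float

    def to_dict(self) -> dict[str, Any]:
        return _clean(vars(self))


@dataclass
class AnalysisReport:
    """Every output of :func:`run_full_analysis`, JSON-serializable."""

    provenance: str = ""
    config: dict[str, Any] = field(default_factory=dict)
    group_tests: dict[str, dict[str, Any]] = field(default_factory=dict)
    cert1_test: dict[str, Any] | None = None
    quartile_reference: dict[str, list[float]] = field(default_factory=dict)
    regressions: dict[str, dict[str, Any]] = field(default_factory=dict)
    ancovas: list[dict[str, Any]] = field(default_factory=list)
    associations: dict[str, dict[str, Any]] = field(default_factory=dict)
    contingency: dict[str, Any] | None = None
    stage_errors: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return _clean(vars(self))

    @classmethod
    def from_dict(cls, payload: Mapping[str, Any]) -> "AnalysisReport":
        return cls(**{k: payload[k] for k in payload})


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _as_frame(cohort: CohortFrame | pd.DataFrame) -> pd.DataFrame:
    if isinstance(cohort, CohortFrame):
        return cohort.to_dataframe()
    return cohort


def _adjust(p_values: Sequence[float], method: str) -> list[float]:
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if method == "none":
        adj = p
    elif method == "bonferroni":
        adj = np.minimum(1.0, p * m)
    elif method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(1.0, running)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return [float(v) for v in adj]


def kruskal_dunn(
    cohort: CohortFrame | pd.DataFrame,
    variable: str,
    adjustment: str = "bonferroni",
) -> GroupTestResult:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise post-hoc z-tests.

    Both the omnibus H statistic and the Dunn variance term use the
    standard tie correction on pooled mid-ranks.  When every observation is
    identical the result is flagged degenerate with H = 0 and p = 1.
    """
    df = _as_frame(cohort)
    if variable not in df.columns:
        raise KeyError(f"variable {variable!r} not in cohort")
    data = df[["group", variable]].dropna()
    groups = sorted(data["group"].unique())
    samples = {g: data.loc[data["group"] == g, variable].to_numpy(float) for g in groups}
    for g, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations for {variable!r}")
    if len(groups) < 2:
        raise ValueError("need at least two groups")

    summaries = {
        g: {
            "n": int(len(v)),
            "q25": float(np.quantile(v, 0.25)),
            "median": float(np.median(v)),
            "q75": float(np.quantile(v, 0.75)),
        }
        for g, v in samples.items()
    }

    pooled = data[variable].to_numpy(float)
    n_total = len(pooled)
    degenerate = bool(np.all(pooled == pooled[0]))
    if degenerate:
        statistic, p_value = 0.0, 1.0
    else:
        statistic, p_value = stats.kruskal(*samples.values())

    ranks = stats.rankdata(pooled)
    data = data.assign(_rank=ranks)
    mean_rank = data.groupby("group")["_rank"].mean()
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    z_values, p_raw = [], []
    for a, b in pairs:
        var = base_var * (1.0 / len(samples[a]) + 1.0 / len(samples[b]))
        if var <= 0:
            z = 0.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / math.sqrt(var)
        z_values.append(float(z))
        p_raw.append(float(2.0 * stats.norm.sf(abs(z))))
    p_adj = _adjust(p_raw, adjustment)
    pairwise = [
        {"group_a": a, "group_b": b, "z": z, "p_raw": pr, "p_adjusted": pa}
        for (a, b), z, pr, pa in zip(pairs, z_values, p_raw, p_adj)
    ]
    return GroupTestResult(
        variable=variable,
        summaries=summaries,
        statistic=float(statistic),
        df=len(groups) - 1,
        p_value=float(p_value),
        pairwise=pairwise,
        degenerate=degenerate,
    )


def ols_multiple_regression(
    cohort: CohortFrame | pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
) -> RegressionResult:
    """OLS of *outcome* on *predictors* with intercept; two-sided t-tests."""
    df = _as_frame(cohort)
    predictors = list(predictors)
    cols = [outcome] + predictors
    data = df[cols].dropna()
    if len(data) < len(predictors) + 2:
        raise ValueError(
            f"{len(data)} complete cases for outcome {outcome!r}; "
            f"need at least {len(predictors) + 2}"
        )
    x = sm.add_constant(data[predictors].to_numpy(float), has_constant="add")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        collinear = _collinear_predictors(data[predictors])
        raise ValueError(f"rank-deficient design; collinear predictors: {collinear}")
    fit = sm.OLS(data[outcome].to_numpy(float), x).fit()
    terms = ["intercept"] + predictors
    coefficients = {
        term: {"coef": float(c), "se": float(s), "p": float(p)}
        for term, c, s, p in zip(terms, fit.params, fit.bse, fit.pvalues)
    }
    return RegressionResult(
        outcome=outcome,
        predictors=predictors,
        n=int(len(data)),
        r_squared=float(fit.rsquared),
        coefficients=coefficients,
    )


def _collinear_predictors(frame: pd.DataFrame) -> list[str]:
    """Name predictors involved in an exact linear dependence."""
    flagged = []
    x = frame.to_numpy(float)
    full_rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(x)), x]))
    for j, name in enumerate(frame.columns):
        reduced = np.column_stack([np.ones(len(x)), np.delete(x, j, axis=1)])
        if np.linalg.matrix_rank(reduced) == full_rank:
            flagged.append(name)
    return flagged or list(frame.columns)


def rank_ancova(
    cohort: CohortFrame | pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    reference_group: str = Group.NW.value,
    method: str = "rank_linear",
) -> AncovaResult:
    """Covariate-adjusted group comparison on rank-transformed data.

    ``"rank_linear"`` (Conover-Iman style) replaces outcome and covariates
    by pooled mid-ranks and fits ``rank(y) ~ group + rank(covariates)``;
    each non-reference group's dummy coefficient gives the adjusted
    contrast against the reference.  ``"quade"`` first regresses the
    outcome ranks on the covariate ranks alone and compares groups on the
    residuals.  With an empty covariate set both reduce to the unadjusted
    rank model.
    """
    df = _as_frame(cohort)
    covariates = list(covariates)
    data = df[["group", outcome] + covariates].dropna()
    counts = data.groupby("group").size()
    if (counts < 3).any() or len(counts) < 2:
        raise ValueError("need at least two groups with >= 3 complete subjects each")
    if reference_group not in counts.index:
        raise ValueError(f"reference group {reference_group!r} absent from cohort")
    for c in covariates:
        if data[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant")

    y = stats.rankdata(data[outcome].to_numpy(float))
    cov_ranks = np.column_stack(
        [stats.rankdata(data[c].to_numpy(float)) for c in covariates]
    ) if covariates else np.empty((len(data), 0))
    groups = sorted(g for g in counts.index if g != reference_group)
    dummies = np.column_stack(
        [(data["group"] == g).to_numpy(float) for g in groups]
    )

    if method == "rank_linear":
        x = sm.add_constant(np.column_stack([dummies, cov_ranks]), has_constant="add")
        fit = sm.OLS(y, x).fit()
        contrasts = {
            g: {
                "estimate": float(fit.params[1 + i]),
                "se": float(fit.bse[1 + i]),
                "p": float(fit.pvalues[1 + i]),
            }
            for i, g in enumerate(groups)
        }
    elif method == "quade":
        if covariates:
            stage1 = sm.OLS(y, sm.add_constant(cov_ranks, has_constant="add")).fit()
            resid = stage1.resid
        else:
            resid = y - y.mean()
        fit = sm.OLS(resid, sm.add_constant(dummies, has_constant="add")).fit()
        contrasts = {
            g: {
                "estimate": float(fit.params[1 + i]),
                "se": float(fit.bse[1 + i]),
                "p": float(fit.pvalues[1 + i]),
            }
            for i, g in enumerate(groups)
        }
    else:
        raise ValueError(f"unknown ANCOVA method {method!r}")
    return AncovaResult(
        outcome=outcome,
        covariates=covariates,
        method=method,
        reference_group=reference_group,
        n=int(len(data)),
        contrasts=contrasts,
    )


def spearman_with_linfit(
    cohort: CohortFrame | pd.DataFrame,
    x: str,
    y: str,
) -> AssociationResult:
    """Spearman rank correlation plus a descriptive least-squares line of y on x."""
    df = _as_frame(cohort)
    data = df[[x, y]].dropna()
    if len(data) < 4:
        raise ValueError(f"need at least 4 paired observations, got {len(data)}")
    xv = data[x].to_numpy(float)
    yv = data[y].to_numpy(float)
    constant = bool(np.all(xv == xv[0]) or np.all(yv == yv[0]))
    if constant:
        rho, rho_p = None, None
    else:
        rho_res = stats.spearmanr(xv, yv)
        rho, rho_p = float(rho_res.statistic), float(rho_res.pvalue)
    if np.all(xv == xv[0]):
        slope, intercept, slope_p = 0.0, float(np.mean(yv)), 1.0
    else:
        lin = stats.linregress(xv, yv)
        slope, intercept, slope_p = float(lin.slope), float(lin.intercept), float(lin.pvalue)
    return AssociationResult(
        x=x,
        y=y,
        n=int(len(data)),
        rho=rho,
        rho_p=rho_p,
        slope=slope,
        intercept=intercept,
        slope_p=slope_p,
        constant_input=constant,
    )


def risk_category_contingency(
    cohort: CohortFrame | pd.DataFrame,
    categories: Sequence[str] | None = None,
    exact: str = "auto",
    expected_min: float = 5.0,
    mc_permutations: int = 4999,
    mc_seed: int = 0,
) -> ContingencyResult:
    """Group-by-risk-category contingency test on a scored cohort.

    Expects a ``category`` column (as produced by
    :func:`certscore.ceramide_scoring.score_cohort`).  All four risk
    categories are kept as columns even when empty, so the degrees of
    freedom are always ``(groups - 1) × 3``.  Pearson chi-square by
    default; when any expected count falls below *expected_min* and
    ``exact="auto"`` (or always with ``exact="always"``) the p-value is
    replaced by a seeded Monte Carlo permutation estimate of the exact
    conditional test, the chi-square statistic being the discrepancy
    measure.
    """
    df = _as_frame(cohort)
    if "category" not in df.columns:
        raise KeyError("cohort has no 'category' column; score it first")
    if (df["group"] == Group.UNASSIGNED.value).any():
        raise ValueError("cohort contains UNASSIGNED subjects")
    categories = list(categories or _CATEGORY_ORDER)
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups for a contingency test")
    table = (
        pd.crosstab(df["group"], df["category"])
        .reindex(index=groups, columns=categories, fill_value=0)
        .to_numpy()
    )
    # empty category columns contribute nothing to the statistic but the
    # nominal degrees of freedom keep the full table dimension
    nonzero = table.sum(axis=0) > 0
    stat_table = table[:, nonzero]
    statistic = _pearson_stat(stat_table)
    df_full = (len(groups) - 1) * (len(categories) - 1)
    p_value = float(stats.chi2.sf(statistic, df_full))
    method = "pearson"
    expected = np.outer(stat_table.sum(axis=1), stat_table.sum(axis=0)) / stat_table.sum()
    min_expected = float(expected.min())
    if exact == "always" or (exact == "auto" and min_expected < expected_min):
        p_value = _monte_carlo_chi2_p(stat_table, mc_permutations, mc_seed)
        method = "monte_carlo_exact"
    return ContingencyResult(
        groups=[str(g) for g in groups],
        categories=[str(c) for c in categories],
        table=[[int(v) for v in row] for row in table],
        statistic=float(statistic),
        df=int(df_full),
        p_value=float(p_value),
        method=method,
        min_expected=min_expected,
    )


def _monte_carlo_chi2_p(table: np.ndarray, permutations: int, seed: int) -> float:
    """Permutation p-value for independence, conditioning on the margins."""
    rng = np.random.default_rng(seed)
    observed = _pearson_stat(table)
    row_labels = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    col_labels = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(col_labels)
        sim = np.zeros_like(table)
        np.add.at(sim, (row_labels, perm), 1)
        with np.errstate(invalid="ignore"):
            sim_stat = _pearson_stat(sim)
        if sim_stat >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (permutations + 1)


def _pearson_stat(table: np.ndarray) -> float:
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    mask = expected > 0
    return float(((table - expected)[mask] ** 2 / expected[mask]).sum())


# ---------------------------------------------------------------------------
# Derived columns and the end-to-end driver
# ---------------------------------------------------------------------------

def derive_analysis_frame(cohort: CohortFrame | pd.DataFrame) -> pd.DataFrame:
    """Add ratio, HOMA-IR, Framingham risk and vascular-age columns.

    Derived values are left missing (NaN) wherever their inputs are;
    out-of-range ages are extrapolated silently (the subject-level API
    warns instead).
    """
    df = _as_frame(cohort).copy()
    df = add_ratio_columns(df)
    homa = np.full(len(df), np.nan)
    ok = df["insulin"].notna() & df["glucose"].notna()
    homa[ok.to_numpy()] = [
        homa_ir(i, g) for i, g in zip(df.loc[ok, "insulin"], df.loc[ok, "glucose"])
    ]
    df["homa_ir"] = homa

    frs = np.full(len(df), np.nan)
    va = np.full(len(df), np.nan)
    needed = df[["age", "tc", "hdl", "sbp"]].notna().all(axis=1) & df["smoking"].notna()
    for i in np.flatnonzero(needed.to_numpy()):
        row = df.iloc[i]
        risk = frs_2008(
            row["sex"],
            row["age"],
            row["tc"],
            row["hdl"],
            row["sbp"],
            bool(row.get("treated_htn") or False),
            bool(row["smoking"]),
            bool(row.get("diabetes") or False),
            out_of_range="silent",
        )
        frs[i] = risk
        va[i] = vascular_age(risk, row["sex"]).years
    df["frs"] = frs
    df["va"] = va
    return df


def run_full_analysis(
    cohort: CohortFrame,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Execute the whole battery on one cohort, deterministically.

    Stages run in a fixed order: per-variable group tests, CERT1 scoring
    (reference fit on the pooled cohort) and its group test, the
    regression battery, the ANCOVA battery, CERT1-vs-risk associations,
    and the risk-category contingency test.  A stage that cannot run on
    the given cohort (for example group tests on a single-group cohort)
    records its error under ``stage_errors`` with the stage name and the
    remaining stages continue.
    """
    config = config or AnalysisConfig()
    report = AnalysisReport(provenance=cohort.provenance, config=config.to_dict())

    df = derive_analysis_frame(cohort)
    reference = fit_quartile_reference(df)
    report.quartile_reference = {
        name: [float(v) for v in triple] for name, triple in reference.cutoffs.items()
    }
    scored = score_cohort(df, reference)
    scored["cert1"] = scored["cert1"].astype(float)

    if config.run_group_tests:
        for variable in config.group_test_variables:
            if variable not in scored.columns or scored[variable].isna().all():
                continue
            try:
                res = kruskal_dunn(scored, variable, adjustment=config.adjustment)
                report.group_tests[variable] = res.to_dict()
            except (ValueError, KeyError) as exc:
                report.stage_errors[f"group_test:{variable}"] = str(exc)
        try:
            report.cert1_test = kruskal_dunn(
                scored, "cert1", adjustment=config.adjustment
            ).to_dict()
        except ValueError as exc:
            report.stage_errors["group_test:cert1"] = str(exc)

    if config.run_regressions:
        for outcome in config.regression_outcomes:
            try:
                res = ols_multiple_regression(
                    scored, outcome, config.regression_predictors
                )
                report.regressions[outcome] = res.to_dict()
            except (ValueError, KeyError) as exc:
                report.stage_errors[f"regression:{outcome}"] = str(exc)

    if config.run_ancova:
        for covariates in config.ancova_covariate_sets:
            try:
                res = rank_ancova(
                    scored,
                    "cert1",
                    covariates,
                    reference_group=config.reference_group,
                    method=config.ancova_method,
                )
                report.ancovas.append(res.to_dict())
            except (ValueError, KeyError) as exc:
                report.stage_errors[f"ancova:{'+'.join(covariates)}"] = str(exc)

    if config.run_associations:
        for x, y in (("cert1", "frs"), ("cert1", "va")):
            try:
                res = spearman_with_linfit(scored, x, y)
                report.associations[f"{x}~{y}"] = res.to_dict()
            except (ValueError, KeyError) as exc:
                report.stage_errors[f"association:{x}~{y}"] = str(exc)

    if config.run_contingency:
        try:
            res = risk_category_contingency(
                scored,
                exact=config.contingency_exact,
                expected_min=config.expected_min,
                mc_permutations=config.mc_permutations,
                mc_seed=config.mc_seed,
            )
            report.contingency = res.to_dict()
        except (ValueError, KeyError) as exc:
            report.stage_errors["contingency"] = str(exc)

    return report
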