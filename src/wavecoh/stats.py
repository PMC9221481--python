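"""Statistical comparison layer: paired tests, effect sizes, normality
routing and repeated-measures ANOVA.

Conventions follow the study design: two-tailed tests at alpha = 0.05;
Shapiro-Wilk on the paired differences decides between the paired t-test
(effect size Cohen's dz = |MD| / SD_MD, which equals |t| / sqrt(n)) and the
Wilcoxon signed-rank test (effect size r = |z| / sqrt(n)); one-way
repeated-measures ANOVA uses the Greenhouse-Geisser correction when
Mauchly's test rejects sphericity, with partial eta squared as effect size.
No multiple-testing correction is applied by default (the exploratory
design accepts the multiplicity), but Benjamini-Hochberg is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .exceptions import ConfigError, DegenerateDataError
from .pairing import ComparisonCell

ALPHA = 0.05


@dataclass
class StatResult:
    """One comparison's test statistic, p value and effect size."""

    test: str  # "paired_t" | "wilcoxon" | "rm_anova"
    statistic: float
    df: float | None
    p: float
    effect: str  # "dz" | "r" | "eta_sq"
    effect_value: float
    normality_route: str  # "parametric" | "nonparametric"
    df2: float | None = None  # error df (RM ANOVA)
    z: float | None = None  # normal-approximation z (Wilcoxon)


def coefficient_of_variation(values: np.ndarray) -> float | None:
    """SD / mean (sample SD); ``None`` when the mean vanishes."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean == 0:
        return None
    return float(values.std(ddof=1) / mean)


def p_from_t(t: float, df: float) -> float:
    """Two-tailed tail probability of the central t distribution."""
    if df < 1:
        raise ConfigError(f"df={df} < 1")
    return float(2.0 * sstats.t.sf(abs(t), df))


def cohens_dz_from_t(t: float, n: int) -> float:
    """dz = |t| / sqrt(n) for a paired design."""
    return abs(t) / np.sqrt(n)


def paired_t(values_a: np.ndarray, values_b: np.ndarray) -> StatResult:
    """Paired-samples t-test with Cohen's dz."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ConfigError("paired_t needs two equal-length samples, n >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("paired differences have zero variance")
    n = diff.size
    t = diff.mean() / (sd / np.sqrt(n))
    return StatResult(
        test="paired_t", statistic=float(t), df=float(n - 1), p=p_from_t(t, n - 1),
        effect="dz", effect_value=float(abs(diff.mean()) / sd),
        normality_route="parametric",
    )


def wilcoxon_signed_rank(values_a: np.ndarray, values_b: np.ndarray) -> StatResult:
    """Wilcoxon signed-rank test with effect size r = |z| / sqrt(n).

    Zero differences are dropped (the signed-rank convention); the p value
    is exact for small tie-free samples and otherwise comes from the
    tie-corrected normal approximation, whose z also yields r.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    diff = (a - b)[(a - b) != 0]
    if diff.size == 0:
        raise DegenerateDataError("all paired differences are zero")
    n = diff.size
    ranks = sstats.rankdata(np.abs(diff))
    w_plus = ranks[diff > 0].sum()
    mu = n * (n + 1) / 4.0
    # tie correction to the null variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_plus - mu) / np.sqrt(sigma2) if sigma2 > 0 else 0.0
    has_ties = np.unique(np.abs(diff)).size < n
    if n <= 25 and not has_ties:
        p = float(sstats.wilcoxon(diff, method="exact").pvalue)
    else:
        p = float(2.0 * sstats.norm.sf(abs(z)))
    return StatResult(
        test="wilcoxon", statistic=float(w_plus), df=None, p=p,
        effect="r", effect_value=float(abs(z) / np.sqrt(n)),
        normality_route="nonparametric", z=float(z),
    )


def normality_gate(values: np.ndarray, alpha: float = ALPHA) -> str:
    """Shapiro-Wilk routing: 'parametric' iff p > alpha (applied to the
    paired differences in comparisons)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ConfigError("normality check needs n >= 3")
    if values.std() == 0:
        raise DegenerateDataError("constant sample: normality undefined")
    p = sstats.shapiro(values).pvalue
    return "parametric" if p > alpha else "nonparametric"


def rm_anova_gg(matrix: np.ndarray) -> StatResult:
    """One-way repeated-measures ANOVA on a units x conditions matrix.

    Greenhouse-Geisser-corrected degrees of freedom and p value are used
    when Mauchly's sphericity test rejects; the effect size is partial eta
    squared SS_effect / (SS_effect + SS_error).
    """
    import pingouin as pg

    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 3:
        raise ConfigError("rm_anova_gg needs a units x conditions matrix, >=3 units, >=2 conditions")
    if np.isnan(m).any():
        raise DegenerateDataError("missing cells: repeated-measures design must be complete")
    n_units, k = m.shape
    if np.allclose(m, m[:, [0]]):
        # identical conditions: no effect by construction
        return StatResult(
            test="rm_anova", statistic=0.0, df=float(k - 1), df2=float((k - 1) * (n_units - 1)),
            p=1.0, effect="eta_sq", effect_value=0.0, normality_route="parametric",
        )
    long = pd.DataFrame(
        {
            "value": m.ravel(),
            "unit": np.repeat(np.arange(n_units), k),
            "condition": np.tile(np.arange(k), n_units),
        }
    )
    aov = pg.rm_anova(
        data=long, dv="value", within="condition", subject="unit",
        correction=True, detailed=True, effsize="np2",
    ).rename(columns={"p-unc": "p_unc", "p-GG-corr": "p_GG_corr"})
    row = aov.iloc[0]
    use_gg = False
    if k > 2:
        spher = pg.sphericity(long, dv="value", within="condition", subject="unit")
        use_gg = (not bool(spher.spher)) and "p_GG_corr" in aov.columns
    if use_gg:
        eps = float(row["eps"])
        df1, df2 = eps * (k - 1), eps * (k - 1) * (n_units - 1)
        p = float(row["p_GG_corr"])
    else:
        df1, df2 = float(k - 1), float((k - 1) * (n_units - 1))
        p = float(row["p_unc"])
    return StatResult(
        test="rm_anova", statistic=float(row["F"]), df=df1, df2=df2, p=p,
        effect="eta_sq", effect_value=float(row["np2"]),
        normality_route="parametric",
    )


# --------------------------------------------------------------------------
# real-vs-random comparison tables


def compare_cell_pair(real: ComparisonCell, random: ComparisonCell) -> StatResult:
    """Route one matched cell pair through the normality gate and the
    corresponding paired test."""
    if real.n != random.n:
        raise ConfigError(
            f"{real.region_combo}: unmatched unit counts {real.n} vs {random.n}"
        )
    diff = real.values - random.values
    route = normality_gate(diff)
    if route == "parametric":
        return paired_t(real.values, random.values)
    return wilcoxon_signed_rank(real.values, random.values)


def compare_real_vs_random(
    cells_real: list[ComparisonCell],
    cells_random: list[ComparisonCell],
    label_real: str = "AB_IMA",
    label_random: str = "rand",
) -> pd.DataFrame:
    """Per region combination and parameter, the full comparison row set:
    mode, n, M, SD, CV, t/z, df, p and effect size (two rows per comparison,
    mirroring the published table layout)."""
    index_real = {(c.region_combo, c.parameter): c for c in cells_real}
    index_random = {(c.region_combo, c.parameter): c for c in cells_random}
    missing = set(index_real).symmetric_difference(index_random)
    if missing:
        raise ConfigError(f"unmatched region combos: {sorted(missing)}")
    rows = []
    for key in sorted(index_real):
        real, random = index_real[key], index_random[key]
        try:
            res = compare_cell_pair(real, random)
            stat = res.z if res.test == "wilcoxon" else res.statistic
            stat_info = dict(
                t_or_z=round(float(stat), 3), df=res.df, p=round(res.p, 3),
                effect=res.effect, effect_value=round(res.effect_value, 3),
                test=res.test,
            )
        except DegenerateDataError:
            stat_info = dict(t_or_z=np.nan, df=np.nan, p=np.nan,
                             effect="", effect_value=np.nan, test="degenerate")
        for label, cell in ((label_real, real), (label_random, random)):
            rows.append(
                dict(
                    region_combo=cell.region_combo, parameter=cell.parameter,
                    mode=label, n=cell.n, M=round(cell.mean, 3), SD=round(cell.sd, 3),
                    CV=round(cell.cv, 3) if cell.cv is not None else np.nan,
                    **stat_info,
                )
            )
    return pd.DataFrame(rows)


def compare_tasks(
    units_task: pd.DataFrame, task_a: str = "HIMA", task_b: str = "PIMA"
) -> pd.DataFrame:
    """Paired comparison of two motor tasks from task-grouped aggregates.

    ``units_task`` is the output of ``aggregate(..., 'task_grouped')``; per
    region combination and parameter, the per-partner unit means under the
    two tasks form the paired samples.
    """
    rows = []
    for (combo, parameter), sub in units_task.groupby(["region_combo", "parameter"]):
        pivot = sub.pivot_table(index=["unit", "partner"], columns="task", values="value")
        if task_a not in pivot.columns or task_b not in pivot.columns:
            continue
        pivot = pivot.dropna(subset=[task_a, task_b])
        a = pivot[task_a].to_numpy()
        b = pivot[task_b].to_numpy()
        if a.size < 3:
            continue
        try:
            route = normality_gate(a - b)
            res = paired_t(a, b) if route == "parametric" else wilcoxon_signed_rank(a, b)
        except DegenerateDataError:
            continue
        stat = res.z if res.test == "wilcoxon" else res.statistic
        rows.append(
            dict(
                region_combo=combo, parameter=parameter, n=a.size,
                M_a=round(float(a.mean()), 3), M_b=round(float(b.mean()), 3),
                SD_a=round(float(a.std(ddof=1)), 3), SD_b=round(float(b.std(ddof=1)), 3),
                t_or_z=round(float(stat), 3), df=res.df, p=round(res.p, 3),
                effect=res.effect, effect_value=round(res.effect_value, 3), test=res.test,
            )
        )
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p values (off by default in reports; the design accepts
    multiplicity)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
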