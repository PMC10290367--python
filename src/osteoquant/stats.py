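"""Two-group comparison battery for preclinical two-arm studies.

Implements the evaluation statistics used for small two-arm animal
experiments: pooled-variance Student's t, Levene's variance test,
Lilliefors/Kolmogorov-Smirnov normality screening, exact Mann-Whitney U for
the small-sample regime (full enumeration with midranks, so ties are
handled correctly), Cohen's d from raw samples or published (mean, SD, n)
summaries, a parametric/nonparametric selection rule, and a group-table
report builder mirroring the familiar "mean +/- SD per arm, p, d" layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

__all__ = [
    "students_t",
    "cohens_d",
    "cohens_d_from_summary",
    "levene",
    "ks_normality",
    "mann_whitney_u",
    "choose_test",
    "group_table",
    "SubjectRecord",
    "GroupComparison",
]

ALPHA = 0.05


@dataclass(frozen=True)
class SubjectRecord:
    """One animal's measurements across the evaluation chain."""

    subject_id: str
    arm: str  # "Control" | "CEMF"
    model: str  # "3mm" | "17mm"
    callus_volume: float | None = None  # cm^3
    callus_density: float | None = None  # mg HA/cm^3
    vtr_op: float | None = None  # Nm^2/deg
    vtr_nonop: float | None = None
    normalized_vtr: float | None = None  # %
    rigidity_op: float | None = None  # Nm^2/deg
    rigidity_nonop: float | None = None
    normalized_rigidity: float | None = None  # %
    tissue_fractions: dict = field(default_factory=dict)  # class -> %


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    mean_sd_a: tuple[float, float]
    mean_sd_b: tuple[float, float]
    n_a: int
    n_b: int
    test_used: str  # "t" | "mann_whitney"
    statistic: float
    p_two_tailed: float
    cohens_d: float
    significant: bool
    alpha: float = ALPHA


def _as_arrays(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    return a, b


def students_t(sample_a, sample_b):
    """Pooled-variance two-sample t test.

    Returns ``(t, df, p_two_tailed)``. Degenerate zero-variance samples use
    the documented convention: equal means -> p = 1, unequal means -> p = 0.
    """
    a, b = _as_arrays(sample_a, sample_b)
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, df, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)


def cohens_d(sample_a, sample_b) -> float:
    """Standardized mean difference (b - a) over the pooled SD."""
    a, b = _as_arrays(sample_a, sample_b)
    return cohens_d_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def cohens_d_from_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> float:
    """Cohen's d from published (mean, SD, n) group summaries.

    ``d = (mean_b - mean_a) / s_pooled`` with
    ``s_pooled = sqrt(((n_a-1) sd_a^2 + (n_b-1) sd_b^2) / (n_a+n_b-2))``.
    Zero pooled SD yields NaN (undefined effect size).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("summaries need n >= 2 per group")
    s_pooled = math.sqrt(
        ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    )
    if s_pooled == 0:
        return float("nan")
    return (mean_b - mean_a) / s_pooled


def levene(sample_a, sample_b):
    """Levene's test for equality of variances (mean-centred variant)."""
    a, b = _as_arrays(sample_a, sample_b)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 0.0, 1.0
    w, p = sps.levene(a, b, center="mean")
    if not np.isfinite(w):
        return 0.0, 1.0
    return float(w), float(p)


def ks_normality(sample):
    """Kolmogorov-Smirnov normality screen with estimated parameters.

    Since the reference normal's mean/SD are taken from the sample, this is
    the Lilliefors variant; p-values come from the standard Lilliefors
    table. A constant sample is declared non-normal (p = 0) by convention.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("normality screening needs n >= 3")
    if np.ptp(x) == 0:
        return 1.0, 0.0
    d, p = _lilliefors(x, dist="norm", pvalmethod="table")
    return float(d), float(p)


@lru_cache(maxsize=32)
def _labelings(n_total: int, n_a: int) -> np.ndarray:
    """All C(n_total, n_a) index sets for group A, as an array."""
    return np.array(list(combinations(range(n_total), n_a)), dtype=np.intp)


def mann_whitney_u(sample_a, sample_b, exact_max_n: int = 14):
    """Mann-Whitney U with an exact small-sample path.

    For ``n_a + n_b <= exact_max_n`` the two-tailed p-value is computed by
    full enumeration of all C(n_a+n_b, n_a) group labelings of the pooled
    midranks (ties handled exactly); larger samples use the normal
    approximation with tie correction. Returns ``(U_a, p_two_tailed)``
    where ``U_a`` counts pairs won by sample A (midranks for ties).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    if n_a + n_b <= exact_max_n:
        mu = n_a * n_b / 2.0
        dev = abs(u_obs - mu)
        combos = _labelings(n_a + n_b, n_a)
        u_all = ranks[combos].sum(axis=1) - n_a * (n_a + 1) / 2.0
        hits = int(np.count_nonzero(np.abs(u_all - mu) >= dev - 1e-12))
        return u_obs, hits / combos.shape[0]
    _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(p)


def choose_test(sample_a, sample_b, normality_alpha: float = ALPHA):
    """Parametric/nonparametric selection rule.

    Student's t is used only when both samples pass the KS normality screen
    and Levene's homogeneity test at ``normality_alpha``; otherwise
    Mann-Whitney. Returns ``(choice, diagnostics)`` where diagnostics carry
    the triggering p-values.
    """
    _, p_norm_a = ks_normality(sample_a)
    _, p_norm_b = ks_normality(sample_b)
    _, p_lev = levene(sample_a, sample_b)
    diag = {"ks_p_a": p_norm_a, "ks_p_b": p_norm_b, "levene_p": p_lev}
    if p_norm_a > normality_alpha and p_norm_b > normality_alpha and p_lev > normality_alpha:
        return "t", diag
    return "mann_whitney", diag


# parameters the study battery analyses parametrically (morphometry, VTR,
# histomorphometry) vs nonparametrically (biomechanics, ordinal scores)
DEFAULT_TEST_OVERRIDES: dict[str, str] = {
    "callus_volume": "t",
    "callus_density": "t",
    "vtr_op": "t",
    "vtr_nonop": "t",
    "normalized_vtr": "t",
    "rigidity_op": "mann_whitney",
    "rigidity_nonop": "mann_whitney",
    "normalized_rigidity": "mann_whitney",
}


def group_table(
    records,
    parameters: list[str] | None = None,
    test_overrides: dict[str, str] | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Build a two-arm comparison table from subject records.

    ``records`` is a list of :class:`SubjectRecord` or a DataFrame with an
    ``arm`` column. Per parameter: mean +/- SD per arm, the chosen test
    (per override map, histomorphometry-style ``tissue_*`` columns default
    to t, everything unknown to the automatic selection rule), two-tailed
    p, Cohen's d, and the significance flag at ``alpha``. Subjects missing
    a parameter are excluded pairwise and counted in ``n_missing``.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for r in records:
            row = {k: v for k, v in r.__dict__.items() if k != "tissue_fractions"}
            for cls, pct in r.tissue_fractions.items():
                row[f"tissue_{cls}"] = pct
            rows.append(row)
        df = pd.DataFrame(rows)
    arms = sorted(df["arm"].unique())
    if len(arms) != 2:
        raise ValueError(f"need exactly 2 arms, got {arms}")
    arm_a, arm_b = arms
    if "Control" in arms:  # report Control first by convention
        arm_a = "Control"
        arm_b = next(a for a in arms if a != "Control")
    if parameters is None:
        skip = {"subject_id", "arm", "model", "seed"}
        parameters = [
            c for c in df.columns
            if c not in skip and pd.api.types.is_numeric_dtype(df[c])
        ]
    overrides = dict(DEFAULT_TEST_OVERRIDES)
    if test_overrides:
        overrides.update(test_overrides)

    out = []
    for param in parameters:
        if param not in df.columns:
            out.append({"parameter": param, "error": "missing column"})
            continue
        sub = df[["arm", param]].dropna()
        a = sub.loc[sub["arm"] == arm_a, param].to_numpy(dtype=float)
        b = sub.loc[sub["arm"] == arm_b, param].to_numpy(dtype=float)
        n_missing = len(df) - len(sub)
        if a.size < 2 or b.size < 2:
            out.append(
                {"parameter": param, "n_missing": n_missing,
                 "error": "insufficient paired data"}
            )
            continue
        rule = overrides.get(param)
        if rule is None and param.startswith("tissue_"):
            rule = "t"
        if rule is None or rule == "auto":
            rule, _diag = choose_test(a, b)
        if rule == "t":
            stat, _df_t, p = students_t(a, b)
        elif rule == "mann_whitney":
            stat, p = mann_whitney_u(a, b)
        else:
            raise ValueError(f"unknown test override {rule!r} for {param}")
        d = cohens_d(a, b)
        out.append(
            {
                "parameter": param,
                f"mean_{arm_a}": a.mean(),
                f"sd_{arm_a}": a.std(ddof=1),
                f"mean_{arm_b}": b.mean(),
                f"sd_{arm_b}": b.std(ddof=1),
                f"n_{arm_a}": a.size,
                f"n_{arm_b}": b.size,
                "n_missing": n_missing,
                "test_used": rule,
                "statistic": stat,
                "p_two_tailed": p,
                "cohens_d": d,
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(out)


def table_to_markdown(table: pd.DataFrame) -> str:
    """Render a group table in the two-arm report layout."""
    arms = [c.removeprefix("mean_") for c in table.columns if c.startswith("mean_")]
    lines = [
        f"| Parameter | {arms[0]} (mean ± SD) | {arms[1]} (mean ± SD) | test | p | d |",
        "|---|---|---|---|---|---|",
    ]
    for _, row in table.iterrows():
        if "error" in table.columns and isinstance(row.get("error"), str):
            lines.append(f"| {row['parameter']} | — | — | — | {row['error']} | — |")
            continue
        star = "*" if row["significant"] else ""
        lines.append(
            f"| {row['parameter']} "
            f"| {row[f'mean_{arms[0]}']:.2f} ± {row[f'sd_{arms[0]}']:.2f} "
            f"| {row[f'mean_{arms[1]}']:.2f} ± {row[f'sd_{arms[1]}']:.2f} "
            f"| {row['test_used']} | {row['p_two_tailed']:.3f}{star} "
            f"| {row['cohens_d']:.2f} |"
        )
    return "\n".join(lines)
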