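"""Inclusion/recurrence rules and the study's statistical comparisons.

Nonparametric two-group comparison (Mann-Whitney, exact by enumeration for
small samples), K-group comparison (Kruskal-Wallis with Dunn post hoc on
pooled midranks, Bonferroni-adjusted by default), Spearman rank correlation
(exact permutation p for n <= 8) and the ANOVA designs (one-way with Tukey
HSD, two-way factorial).  All tests are two-sided at alpha = 0.05 and take
patient-level summaries, not pooled ganglia, as their unit of analysis.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

RUTGEERTS_ORDER = {"i0": 0, "i1": 1, "i2": 2, "i3": 3, "i4": 4}
EXACT_ENUMERATION_LIMIT = 12  # pooled n at or below which Mann-Whitney enumerates


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float
    p_unadjusted: float
    p_adjusted: float


@dataclass
class TestReport:
    """Outcome of one statistical test, with post hoc comparisons if any."""

    test: str
    statistic: float
    p_value: float
    n_per_group: dict[str, int]
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    effects: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


# ---------------------------------------------------------------------------
# inclusion and recurrence rules
# ---------------------------------------------------------------------------


def apply_inclusion_and_recurrence(
    cohort: pd.DataFrame,
    min_ganglia: int = 10,
    control_label: str = "Ctrl",
) -> pd.DataFrame:
    """Apply the cohort inclusion rule and the postoperative recurrence
    definition to a per-ganglion table.

    Subjects with fewer than ``min_ganglia`` ganglia are excluded.  Each
    remaining non-control subject is labeled ``recurrent`` iff their
    Rutgeerts score is at least i1 **or** clinical recurrence at 18 months
    is recorded; subjects with neither assessment are labeled
    ``lost_to_followup`` (excluded from recurrence splits); control
    subjects are labeled ``control``.  The result carries a
    ``recurrence_status`` column.
    """
    required = {"patient_id", "ganglion_id"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    table = cohort.copy()
    counts = table.groupby("patient_id")["ganglion_id"].count()
    keep = counts[counts >= min_ganglia].index
    table = table[table["patient_id"].isin(keep)].copy()

    def _status(sub: pd.DataFrame) -> str:
        if "group" in sub.columns and (sub["group"] == control_label).all():
            return "control"
        rutgeerts = sub["rutgeerts"].dropna() if "rutgeerts" in sub.columns else pd.Series(dtype=object)
        clinical = (
            sub["clinical_recurrence_18mo"].dropna()
            if "clinical_recurrence_18mo" in sub.columns
            else pd.Series(dtype=object)
        )
        for score in rutgeerts.unique():
            if score not in RUTGEERTS_ORDER:
                raise ValueError(f"unknown Rutgeerts level: {score!r}")
        has_rutgeerts = len(rutgeerts) > 0
        has_clinical = len(clinical) > 0
        if not has_rutgeerts and not has_clinical:
            return "lost_to_followup"
        endoscopic = has_rutgeerts and max(RUTGEERTS_ORDER[s] for s in rutgeerts) >= 1
        clinical_rec = has_clinical and bool(clinical.astype(bool).any())
        return "recurrent" if (endoscopic or clinical_rec) else "non_recurrent"

    status = {pid: _status(sub) for pid, sub in table.groupby("patient_id")}
    table["recurrence_status"] = table["patient_id"].map(status)
    return table


def patient_level_means(
    cohort: pd.DataFrame, value: str = "n_tcells_apposed", group: str = "group"
) -> pd.DataFrame:
    """Per-patient mean of a per-ganglion quantity — the unit of analysis
    of the group comparisons (one dot per patient)."""
    return (
        cohort.groupby(["patient_id", group], sort=False)[value]
        .mean()
        .reset_index()
        .rename(columns={value: "mean_" + value})
    )


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    ra = ranks[: len(a)].sum()
    return ra - len(a) * (len(a) + 1) / 2.0


def _exact_mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided p by full enumeration of group assignments (handles ties
    via midranks); p = min(1, 2 * min(P(U <= u), P(U >= u)))."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    us = np.array(
        [
            sum(ranks[list(idx)]) - n_a * (n_a + 1) / 2.0
            for idx in itertools.combinations(range(len(pooled)), n_a)
        ]
    )
    eps = 1e-9
    cdf = float((us <= u_obs + eps).mean())
    sf = float((us >= u_obs - eps).mean())
    return min(1.0, 2.0 * min(cdf, sf))


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    names: tuple[str, str] = ("A", "B"),
) -> TestReport:
    """Two-sided Mann-Whitney U test.

    The U statistic is computed from midranks.  For pooled n at most 12 the
    two-sided p is exact by enumeration of all group assignments; larger
    samples use the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(a, b)
    if a.size + b.size <= EXACT_ENUMERATION_LIMIT:
        p = _exact_mannwhitney_p(a, b)
        method = "exact-enumeration"
    else:
        _, p = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(p)
        method = "normal-approximation"
    return TestReport(
        test=f"mann-whitney ({method})",
        statistic=float(u),
        p_value=p,
        n_per_group={names[0]: a.size, names[1]: b.size},
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------


def kruskal_dunn(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
    adjust: str = "bonferroni",
) -> TestReport:
    """Tie-corrected Kruskal-Wallis H with Dunn post hoc comparisons.

    Dunn z statistics are computed on pooled midranks with the tie
    correction; pairwise p-values are multiplicity-adjusted over all pairs
    (``bonferroni`` default, ``holm`` or ``none`` available).  All values
    identical across groups yields H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need at least two non-empty groups")
    if adjust not in {"bonferroni", "holm", "none"}:
        raise ValueError(f"unknown adjustment {adjust!r}")
    if names is None:
        names = [f"group{i + 1}" for i in range(len(arrays))]
    n_per_group = {str(nm): a.size for nm, a in zip(names, arrays)}
    pooled = np.concatenate(arrays)

    if np.ptp(pooled) == 0:
        pairwise = [
            PairwiseComparison(str(names[i]), str(names[j]), 0.0, 1.0, 1.0)
            for i, j in itertools.combinations(range(len(arrays)), 2)
        ]
        return TestReport(
            test="kruskal-wallis + dunn",
            statistic=0.0,
            p_value=1.0,
            n_per_group=n_per_group,
            pairwise=pairwise,
        )

    h, p = sps.kruskal(*arrays)

    ranks = sps.rankdata(pooled)
    sizes = [a.size for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(arrays))
    ]
    n_total = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    comparisons = []
    raw_ps = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        comparisons.append((str(names[i]), str(names[j]), z))
        raw_ps.append(min(1.0, p_raw))
    if adjust == "none":
        adjusted = list(raw_ps)
    else:
        adjusted = list(multipletests(raw_ps, method=adjust)[1])

    pairwise = [
        PairwiseComparison(a, b, z, p_raw, p_adj)
        for (a, b, z), p_raw, p_adj in zip(comparisons, raw_ps, adjusted)
    ]
    return TestReport(
        test="kruskal-wallis + dunn",
        statistic=float(h),
        p_value=float(p),
        n_per_group=n_per_group,
        pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def spearman(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 8
) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on midranks) with two-sided p.

    For n at most ``exact_limit`` the p-value is exact by enumeration of
    all permutations of one variable; larger n uses the t-approximation.
    Constant input is an error (rho undefined).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    rx = sps.rankdata(xa)
    ry = sps.rankdata(ya)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = xa.size
    if n <= exact_limit:
        rx_c = rx - rx.mean()
        denom = math.sqrt((rx_c**2).sum())
        count = 0
        total = 0
        abs_obs = abs(rho)
        for perm in itertools.permutations(ry):
            ry_p = np.asarray(perm)
            ry_c = ry_p - ry_p.mean()
            r = float((rx_c * ry_c).sum()) / (denom * math.sqrt((ry_c**2).sum()))
            total += 1
            if abs(r) >= abs_obs - 1e-12:
                count += 1
        p = count / total
    else:
        p = float(sps.spearmanr(xa, ya).pvalue)
    return rho, p


# ---------------------------------------------------------------------------
# ANOVA designs
# ---------------------------------------------------------------------------


def anova_oneway_tukey(
    groups: Sequence[Sequence[float]], names: Sequence[str] | None = None
) -> TestReport:
    """One-way ANOVA F with Tukey HSD adjusted pairwise comparisons."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need at least two non-empty groups")
    if names is None:
        names = [f"group{i + 1}" for i in range(len(arrays))]
    f, p = sps.f_oneway(*arrays)
    tukey = sps.tukey_hsd(*arrays)
    pairwise = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        p_adj = float(tukey.pvalue[i, j])
        pairwise.append(
            PairwiseComparison(
                str(names[i]),
                str(names[j]),
                float(tukey.statistic[i, j]),
                p_adj,  # Tukey HSD p is inherently family-adjusted
                p_adj,
            )
        )
    return TestReport(
        test="one-way anova + tukey",
        statistic=float(f),
        p_value=float(p),
        n_per_group={str(nm): a.size for nm, a in zip(names, arrays)},
        pairwise=pairwise,
    )


def anova_twoway(
    table: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    interaction: bool = True,
) -> TestReport:
    """Two-way factorial ANOVA (e.g. condition x size-bin).

    F statistics come from the standard sums-of-squares decomposition
    (type II, via OLS).  Every factor cell must be non-empty.  The reported
    ``statistic``/``p_value`` are those of ``factor_a``; the ``effects``
    mapping carries (F, p) for both factors and the interaction.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = table[[value, factor_a, factor_b]].copy()
    data.columns = ["y", "fa", "fb"]
    cells = data.groupby(["fa", "fb"], observed=True).size()
    expected = len(data["fa"].unique()) * len(data["fb"].unique())
    if len(cells) < expected or (cells == 0).any():
        raise ValueError("two-way design has an empty factor cell")
    formula = "y ~ C(fa) * C(fb)" if interaction else "y ~ C(fa) + C(fb)"
    model = smf.ols(formula, data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    effects = {}
    rename = {"C(fa)": factor_a, "C(fb)": factor_b, "C(fa):C(fb)": "interaction"}
    for row, label in rename.items():
        if row in anova.index:
            effects[label] = (float(anova.loc[row, "F"]), float(anova.loc[row, "PR(>F)"]))
    f_a, p_a = effects[factor_a]
    return TestReport(
        test="two-way anova",
        statistic=f_a,
        p_value=p_a,
        n_per_group={str(k): int(v) for k, v in cells.items()},
        effects=effects,
    )


def anova_suite(
    data, design: str = "oneway_tukey", **kwargs
) -> TestReport:
    """Dispatch to the ANOVA design used in a given figure panel."""
    if design == "oneway_tukey":
        return anova_oneway_tukey(data, **kwargs)
    if design == "twoway":
        return anova_twoway(data, **kwargs)
    raise ValueError(f"unknown design {design!r}")
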