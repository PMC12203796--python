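"""Group comparisons and the multiple-testing layer.

Two-sample comparisons are gated by Shapiro-Wilk normality: both groups
normal -> Welch t-test with mean +/- SD summaries; otherwise a rank test
with median + IQR summaries.  Primary-hypothesis p-values use Bonferroni
(family of 3); secondary p-values use Benjamini-Hochberg (family of 12).
Summary values are reported to two significant figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from ._utils import round_sig

__all__ = [
    "GroupComparison",
    "ProportionsTest",
    "DensityComparison",
    "normality_gate",
    "compare_groups",
    "bonferroni",
    "benjamini_hochberg",
    "wilson_proportions_test",
    "pv_density_analysis",
    "correct_comparisons",
]


def normality_gate(values, alpha: float = 0.05) -> str:
    """'normal' when Shapiro-Wilk p > alpha, else 'non-normal'."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("normality testing needs n >= 3")
    if np.ptp(x) == 0:
        warnings.warn("constant sample; treated as non-normal")
        return "non-normal"
    _, p = stats.shapiro(x)
    return "normal" if p > alpha else "non-normal"


def _summary(x: np.ndarray, gate: str, sig: int = 2) -> dict:
    if gate == "normal":
        return {
            "style": "mean±SD",
            "center": round_sig(float(np.mean(x)), sig),
            "spread": round_sig(float(np.std(x, ddof=1)), sig) if len(x) > 1 else 0.0,
        }
    q25, q75 = np.percentile(x, [25, 75])
    return {
        "style": "median+IQR",
        "center": round_sig(float(np.median(x)), sig),
        "spread": (round_sig(float(q25), sig), round_sig(float(q75), sig)),
    }


@dataclass
class GroupComparison:
    variable: str
    test: str  # 't' or 'wilcoxon'
    statistic: float
    p_value: float
    tier: str  # 'primary' or 'secondary'
    n_a: int
    n_b: int
    gate_a: str
    gate_b: str
    summary_a: dict
    summary_b: dict
    p_corrected: Optional[float] = None
    correction: Optional[str] = None


def compare_groups(
    a,
    b,
    variable: str = "",
    tier: str = "secondary",
    welch: bool = True,
    rank_test: str = "ranksum",
    gate_alpha: float = 0.05,
) -> GroupComparison:
    """Normality-gated two-sample comparison of independent groups.

    ``rank_test='signed-rank'`` is available for parity with the source
    analysis, but requires paired (equal-length) samples; the rank-sum
    (Mann-Whitney) test is the default for independent groups.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    gate_a = normality_gate(a, gate_alpha)
    gate_b = normality_gate(b, gate_alpha)
    if gate_a == "normal" and gate_b == "normal":
        res = stats.ttest_ind(a, b, equal_var=not welch)
        test, statistic, p = "t", float(res.statistic), float(res.pvalue)
    elif rank_test == "signed-rank":
        if len(a) != len(b):
            raise ValueError("signed-rank test requires paired samples")
        res = stats.wilcoxon(a, b)
        test, statistic, p = "wilcoxon", float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test, statistic, p = "wilcoxon", float(res.statistic), float(res.pvalue)
    return GroupComparison(
        variable=variable,
        test=test,
        statistic=statistic,
        p_value=p,
        tier=tier,
        n_a=len(a),
        n_b=len(b),
        gate_a=gate_a,
        gate_b=gate_b,
        summary_a=_summary(a, gate_a),
        summary_b=_summary(b, gate_b),
    )


def bonferroni(p_values, m: Optional[int] = None) -> np.ndarray:
    """min(1, p * m) elementwise; m defaults to the number of tests."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("family size m smaller than the number of p-values")
    return np.minimum(1.0, p * m)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjustment: p * m / rank with downward monotonisation."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class ProportionsTest:
    statistic: float
    p_value: float
    proportion_1: float
    proportion_2: float
    ci_1: tuple
    ci_2: tuple
    continuity_correction: bool


def wilson_proportions_test(k1: int, n1: int, k2: int, n2: int, correction: bool = True) -> ProportionsTest:
    """Two-sample chi-square test of equal proportions with Wilson score CIs.

    Continuity correction follows the R ``prop.test`` convention (the Yates
    term is capped at |O - E|, so identical proportions give chi2 = 0).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("group size must be >= 1")
        if not 0 <= k <= n:
            raise ValueError("count outside [0, n]")
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    E = row @ col / obs.sum()
    if np.any(E == 0):
        stat, p = 0.0, 1.0
    else:
        yates = min(0.5, abs(obs[0, 0] - E[0, 0])) if correction else 0.0
        stat = float((((np.abs(obs - E) - yates) ** 2) / E).sum())
        p = float(stats.chi2.sf(stat, df=1))
    ci1 = proportion_confint(k1, n1, method="wilson")
    ci2 = proportion_confint(k2, n2, method="wilson")
    return ProportionsTest(
        statistic=stat,
        p_value=p,
        proportion_1=k1 / n1,
        proportion_2=k2 / n2,
        ci_1=tuple(map(float, ci1)),
        ci_2=tuple(map(float, ci2)),
        continuity_correction=correction,
    )


@dataclass
class DensityComparison:
    group_means: dict
    group_sems: dict
    n_sections: dict
    f_statistic: float
    p_value: float
    percent_difference: float
    reference_group: str
    dropped_sections: int = 0
    animal_level: dict = field(default_factory=dict)


def pv_density_analysis(sections: pd.DataFrame, reference: str = "WT") -> DensityComparison:
    """Section-level one-way ANOVA of PV+ density by genotype.

    Density = count / area per section.  Percent difference is relative to
    the reference (WT) group mean.  An animal-level sensitivity analysis
    (per-animal mean densities, Welch t-test) is reported alongside as
    advisory, addressing section-level pseudoreplication.
    """
    req = {"animal", "genotype", "area_mm2", "count"}
    missing = req - set(sections.columns)
    if missing:
        raise ValueError(f"sections table missing columns: {sorted(missing)}")
    n0 = len(sections)
    sec = sections[sections["area_mm2"] > 0].copy()
    dropped = n0 - len(sec)
    if dropped:
        warnings.warn(f"rejected {dropped} zero/negative-area sections")
    sec["density"] = sec["count"] / sec["area_mm2"]
    genos = sorted(sec["genotype"].unique())
    if reference not in genos:
        reference = genos[0]
    groups = {g: sec.loc[sec["genotype"] == g, "density"].to_numpy() for g in genos}
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need at least 2 sections per genotype")
    f_stat, p = stats.f_oneway(*groups.values())
    means = {g: float(np.mean(v)) for g, v in groups.items()}
    sems = {g: float(stats.sem(v)) for g, v in groups.items()}
    others = [g for g in genos if g != reference]
    pct = float("nan")
    if others:
        pct = (means[others[0]] - means[reference]) / means[reference] * 100.0

    per_animal = sec.groupby(["genotype", "animal"])["density"].mean()
    animal_level = {}
    if len(genos) == 2 and all(len(per_animal[g]) >= 2 for g in genos):
        t_res = stats.ttest_ind(per_animal[others[0]], per_animal[reference], equal_var=False)
        animal_level = {
            "test": "welch-t (per-animal means, advisory)",
            "statistic": float(t_res.statistic),
            "p_value": float(t_res.pvalue),
            "n_animals": {g: int(len(per_animal[g])) for g in genos},
        }
    return DensityComparison(
        group_means=means,
        group_sems=sems,
        n_sections={g: int(len(v)) for g, v in groups.items()},
        f_statistic=float(f_stat),
        p_value=float(p),
        percent_difference=pct,
        reference_group=reference,
        dropped_sections=dropped,
        animal_level=animal_level,
    )


def correct_comparisons(
    comparisons: Sequence[GroupComparison],
    primary_m: int = 3,
) -> list:
    """Apply the tiered corrections in place: Bonferroni to the primary
    family (size ``primary_m``), Benjamini-Hochberg across the secondary
    family.  Returns the same list."""
    primary = [c for c in comparisons if c.tier == "primary"]
    secondary = [c for c in comparisons if c.tier == "secondary"]
    if primary:
        corr = bonferroni([c.p_value for c in primary], m=max(primary_m, len(primary)))
        for c, pc in zip(primary, corr):
            c.p_corrected, c.correction = float(pc), "bonferroni"
    if secondary:
        corr = benjamini_hochberg([c.p_value for c in secondary])
        for c, pc in zip(secondary, corr):
            c.p_corrected, c.correction = float(pc), "benjamini-hochberg"
    return list(comparisons)
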