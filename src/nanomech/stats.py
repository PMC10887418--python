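"""Two-group comparison with normality-driven test selection.

The decision procedure mirrors common biomedical practice: Shapiro–Wilk
normality on each group; if both pass, Levene homoscedasticity decides
between the pooled-variance Student t-test and Welch's t-test; if either
group fails normality, the nonparametric Wilcoxon rank-sum (Mann–Whitney)
test is used.  All tests are two-sided and unpaired.  Significance stars
follow the usual thresholds: * p < 0.05, ** p < 0.01, *** p < 0.001, ns
otherwise (strict inequalities, so p = 0.05 is ns).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import stats as sps

__all__ = ["TestDecision", "compare_groups", "star_label", "wilcoxon_rank_sum"]

#: group sizes up to which the rank-sum null is enumerated exactly
EXACT_RANKSUM_MAX_N = 12


def star_label(p_value: float) -> str:
    """Significance stars for a p-value (strict thresholds)."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError("p-value must lie in [0, 1]")
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


@dataclass
class TestDecision:
    """Full record of the test-selection procedure for one comparison."""

    shapiro_p_a: float
    shapiro_p_b: float
    levene_p: Optional[float]
    chosen_test: str  # student_pooled | welch | wilcoxon
    statistic: float
    p_value: float
    stars: str
    alpha: float = 0.05
    n_a: int = 0
    n_b: int = 0

    def summary(self) -> str:
        lev = "-" if self.levene_p is None else f"{self.levene_p:.4g}"
        return "\n".join(
            [
                "Two-group comparison",
                "=" * 40,
                f"n:             {self.n_a} vs {self.n_b}",
                f"Shapiro p:     {self.shapiro_p_a:.4g} / {self.shapiro_p_b:.4g}",
                f"Levene p:      {lev}",
                f"chosen test:   {self.chosen_test}",
                f"statistic:     {self.statistic:.4g}",
                f"p-value:       {self.p_value:.4g}",
                f"significance:  {self.stars}",
            ]
        )

    def to_dict(self) -> dict:
        return asdict(self)


def compare_groups(
    sample_a, sample_b, alpha: float = 0.05
) -> TestDecision:
    """Run the Shapiro -> Levene -> t / Wilcoxon selection procedure.

    Levene uses the median-centered (Brown–Forsythe) variant.  When Levene
    rejects under normality, Welch's t-test replaces the pooled Student
    test.  The Wilcoxon rank-sum branch enumerates the exact null for small
    tie-free samples and otherwise uses the normal approximation with
    continuity correction and midrank tie handling.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")

    # degenerate: no variance anywhere
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return TestDecision(
            shapiro_p_a=1.0,
            shapiro_p_b=1.0,
            levene_p=None,
            chosen_test="student_pooled",
            statistic=0.0,
            p_value=1.0,
            stars="ns",
            alpha=alpha,
            n_a=a.size,
            n_b=b.size,
        )

    shapiro_p_a = _shapiro_p(a)
    shapiro_p_b = _shapiro_p(b)

    levene_p: Optional[float] = None
    if shapiro_p_a > alpha and shapiro_p_b > alpha:
        levene_p = float(sps.levene(a, b, center="median").pvalue)
        if levene_p > alpha:
            chosen = "student_pooled"
            res = sps.ttest_ind(a, b, equal_var=True)
        else:
            chosen = "welch"
            res = sps.ttest_ind(a, b, equal_var=False)
        statistic, p_value = float(res.statistic), float(res.pvalue)
    else:
        chosen = "wilcoxon"
        statistic, p_value = wilcoxon_rank_sum(a, b)

    if np.isnan(p_value):  # e.g. both groups constant and equal variance zero
        statistic, p_value = 0.0, 1.0
    p_value = min(1.0, p_value)
    return TestDecision(
        shapiro_p_a=shapiro_p_a,
        shapiro_p_b=shapiro_p_b,
        levene_p=levene_p,
        chosen_test=chosen,
        statistic=statistic,
        p_value=p_value,
        stars=star_label(p_value),
        alpha=alpha,
        n_a=a.size,
        n_b=b.size,
    )


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) statistic and p-value.

    Exact null enumeration for small tie-free samples
    (min(n) <= EXACT_RANKSUM_MAX_N), otherwise the normal approximation
    with continuity correction; ties handled via midranks.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = (
        "exact"
        if (min(a.size, b.size) <= EXACT_RANKSUM_MAX_N and not has_ties)
        else "asymptotic"
    )
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro–Wilk p-value; a constant sample counts as non-normal (p=0)."""
    if np.ptp(x) == 0:
        return 0.0
    return float(sps.shapiro(x).pvalue)
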