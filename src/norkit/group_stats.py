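"""Per-metric two-group inference with assumption-driven test choice.

For each behavioral indicator the workflow is: Shapiro–Wilk normality on
each group; if either fails (p < alpha) use the Mann–Whitney U test;
otherwise Levene's test (mean-centred) for variance homogeneity, choosing
Student's t when variances are homogeneous and Welch's t otherwise.
P-values are corrected per indicator family (traditional: 6 tests; refined:
30) by Benjamini–Hochberg step-up, reported as q. Effect sizes: Cohen's d
(pooled SD, reference group first — an increase in the comparison group
gives negative d) on the t paths, rank correlation r = |Z|/sqrt(N) on the
Mann–Whitney path. Manual-vs-system concordance uses Pearson correlation
plus a paired t-test on the differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSample",
    "GroupComparison",
    "ConcordanceResult",
    "InsufficientSampleError",
    "choose_test",
    "compare_groups",
    "cohens_d",
    "rank_r",
    "bh_correct",
    "concordance",
    "compare_metric_tables",
    "concordance_table",
]


class InsufficientSampleError(ValueError):
    """Fewer subjects than the inference workflow requires."""


@dataclass(frozen=True)
class GroupSample:
    """One group's per-subject values for a single metric."""

    label: str
    values: tuple[float, ...]
    n_dropped_missing: int = 0  # subjects excluded for undefined metric values

    @staticmethod
    def from_values(label: str, values) -> "GroupSample":
        arr = np.asarray(list(values), dtype=float)
        keep = np.isfinite(arr)
        return GroupSample(
            label=label,
            values=tuple(arr[keep]),
            n_dropped_missing=int((~keep).sum()),
        )

    @property
    def n(self) -> int:
        return len(self.values)

    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    test: str  # student_t | welch_t | mann_whitney
    p: float
    q: float
    effect_size: float
    effect_type: str  # cohens_d | rank_r
    family: str = ""
    n_a: int = 0
    n_b: int = 0


@dataclass(frozen=True)
class ConcordanceResult:
    metric: str
    pearson_r: float
    pearson_p: float
    paired_t_p: float


def _check_n(a: GroupSample, b: GroupSample) -> None:
    if a.n < 3 or b.n < 3:
        raise InsufficientSampleError(
            f"need >= 3 subjects per group, got {a.label}: {a.n}, {b.label}: {b.n}"
        )


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro–Wilk p; a zero-variance sample is treated as non-normal (p=0)."""
    if np.ptp(x) == 0:
        return 0.0
    return float(stats.shapiro(x).pvalue)


def choose_test(a: GroupSample, b: GroupSample, alpha: float = 0.05) -> str:
    """Assumption-driven test selection (normality, then variance homogeneity)."""
    _check_n(a, b)
    xa, xb = a.array(), b.array()
    if _shapiro_p(xa) < alpha or _shapiro_p(xb) < alpha:
        return "mann_whitney"
    if float(stats.levene(xa, xb, center="mean").pvalue) < alpha:
        return "welch_t"
    return "student_t"


def cohens_d(a: GroupSample, b: GroupSample) -> float:
    """Pooled-SD standardized mean difference (mean_a − mean_b) / s_pooled.

    Group ``a`` is the reference: an increase in group ``b`` yields negative d.
    """
    xa, xb = a.array(), b.array()
    na, nb = len(xa), len(xb)
    sp2 = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("Cohen's d undefined: pooled standard deviation is zero")
    return float((xa.mean() - xb.mean()) / math.sqrt(sp2))


def _mw_z(xa: np.ndarray, xb: np.ndarray) -> float:
    """Tie-corrected normal-approximation Z for the Mann–Whitney U statistic."""
    na, nb = len(xa), len(xb)
    n = na + nb
    combined = np.concatenate([xa, xb])
    ranks = stats.rankdata(combined)
    u_a = ranks[:na].sum() - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # all values tied
        return 0.0
    return float((u_a - mu) / math.sqrt(sigma2))


def rank_r(a: GroupSample, b: GroupSample) -> float:
    """Rank-biserial-style effect size r = |Z| / sqrt(n_a + n_b), in [0, 1]."""
    if a.n + b.n < 4:
        raise InsufficientSampleError("rank r requires n_a + n_b >= 4")
    z = _mw_z(a.array(), b.array())
    return abs(z) / math.sqrt(a.n + b.n)


def compare_groups(
    a: GroupSample, b: GroupSample, alpha: float = 0.05
) -> tuple[float, float, str, str]:
    """Two-sided p and effect size from the assumption-chosen test.

    Returns ``(p, effect_size, effect_type, test)``. Degenerate case: both
    groups constant with equal means -> p = 1, effect 0 by convention.
    """
    _check_n(a, b)
    xa, xb = a.array(), b.array()
    if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] == xb[0]:
        return 1.0, 0.0, "cohens_d", "student_t"
    test = choose_test(a, b, alpha)
    if test == "mann_whitney":
        p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic").pvalue)
        return p, rank_r(a, b), "rank_r", test
    equal_var = test == "student_t"
    p = float(stats.ttest_ind(xa, xb, equal_var=equal_var).pvalue)
    return p, cohens_d(a, b), "cohens_d", test


def bh_correct(pvalues, family: str = "") -> list[float]:
    """Benjamini–Hochberg step-up q-values, returned in input order."""
    arr = np.asarray(list(pvalues), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise ValueError(f"p-values must lie in [0, 1] (family {family!r})")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return [float(v) for v in q]


def concordance(manual, system, metric: str = "") -> ConcordanceResult:
    """Manual-vs-system agreement: Pearson r (+p) and paired-t p on differences."""
    xm = np.asarray(list(manual), dtype=float)
    xs = np.asarray(list(system), dtype=float)
    if len(xm) != len(xs):
        raise ValueError("manual and system vectors must be paired (equal length)")
    if len(xm) < 3:
        raise InsufficientSampleError("concordance requires >= 3 paired subjects")
    if np.ptp(xm) == 0 or np.ptp(xs) == 0:
        raise ValueError("Pearson r undefined: zero variance in one vector")
    r, rp = stats.pearsonr(xm, xs)
    diffs = xm - xs
    if np.ptp(diffs) == 0 and diffs[0] == 0:
        tp = 1.0  # identical vectors: no paired difference at all
    else:
        tp = float(stats.ttest_rel(xm, xs).pvalue)
    return ConcordanceResult(metric=metric, pearson_r=float(r), pearson_p=float(rp), paired_t_p=tp)


def compare_metric_tables(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    families: dict[str, tuple[str, ...]],
    alpha: float = 0.05,
    label_a: str = "A",
    label_b: str = "B",
) -> list[GroupComparison]:
    """Full workflow over two per-subject metric tables (one row per animal).

    Every indicator must belong to exactly one family; BH correction is
    applied within each family. Subjects with a missing (undefined) value
    for an indicator are dropped from that indicator's test.
    """
    cols_a = [c for c in table_a.columns if c != "session_id"]
    cols_b = [c for c in table_b.columns if c != "session_id"]
    if set(cols_a) != set(cols_b):
        diff = set(cols_a) ^ set(cols_b)
        raise ValueError(f"metric tables disagree on indicators: {sorted(diff)}")
    mapped = {m for fam in families.values() for m in fam}
    missing = set(cols_a) - mapped
    if missing:
        raise ValueError(f"family map missing indicator(s): {sorted(missing)}")

    results: list[GroupComparison] = []
    for fam_label, members in families.items():
        partial = []
        for metric in members:
            if metric not in cols_a:
                continue
            ga = GroupSample.from_values(label_a, table_a[metric])
            gb = GroupSample.from_values(label_b, table_b[metric])
            try:
                p, eff, eff_type, test = compare_groups(ga, gb, alpha)
            except InsufficientSampleError:
                # e.g. a preference undefined for most animals: report, don't test
                partial.append((metric, "insufficient_n", math.nan, math.nan,
                                "none", ga.n, gb.n))
                continue
            partial.append((metric, test, p, eff, eff_type, ga.n, gb.n))
        testable = [row for row in partial if not math.isnan(row[2])]
        qs = iter(bh_correct([row[2] for row in testable], family=fam_label))
        for metric, test, p, eff, eff_type, na, nb in partial:
            q = next(qs) if not math.isnan(p) else math.nan
            results.append(
                GroupComparison(
                    metric=metric, test=test, p=p, q=q,
                    effect_size=eff, effect_type=eff_type,
                    family=fam_label, n_a=na, n_b=nb,
                )
            )
    return results


def concordance_table(manual: pd.DataFrame, system: pd.DataFrame) -> list[ConcordanceResult]:
    """Per-indicator concordance from long-format tables (subject, indicator, value)."""
    out = []
    for indicator in manual["indicator"].unique():
        m = manual[manual["indicator"] == indicator].set_index("subject")["value"]
        s = system[system["indicator"] == indicator].set_index("subject")["value"]
        subjects = m.index.intersection(s.index)
        out.append(concordance(m.loc[subjects], s.loc[subjects], metric=str(indicator)))
    return out
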