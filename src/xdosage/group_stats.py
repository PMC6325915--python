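"""Cross-group hypothesis tests on derived dosage statistics.

Three comparisons from the study design: Student's t-test of RXE between
sexes, Wilcoxon rank-sum (Mann-Whitney) tests for maternal-diet effects on
RXE, and one-way ANOVA on per-sample counts of expressed X-linked genes
across diet groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import ExpressionMatrix, GeneAnnotation, ValidationError
from .dosage_metrics import RelativeExpressionResult

EXACT_RANKSUM_MAX_N = 8


@dataclass(frozen=True)
class GroupComparison:
    test_name: str  # t_test | wilcoxon_rank_sum | one_way_anova
    groups: dict[str, tuple[float, ...]]
    statistic: float
    p_value: float


def _collect(results: Iterable[RelativeExpressionResult], attr: str) -> dict[str, list[float]]:
    groups: dict[str, list[float]] = {}
    for r in results:
        groups.setdefault(getattr(r, attr), []).append(r.rxe)
    return groups


def two_sample_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled-variance (classic Student) by
    default, Welch on request.  Identical constant groups give (0, 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("t-test needs >= 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U).

    Exact null enumeration when both groups have <= 8 observations and no
    ties are present; otherwise the normal approximation with tie correction
    and continuity correction.  Returns (U of the first group, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("rank-sum test needs >= 1 value per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # every observation tied: no evidence of a shift in either direction
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(a) <= EXACT_RANKSUM_MAX_N and len(b) <= EXACT_RANKSUM_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA F and p across >= 2 groups.

    When every group is constant with equal means (zero between- and
    within-group variance) the convention F = 0, p = 1 applies.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    for name, arr in zip(groups, arrays):
        if len(arr) < 2:
            raise ValidationError(f"ANOVA group {name!r} needs >= 2 values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# named comparisons of the study
# ---------------------------------------------------------------------------

def compare_rxe_by_sex(
    results: Iterable[RelativeExpressionResult],
    welch: bool = False,
) -> GroupComparison:
    """Student's t-test of per-sample RXE between females and males.

    Callers wanting a per-tissue comparison (the study's framing: "in the
    same tissue") filter the results before calling; `unknown` sex is ignored.
    """
    groups = {k: v for k, v in _collect(results, "sex").items() if k != "unknown"}
    if len(groups) != 2:
        raise ValidationError(
            f"sex comparison needs exactly two sex groups, got {sorted(groups)}"
        )
    (ga, gb) = groups.values()
    stat, p = two_sample_t(ga, gb, welch=welch)
    return GroupComparison(
        test_name="t_test",
        groups={k: tuple(v) for k, v in groups.items()},
        statistic=stat,
        p_value=p,
    )


def compare_rxe_by_diet(
    results: Iterable[RelativeExpressionResult],
    reference: str,
    alternative: str,
) -> GroupComparison:
    """Wilcoxon rank-sum test of per-sample RXE between two diet groups."""
    groups = _collect(results, "treatment")
    for level in (reference, alternative):
        if level not in groups or not groups[level]:
            raise ValidationError(f"treatment group {level!r} is empty")
    stat, p = rank_sum_test(groups[reference], groups[alternative])
    return GroupComparison(
        test_name="wilcoxon_rank_sum",
        groups={
            reference: tuple(groups[reference]),
            alternative: tuple(groups[alternative]),
        },
        statistic=stat,
        p_value=p,
    )


def anova_expressed_counts(
    counts: Mapping[str, Sequence[float]],
) -> GroupComparison:
    """One-way ANOVA on per-sample expressed X-linked gene counts across
    treatments (run per tissue by the pipeline)."""
    stat, p = one_way_anova(counts)
    return GroupComparison(
        test_name="one_way_anova",
        groups={k: tuple(float(x) for x in v) for k, v in counts.items()},
        statistic=stat,
        p_value=p,
    )


def count_expressed_x_genes(
    matrix: ExpressionMatrix,
    annotation: GeneAnnotation,
    threshold: float = 1.0,
) -> dict[str, int]:
    """Per-sample count of X-linked genes at or above the expression threshold."""
    x_genes = matrix.gene_ids.intersection(annotation.x_gene_ids)
    if len(annotation.x_gene_ids) == 0:
        raise ValidationError("annotation has no X-linked genes")
    sub = matrix.values.loc[x_genes]
    counts = (sub.to_numpy() >= threshold).sum(axis=0)
    return {str(s): int(c) for s, c in zip(matrix.sample_ids, counts)}


def expressed_x_count_table(
    matrix: ExpressionMatrix,
    annotation: GeneAnnotation,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Mean +/- SD of expressed X-linked gene counts per tissue x treatment,
    with the per-tissue ANOVA p-value across treatments."""
    counts = count_expressed_x_genes(matrix, annotation, threshold)
    meta = matrix.samples
    df = pd.DataFrame(
        {
            "tissue": meta["tissue"],
            "treatment": meta["treatment"],
            "count": [counts[s] for s in meta.index],
        }
    )
    rows = []
    for tissue, sub in df.groupby("tissue", sort=True):
        by_trt = {t: g["count"].to_list() for t, g in sub.groupby("treatment", sort=True)}
        p = np.nan
        if len(by_trt) >= 2 and all(len(v) >= 2 for v in by_trt.values()):
            _, p = one_way_anova(by_trt)
        for trt, vals in by_trt.items():
            rows.append(
                {
                    "tissue": tissue,
                    "treatment": trt,
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "anova_p": p,
                }
            )
    return pd.DataFrame(rows)


def comparisons_to_frame(
    comparisons: Iterable[tuple[str, GroupComparison]],
) -> pd.DataFrame:
    """Serialize named comparisons: test, groups, per-group n, statistic, p."""
    rows = []
    for name, comp in comparisons:
        rows.append(
            {
                "comparison": name,
                "test": comp.test_name,
                "groups": ",".join(comp.groups),
                "n_per_group": ",".join(str(len(v)) for v in comp.groups.values()),
                "statistic": comp.statistic,
                "p_value": comp.p_value,
            }
        )
    return pd.DataFrame(rows)
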