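"""Chromosome-relative expression statistics for X dosage-compensation analysis.

The central quantity is the relative X expression

    RXE = log2(x) - log2(a)

where ``x`` is the mean TPM over X-linked genes and ``a`` the mean TPM over
autosomal genes in a sample.  Under Ohno's hypothesis the single active X is
transcriptionally upregulated to balance diploid autosomes: RXE >= 0 indicates
complete compensatory upregulation, -1 < RXE < 0 partial upregulation, and
RXE <= -1 none (an X:A ratio of 0.5, the naive expectation for one active X
copy against two autosomal copies).

The per-autosome analogue

    RGE_i = log2(a_i) - log2(a_{n-i})

compares the mean TPM of autosome ``i`` against the mean over all other
autosomes (``n - i``), giving the band of normal chromosome-level activity
against which the X is judged.  The X never enters either side of an RGE.

Both statistics are computed within a gene subgroup: all genes, expressed
genes (TPM >= 1 by default), genes subject to X inactivation (expressed genes
minus PAR genes, which escape XCI), or dosage-sensitive genes (expressed in
every sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import (
    ExpressionMatrix,
    GeneAnnotation,
    ValidationError,
    X_CHROMOSOME,
)

logger = logging.getLogger("xdosage")

SUBGROUP_NAMES = ("ALL", "EXPRESSED", "XCI_SUBJECT", "DOSAGE_SENSITIVE")
RxeMethod = Literal["log_of_mean", "mean_of_log"]
#: how gene-set summaries are formed before the log2 ratio; the default takes
#: the log of the gene-set mean TPM
DEFAULT_RXE_METHOD: RxeMethod = "log_of_mean"


@dataclass(frozen=True)
class SubgroupSpec:
    """Which genes enter the X and autosomal means.

    ``ALL``: every annotated gene.  ``EXPRESSED``: genes at or above the
    expression threshold in the queried sample.  ``XCI_SUBJECT``: expressed
    genes minus PAR genes (which escape X inactivation).
    ``DOSAGE_SENSITIVE``: genes at or above the threshold in *every* sample
    of the matrix (ubiquitously expressed, largely housekeeping).
    """

    name: str = "ALL"
    expressed_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in SUBGROUP_NAMES:
            raise ValueError(f"subgroup must be one of {SUBGROUP_NAMES}, got {self.name!r}")
        if not self.expressed_threshold > 0:
            raise ValueError("expressed_threshold must be > 0")


@dataclass(frozen=True)
class ExpressionBand:
    """A TPM band used for reporting (e.g. lowly / highly expressed genes)."""

    name: str
    lower: float
    upper: float = float("inf")
    lower_inclusive: bool = True
    upper_inclusive: bool = False

    def contains(self, tpm: np.ndarray | float) -> np.ndarray | bool:
        lo = tpm >= self.lower if self.lower_inclusive else tpm > self.lower
        hi = tpm <= self.upper if self.upper_inclusive else tpm < self.upper
        return lo & hi


#: 1 <= TPM < 50
LOW_EXPRESSION_BAND = ExpressionBand("low", 1.0, 50.0)
#: TPM > 100
HIGH_EXPRESSION_BAND = ExpressionBand("high", 100.0, lower_inclusive=False)


@dataclass
class RelativeExpressionResult:
    """Per-sample RXE plus the per-autosome RGE profile and gene-set sizes."""

    sample_id: str
    rxe: float
    rge_by_chromosome: dict[str, float] = field(default_factory=dict)
    subgroup: SubgroupSpec = field(default_factory=SubgroupSpec)
    n_x_genes: int = 0
    n_autosomal_genes: int = 0
    tissue: str = "unknown"
    sex: str = "unknown"
    treatment: str = "unknown"


@dataclass(frozen=True)
class CompensationCall:
    """Dosage-compensation classification of one RXE value."""

    label: str  # complete | partial | none
    rxe: float


@dataclass(frozen=True)
class BoxplotSummary:
    """Tukey-style boxplot statistics: hinges at the 25th/75th percentiles,
    whiskers at the most extreme data points within 1.5 x IQR of the hinges,
    labeled outliers beyond the whiskers."""

    lower_hinge: float
    upper_hinge: float
    iqr: float
    lower_whisker: float
    upper_whisker: float
    outliers: tuple[tuple[str, float], ...]


# ---------------------------------------------------------------------------
# gene subgroup construction
# ---------------------------------------------------------------------------

def select_subgroup(
    matrix: ExpressionMatrix,
    annotation: GeneAnnotation,
    spec: SubgroupSpec,
    sample_id: str,
) -> pd.Index:
    """Gene ids entering the dosage statistics for one sample under a subgroup.

    Membership is evaluated on the intersection of matrix genes and annotated
    genes.  EXPRESSED is per-sample (a gene may pass the threshold in one
    sample and not another); DOSAGE_SENSITIVE requires the threshold in every
    sample of the matrix.
    """
    if sample_id not in matrix.sample_ids:
        raise KeyError(f"sample {sample_id!r} not in matrix")
    genes = matrix.gene_ids.intersection(annotation.gene_ids)
    if spec.name == "ALL":
        selected = genes
    elif spec.name == "EXPRESSED":
        col = matrix.values.loc[genes, sample_id]
        selected = genes[col.to_numpy() >= spec.expressed_threshold]
    elif spec.name == "XCI_SUBJECT":
        col = matrix.values.loc[genes, sample_id]
        expressed = genes[col.to_numpy() >= spec.expressed_threshold]
        selected = expressed.difference(annotation.par_gene_ids, sort=False)
    elif spec.name == "DOSAGE_SENSITIVE":
        sub = matrix.values.loc[genes]
        selected = genes[(sub.to_numpy() >= spec.expressed_threshold).all(axis=1)]
    else:  # pragma: no cover - guarded by SubgroupSpec
        raise ValueError(spec.name)
    if len(selected) == 0:
        raise ValidationError(
            f"subgroup {spec.name} is empty for sample {sample_id!r}; "
            "gene-set mean undefined"
        )
    return selected


# ---------------------------------------------------------------------------
# RXE / RGE
# ---------------------------------------------------------------------------

def _set_summary(values: np.ndarray, method: RxeMethod) -> float:
    """log2 summary of a gene set: log2(mean TPM), or mean of log2(TPM)."""
    if method == "log_of_mean":
        m = float(values.mean())
        return np.log2(m) if m > 0 else -np.inf
    with np.errstate(divide="ignore"):
        return float(np.mean(np.log2(values)))


def compute_rxe(
    matrix: ExpressionMatrix,
    annotation: GeneAnnotation,
    spec: SubgroupSpec,
    sample_id: str,
    method: RxeMethod = DEFAULT_RXE_METHOD,
) -> RelativeExpressionResult:
    """Relative X expression for one sample within a gene subgroup.

    RXE = log2(mean TPM over X-linked subgroup genes) - log2(mean TPM over
    autosomal subgroup genes).  Scale-invariant: rescaling a sample's TPM
    column leaves RXE unchanged.
    """
    genes = select_subgroup(matrix, annotation, spec, sample_id)
    x_genes = genes.intersection(annotation.x_gene_ids, sort=False)
    a_genes = genes.intersection(annotation.autosomal_gene_ids, sort=False)
    if len(x_genes) == 0:
        raise ValidationError(
            f"subgroup {spec.name}, sample {sample_id!r}: no X-linked genes"
        )
    if len(a_genes) == 0:
        raise ValidationError(
            f"subgroup {spec.name}, sample {sample_id!r}: no autosomal genes"
        )
    col = matrix.values[sample_id]
    x_vals = col.loc[x_genes].to_numpy()
    a_vals = col.loc[a_genes].to_numpy()
    if method == "log_of_mean":
        if x_vals.mean() <= 0:
            raise ValidationError(
                f"sample {sample_id!r}: X-linked gene-set mean is zero; RXE undefined"
            )
        if a_vals.mean() <= 0:
            raise ValidationError(
                f"sample {sample_id!r}: autosomal gene-set mean is zero; RXE undefined"
            )
    rxe = _set_summary(x_vals, method) - _set_summary(a_vals, method)
    meta = matrix.samples.loc[sample_id]
    return RelativeExpressionResult(
        sample_id=sample_id,
        rxe=float(rxe),
        subgroup=spec,
        n_x_genes=len(x_genes),
        n_autosomal_genes=len(a_genes),
        tissue=meta["tissue"],
        sex=meta["sex"],
        treatment=meta["treatment"],
    )


def compute_rge(
    matrix: ExpressionMatrix,
    annotation: GeneAnnotation,
    spec: SubgroupSpec,
    sample_id: str,
    method: RxeMethod = DEFAULT_RXE_METHOD,
) -> dict[str, float]:
    """Relative expression of each autosome against all other autosomes.

    For autosome i: RGE_i = log2(mean TPM of subgroup genes on i) - log2(mean
    TPM of subgroup genes on all other autosomes).  The X chromosome (and Y/MT)
    never enters either side.  Autosomes with an empty subgroup gene set are
    omitted with a warning.
    """
    genes = select_subgroup(matrix, annotation, spec, sample_id)
    chrom = annotation.frame["chromosome"].loc[
        genes.intersection(annotation.autosomal_gene_ids, sort=False)
    ]
    autosomes = [c for c in annotation.autosomes]
    if sum(1 for c in autosomes if (chrom == c).any()) < 2:
        raise ValidationError(
            f"RGE requires >=2 autosomes with subgroup genes (sample {sample_id!r})"
        )
    col = matrix.values[sample_id]
    rge: dict[str, float] = {}
    for c in autosomes:
        on_c = chrom.index[chrom == c]
        if len(on_c) == 0:
            logger.warning(
                "autosome %s has no %s genes in sample %s; RGE omitted",
                c, spec.name, sample_id,
            )
            continue
        rest = chrom.index[chrom != c]
        rge[c] = float(
            _set_summary(col.loc[on_c].to_numpy(), method)
            - _set_summary(col.loc[rest].to_numpy(), method)
        )
    return rge


def relative_expression(
    matrix: ExpressionMatrix,
    annotation: GeneAnnotation,
    spec: SubgroupSpec | None = None,
    method: RxeMethod = DEFAULT_RXE_METHOD,
    with_rge: bool = True,
) -> list[RelativeExpressionResult]:
    """RXE (and optionally the RGE profile) for every sample of a matrix."""
    spec = spec or SubgroupSpec()
    results = []
    for sample_id in matrix.sample_ids:
        res = compute_rxe(matrix, annotation, spec, sample_id, method)
        if with_rge:
            res.rge_by_chromosome = compute_rge(matrix, annotation, spec, sample_id, method)
        results.append(res)
    return results


def classify_compensation(rxe: float) -> CompensationCall:
    """Classify an RXE value: complete (>= 0), partial (-1 < RXE < 0) or no
    (<= -1) X-chromosome upregulation.  The labels partition the real line."""
    if not np.isfinite(rxe):
        raise ValidationError(f"cannot classify non-finite RXE {rxe!r}")
    if rxe >= 0:
        label = "complete"
    elif rxe > -1:
        label = "partial"
    else:
        label = "none"
    return CompensationCall(label=label, rxe=float(rxe))


# ---------------------------------------------------------------------------
# summaries across samples / chromosomes
# ---------------------------------------------------------------------------

def summarize_group(values: Iterable[tuple[str, float]]) -> BoxplotSummary:
    """Tukey boxplot summary of labeled values.

    Hinges are the 25th/75th percentiles by linear interpolation; whiskers
    extend to the most extreme data points within 1.5 x IQR of the hinges;
    values beyond the whiskers are returned as labeled outliers.
    """
    pairs = list(values)
    if len(pairs) < 2:
        raise ValidationError("boxplot summary needs >= 2 values")
    labels = [p[0] for p in pairs]
    vals = np.asarray([p[1] for p in pairs], dtype=float)
    q1, q3 = np.percentile(vals, [25, 75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    lower_whisker, upper_whisker = float(inside.min()), float(inside.max())
    outliers = tuple(
        (lab, float(v))
        for lab, v in zip(labels, vals)
        if v < lower_whisker or v > upper_whisker
    )
    return BoxplotSummary(
        lower_hinge=float(q1),
        upper_hinge=float(q3),
        iqr=float(iqr),
        lower_whisker=lower_whisker,
        upper_whisker=upper_whisker,
        outliers=outliers,
    )


def tissue_mean_rxe(
    results: Iterable[RelativeExpressionResult],
    grouping: str = "tissue",
) -> dict[str, float]:
    """Arithmetic mean of per-sample RXE within each tissue (or treatment)
    group — the red-dot summaries of the RXE boxplots."""
    if grouping not in ("tissue", "treatment"):
        raise ValueError("grouping must be 'tissue' or 'treatment'")
    groups: dict[str, list[float]] = {}
    for res in results:
        key = getattr(res, grouping)
        groups.setdefault(key, []).append(res.rxe)
    return {k: float(np.mean(v)) for k, v in groups.items()}


def activity_gene_count_correlation(
    rge_by_chromosome: Mapping[str, float],
    expressed_counts: Mapping[str, int],
) -> float:
    """Pearson correlation between chromosome expression activity (mean RGE)
    and the number of expressed genes per chromosome.

    In sheep, gene-dense autosomes tend to be transcriptionally "quieter"
    per gene, giving a strong negative correlation.
    """
    if set(rge_by_chromosome) != set(expressed_counts):
        raise ValidationError("chromosome keys differ between RGE and count mappings")
    chroms = sorted(rge_by_chromosome)
    if len(chroms) < 3:
        raise ValidationError("correlation needs >= 3 chromosomes")
    x = np.asarray([rge_by_chromosome[c] for c in chroms], dtype=float)
    y = np.asarray([expressed_counts[c] for c in chroms], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def results_to_frame(results: Iterable[RelativeExpressionResult]) -> pd.DataFrame:
    """Tabulate per-sample results: one row per sample with RXE, its
    compensation class, gene-set sizes and sample metadata."""
    rows = []
    for r in results:
        rows.append(
            {
                "sample_id": r.sample_id,
                "subgroup": r.subgroup.name,
                "tissue": r.tissue,
                "sex": r.sex,
                "treatment": r.treatment,
                "rxe": r.rxe,
                "compensation": classify_compensation(r.rxe).label,
                "n_x_genes": r.n_x_genes,
                "n_autosomal_genes": r.n_autosomal_genes,
            }
        )
    return pd.DataFrame(rows)


def rge_to_frame(results: Iterable[RelativeExpressionResult]) -> pd.DataFrame:
    """Long-format RGE table: one row per (sample, autosome)."""
    rows = []
    for r in results:
        for chrom, value in r.rge_by_chromosome.items():
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "subgroup": r.subgroup.name,
                    "tissue": r.tissue,
                    "chromosome": chrom,
                    "rge": value,
                }
            )
    return pd.DataFrame(rows)
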