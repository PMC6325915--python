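"""Bootstrap differential expression between treatment groups.

Replicate samples are resampled with replacement within each group
(stratified bootstrap) and the between-group fold change of gene-set means is
recomputed on each of the (default 200) bootstrap replicates.  The empirical
two-sided p-value is twice the smaller tail of the bootstrap fold-change
distribution around 1, clipped below at 1/n_replicates so a finite resample
never reports zero.  A gene is called differentially expressed when
|log2 fold change| exceeds 1 and p <= 0.05 (both configurable).

The resampling unit is the sample (matrix column): the pipeline ingests
gene-level TPM, so read-level resampling is out of reach by design.  Fold
changes are ratios of observed group means; ratios against a zero mean follow
the conventions 0/0 -> 1, x/0 -> +inf, 0/x -> 0, and the reported log2 fold
change may be +/-infinity when one group is entirely silent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation_io import ExpressionMatrix, GeneAnnotation, ValidationError

logger = logging.getLogger("xdosage")


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap-DE parameters: number of stratified resamples, the log2
    fold-change call threshold, the significance level, and the seed."""

    n_replicates: int = 200
    fc_threshold_log2: float = 1.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class DEGRecord:
    """Per-gene bootstrap DE outcome.  ``log2_fc`` is the log2 ratio of
    observed group means (alternative over reference) and may be +/-inf when
    exactly one group mean is zero."""

    gene_id: str
    mean_control_tpm: float
    mean_treated_tpm: float
    log2_fc: float
    p_value: float
    significant: bool


def _fold_change(alt: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Elementwise alt/ref with 0/0 -> 1, x/0 -> +inf, 0/x -> 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = alt / ref
    fc = np.where((ref == 0) & (alt == 0), 1.0, fc)
    fc = np.where((ref == 0) & (alt > 0), np.inf, fc)
    return fc


def _log2_ratio(alt: float, ref: float) -> float:
    if ref == 0 and alt == 0:
        return 0.0
    if ref == 0:
        return math.inf
    if alt == 0:
        return -math.inf
    return math.log2(alt / ref)


def bootstrap_de(
    matrix: ExpressionMatrix,
    group_column: str,
    reference_level: str,
    alternative_level: str,
    config: BootstrapConfig | None = None,
    bh_adjust: bool = False,
) -> list[DEGRecord]:
    """Call differential expression between two levels of a metadata column.

    For every gene the observed group means and their log2 ratio are computed;
    then ``config.n_replicates`` stratified bootstrap resamples of the sample
    columns yield an empirical fold-change distribution, and the two-sided
    p-value is ``2 * min(P(FC_b >= 1), P(FC_b <= 1))`` clipped to
    ``[1/n_replicates, 1]``.  Significance requires
    ``|log2_fc| > fc_threshold_log2`` and ``p <= alpha``.

    Each group's resampling stream is seeded by the group's *label* (levels in
    sorted order), so swapping reference and alternative leaves every p-value
    unchanged and exactly negates every log2 fold change.

    ``bh_adjust`` applies Benjamini-Hochberg across genes before flagging
    significance; it is off by default (raw p-values are the study convention).
    """
    config = config or BootstrapConfig()
    if group_column not in matrix.samples.columns:
        raise ValidationError(f"metadata has no column {group_column!r}")
    labels = matrix.samples[group_column]
    ref_ids = list(labels.index[labels == reference_level])
    alt_ids = list(labels.index[labels == alternative_level])
    if not ref_ids:
        raise ValidationError(f"group {reference_level!r} has zero samples")
    if not alt_ids:
        raise ValidationError(f"group {alternative_level!r} has zero samples")

    values = matrix.values
    ref = values[ref_ids].to_numpy()
    alt = values[alt_ids].to_numpy()
    obs_ref = ref.mean(axis=1)
    obs_alt = alt.mean(axis=1)

    # one child stream per group, assigned by sorted level name so that the
    # resampling of a group does not depend on which side it is called from
    children = np.random.SeedSequence(config.seed).spawn(2)
    order = sorted([reference_level, alternative_level])
    streams = dict(zip(order, children))
    B = config.n_replicates

    def _boot_means(data: np.ndarray, level: str) -> np.ndarray:
        """(genes x B) matrix of resampled group means via a weight matrix."""
        rng = np.random.default_rng(streams[level])
        n = data.shape[1]
        idx = rng.integers(0, n, size=(B, n))
        weights = np.zeros((n, B))
        for b in range(B):
            np.add.at(weights[:, b], idx[b], 1.0 / n)
        return data @ weights

    ref_means = _boot_means(ref, reference_level)
    alt_means = _boot_means(alt, alternative_level)
    fc = _fold_change(alt_means, ref_means)
    prop_ge = (fc >= 1.0).mean(axis=1)
    prop_le = (fc <= 1.0).mean(axis=1)
    p = np.clip(2.0 * np.minimum(prop_ge, prop_le), 1.0 / B, 1.0)

    log2fc = np.array(
        [_log2_ratio(a, r) for a, r in zip(obs_alt, obs_ref)], dtype=float
    )
    p_for_calls = p
    if bh_adjust:
        from scipy.stats import false_discovery_control

        p_for_calls = false_discovery_control(p, method="bh")
    significant = (np.abs(log2fc) > config.fc_threshold_log2) & (
        p_for_calls <= config.alpha
    )
    return [
        DEGRecord(
            gene_id=str(g),
            mean_control_tpm=float(obs_ref[i]),
            mean_treated_tpm=float(obs_alt[i]),
            log2_fc=float(log2fc[i]),
            p_value=float(p_for_calls[i]),
            significant=bool(significant[i]),
        )
        for i, g in enumerate(values.index)
    ]


def filter_x_linked(
    degs: Iterable[DEGRecord], annotation: GeneAnnotation
) -> list[DEGRecord]:
    """Subset DE records to X-linked genes, preserving order."""
    chrom = annotation.frame["chromosome"]
    out = []
    for rec in degs:
        if rec.gene_id not in chrom.index:
            raise ValidationError(f"gene {rec.gene_id!r} missing from annotation")
        if chrom[rec.gene_id] == "X":
            out.append(rec)
    return out


def degs_to_frame(
    degs: Iterable[DEGRecord],
    comparison: str = "",
    tissue: str = "",
) -> pd.DataFrame:
    """DE records as a table with literal ``inf``/``-inf`` fold changes."""
    rows = [
        {
            "comparison": comparison,
            "tissue": tissue,
            "gene": r.gene_id,
            "expression_controls_tpm": r.mean_control_tpm,
            "expression_treated_tpm": r.mean_treated_tpm,
            "log2_fc": "inf" if r.log2_fc == math.inf
            else "-inf" if r.log2_fc == -math.inf
            else r.log2_fc,
            "p_value": r.p_value,
            "significant": r.significant,
        }
        for r in degs
    ]
    return pd.DataFrame(rows)


def write_deg_table(
    degs: Sequence[DEGRecord],
    path: str | Path,
    comparison: str = "",
    tissue: str = "",
) -> None:
    degs_to_frame(degs, comparison=comparison, tissue=tissue).to_csv(
        path, sep="\t", index=False
    )
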