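"""Synthetic expression datasets with known dosage-compensation structure.

The generator emulates the statistical shape of a sheep fetal RNA-seq study:
26 autosome pairs plus X (~20,519 genes, 1,228 X-linked of which 20 are
pseudoautosomal), tissues {brain, kidney, lung} under maternal-diet groups
Con (n = 7), Over (n = 4) and Res (n = 4), log-normal per-gene baseline
expression with multiplicative per-sample noise, and planted diet-responsive
differentially expressed genes.

The dosage model is analytic by construction: each autosomal gene is
transcribed from two copies, each non-PAR X-linked gene from a single active
copy whose per-copy rate is multiplied by the upregulation factor ``u``, and
each PAR gene from two copies (PAR genes escape X inactivation).  Ignoring the
small PAR contribution, the expected relative X expression is therefore

    RXE_true = log2(u) - 1

(u = 1: no compensatory upregulation, RXE = -1; u = 2: complete compensation,
RXE = 0).  This is the ground truth that parameter-recovery tests estimate.

TPM renormalization (columns to one million) rescales every gene in a sample
by the same factor and so never changes RXE.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation_io import (
    ExpressionMatrix,
    GeneAnnotation,
    GeneRecord,
    TPM_TOTAL,
    ValidationError,
    write_gene_map,
)

logger = logging.getLogger("xdosage")

# approximate sheep (Oar) chromosome sizes in Mb, used only as weights for
# apportioning autosomal genes; chromosomes 1-3 are the large fused elements
_SHEEP_CHROM_MB = {
    "1": 276, "2": 249, "3": 224, "4": 119, "5": 108, "6": 117, "7": 100,
    "8": 91, "9": 95, "10": 86, "11": 62, "12": 79, "13": 83, "14": 63,
    "15": 80, "16": 71, "17": 72, "18": 68, "19": 61, "20": 51, "21": 50,
    "22": 51, "23": 62, "24": 42, "25": 45, "26": 44,
}
_N_AUTOSOMAL_GENES = 19_291
_N_X_GENES = 1_228
_N_PAR_GENES = 20


def sheep_gene_counts() -> dict[str, int]:
    """Genes per chromosome emulating the sheep annotation: 19,291 autosomal
    genes apportioned by chromosome size over 26 autosomes, plus 1,228 on X
    (20,519 total)."""
    weights = np.array([_SHEEP_CHROM_MB[str(i)] for i in range(1, 27)], dtype=float)
    raw = weights / weights.sum() * _N_AUTOSOMAL_GENES
    counts = np.floor(raw).astype(int)
    # hand the rounding remainder to the largest fractional parts
    remainder = _N_AUTOSOMAL_GENES - counts.sum()
    for i in np.argsort(raw - counts)[::-1][:remainder]:
        counts[i] += 1
    out = {str(i): int(c) for i, c in zip(range(1, 27), counts)}
    out["X"] = _N_X_GENES
    return out


@dataclass(frozen=True)
class DesignGroup:
    """One cell of the sampling design: tissue x treatment x sex with a
    replicate count."""

    tissue: str
    treatment: str
    n_samples: int
    sex: str = "unknown"


@dataclass(frozen=True)
class PlantedEffect:
    """A diet-responsive effect: the gene's rate is multiplied by
    ``2**log2_effect`` in every sample of the given treatment group."""

    gene_id: str
    treatment: str
    log2_effect: float


def default_design() -> list[DesignGroup]:
    """Three fetal tissues under Con (n=7), Over (n=4), Res (n=4), with sexes
    split within each diet group (4F/3M, 2F/2M, 2F/2M)."""
    design = []
    for tissue in ("brain", "kidney", "lung"):
        design += [
            DesignGroup(tissue, "Con", 4, "female"),
            DesignGroup(tissue, "Con", 3, "male"),
            DesignGroup(tissue, "Over", 2, "female"),
            DesignGroup(tissue, "Over", 2, "male"),
            DesignGroup(tissue, "Res", 2, "female"),
            DesignGroup(tissue, "Res", 2, "male"),
        ]
    return design


def default_planted_degs() -> list[PlantedEffect]:
    """Eight diet-responsive X-linked genes with |log2 effect| >= 3,
    mirroring the magnitude of the strongest diet effects in the emulated
    study (both inductions and near-silencings)."""
    return [
        PlantedEffect("gX_0100", "Over", -5.5),
        PlantedEffect("gX_0200", "Over", -4.5),
        PlantedEffect("gX_0300", "Over", 4.7),
        PlantedEffect("gX_0400", "Over", -3.3),
        PlantedEffect("gX_0500", "Res", 5.2),
        PlantedEffect("gX_0600", "Res", -5.2),
        PlantedEffect("gX_0700", "Res", 3.5),
        PlantedEffect("gX_0800", "Res", -5.4),
    ]


@dataclass
class SyntheticConfig:
    """Full description of a simulated dataset.

    Parameters
    ----------
    genes_per_chromosome
        Genes on each chromosome label ("1".."26" and "X" by default).
    n_par_genes
        How many X-linked genes are pseudoautosomal (two active copies).
    length_log2_mean, length_log2_sd
        Log2-normal gene-length distribution (defaults center near 2 kb).
    baseline_log2_mean, baseline_log2_sd
        Per-gene baseline expression rate ~ 2**Normal(mean, sd); sd = 0 gives
        identical baselines (useful for exact analytic checks).
    sample_noise_log2_sd
        Multiplicative per-gene, per-sample noise ~ 2**Normal(0, sd).
    upregulation_factor_u
        Per-copy transcription multiplier of the single active X; the true
        RXE is log2(u) - 1.
    silent_fraction
        Fraction of genes zeroed in every sample (never planted DE genes).
    design, planted_degs, seed
        Sampling design, diet-responsive effects, and the RNG seed.
    """

    genes_per_chromosome: dict[str, int] = field(default_factory=sheep_gene_counts)
    n_par_genes: int = _N_PAR_GENES
    length_log2_mean: float = 11.0
    length_log2_sd: float = 1.0
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    sample_noise_log2_sd: float = 0.25
    upregulation_factor_u: float = 1.8
    silent_fraction: float = 0.4
    design: list[DesignGroup] = field(default_factory=default_design)
    planted_degs: list[PlantedEffect] = field(default_factory=default_planted_degs)
    seed: int = 0

    def __post_init__(self) -> None:
        for chrom, n in self.genes_per_chromosome.items():
            if n < 1:
                raise ValidationError(f"chromosome {chrom!r}: gene count must be >= 1")
        if self.upregulation_factor_u <= 0:
            raise ValidationError("upregulation_factor_u must be > 0")
        if not 0 <= self.silent_fraction < 1:
            raise ValidationError("silent_fraction must be in [0, 1)")
        if self.baseline_log2_sd < 0 or self.sample_noise_log2_sd < 0:
            raise ValidationError("dispersion parameters must be >= 0")
        n_x = self.genes_per_chromosome.get("X", 0)
        if self.n_par_genes > n_x:
            raise ValidationError("n_par_genes cannot exceed the X gene count")
        self.design = [
            g if isinstance(g, DesignGroup) else DesignGroup(**g) for g in self.design
        ]
        self.planted_degs = [
            p if isinstance(p, PlantedEffect) else PlantedEffect(**p)
            for p in self.planted_degs
        ]


# four independent child streams of the config seed, consumed in fixed order
_STREAM_LENGTHS, _STREAM_BASELINE, _STREAM_SILENT, _STREAM_NOISE = range(4)


def _stream(config: SyntheticConfig, which: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[which])


def _gene_ids(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    """Deterministic gene ids and chromosome labels, in chromosome order."""
    ids, chroms = [], []
    for chrom, n in config.genes_per_chromosome.items():
        for k in range(1, n + 1):
            ids.append(f"g{chrom}_{k:04d}")
            chroms.append(chrom)
    return ids, chroms


def generate_annotation(config: SyntheticConfig) -> GeneAnnotation:
    """Deterministic gene universe for a config: ids, chromosomes, log-normal
    lengths, and exactly ``n_par_genes`` PAR flags on the first X genes."""
    ids, chroms = _gene_ids(config)
    rng = _stream(config, _STREAM_LENGTHS)
    lengths = np.maximum(
        np.round(2 ** rng.normal(config.length_log2_mean, config.length_log2_sd, len(ids))),
        1,
    ).astype(int)
    par = {f"gX_{k:04d}" for k in range(1, config.n_par_genes + 1)}
    records = [
        GeneRecord(gid, chrom, int(length), is_par=gid in par)
        for gid, chrom, length in zip(ids, chroms, lengths)
    ]
    return GeneAnnotation(records)


def _sample_metadata(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for group in config.design:
        if group.n_samples < 1:
            raise ValidationError(
                f"design group {group.tissue}/{group.treatment} has zero samples"
            )
        for k in range(1, group.n_samples + 1):
            sid = f"{group.tissue}_{group.treatment}_{group.sex[0].upper()}{k}"
            rows.append(
                {
                    "sample_id": sid,
                    "tissue": group.tissue,
                    "sex": group.sex,
                    "treatment": group.treatment,
                    "dataset": "synthetic",
                }
            )
    meta = pd.DataFrame(rows).set_index("sample_id")
    if meta.index.has_duplicates:
        raise ValidationError("design produces duplicate sample ids")
    return meta


def _ground_truth(config: SyntheticConfig) -> pd.DataFrame:
    """Per-gene truth shared by the generator and :func:`truth_table`."""
    ids, chroms = _gene_ids(config)
    n = len(ids)
    baseline_rng = _stream(config, _STREAM_BASELINE)
    if config.baseline_log2_sd > 0:
        baseline = 2.0 ** baseline_rng.normal(
            config.baseline_log2_mean, config.baseline_log2_sd, n
        )
    else:
        baseline = np.full(n, 2.0**config.baseline_log2_mean)

    effects = pd.Series(0.0, index=pd.Index(ids, name="gene_id"))
    planted_treatment = pd.Series("", index=effects.index)
    for p in config.planted_degs:
        if p.gene_id not in effects.index:
            raise ValidationError(f"planted DE gene {p.gene_id!r} not in gene universe")
        effects[p.gene_id] = p.log2_effect
        planted_treatment[p.gene_id] = p.treatment

    planted_mask = planted_treatment != ""
    silent = np.zeros(n, dtype=bool)
    n_silent = int(np.floor(config.silent_fraction * n))
    if n_silent:
        eligible = np.flatnonzero(~planted_mask.to_numpy())
        silent_rng = _stream(config, _STREAM_SILENT)
        chosen = silent_rng.choice(eligible, size=min(n_silent, len(eligible)), replace=False)
        silent[chosen] = True

    return pd.DataFrame(
        {
            "chromosome": chroms,
            "baseline_rate": baseline,
            "is_planted_deg": planted_mask.to_numpy(),
            "planted_treatment": planted_treatment.to_numpy(),
            "log2_effect": effects.to_numpy(),
            "is_silent": silent,
        },
        index=effects.index,
    )


def truth_table(config: SyntheticConfig) -> pd.DataFrame:
    """Ground-truth table (the oracle for recovery tests): gene, chromosome,
    baseline rate, planted-DE flag and effect, silent flag."""
    return _ground_truth(config).reset_index()


def generate_expression(
    annotation: GeneAnnotation, config: SyntheticConfig
) -> ExpressionMatrix:
    """Simulate a TPM matrix for the configured design.

    Per gene g and sample s:

        rate = baseline_g * copies_g * 2**(planted effect if s's treatment
               matches) * 2**Normal(0, sample_noise_log2_sd)

    with copies = 2 for autosomal and PAR genes, ``u`` for non-PAR X-linked
    genes (single upregulated active copy).  Silent genes are zero everywhere.
    Columns are then renormalized to TPM (sum 1e6), which preserves all
    within-sample expression ratios and hence RXE/RGE.
    """
    truth = _ground_truth(config)
    if not truth.index.equals(annotation.gene_ids):
        raise ValidationError(
            "annotation does not match the config's gene universe; "
            "use generate_annotation(config)"
        )
    meta = _sample_metadata(config)
    chrom = truth["chromosome"].to_numpy()
    is_par = annotation.frame["is_par"].to_numpy()
    copies = np.where(
        chrom == "X",
        np.where(is_par, 2.0, config.upregulation_factor_u),
        2.0,
    )
    base = truth["baseline_rate"].to_numpy() * copies

    effect = np.ones((len(truth), len(meta)))
    treatments = meta["treatment"].to_numpy()
    planted = truth[truth["is_planted_deg"]]
    for gid, row in planted.iterrows():
        pos = truth.index.get_loc(gid)
        effect[pos, treatments == row["planted_treatment"]] = 2.0 ** row["log2_effect"]

    rates = base[:, None] * effect
    if config.sample_noise_log2_sd > 0:
        noise_rng = _stream(config, _STREAM_NOISE)
        rates = rates * 2.0 ** noise_rng.normal(
            0.0, config.sample_noise_log2_sd, rates.shape
        )
    rates[truth["is_silent"].to_numpy()] = 0.0

    totals = rates.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("a sample has zero total expression")
    tpm = rates / totals * TPM_TOTAL
    values = pd.DataFrame(tpm, index=truth.index, columns=meta.index)
    return ExpressionMatrix(values, meta)


def true_rxe(config: SyntheticConfig) -> float:
    """Analytic RXE implied by the upregulation factor, ignoring the small
    PAR contribution: log2(u) - 1."""
    return float(np.log2(config.upregulation_factor_u) - 1.0)


# ---------------------------------------------------------------------------
# config and dataset serialization
# ---------------------------------------------------------------------------

def config_to_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["design"] = [dataclasses.asdict(g) for g in config.design]
    d["planted_degs"] = [dataclasses.asdict(p) for p in config.planted_degs]
    return d


def config_from_dict(d: dict) -> SyntheticConfig:
    return SyntheticConfig(**d)


def save_config(config: SyntheticConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path: str | Path) -> SyntheticConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def write_dataset(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write a complete dataset in the pipeline's TSV dialects:
    gene map, expression matrix, sample metadata, PAR list, truth table and
    the config itself.  Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = generate_annotation(config)
    matrix = generate_expression(annotation, config)
    paths = {
        "gene_map": out / "gene_map.tsv",
        "expression": out / "expression.tsv",
        "metadata": out / "metadata.tsv",
        "par_list": out / "par_list.txt",
        "truth": out / "truth.tsv",
        "config": out / "config.yaml",
    }
    write_gene_map(annotation, paths["gene_map"])
    matrix.write(paths["expression"], paths["metadata"])
    paths["par_list"].write_text(
        "# pseudoautosomal genes\n" + "".join(f"{g}\n" for g in annotation.par_gene_ids)
    )
    truth_table(config).to_csv(paths["truth"], sep="\t", index=False)
    save_config(config, paths["config"])
    return paths
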