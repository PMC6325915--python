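"""Gene annotation and expression-matrix I/O.

This module owns the external formats of the pipeline — gene maps (TSV or
Ensembl-style GTF), pseudoautosomal-region (PAR) gene lists, TPM expression
matrices with per-sample metadata — plus TPM computation from raw counts and
chromosome-label normalization.  Everything downstream (dosage metrics,
differential expression, group statistics) consumes the two containers defined
here: :class:`GeneAnnotation` and :class:`ExpressionMatrix`.

Conventions
-----------
* Chromosome labels are normalized by stripping a leading ``chr`` prefix
  (case-insensitive) and upper-casing the sex chromosome, so ``chrx``/``ChrX``
  and ``X`` collapse to ``"X"``.  Sheep autosomes are labeled ``"1"``..``"26"``.
* The Y chromosome and the mitochondrion, when present, are recognized but
  excluded from every autosome set (neither is part of the autosomal reference
  used by the dosage statistics).
* TPM columns sum to one million; :func:`compute_tpm` enforces this and
  validation checks it for matrices claimed to be TPM.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("xdosage")

X_CHROMOSOME = "X"
#: chromosomes never counted as autosomal (not annotated in the sheep genome
#: reference used here, and biologically outside the X:A comparison)
EXCLUDED_CHROMOSOMES = frozenset({"Y", "MT"})
TPM_TOTAL = 1_000_000.0
VALID_SEXES = ("female", "male", "unknown")


class FormatError(ValueError):
    """A file does not conform to the expected dialect (missing columns, bad header)."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a semantic invariant."""


def normalize_chromosome(label: object) -> str:
    """Normalize a chromosome label: strip ``chr`` prefix, canonical sex/MT names.

    Idempotent: ``normalize_chromosome(normalize_chromosome(s)) == normalize_chromosome(s)``.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    low = s.lower()
    if low == "x":
        return "X"
    if low == "y":
        return "Y"
    if low in ("mt", "m", "mito"):
        return "MT"
    return s


@dataclass(frozen=True)
class GeneRecord:
    """One gene: identifier, chromosome assignment, length and PAR membership."""

    gene_id: str
    chromosome: str
    length_bp: int
    is_par: bool = False

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be a nonempty string")
        if self.length_bp < 1:
            raise ValidationError(
                f"gene {self.gene_id!r}: length_bp must be >= 1, got {self.length_bp}"
            )
        if self.is_par and self.chromosome != X_CHROMOSOME:
            raise ValidationError(
                f"gene {self.gene_id!r}: is_par=True requires chromosome 'X', "
                f"got {self.chromosome!r}"
            )


class GeneAnnotation:
    """Gene universe: gene -> chromosome, length, PAR flag.

    Partitions genes into X-linked and autosomal sets; the Y chromosome and
    mitochondrion are excluded from the autosome set.
    """

    def __init__(
        self,
        records: Iterable[GeneRecord],
        chromosome_set: Sequence[str] | None = None,
    ) -> None:
        records = list(records)
        seen: set[str] = set()
        for rec in records:
            if rec.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {rec.gene_id!r} in annotation")
            seen.add(rec.gene_id)
        self._records = records
        if chromosome_set is None:
            chromosome_set = list(dict.fromkeys(r.chromosome for r in records))
        else:
            chromosome_set = [normalize_chromosome(c) for c in chromosome_set]
            missing = {r.chromosome for r in records} - set(chromosome_set)
            if missing:
                raise ValidationError(
                    f"records reference chromosomes outside chromosome_set: {sorted(missing)}"
                )
        self.chromosome_set: list[str] = list(chromosome_set)
        self._frame = pd.DataFrame(
            {
                "chromosome": np.array([r.chromosome for r in records], dtype=object),
                "length_bp": np.array([r.length_bp for r in records], dtype=np.int64),
                "is_par": np.array([r.is_par for r in records], dtype=bool),
            },
            index=pd.Index([r.gene_id for r in records], name="gene_id"),
        )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._records)

    @property
    def records(self) -> list[GeneRecord]:
        return list(self._records)

    @property
    def frame(self) -> pd.DataFrame:
        """Annotation as a DataFrame indexed by gene_id (chromosome, length_bp, is_par)."""
        return self._frame

    # -- partitions ---------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self._frame.index

    @property
    def autosomes(self) -> list[str]:
        return [
            c
            for c in self.chromosome_set
            if c != X_CHROMOSOME and c not in EXCLUDED_CHROMOSOMES
        ]

    @property
    def x_gene_ids(self) -> pd.Index:
        return self._frame.index[self._frame["chromosome"] == X_CHROMOSOME]

    @property
    def autosomal_gene_ids(self) -> pd.Index:
        chrom = self._frame["chromosome"]
        mask = (chrom != X_CHROMOSOME) & ~chrom.isin(EXCLUDED_CHROMOSOMES)
        return self._frame.index[mask]

    @property
    def par_gene_ids(self) -> pd.Index:
        return self._frame.index[self._frame["is_par"]]

    def genes_on(self, chromosome: str) -> pd.Index:
        return self._frame.index[self._frame["chromosome"] == normalize_chromosome(chromosome)]

    def with_par(self, par_gene_ids: Iterable[str]) -> "GeneAnnotation":
        """Return a copy with ``is_par`` set for the given X-linked genes."""
        par = set(par_gene_ids)
        new_records = []
        for rec in self._records:
            if rec.gene_id in par and not rec.is_par:
                if rec.chromosome != X_CHROMOSOME:
                    raise ValidationError(
                        f"PAR gene {rec.gene_id!r} is on chromosome "
                        f"{rec.chromosome!r}, not 'X'"
                    )
                rec = replace(rec, is_par=True)
            new_records.append(rec)
        return GeneAnnotation(new_records, self.chromosome_set)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneAnnotation":
        records = [
            GeneRecord(
                gene_id=str(gid),
                chromosome=normalize_chromosome(row["chromosome"]),
                length_bp=int(row["length_bp"]),
                is_par=bool(row.get("is_par", False)),
            )
            for gid, row in frame.iterrows()
        ]
        return cls(records)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample study metadata (tissue, sex, diet treatment, source dataset)."""

    sample_id: str
    tissue: str = "unknown"
    sex: str = "unknown"
    treatment: str = "unknown"
    dataset: str = "unknown"

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be nonempty")
        if self.sex not in VALID_SEXES:
            raise ValidationError(
                f"sample {self.sample_id!r}: sex must be one of {VALID_SEXES}, got {self.sex!r}"
            )


METADATA_COLUMNS = ("tissue", "sex", "treatment", "dataset")


def _metadata_frame(samples: Iterable[SampleMetadata]) -> pd.DataFrame:
    samples = list(samples)
    return pd.DataFrame(
        {col: [getattr(s, col) for s in samples] for col in METADATA_COLUMNS},
        index=pd.Index([s.sample_id for s in samples], name="sample_id"),
    )


class ExpressionMatrix:
    """Nonnegative expression values (genes x samples, TPM) with sample metadata.

    ``values`` is a DataFrame whose rows are gene_ids and whose columns are
    sample_ids; ``samples`` is a metadata DataFrame indexed by sample_id with
    columns tissue, sex, treatment, dataset, aligned one-to-one with the value
    columns.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: pd.DataFrame | Iterable[SampleMetadata] | None = None,
    ) -> None:
        values = values.astype(float)
        arr = values.to_numpy()
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value at gene {values.index[bad[0]]!r}, "
                f"sample {values.columns[bad[1]]!r}"
            )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression value {arr[bad[0], bad[1]]} at gene "
                f"{values.index[bad[0]]!r}, sample {values.columns[bad[1]]!r}"
            )
        if values.columns.has_duplicates:
            raise ValidationError("duplicate sample_ids in expression matrix")
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene_id {dup!r} in expression matrix")

        if samples is None:
            samples = _metadata_frame(
                SampleMetadata(sample_id=str(c)) for c in values.columns
            )
        elif not isinstance(samples, pd.DataFrame):
            samples = _metadata_frame(samples)
        missing = [c for c in values.columns if c not in samples.index]
        if missing:
            raise ValidationError(
                f"samples missing from metadata: {missing}"
            )
        samples = samples.loc[values.columns, list(METADATA_COLUMNS)]
        bad_sex = set(samples["sex"]) - set(VALID_SEXES)
        if bad_sex:
            raise ValidationError(f"invalid sex labels in metadata: {sorted(bad_sex)}")
        self.values = values
        self.samples = samples

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def column(self, sample_id: str) -> pd.Series:
        if sample_id not in self.values.columns:
            raise KeyError(f"sample {sample_id!r} not in matrix")
        return self.values[sample_id]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.samples.loc[list(sample_ids)])

    def write(self, path: str | Path, meta_path: str | Path) -> None:
        """Write the value table and metadata as the TSV dialects read back by
        :func:`read_expression_matrix`."""
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
        meta = self.samples.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_gene_map(path: str | Path, format: str | None = None) -> GeneAnnotation:
    """Read a gene map (gene -> chromosome, length) from TSV or GTF.

    Parameters
    ----------
    path
        Input file.  TSV requires columns ``gene_id``, ``chromosome``,
        ``length_bp`` and optionally ``is_par`` (0/1).  GTF is read for
        features of type ``gene`` only; gene length is an explicit ``length``
        attribute when present, else ``end - start + 1`` (1-based inclusive
        coordinates).
    format
        ``"tsv"`` or ``"gtf"``; inferred from the suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "gtf" if path.suffix.lower() in (".gtf", ".gff", ".gff3") else "tsv"
    if format == "tsv":
        return _read_gene_map_tsv(path)
    if format == "gtf":
        return _read_gene_map_gtf(path)
    raise ValueError(f"unknown gene-map format {format!r}")


def _read_gene_map_tsv(path: Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    required = {"gene_id", "chromosome", "length_bp"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: gene map missing columns {sorted(missing)}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    has_par = "is_par" in df.columns
    records = [
        GeneRecord(
            gene_id=row.gene_id,
            chromosome=normalize_chromosome(row.chromosome),
            length_bp=int(row.length_bp),
            is_par=bool(int(row.is_par)) if has_par else False,
        )
        for row in df.itertuples(index=False)
    ]
    return GeneAnnotation(records)


def _read_gene_map_gtf(path: Path) -> GeneAnnotation:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gene_ids = feat.attributes.get("gene_id", [])
        if not gene_ids:
            raise FormatError(f"{path}: gene feature without gene_id attribute")
        gid = gene_ids[0]
        if gid in seen:
            raise ValidationError(f"{path}: duplicate gene_id {gid!r}")
        seen.add(gid)
        if "length" in feat.attributes:
            length = int(feat.attributes["length"][0])
        else:
            length = feat.end - feat.start + 1
        records.append(
            GeneRecord(
                gene_id=gid,
                chromosome=normalize_chromosome(feat.seqid),
                length_bp=length,
            )
        )
    return GeneAnnotation(records)


def write_gene_map(annotation: GeneAnnotation, path: str | Path) -> None:
    """Write an annotation in the TSV dialect read by :func:`read_gene_map`."""
    df = annotation.frame.copy()
    df["is_par"] = df["is_par"].astype(int)
    df.to_csv(path, sep="\t")


def read_par_list(path: str | Path, annotation: GeneAnnotation) -> GeneAnnotation:
    """Flag pseudoautosomal genes listed one-per-line in a plain-text file.

    PAR genes sit in the homologous region shared by X and Y and escape X
    inactivation, so they are removed from the "subject to XCI" subgroup
    downstream.  Listed genes absent from the annotation are reported as
    warnings (annotations routinely lag the PAR literature); a listed gene
    present but assigned to an autosome is an error.
    """
    path = Path(path)
    listed: list[str] = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            listed.append(line)
    known = set(annotation.gene_ids)
    present = [g for g in listed if g in known]
    absent = [g for g in listed if g not in known]
    if absent:
        warnings.warn(
            f"{len(absent)} PAR-listed genes not in annotation: {absent}",
            UserWarning,
            stacklevel=2,
        )
    return annotation.with_par(present)


def read_expression_matrix(path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (first column gene_id, one column per sample)
    and its sample-metadata TSV (keyed by sample_id)."""
    path, meta_path = Path(path), Path(meta_path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id', got {df.index.name!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad][0]
            raise ValidationError(
                f"{path}: non-numeric value {df.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
            )
        df[col] = coerced
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise FormatError(f"{meta_path}: metadata must have a 'sample_id' column")
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"{meta_path}: duplicate sample_id {dup!r}")
    meta = meta.set_index("sample_id")
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            meta[col] = "unknown"
    extra = [s for s in meta.index if s not in df.columns]
    if extra:
        logger.info("metadata rows without matrix columns ignored: %s", extra)
    return ExpressionMatrix(df, meta)


def compute_tpm(
    counts: pd.DataFrame,
    annotation: GeneAnnotation,
    samples: pd.DataFrame | Iterable[SampleMetadata] | None = None,
) -> ExpressionMatrix:
    """Convert raw gene-level counts to TPM.

    TPM normalizes for gene length first and then for sequencing depth:
    per sample, ``rate_g = count_g / (length_bp_g / 1000)`` (reads per
    kilobase), then ``TPM_g = rate_g / sum(rates) * 1e6``.  Columns of the
    result sum to one million.

    Raises
    ------
    ValidationError
        If a counted gene has no length in the annotation, or a sample has
        all-zero counts (TPM undefined).
    """
    lengths = annotation.frame["length_bp"].reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()][:5])
        raise ValidationError(f"genes without annotation length: {missing}")
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("counts must be nonnegative")
    rates = arr / (lengths.to_numpy()[:, None] / 1000.0)
    totals = rates.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"sample {counts.columns[zero[0]]!r} has all-zero counts; TPM undefined"
        )
    tpm = rates / totals * TPM_TOTAL
    values = pd.DataFrame(tpm, index=counts.index, columns=counts.columns)
    return ExpressionMatrix(values, samples)
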