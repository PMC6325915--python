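import numpy as np
import pandas as pd
import pytest

from xdosage import ExpressionMatrix, GeneAnnotation, GeneRecord


def make_annotation(spec):
    """Build an annotation from {chromosome: n_genes}; ids '<chrom>g<i>'.

    Pass a chromosome key like ('X', n, n_par) to flag the first n_par ids.
    """
    records = []
    for entry in spec.items() if isinstance(spec, dict) else spec:
        if len(entry) == 3:
            chrom, n, n_par = entry
        else:
            (chrom, n), n_par = entry, 0
        for i in range(1, n + 1):
            records.append(
                GeneRecord(f"{chrom}g{i}", chrom, 1000, is_par=i <= n_par)
            )
    return GeneAnnotation(records)


def make_matrix(annotation, columns):
    """Expression matrix over an annotation's genes.

    ``columns`` maps sample_id -> scalar | per-gene array | {gene_id: value}
    (dict values default to 0 for unlisted genes).  Metadata defaults to
    unknown and can be overridden by passing (values, meta_dict) tuples.
    """
    genes = list(annotation.gene_ids)
    data, meta_rows = {}, {}
    for sid, value in columns.items():
        meta = {}
        if isinstance(value, tuple):
            value, meta = value
        if isinstance(value, dict):
            col = [float(value.get(g, 0.0)) for g in genes]
        elif np.isscalar(value):
            col = [float(value)] * len(genes)
        else:
            col = list(map(float, value))
        data[sid] = col
        meta_rows[sid] = {
            "tissue": meta.get("tissue", "unknown"),
            "sex": meta.get("sex", "unknown"),
            "treatment": meta.get("treatment", "unknown"),
            "dataset": meta.get("dataset", "unknown"),
        }
    values = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    samples = pd.DataFrame.from_dict(meta_rows, orient="index")
    samples.index.name = "sample_id"
    return ExpressionMatrix(values, samples)


@pytest.fixture
def small_annotation():
    """Two autosomes (4 + 3 genes) and X (3 genes, first one PAR)."""
    return make_annotation([("1", 4), ("2", 3), ("X", 3, 1)])


@pytest.fixture
def uniform_matrix(small_annotation):
    """All genes at TPM 100 in two samples."""
    return make_matrix(small_annotation, {"s1": 100.0, "s2": 100.0})
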