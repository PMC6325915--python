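"""RXE/RGE computation, gene subgroups, compensation classes, boxplot stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xdosage import (
    SubgroupSpec,
    ValidationError,
    activity_gene_count_correlation,
    classify_compensation,
    compute_rge,
    compute_rxe,
    select_subgroup,
    summarize_group,
    tissue_mean_rxe,
)
from xdosage.dosage_metrics import RelativeExpressionResult

from conftest import make_annotation, make_matrix


# ---------------------------------------------------------------------------
# subgroup selection
# ---------------------------------------------------------------------------

class TestSubgroups:
    def test_expressed_threshold_is_inclusive(self, small_annotation):
        m = make_matrix(
            small_annotation, {"s": {"1g1": 1.0, "1g2": 0.99, "Xg1": 5.0}}
        )
        genes = select_subgroup(m, small_annotation, SubgroupSpec("EXPRESSED"), "s")
        assert "1g1" in genes  # TPM exactly 1.0 counts as expressed
        assert "1g2" not in genes

    def test_dosage_sensitive_requires_every_sample(self, small_annotation):
        cols = {f"s{i}": {"1g1": 10.0, "Xg1": 10.0} for i in range(9)}
        cols["s9"] = {"1g1": 0.5, "Xg1": 10.0}  # 1g1 drops out in 1 of 10
        m = make_matrix(small_annotation, cols)
        genes = select_subgroup(
            m, small_annotation, SubgroupSpec("DOSAGE_SENSITIVE"), "s0"
        )
        assert "Xg1" in genes and "1g1" not in genes

        cols["s9"] = {"1g1": 1.0, "Xg1": 10.0}
        m = make_matrix(small_annotation, cols)
        genes = select_subgroup(
            m, small_annotation, SubgroupSpec("DOSAGE_SENSITIVE"), "s0"
        )
        assert "1g1" in genes  # 10 of 10 samples

    def test_xci_subject_removes_par_genes(self, small_annotation):
        # Xg1 is PAR in the fixture; expressed but excluded from XCI_SUBJECT
        m = make_matrix(small_annotation, {"s": {"Xg1": 50.0, "Xg2": 5.0, "1g1": 2.0}})
        expressed = select_subgroup(m, small_annotation, SubgroupSpec("EXPRESSED"), "s")
        xci = select_subgroup(m, small_annotation, SubgroupSpec("XCI_SUBJECT"), "s")
        assert "Xg1" in expressed and "Xg1" not in xci
        assert "Xg2" in xci

    def test_empty_subgroup_is_error(self, small_annotation):
        m = make_matrix(small_annotation, {"s": 0.5})
        with pytest.raises(ValidationError, match="empty"):
            select_subgroup(m, small_annotation, SubgroupSpec("EXPRESSED"), "s")


# ---------------------------------------------------------------------------
# RXE
# ---------------------------------------------------------------------------

class TestRxe:
    @pytest.mark.parametrize(
        "x_tpm, expected",
        [(100.0, 0.0), (50.0, -1.0), (60.0, np.log2(0.6))],
    )
    def test_against_direct_arithmetic(self, small_annotation, x_tpm, expected):
        m = make_matrix(
            small_annotation,
            {"s": {g: (x_tpm if g.startswith("X") else 100.0)
                   for g in small_annotation.gene_ids}},
        )
        res = compute_rxe(m, small_annotation, SubgroupSpec("ALL"), "s")
        assert res.rxe == pytest.approx(expected, abs=1e-12)
        assert res.n_x_genes == 3 and res.n_autosomal_genes == 7

    def test_zero_mean_error_names_the_set(self, small_annotation):
        m = make_matrix(small_annotation, {"s": {"1g1": 10.0}})  # all X at 0
        with pytest.raises(ValidationError, match="X-linked"):
            compute_rxe(m, small_annotation, SubgroupSpec("ALL"), "s")

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, scale):
        ann = make_annotation([("1", 5), ("X", 3)])
        rng = np.random.default_rng(7)
        tpm = rng.lognormal(2, 1, len(ann.gene_ids))
        m1 = make_matrix(ann, {"s": tpm})
        m2 = make_matrix(ann, {"s": tpm * scale})
        r1 = compute_rxe(m1, ann, SubgroupSpec("ALL"), "s")
        r2 = compute_rxe(m2, ann, SubgroupSpec("ALL"), "s")
        assert r1.rxe == pytest.approx(r2.rxe, abs=1e-9)

    def test_par_removal_only_moves_x_side(self):
        # PAR gene expressed low: dropping it raises the X mean, leaves A mean
        ann = make_annotation([("1", 4), ("X", 4, 1)])
        vals = {"1g1": 80.0, "1g2": 90.0, "1g3": 100.0, "1g4": 110.0,
                "Xg1": 2.0, "Xg2": 60.0, "Xg3": 70.0, "Xg4": 80.0}
        m = make_matrix(ann, {"s": vals})
        expressed = compute_rxe(m, ann, SubgroupSpec("EXPRESSED"), "s")
        xci = compute_rxe(m, ann, SubgroupSpec("XCI_SUBJECT"), "s")
        assert xci.n_autosomal_genes == expressed.n_autosomal_genes
        assert xci.n_x_genes == expressed.n_x_genes - 1
        assert xci.rxe > expressed.rxe

    def test_mean_of_log_option(self):
        ann = make_annotation([("1", 2), ("X", 2)])
        m = make_matrix(ann, {"s": {"1g1": 4.0, "1g2": 16.0, "Xg1": 2.0, "Xg2": 8.0}})
        res = compute_rxe(m, ann, SubgroupSpec("ALL"), "s", method="mean_of_log")
        # mean(log2 X) = (1+3)/2 = 2; mean(log2 A) = (2+4)/2 = 3
        assert res.rxe == pytest.approx(-1.0)


# ---------------------------------------------------------------------------
# RGE
# ---------------------------------------------------------------------------

def brute_force_rge(matrix, annotation, sample_id):
    """Independent two-set mean computation, one autosome at a time."""
    col = matrix.values[sample_id]
    chrom = annotation.frame["chromosome"]
    out = {}
    for c in annotation.autosomes:
        on = [g for g in annotation.gene_ids
              if chrom[g] == c and g in matrix.gene_ids]
        off = [g for g in annotation.gene_ids
               if chrom[g] not in (c, "X", "Y", "MT") and g in matrix.gene_ids]
        if on:
            out[c] = float(np.log2(np.mean([col[g] for g in on]))
                           - np.log2(np.mean([col[g] for g in off])))
    return out


class TestRge:
    def test_symmetry_all_equal(self, small_annotation, uniform_matrix):
        rge = compute_rge(uniform_matrix, small_annotation, SubgroupSpec("ALL"), "s1")
        assert set(rge) == {"1", "2"}
        assert all(v == pytest.approx(0.0) for v in rge.values())

    def test_doubled_chromosome(self):
        ann = make_annotation([("5", 3), ("6", 3), ("7", 3), ("X", 1)])
        vals = {g: (200.0 if g.startswith("5") else 100.0) for g in ann.gene_ids}
        rge = compute_rge(make_matrix(ann, {"s": vals}), ann, SubgroupSpec("ALL"), "s")
        assert rge["5"] == pytest.approx(1.0)

    def test_two_autosomes_mirror(self):
        ann = make_annotation([("1", 2), ("2", 2), ("X", 1)])
        vals = {"1g1": 100.0, "1g2": 100.0, "2g1": 50.0, "2g2": 50.0, "Xg1": 80.0}
        rge = compute_rge(make_matrix(ann, {"s": vals}), ann, SubgroupSpec("ALL"), "s")
        assert rge["1"] == pytest.approx(1.0)
        assert rge["2"] == pytest.approx(-1.0)

    def test_agrees_with_brute_force_oracle(self):
        ann = make_annotation([(str(i), 5) for i in range(1, 7)] + [("X", 4)])
        rng = np.random.default_rng(42)
        m = make_matrix(ann, {"s": rng.lognormal(3, 1.5, len(ann.gene_ids))})
        rge = compute_rge(m, ann, SubgroupSpec("ALL"), "s")
        oracle = brute_force_rge(m, ann, "s")
        assert set(rge) == set(oracle)
        for c in rge:
            assert rge[c] == pytest.approx(oracle[c], abs=1e-12)

    def test_x_never_enters(self):
        ann = make_annotation([("1", 3), ("2", 3), ("X", 3)])
        base = {g: 100.0 for g in ann.gene_ids}
        loud = dict(base, **{g: 10_000.0 for g in base if g.startswith("X")})
        r1 = compute_rge(make_matrix(ann, {"s": base}), ann, SubgroupSpec("ALL"), "s")
        r2 = compute_rge(make_matrix(ann, {"s": loud}), ann, SubgroupSpec("ALL"), "s")
        assert r1 == r2


# ---------------------------------------------------------------------------
# compensation classification
# ---------------------------------------------------------------------------

class TestClassification:
    @pytest.mark.parametrize(
        "rxe, label",
        [(0.16, "complete"), (0.0, "complete"), (-0.12, "partial"),
         (-0.999, "partial"), (-1.0, "none"), (-3.0, "none")],
    )
    def test_thresholds(self, rxe, label):
        assert classify_compensation(rxe).label == label

    @given(st.floats(allow_nan=False, allow_infinity=False, width=64))
    @settings(max_examples=300, derandomize=True)
    def test_partition_of_the_real_line(self, rxe):
        call = classify_compensation(rxe)
        expected = "complete" if rxe >= 0 else ("partial" if rxe > -1 else "none")
        assert call.label == expected

    def test_non_finite_rejected(self):
        for bad in (np.nan, np.inf, -np.inf):
            with pytest.raises(ValidationError):
                classify_compensation(bad)


# ---------------------------------------------------------------------------
# boxplot summaries
# ---------------------------------------------------------------------------

class TestBoxplot:
    def test_linear_interpolation_hinges(self):
        s = summarize_group([(str(i), float(i)) for i in range(1, 10)])
        assert (s.lower_hinge, s.upper_hinge) == (3.0, 7.0)
        assert s.iqr == 4.0
        assert s.outliers == ()
        assert (s.lower_whisker, s.upper_whisker) == (1.0, 9.0)

    def test_outlier_labeled(self):
        s = summarize_group([("a", 0.0), ("b", 0.0), ("c", 0.0), ("d", 0.0), ("e", 10.0)])
        assert s.iqr == 0.0
        assert s.outliers == (("e", 10.0),)
        assert s.upper_whisker == 0.0

    def test_constant_values(self):
        s = summarize_group([("a", 2.0), ("b", 2.0), ("c", 2.0)])
        assert s.lower_hinge == s.upper_hinge == 2.0
        assert s.outliers == ()

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValidationError):
            summarize_group([("a", 1.0)])

    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=2, max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_invariants(self, vals):
        s = summarize_group([(str(i), v) for i, v in enumerate(vals)])
        assert s.lower_hinge <= s.upper_hinge
        assert s.iqr == pytest.approx(s.upper_hinge - s.lower_hinge)
        for _, v in s.outliers:
            assert v < s.lower_whisker or v > s.upper_whisker
        assert s.lower_whisker >= s.lower_hinge - 1.5 * s.iqr - 1e-9
        assert s.upper_whisker <= s.upper_hinge + 1.5 * s.iqr + 1e-9


# ---------------------------------------------------------------------------
# group means / correlation
# ---------------------------------------------------------------------------

def _res(sample_id, rxe, tissue="brain", treatment="Con"):
    return RelativeExpressionResult(
        sample_id=sample_id, rxe=rxe, tissue=tissue, treatment=treatment
    )


class TestTissueMeans:
    def test_identity_and_mean(self):
        results = [_res("a", -0.2), _res("b", 0.0), _res("c", 0.3, tissue="lung")]
        means = tissue_mean_rxe(results)
        assert means["brain"] == pytest.approx(-0.1)
        assert means["lung"] == pytest.approx(0.3)

    def test_permutation_invariance(self):
        results = [_res(str(i), x) for i, x in enumerate([-0.4, 0.1, 0.2, -0.3])]
        forward = tissue_mean_rxe(results)
        backward = tissue_mean_rxe(list(reversed(results)))
        assert forward == backward


class TestActivityCorrelation:
    def test_perfect_anticorrelation(self):
        r = activity_gene_count_correlation(
            {"1": 0.3, "2": 0.0, "3": -0.3}, {"1": 100, "2": 200, "3": 300}
        )
        assert r == pytest.approx(-1.0)

    def test_affine_map_gives_plus_one(self):
        counts = {"1": 100, "2": 250, "3": 400, "4": 120}
        rge = {c: 0.01 * n - 2 for c, n in counts.items()}
        assert activity_gene_count_correlation(rge, counts) == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        chroms = [str(i) for i in range(1, 11)]
        x = rng.normal(0, 0.4, 10)
        y = rng.integers(100, 900, 10)
        r = activity_gene_count_correlation(
            dict(zip(chroms, x)), dict(zip(chroms, y))
        )
        xv, yv = x - x.mean(), y - y.mean()
        oracle = float((xv * yv).sum() / np.sqrt((xv**2).sum() * (yv**2).sum()))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_key_mismatch_and_degenerate(self):
        with pytest.raises(ValidationError):
            activity_gene_count_correlation({"1": 0.1, "2": 0.2}, {"1": 5, "3": 6})
        with pytest.raises(ValidationError, match="variance"):
            activity_gene_count_correlation(
                {"1": 0.1, "2": 0.1, "3": 0.1}, {"1": 5, "2": 6, "3": 7}
            )
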