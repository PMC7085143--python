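"""Normalization chain and sample QC."""

import numpy as np
import pandas as pd
import pytest

import txbench as tb
from txbench.preprocess import STD_FLOOR


def _count_matrix(counts, lengths=None):
    counts = np.asarray(counts)
    n, p = counts.shape
    return tb.CountMatrix(
        counts=counts,
        gene_ids=np.array([f"g{i}" for i in range(p)]),
        gene_lengths=np.ones(p) if lengths is None else np.asarray(lengths, float),
        sample_ids=np.array([f"s{i}" for i in range(n)]),
    )


def _metadata(n, **overrides):
    base = {
        "sample_id": [f"s{i}" for i in range(n)],
        "tissue": ["liver"] * n,
        "study": ["ST0"] * n,
        "accession": [f"GSM{i}" for i in range(n)],
        "is_cell_line": [False] * n,
        "is_single_cell": [False] * n,
    }
    base.update(overrides)
    return tb.SampleMetadata(pd.DataFrame(base))


def _annotation(p, n_o=None, n_ot=0):
    n_o = p if n_o is None else n_o
    return tb.GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(p)],
                "in_O": np.arange(p) < n_o,
                "in_OT": np.arange(p) < n_ot,
            }
        )
    )


class TestTPM:
    def test_equal_counts_equal_lengths_split_evenly(self):
        out = tb.to_tpm(_count_matrix([[10, 10]]))
        np.testing.assert_allclose(out.values, [[5e5, 5e5]])

    def test_length_normalization(self):
        out = tb.to_tpm(_count_matrix([[10, 10]], lengths=[1, 2]))
        np.testing.assert_allclose(out.values, [[666666.67, 333333.33]], rtol=1e-6)

    def test_rows_sum_to_one_million(self, small_dataset):
        tpm = tb.to_tpm(small_dataset.counts)
        np.testing.assert_allclose(tpm.values.sum(axis=1), 1e6, rtol=1e-9)

    def test_all_zero_sample_rejected_by_name(self):
        cm = _count_matrix([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="s1"):
            tb.to_tpm(cm)


class TestCLR:
    def test_uniform_vector_maps_to_zero(self):
        tpm = tb.ExpressionMatrix(
            np.full((1, 4), 2.5e5), "tpm", "all", np.arange(4), np.array(["s0"])
        )
        np.testing.assert_allclose(tb.to_clr(tpm).values, 0.0, atol=1e-12)

    def test_hand_computed_values(self):
        tpm = tb.ExpressionMatrix(
            np.array([[5e5, 2.5e5, 2.5e5]]), "tpm", "all", np.arange(3), np.array(["s0"])
        )
        np.testing.assert_allclose(
            tb.to_clr(tpm).values, [[0.4621, -0.2310, -0.2310]], atol=1e-4
        )

    def test_scale_invariance_and_zero_row_sums(self, small_dataset):
        tpm = tb.to_tpm(small_dataset.counts)
        clr = tb.to_clr(tpm)
        scaled = tb.ExpressionMatrix(
            tpm.values * 7.3, "tpm", "all", tpm.gene_ids, tpm.sample_ids
        )
        np.testing.assert_allclose(tb.to_clr(scaled).values, clr.values, atol=1e-9)
        assert np.abs(clr.values.sum(axis=1)).max() < 1e-9


class TestQCFilter:
    def test_single_cell_line_removed(self):
        n = 10
        cm = _count_matrix(np.ones((n, 4), dtype=int))
        meta = _metadata(n, is_cell_line=[True] + [False] * (n - 1))
        res = tb.qc_filter(cm, meta, _annotation(4), {"liver"})
        assert res.keep_mask.sum() == n - 1
        assert res.criterion_matches["cell_line"] == 1

    def test_overlapping_criteria_counted_non_exclusively(self):
        counts = np.ones((3, 10), dtype=int)
        counts[0, :4] = 0  # 40% > 30% zeros among O genes
        cm = _count_matrix(counts)
        meta = _metadata(3, accession=["A", "A", "B"])  # s0 also duplicated
        res = tb.qc_filter(cm, meta, _annotation(10), {"liver"})
        assert res.criterion_matches["zero_fraction_O"] == 1
        assert res.criterion_matches["duplicate_accession"] == 2
        assert res.n_removed == 2  # s0 removed once, s1 by duplication

    def test_exactly_thirty_percent_zeros_is_kept(self):
        counts = np.ones((1, 10), dtype=int)
        counts[0, :3] = 0  # exactly 30%: rule is strictly "more than 30%"
        res = tb.qc_filter(_count_matrix(counts), _metadata(1), _annotation(10), {"liver"})
        assert res.keep_mask.all()

    def test_missing_tissue_matches_reference_rule(self):
        meta = _metadata(2, tissue=["liver", None])
        res = tb.qc_filter(
            _count_matrix(np.ones((2, 4), int)), meta, _annotation(4), {"liver"}
        )
        assert res.criterion_matches["tissue_not_in_reference"] == 1
        assert res.keep_mask.tolist() == [True, False]

    def test_removed_count_equals_union_of_match_sets(self, small_dataset):
        cm, meta = tb.inject_qc_violations(
            small_dataset.counts,
            small_dataset.metadata,
            small_dataset.annotation,
            {"cell_line": 4, "duplicate_accession": 4, "zero_fraction_O": 3},
            seed=7,
        )
        res = tb.qc_filter(
            cm, meta, small_dataset.annotation, {f"tissue_{t}" for t in range(3)}
        )
        union = np.zeros(cm.n_samples, dtype=bool)
        for mask in res.match_masks.values():
            union |= mask
        assert res.n_removed == union.sum()

    def test_misaligned_metadata_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            tb.qc_filter(
                _count_matrix(np.ones((3, 4), int)), _metadata(2), _annotation(4), {"liver"}
            )


class TestGeneSets:
    def test_all_is_identity(self, small_dataset, small_clr):
        out = tb.select_gene_set(small_clr, small_dataset.annotation, "all")
        np.testing.assert_array_equal(out.values, small_clr.values)

    def test_ot_has_expected_width(self, small_dataset, small_clr):
        out = tb.select_gene_set(small_clr, small_dataset.annotation, "OT")
        assert out.n_genes == 30
        assert out.gene_set == "OT"

    def test_subset_does_not_recompute_normalization(self, small_dataset, small_clr):
        """CLR rows restricted to O genes no longer sum to zero: the
        transform is defined on all genes and values are taken verbatim."""
        out = tb.select_gene_set(small_clr, small_dataset.annotation, "O")
        assert np.abs(out.values.sum(axis=1)).max() > 1e-3
        full = tb.select_gene_set(small_clr, small_dataset.annotation, "all")
        np.testing.assert_array_equal(
            out.values, full.values[:, small_dataset.annotation.mask("O")]
        )

    def test_empty_set_rejected(self, small_clr):
        p = small_clr.n_genes
        annot = _annotation(p, n_o=0)
        with pytest.raises(ValueError, match="empty"):
            tb.select_gene_set(small_clr, annot, "O")

    def test_ot_must_nest_in_o(self):
        with pytest.raises(ValueError, match="subset"):
            tb.GeneAnnotation(
                pd.DataFrame(
                    {"gene_id": ["a"], "in_O": [False], "in_OT": [True]}
                )
            )


class TestTissueReference:
    def _clr(self, values, sample_ids):
        values = np.asarray(values, float)
        return tb.ExpressionMatrix(
            values, "clr", "all", np.arange(values.shape[1]), np.asarray(sample_ids)
        )

    def test_zero_variance_hits_std_floor(self):
        clr = self._clr([[1.0, -1.0], [1.0, -1.0]], ["s0", "s1"])
        meta = _metadata(2)
        ref = tb.build_tissue_reference(clr, meta, np.array([True, True]))
        np.testing.assert_allclose(ref.mean_clr, [[1.0, -1.0]])
        np.testing.assert_allclose(ref.std_clr, STD_FLOOR)

    def test_single_reference_sample_rejected(self):
        clr = self._clr([[1.0, 2.0], [0.0, 0.0]], ["s0", "s1"])
        meta = _metadata(2, tissue=["liver", "lung"])
        with pytest.raises(ValueError, match="reference sample"):
            tb.build_tissue_reference(clr, meta, np.array([True, True]))

    def test_moment_recovery(self):
        rng = np.random.default_rng(0)
        mu, sd = np.array([0.5, -1.0, 2.0]), np.array([0.3, 1.0, 0.7])
        values = rng.normal(mu, sd, size=(500, 3))
        clr = self._clr(values, [f"s{i}" for i in range(500)])
        ref = tb.build_tissue_reference(clr, _metadata(500), np.ones(500, bool))
        np.testing.assert_allclose(ref.mean_clr[0], mu, atol=0.15)
        np.testing.assert_allclose(ref.std_clr[0], sd, rtol=0.15)


class TestZScore:
    def _setup(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(200, 5))
        clr = tb.ExpressionMatrix(
            values, "clr", "all", np.arange(5),
            np.array([f"s{i}" for i in range(200)]),
        )
        meta = _metadata(200)
        ref = tb.build_tissue_reference(clr, meta, np.ones(200, bool))
        return clr, meta, ref

    def test_mean_maps_to_zero_and_one_sd_to_one(self):
        clr, meta, ref = self._setup()
        probe = tb.ExpressionMatrix(
            np.vstack([ref.mean_clr[0], ref.mean_clr[0] + ref.std_clr[0]]),
            "clr", "all", clr.gene_ids, np.array(["p0", "p1"]),
        )
        z = tb.to_zscore(probe, _metadata(2, sample_id=["p0", "p1"]), ref)
        np.testing.assert_allclose(z.values[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(z.values[1], 1.0, atol=1e-12)

    def test_reference_samples_standardize_to_unit_moments(self):
        clr, meta, ref = self._setup()
        z = tb.to_zscore(clr, meta, ref)
        np.testing.assert_allclose(z.values.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.values.std(axis=0), 1.0, rtol=1e-10)

    def test_unknown_tissue_error_names_sample(self):
        clr, meta, ref = self._setup()
        bad_meta = _metadata(200, tissue=["liver"] * 199 + ["brain"])
        with pytest.raises(KeyError, match="brain"):
            tb.to_zscore(clr, bad_meta, ref)


class TestZTernary:
    def _z(self, values):
        values = np.atleast_2d(np.asarray(values, float))
        return tb.ExpressionMatrix(
            values, "zscore", "all", np.arange(values.shape[1]),
            np.array([f"s{i}" for i in range(values.shape[0])]),
        )

    @pytest.mark.parametrize(
        "z_in, expected",
        [
            ([-3.0, 0.0, 2.5], [-1.0, 0.0, 1.0]),
            ([2.0, -2.0], [0.0, 0.0]),  # boundary maps inside the normal band
            ([1.99, -1.99, 0.5], [0.0, 0.0, 0.0]),
        ],
    )
    def test_threshold_rules(self, z_in, expected):
        np.testing.assert_array_equal(tb.to_zternary(self._z(z_in)).values[0], expected)

    def test_thresholding_is_pure_with_ternary_range(self):
        z = self._z(np.linspace(-4, 4, 33))
        once = tb.to_zternary(z)
        again = tb.to_zternary(z)
        np.testing.assert_array_equal(once.values, again.values)
        assert set(np.unique(once.values)) <= {-1.0, 0.0, 1.0}
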