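"""Pearson co-expression, condition contrast and prioritization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltnet import (
    BlockSpec,
    ExpressionMatrix,
    SimulationConfig,
    ValidationError,
    classify_reported,
    connectivity_counts,
    contrast_conditions,
    correlation_map,
    generate_expression,
    pearson_r,
    prioritize,
    threshold_network,
)
from saltnet.datasets import (
    load_coexpression_pairs,
    load_ssg_obesity_status,
    obesity_annotation,
    unreported_ssgs,
)


class TestPearsonR:
    def test_perfect_and_anti_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_oracle(self):
        """Direct evaluation of the product-moment formula gives 0.6."""
        assert pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_gives_missing(self):
        assert np.isnan(pearson_r([1, 1, 1], [1, 2, 3]))

    @pytest.mark.parametrize("x, y", [([1, 2], [1, 2]), ([1, 2, 3], [1, 2])])
    def test_bad_input_rejected(self, x, y):
        with pytest.raises(ValidationError):
            pearson_r(x, y)


class TestCorrelationMap:
    def test_pair_count_and_symmetry(self, small_matrix):
        cmap = correlation_map(small_matrix, "case")
        n = len(cmap.genes)
        assert n * (n - 1) // 2 == 15
        mat = cmap.r.to_numpy()
        assert np.allclose(mat, mat.T, equal_nan=True)
        assert np.allclose(np.diag(mat), 1.0)

    def test_constant_gene_has_missing_row(self, small_matrix):
        values = small_matrix.values.copy()
        values.loc["G2"] = 5.0
        matrix = ExpressionMatrix(values, small_matrix.condition_of)
        cmap = correlation_map(matrix, "case")
        assert cmap.r.loc["G2"].isna().all()
        assert np.isnan(cmap.lookup("G2", "G2"))

    def test_absent_genes_skipped_with_warning(self, small_matrix, caplog):
        cmap = correlation_map(small_matrix, "case", {"G1", "G2", "NOPE"})
        assert set(cmap.genes) == {"G1", "G2"}
        assert "absent" in caplog.text

    def test_block_recovers_planted_rho(self):
        config = SimulationConfig(
            seed=3, n_case=100, blocks=(BlockSpec(size=10, rho=0.9),)
        )
        matrix, truth = generate_expression(config)
        genes = {g for pair in truth.block_pairs for g in pair}
        cmap = correlation_map(matrix, "case", genes)
        iu, ju = np.triu_indices(len(cmap.genes), k=1)
        assert cmap.r.to_numpy()[iu, ju].mean() == pytest.approx(0.9, abs=0.05)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_symmetry_diagonal_property(self, seed):
        rng = np.random.default_rng(seed)
        n_genes, n_samples = int(rng.integers(2, 8)), int(rng.integers(3, 8))
        samples = [f"S{i}" for i in range(n_samples)]
        values = pd.DataFrame(
            rng.standard_normal((n_genes, n_samples)),
            index=[f"G{i}" for i in range(n_genes)],
            columns=samples,
        )
        matrix = ExpressionMatrix(
            values, pd.Series(["case"] * n_samples, index=samples)
        )
        mat = correlation_map(matrix, "case").r.to_numpy()
        assert np.allclose(mat, mat.T, equal_nan=True)
        assert np.allclose(np.diag(mat), 1.0)
        assert np.nanmax(np.abs(mat)) <= 1.0


class TestThresholdNetwork:
    def _map(self, small_matrix):
        return correlation_map(small_matrix, "case")

    def test_boundary_threshold_keeps_only_perfect_pairs(self, small_matrix):
        values = small_matrix.values.copy()
        values.loc["G2"] = values.loc["G1"]  # identical profile: r exactly 1
        matrix = ExpressionMatrix(values, small_matrix.condition_of)
        edges = threshold_network(correlation_map(matrix, "case"), 1.0)
        assert set(map(tuple, edges[["gene_1", "gene_2"]].values)) == {("G1", "G2")}

    def test_larger_threshold_gives_subset(self, small_matrix):
        cmap = self._map(small_matrix)
        loose = threshold_network(cmap, 0.3)
        tight = threshold_network(cmap, 0.6)
        as_sets = lambda frame: {
            frozenset(p) for p in frame[["gene_1", "gene_2"]].values
        }
        assert as_sets(tight) <= as_sets(loose)

    def test_positive_mode_ignores_negative_correlation(self, small_matrix):
        values = small_matrix.values.copy()
        values.loc["G2"] = -values.loc["G1"]
        matrix = ExpressionMatrix(values, small_matrix.condition_of)
        cmap = correlation_map(matrix, "case")
        pos = threshold_network(cmap, 0.8, "positive")
        absolute = threshold_network(cmap, 0.8, "absolute")
        pair = frozenset({"G1", "G2"})
        assert pair not in {frozenset(p) for p in pos[["gene_1", "gene_2"]].values}
        assert pair in {frozenset(p) for p in absolute[["gene_1", "gene_2"]].values}

    def test_null_pairs_rarely_pass(self):
        config = SimulationConfig(seed=29, n_genes=120, n_case=100, blocks=(), n_de=0)
        matrix, _ = generate_expression(config)
        cmap = correlation_map(matrix, "case")
        edges = threshold_network(cmap, 0.8)
        n_pairs = 120 * 119 / 2
        assert len(edges) / n_pairs <= 0.001

    def test_published_pairs_all_pass_at_08(self):
        """Re-filtering the bundled contrast table's disease column at the
        0.8 threshold removes no rows."""
        pairs = load_coexpression_pairs()
        assert (pairs["r_disease"] >= 0.8).all()


class TestContrast:
    def test_published_pair_round_trips(self, tmp_path):
        from saltnet.io import read_contrast, write_contrast

        pairs = load_coexpression_pairs()
        first = pairs.iloc[0]
        assert (first["gene_1"], first["gene_2"]) == ("WNK1", "CALM1")
        assert first["r_disease"] == pytest.approx(0.9439)
        assert first["r_control"] == pytest.approx(0.5472)
        out = tmp_path / "contrast.tsv"
        write_contrast(pairs, out)
        back = read_contrast(out)
        assert np.allclose(back["r_disease"], pairs["r_disease"], atol=5e-5)
        assert np.allclose(back["r_control"], pairs["r_control"], atol=5e-5)

    def test_empty_disease_edges_give_empty_contrast(self, small_matrix):
        cmap = correlation_map(small_matrix, "control")
        empty = threshold_network(correlation_map(small_matrix, "case"), 1.0)
        contrast = contrast_conditions(empty.iloc[0:0], cmap)
        assert len(contrast) == 0

    def test_case_only_block_contrast(self):
        """A case-only block shows r_disease >= 0.8 with control r near 0."""
        config = SimulationConfig(
            seed=37, n_case=100, n_control=100,
            blocks=(BlockSpec(size=10, rho=0.9, condition="case_only"),),
        )
        matrix, truth = generate_expression(config)
        genes = sorted({g for pair in truth.block_pairs for g in pair})
        disease = correlation_map(matrix, "case", genes)
        control = correlation_map(matrix, "control", genes)
        contrast = contrast_conditions(threshold_network(disease, 0.8), control)
        assert len(contrast) >= 0.9 * len(truth.block_pairs)
        assert (contrast["r_disease"] >= 0.8).all()
        assert abs(contrast["r_control"].mean()) < 0.1


class TestConnectivityAndPrioritization:
    def test_published_connectivity_counts(self):
        """The bundled contrast table reproduces the study's connectivity:
        ENPEP 21, WNK1 20, CYP3A5 6, CTSA 3."""
        counts = connectivity_counts(
            load_coexpression_pairs(), unreported_ssgs()
        )
        assert counts["ENPEP"] == 21
        assert counts["WNK1"] == 20
        assert counts["CYP3A5"] == 6
        assert counts["CTSA"] == 3

    def test_empty_contrast_counts_zero(self):
        empty = load_coexpression_pairs().iloc[0:0]
        assert connectivity_counts(empty, {"ENPEP"}) == {"ENPEP": 0}

    def test_published_status_classification(self):
        """23 co-expressed SSGs against the disease annotation: 8 unreported,
        matching the published classification gene by gene."""
        status = load_ssg_obesity_status()
        labels = classify_reported(status["gene"], obesity_annotation())
        assert sum(1 for v in labels.values() if v == "unreported") == 8
        for rec in status.itertuples(index=False):
            assert labels[rec.gene] == rec.role_in_obesity.lower()

    def test_annotation_edge_cases(self):
        assert set(classify_reported({"A", "B"}, set()).values()) == {"unreported"}
        assert set(classify_reported({"A"}, {"A", "B"}).values()) == {"reported"}

    def test_published_shortlist(self):
        """min_connectivity = 3 over the 8 unreported SSGs selects exactly
        the study's 5 prioritized genes, ranked by connectivity."""
        counts = connectivity_counts(load_coexpression_pairs(), unreported_ssgs())
        reported = {g: "unreported" for g in unreported_ssgs()}
        result = prioritize(counts, reported, min_connectivity=3)
        assert result.selected == ["ENPEP", "WNK1", "CYP3A5", "CTSA", "SLC24A3"]
        assert set(result.selected) == {"ENPEP", "WNK1", "CYP3A5", "SLC24A3", "CTSA"}

    def test_min_connectivity_bounds(self):
        counts = connectivity_counts(load_coexpression_pairs(), unreported_ssgs())
        reported = {g: "unreported" for g in unreported_ssgs()}
        assert len(prioritize(counts, reported, 0).selected) == 8
        assert prioritize(counts, reported, 100).selected == []

    def test_reported_genes_never_selected(self):
        result = prioritize(
            {"A": 10, "B": 10}, {"A": "reported", "B": "unreported"}, 3
        )
        assert result.selected == ["B"]
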