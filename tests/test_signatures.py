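"""Specificity scores, gene-set scores and the DE filter rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmekit import signatures as sg
from tests.conftest import make_expression


def brute_force_cluster_score(norm, labels, gene, focal, quantile=0.25):
    """Independent re-derivation of the verbal rule with plain loops."""
    vals = {c: [] for c in labels.unique()}
    for cell in norm.columns:
        vals[labels[cell]].append(norm.loc[gene, cell])
    nonzero = sorted(v for v in vals[focal] if v > 0)
    if not nonzero:
        return 0.0
    t = float(np.quantile(nonzero, quantile))
    h = {c: sum(1 for v in vs if v > t) / len(vs) for c, vs in vals.items()}
    others = max(h[c] for c in h if c != focal)
    if others == 0:
        return 1.0
    if h[focal] == 0:
        return 0.0
    return max(0.0, 1.0 - others / h[focal])


class TestClusterSpecificity:
    def test_exclusive_gene_scores_exactly_one(self):
        norm, labels = make_expression(
            {"C1": list(range(1, 11)), "C2": [0] * 10, "C3": [0] * 10}
        )
        assert sg.cluster_specificity(norm, labels, "g", "C1") == 1.0

    def test_equal_or_higher_competitor_scores_exactly_zero(self):
        # competitor fraction equal to focal
        norm, labels = make_expression(
            {"C1": [1, 2, 3, 4, 5], "C2": [1, 2, 3, 4, 5]}
        )
        assert sg.cluster_specificity(norm, labels, "g", "C1") == 0.0
        # competitor fraction above focal
        norm2, labels2 = make_expression(
            {"C1": [1, 2, 3, 0, 0], "C2": [4, 5, 6, 7, 8]}
        )
        assert sg.cluster_specificity(norm2, labels2, "g", "C1") == 0.0

    def test_matches_brute_force_on_constructed_matrix(self):
        norm, labels = make_expression(
            {
                "C1": [1, 2, 10, 11, 12, 13, 14, 15, 16, 17],
                "C2": [0, 0, 0, 0, 12, 13, 14, 15, 0, 0],
                "C3": [0, 0, 0, 0, 0, 0, 0, 0, 11, 20],
            }
        )
        expected = brute_force_cluster_score(norm, labels, "g", "C1")
        assert 0.0 < expected < 1.0
        assert sg.cluster_specificity(norm, labels, "g", "C1") == pytest.approx(expected)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(20):
            values = {
                c: list(np.round(rng.gamma(1.0, 2.0, size=12) * rng.integers(0, 2, size=12), 3))
                for c in ("C1", "C2", "C3")
            }
            norm, labels = make_expression(values)
            got = sg.cluster_specificity(norm, labels, "g", "C1")
            want = brute_force_cluster_score(norm, labels, "g", "C1")
            assert got == pytest.approx(want, abs=1e-12)

    def test_silent_in_focal_cluster_scores_zero(self):
        norm, labels = make_expression({"C1": [0] * 5, "C2": [1, 2, 3, 4, 5]})
        assert sg.cluster_specificity(norm, labels, "g", "C1") == 0.0

    def test_unknown_cluster_error(self):
        norm, labels = make_expression({"C1": [1, 2], "C2": [0, 0]})
        with pytest.raises(KeyError):
            sg.cluster_specificity(norm, labels, "g", "C9")

    @given(scale=st.floats(min_value=0.1, max_value=50), power=st.floats(min_value=0.5, max_value=3))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_monotone_rescaling(self, scale, power):
        """The score depends only on ranks relative to a within-data
        quantile, so x -> scale * x**power (monotone, zero-preserving)
        cannot change it."""
        rng = np.random.default_rng(7)
        values = {
            c: list(rng.gamma(1.0, 2.0, size=15) * rng.integers(0, 2, size=15))
            for c in ("C1", "C2", "C3")
        }
        norm, labels = make_expression(values)
        base = sg.cluster_specificity(norm, labels, "g", "C1")
        transformed = scale * norm**power
        assert sg.cluster_specificity(transformed, labels, "g", "C1") == pytest.approx(base)


class TestCellTypeSpecificity:
    def test_exclusive_type_scores_one(self):
        norm, types = make_expression({"T": [1, 2, 3, 4], "B": [0] * 4})
        assert sg.cell_type_specificity(norm, types, "g", "T") == 1.0

    def test_uniform_expression_scores_zero(self):
        norm, types = make_expression({"T": [1, 2, 3, 4], "B": [1, 2, 3, 4]})
        assert sg.cell_type_specificity(norm, types, "g", "T") == 0.0

    def test_constructed_fractions_give_expected_ratio(self):
        """Focal fraction 0.9 vs competitor 0.3 -> score 1 - 1/3."""
        focal = [0.1, 0.1] + list(np.linspace(1, 2, 18))
        other = list(np.linspace(1, 2, 6)) + [0.0] * 14
        norm, types = make_expression({"T": focal, "B": other})
        score = sg.cell_type_specificity(norm, types, "g", "T")
        assert score == pytest.approx(1.0 - (0.3 / 0.9))

    def test_single_type_scores_one_with_warning(self):
        norm, types = make_expression({"T": [1, 2, 3]})
        with pytest.warns(UserWarning, match="single cell type"):
            assert sg.cell_type_specificity(norm, types, "g", "T") == 1.0


class TestIdentifySignatures:
    @staticmethod
    def _two_type_matrix():
        """T cells with 2 clusters; B cells as a second type. TREG_MARKERS
        exclusive to T-cluster C2; 'shared' expressed everywhere."""
        treg_markers = ["IL2RA", "BATF", "FOXP3", "TIGIT", "CTLA4", "ICOS"]
        genes = treg_markers + ["shared"]
        n_c1, n_c2, n_b = 10, 10, 10
        cols = [f"t{i}" for i in range(n_c1 + n_c2)] + [f"b{i}" for i in range(n_b)]
        norm = pd.DataFrame(0.0, index=genes, columns=cols)
        rng = np.random.default_rng(0)
        for g in treg_markers:
            norm.loc[g, cols[n_c1 : n_c1 + n_c2]] = rng.uniform(1, 3, size=n_c2)
        norm.loc["shared"] = rng.uniform(1, 3, size=len(cols))
        cluster_labels = pd.Series(
            ["C1"] * n_c1 + ["C2"] * n_c2, index=cols[: n_c1 + n_c2]
        )
        type_labels = pd.Series(
            ["T"] * (n_c1 + n_c2) + ["B"] * n_b, index=cols
        )
        return norm, cluster_labels, type_labels, treg_markers

    def test_planted_treg_markers_all_flagged(self):
        norm, cl, ty, markers = self._two_type_matrix()
        out = sg.identify_signature_genes(
            {"C2": markers + ["shared"]}, norm, cl, ty, focal_type="T"
        )
        flagged = set(out.loc[out["is_signature"], "gene"])
        assert set(markers) <= flagged
        shared = out.set_index("gene").loc["shared"]
        assert shared["combined"] == 0.0 and not shared["is_signature"]

    def test_combined_is_geometric_mean(self):
        norm, cl, ty, markers = self._two_type_matrix()
        out = sg.identify_signature_genes({"C2": markers}, norm, cl, ty, focal_type="T")
        np.testing.assert_allclose(
            out["combined"] ** 2,
            out["cluster_specificity"] * out["cell_type_specificity"],
            atol=1e-12,
        )

    def test_sorted_by_combined_then_gene(self):
        norm, cl, ty, markers = self._two_type_matrix()
        out = sg.identify_signature_genes(
            {"C2": markers + ["shared"]}, norm, cl, ty, focal_type="T"
        )
        key = list(zip(-out["combined"], out["gene"]))
        assert key == sorted(key)

    def test_zero_cluster_specificity_annihilates(self):
        norm, cl, ty, _ = self._two_type_matrix()
        out = sg.identify_signature_genes({"C2": ["shared"]}, norm, cl, ty, focal_type="T")
        assert out.loc[0, "combined"] == 0.0


class TestGeneSetScore:
    def test_printed_two_cell_example(self):
        norm = pd.DataFrame(
            {"cell1": [1, 2, 3, 4, 5], "cell2": [0, 0, 0, 0, 10]},
            index=["PDCD1", "LAG3", "TIGIT", "HAVCR2", "CTLA4"],
            dtype=float,
        )
        scores, missing = sg.gene_set_score(norm, list(sg.EXHAUSTION_GENES))
        assert scores["cell1"] == 3.0
        assert scores["cell2"] == 2.0
        assert missing == []

    def test_singleton_set_identity(self):
        norm = pd.DataFrame({"c": [1.5, 7.0]}, index=["a", "b"])
        scores, _ = sg.gene_set_score(norm, ["b"], min_coverage=0.0)
        assert scores["c"] == 7.0

    def test_all_zero_cell_scores_zero(self):
        norm = pd.DataFrame({"c": [0.0, 0.0]}, index=["a", "b"])
        scores, _ = sg.gene_set_score(norm, ["a", "b"])
        assert scores["c"] == 0.0

    def test_low_coverage_error_names_missing(self):
        norm = pd.DataFrame({"c": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="NOTTHERE"):
            sg.gene_set_score(norm, ["a", "NOTTHERE", "ALSOGONE"])


class TestDETest:
    def test_null_has_nominal_raw_rate_and_no_bh_hits(self, rng):
        """Permuted labels of one population: ~5% raw p < 0.05, essentially
        nothing past BH at FDR 0.05."""
        n_genes, n = 500, 60
        x = rng.gamma(2.0, 1.0, size=(n_genes, 2 * n)) * rng.integers(0, 2, size=(n_genes, 2 * n))
        cols = [f"c{i}" for i in range(2 * n)]
        norm = pd.DataFrame(np.log1p(x), index=[f"g{i}" for i in range(n_genes)], columns=cols)
        res = sg.de_test(norm, cols[:n], cols[n:])
        raw_rate = (res["p_value"] < 0.05).mean()
        assert 0.02 <= raw_rate <= 0.09
        assert res["passes_filter"].sum() <= 2

    def test_planted_shift_passes_all_filters(self, rng):
        n = 200
        cols = [f"c{i}" for i in range(2 * n)]
        base = rng.gamma(2.0, 1.0, size=2 * n) * (rng.uniform(size=2 * n) < 0.5)
        shifted = base.copy()
        shifted[:n] = rng.gamma(2.0, 4.0, size=n) * (rng.uniform(size=n) < 0.6)
        norm = pd.DataFrame(
            np.log1p(np.vstack([shifted, base])), index=["de", "null"], columns=cols
        )
        res = sg.de_test(norm, cols[:n], cols[n:])
        assert res.loc["de", "passes_filter"]
        assert not res.loc["null", "passes_filter"]

    def test_rare_gene_fails_percent_filter(self, rng):
        n = 100
        cols = [f"c{i}" for i in range(2 * n)]
        x = np.zeros(2 * n)
        x[:5] = 50.0  # 5% of group A, 0% of group B -> max pct 0.05 < 0.10
        norm = pd.DataFrame([x], index=["rare"], columns=cols)
        res = sg.de_test(norm, cols[:n], cols[n:])
        assert not res.loc["rare", "passes_filter"]
        assert res.loc["rare", "pct_a"] == pytest.approx(0.05)

    def test_small_group_error(self):
        norm = pd.DataFrame(np.ones((2, 5)), columns=[f"c{i}" for i in range(5)])
        with pytest.raises(ValueError, match="3 cells"):
            sg.de_test(norm, ["c0", "c1"], ["c2", "c3", "c4"])
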