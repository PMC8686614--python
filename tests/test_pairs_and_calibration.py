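import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crtscreen import (
    bh_discoveries,
    flag_miscalibrated,
    ks_uniformity,
    make_cis_pairs,
    make_insilico_negative_pairs,
)


def genes_frame(rows):
    return pd.DataFrame(rows, columns=["id", "chrom", "position", "protein_coding", "is_tf"])


def grnas_frame(rows):
    return pd.DataFrame(rows, columns=["id", "chrom", "position", "targeting_class"])


class TestCisPairs:
    def test_window_boundary_inclusive(self):
        genes = genes_frame([("g1", "chr1", 2_000_000, True, False)])
        grnas = grnas_frame(
            [
                ("r_in", "chr1", 2_999_999, "candidate_enhancer"),
                ("r_edge", "chr1", 3_000_000, "candidate_enhancer"),
                ("r_out", "chr1", 3_000_001, "candidate_enhancer"),
            ]
        )
        pairs = make_cis_pairs(genes, grnas)
        assert set(pairs["grna_id"]) == {"r_in", "r_edge"}

    def test_different_chromosomes_never_pair(self):
        genes = genes_frame([("g1", "chr1", 100, True, False)])
        grnas = grnas_frame([("r1", "chr2", 100, "candidate_enhancer")])
        with pytest.raises(ValueError, match="chromosome"):
            # chr2 absent from gene table entirely -> naming error
            make_cis_pairs(genes, grnas)
        genes2 = genes_frame(
            [("g1", "chr1", 100, True, False), ("g2", "chr2", 10**8, True, False)]
        )
        pairs = make_cis_pairs(genes2, grnas)
        assert pairs.empty  # same-chrom gene is 100 Mb away

    def test_cartesian_within_window(self):
        genes = genes_frame(
            [("g1", "chr1", 1_000_000, True, False), ("g2", "chr1", 1_200_000, True, False)]
        )
        grnas = grnas_frame(
            [
                ("r1", "chr1", 1_100_000, "candidate_enhancer"),
                ("r2", "chr1", 1_300_000, "candidate_enhancer"),
            ]
        )
        assert len(make_cis_pairs(genes, grnas)) == 4

    def test_restricted_to_protein_coding_and_enhancer_class(self):
        genes = genes_frame(
            [("g1", "chr1", 500, True, False), ("g_nc", "chr1", 600, False, False)]
        )
        grnas = grnas_frame(
            [("r1", "chr1", 700, "candidate_enhancer"), ("r_nt", "chr1", 800, "non_targeting")]
        )
        pairs = make_cis_pairs(genes, grnas)
        assert pairs["gene_id"].tolist() == ["g1"] and pairs["grna_id"].tolist() == ["r1"]

    def test_midpoint_from_interval(self):
        genes = genes_frame([("g1", "chr1", 0, True, False)])
        grnas = pd.DataFrame(
            {"id": ["r1"], "chrom": ["chr1"], "start": [999_990], "end": [1_000_030],
             "targeting_class": ["candidate_enhancer"]}
        )
        # midpoint 1,000,010 > 1 Mb -> excluded
        assert make_cis_pairs(genes, grnas).empty

    def test_input_order_invariance(self):
        rng = np.random.default_rng(0)
        genes = genes_frame(
            [(f"g{i}", "chr1", int(p), True, False) for i, p in enumerate(rng.integers(0, 5_000_000, 20))]
        )
        grnas = grnas_frame(
            [(f"r{i}", "chr1", int(p), "candidate_enhancer") for i, p in enumerate(rng.integers(0, 5_000_000, 20))]
        )
        a = make_cis_pairs(genes, grnas)
        b = make_cis_pairs(genes.sample(frac=1, random_state=1), grnas.sample(frac=1, random_state=2))
        pd.testing.assert_frame_equal(a, b)


class TestNegativeControlPairs:
    def _fixture(self, n_grnas=3, n_genes=10):
        genes = [("tf1", "chr1", 5_000_000, True, True)]
        genes += [(f"g{i}", "chr2", 1000 * i, True, False) for i in range(n_genes)]
        grnas = [(f"r{i}", "chr1", 10_000_000 + i, "candidate_enhancer") for i in range(n_grnas)]
        return genes_frame(genes), grnas_frame(grnas)

    def test_count_is_eligible_times_cap(self):
        genes, grnas = self._fixture(n_grnas=3, n_genes=10)
        pairs = make_insilico_negative_pairs(genes, grnas, ["tf1"], genes_per_grna=2, seed=0)
        assert len(pairs) == 6

    def test_grna_near_tf_excluded(self):
        genes, grnas = self._fixture()
        near = grnas_frame([("r_near", "chr1", 5_500_000, "candidate_enhancer")])
        pairs = make_insilico_negative_pairs(
            pd.concat([genes]), pd.concat([grnas, near]), ["tf1"], genes_per_grna=2, seed=0
        )
        assert "r_near" not in set(pairs["grna_id"])

    def test_tf_genes_and_same_chromosome_genes_excluded(self):
        genes, grnas = self._fixture()
        extra = genes_frame(
            [("g_same", "chr1", 99_000_000, True, False), ("tf2", "chr2", 50, True, True)]
        )
        pairs = make_insilico_negative_pairs(
            pd.concat([genes, extra]), grnas, ["tf1", "tf2"], genes_per_grna=100, seed=0
        )
        assert "g_same" not in set(pairs["gene_id"])
        assert "tf2" not in set(pairs["gene_id"])

    def test_downsample_cap_and_reproducibility(self):
        """169 eligible gRNAs x cap 500 -> 84,500 pairs; seed-stable downsample."""
        rng = np.random.default_rng(1)
        genes = [("tf1", "chr1", 0, True, True)]
        genes += [(f"g{i}", f"chr{2 + i % 3}", int(p), True, False)
                  for i, p in enumerate(rng.integers(0, 10**8, 700))]
        grnas = [(f"r{i}", "chr1", 2_000_000 + 1000 * i, "candidate_enhancer")
                 for i in range(169)]
        gdf, rdf = genes_frame(genes), grnas_frame(grnas)
        pairs = make_insilico_negative_pairs(gdf, rdf, ["tf1"], genes_per_grna=500, seed=3)
        assert len(pairs) == 169 * 500 == 84_500
        assert (pairs.groupby("grna_id").size() == 500).all()
        again = make_insilico_negative_pairs(gdf, rdf, ["tf1"], genes_per_grna=500, seed=3)
        pd.testing.assert_frame_equal(pairs, again)
        other = make_insilico_negative_pairs(gdf, rdf, ["tf1"], genes_per_grna=500, seed=4)
        assert set(other["grna_id"]) == set(pairs["grna_id"])
        assert not pairs["gene_id"].equals(other["gene_id"])  # downsample changed

    def test_fewer_genes_than_cap_keeps_all(self, caplog):
        genes, grnas = self._fixture(n_grnas=1, n_genes=4)
        with caplog.at_level("WARNING", logger="crtscreen"):
            pairs = make_insilico_negative_pairs(genes, grnas, ["tf1"], genes_per_grna=500, seed=0)
        assert len(pairs) == 4
        assert any("keeping all" in r.message for r in caplog.records)


class TestKsUniformity:
    def test_near_perfect_uniform_grid(self):
        n = 99
        grid = np.arange(1, n + 1) / (n + 1)
        stat, _ = ks_uniformity(grid)
        assert stat <= 0.02

    def test_point_mass_at_half(self):
        stat, pval = ks_uniformity(np.full(50, 0.5))
        assert stat == pytest.approx(0.5)
        assert pval < 1e-10

    def test_bonferroni_flag_threshold(self):
        ks_p = np.full(1000, 4.9e-5)
        assert flag_miscalibrated(ks_p, alpha=0.05).all()  # threshold 5e-5
        ks_p2 = np.full(1000, 5.1e-5)
        assert not flag_miscalibrated(ks_p2, alpha=0.05).any()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ks_uniformity([0.1, 0.2])
        with pytest.raises(ValueError):
            ks_uniformity([0.0, 0.5, 0.5, 0.5, 0.5])


def bh_oracle(p, fdr):
    """Brute-force BH step-up: largest k with p_(k) <= fdr*k/n; reject the k smallest."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, n + 1):
        if p[order[k - 1]] <= fdr * k / n:
            k_max = k
    reject = np.zeros(n, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestBhDiscoveries:
    def test_hand_example(self):
        p = np.array([0.01, 0.02, 0.04, 0.9])
        assert bh_discoveries(p, fdr=0.1).sum() == 3

    def test_all_ones_no_rejections(self):
        assert bh_discoveries(np.ones(10), fdr=0.1).sum() == 0

    def test_all_below_smallest_threshold(self):
        n = 8
        p = np.full(n, 0.1 / n / 2)
        assert bh_discoveries(p, fdr=0.1).all()

    @settings(max_examples=100, deadline=None)
    @given(
        p=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20),
        fdr=st.sampled_from([0.05, 0.1, 0.2]),
    )
    def test_matches_brute_force_oracle(self, p, fdr):
        np.testing.assert_array_equal(bh_discoveries(p, fdr), bh_oracle(p, fdr))
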