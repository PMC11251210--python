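import numpy as np
import pytest
from conftest import make_matrix
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from svedne import (
    MISSING,
    GeneticMap,
    ValidationError,
    decay_curve,
    fill_genetic_distance,
    ld_scores,
    pairwise_r2,
)
from svedne.ld_engine import LDPairTable

M = MISSING


def brute_force_r2(x, y):
    """Independent oracle: Pearson r² over pairwise-complete samples, or None
    when fewer than 2 shared calls or either site is monomorphic among them."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x >= 0) & (y >= 0)
    xs, ys = x[ok], y[ok]
    if len(xs) < 2 or len(set(xs)) < 2 or len(set(ys)) < 2:
        return None
    r, _ = sps.pearsonr(xs, ys)
    return r * r


class TestPairwiseR2:
    def test_identical_columns_give_one(self):
        G = make_matrix([[0, 1, 2, 0], [0, 1, 2, 0]], positions=[100, 200])
        T = pairwise_r2(G)
        assert T.table["r2"].tolist() == pytest.approx([1.0])

    def test_orthogonal_columns_give_zero(self):
        G = make_matrix([[0, 0, 2, 2], [0, 2, 0, 2]], positions=[100, 200])
        assert pairwise_r2(G).table["r2"].tolist() == pytest.approx([0.0])

    def test_hand_computed_pair(self):
        G = make_matrix([[0, 1, 2, 0, 1, 2], [0, 1, 1, 0, 2, 2]], positions=[100, 200])
        assert pairwise_r2(G).table["r2"].tolist() == pytest.approx([0.5625])

    def test_window_excludes_distant_pairs(self):
        G = make_matrix([[0, 1, 2, 0], [0, 1, 2, 0]], positions=[1, 800_001])
        assert len(pairwise_r2(G, max_bp=750_000)) == 0

    def test_inter_chromosomal_pairs_never_emitted(self):
        a = make_matrix([[0, 1, 2, 0]], positions=[100], chrom="chr1")
        b = make_matrix([[0, 1, 2, 0]], positions=[150], chrom="chr2")
        G = make_matrix([[0, 1, 2, 0]], positions=[100])
        G.variants = a.variants + b.variants
        G.dosage = np.concatenate([a.dosage, b.dosage], axis=1)
        assert len(pairwise_r2(G)) == 0

    def test_monomorphic_pairs_skipped_and_counted(self):
        G = make_matrix([[0, 0, 0, 0], [0, 1, 2, 0]], positions=[100, 200])
        T = pairwise_r2(G)
        assert len(T) == 0 and T.n_skipped == 1

    def test_pairwise_complete_deletion_matches_oracle(self):
        x = [0, 1, M, 2, 0, 1]
        y = [M, 1, 2, 2, 0, 0]
        G = make_matrix([x, y], positions=[100, 200])
        expected = brute_force_r2(x, y)
        assert pairwise_r2(G).table["r2"].tolist() == pytest.approx([expected])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 9)
        m = rng.integers(2, 7)
        cols = rng.choice([M, 0, 1, 2], size=(m, n), p=[0.15, 0.35, 0.2, 0.3])
        pos = np.sort(rng.choice(np.arange(1, 5000), size=m, replace=False))
        G = make_matrix(list(cols), positions=pos)
        T = pairwise_r2(G, max_bp=10_000)
        got = {(r.idx_i, r.idx_j): r.r2 for r in T.table.itertuples()}
        for i in range(m):
            for j in range(i + 1, m):
                want = brute_force_r2(cols[i], cols[j])
                if want is None:
                    assert (i, j) not in got
                else:
                    assert got[(i, j)] == pytest.approx(want, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_invariant_under_allele_label_swap(self, seed):
        rng = np.random.default_rng(seed)
        cols = rng.choice([M, 0, 1, 2], size=(3, 8), p=[0.1, 0.4, 0.2, 0.3])
        G = pairwise_r2(make_matrix(list(cols), positions=[10, 20, 30]), max_bp=100)
        flipped = np.where(cols[1] >= 0, 2 - cols[1], M)
        cols2 = cols.copy()
        cols2[1] = flipped
        G2 = pairwise_r2(make_matrix(list(cols2), positions=[10, 20, 30]), max_bp=100)
        np.testing.assert_allclose(
            G.table["r2"].to_numpy(), G2.table["r2"].to_numpy(), atol=1e-12
        )


class TestDecayCurve:
    def test_single_and_averaged_bins(self):
        # r2 by construction: identical cols -> 1; orthogonal -> 0
        G = make_matrix(
            [[0, 1, 2, 0], [0, 1, 2, 0], [0, 2, 0, 2]], positions=[100, 200, 90_000]
        )
        T = pairwise_r2(G, max_bp=200_000)
        dc = decay_curve(T, bin_width_bp=100_000)
        assert dc.table["n_pairs"].tolist() == [3]
        assert dc.table["mean_r2"].iloc[0] == pytest.approx(np.mean(T.table["r2"]))

    def test_counts_conserved_across_bins(self, sim_panel):
        G, _ = sim_panel
        T = pairwise_r2(G, max_bp=750_000)
        dc = decay_curve(T, bin_width_bp=50_000)
        assert dc.table["n_pairs"].sum() == len(T)

    def test_chromosome_scope(self, sim_panel):
        G, _ = sim_panel
        T = pairwise_r2(G, max_bp=750_000)
        dc1 = decay_curve(T, bin_width_bp=50_000, scope="chr1")
        dc2 = decay_curve(T, bin_width_bp=50_000, scope="chr2")
        assert dc1.table["n_pairs"].sum() + dc2.table["n_pairs"].sum() == len(T)

    def test_bad_bin_width(self):
        G = make_matrix([[0, 1, 2, 0], [0, 1, 2, 0]], positions=[100, 200])
        with pytest.raises(ValidationError):
            decay_curve(pairwise_r2(G), bin_width_bp=0)

    def test_mean_r2_declines_with_distance(self, sim_panel):
        """Drift-recombination equilibrium: bin means trend down with distance."""
        G, _ = sim_panel
        dc = decay_curve(pairwise_r2(G, max_bp=750_000), bin_width_bp=50_000)
        rho, _ = sps.spearmanr(dc.table["bin_left_bp"], dc.table["mean_r2"])
        assert rho < 0


class TestLDScores:
    def test_two_identical_snps_score_one(self):
        G = make_matrix([[0, 1, 2, 0], [0, 1, 2, 0]], positions=[1000, 2000])
        track = ld_scores(G)
        assert track.table["mean_r2"].tolist() == pytest.approx([1.0, 1.0])

    def test_isolated_snp_is_missing(self):
        G = make_matrix([[0, 1, 2, 0], [0, 1, 2, 0]], positions=[1, 2_000_000])
        track = ld_scores(G, window_bp=1_000_000)
        assert track.table["n_neighbors"].tolist() == [0, 0]
        assert track.table["mean_r2"].isna().all()

    def test_three_snp_hand_average(self):
        """Pairwise r2 {(1,2): 0.8, (1,3): 0.2, (2,3): 0.5} -> per-SNP means
        (0.5, 0.65, 0.35), independent of how the pairs were computed."""
        import pandas as pd

        G = make_matrix(
            [[0, 1, 2, 0], [0, 1, 2, 0], [0, 1, 2, 0]], positions=[100, 200, 300]
        )
        pairs = LDPairTable(
            table=pd.DataFrame(
                {
                    "chrom": "chr1",
                    "idx_i": [0, 0, 1],
                    "idx_j": [1, 2, 2],
                    "pos_i": [100, 100, 200],
                    "pos_j": [200, 300, 300],
                    "bp_dist": [100, 200, 100],
                    "r2": [0.8, 0.2, 0.5],
                    "c": np.nan,
                }
            ),
            max_bp=1_000_000,
        )
        track = ld_scores(G, window_bp=1_000_000, r2_cutoff=0.0, pairs=pairs)
        assert track.table["mean_r2"].tolist() == pytest.approx([0.5, 0.65, 0.35])

    def test_cutoff_excludes_weak_pairs(self):
        G = make_matrix(
            [[0, 1, 2, 0], [0, 1, 2, 0], [0, 2, 0, 2]], positions=[100, 200, 300]
        )
        track = ld_scores(G, r2_cutoff=0.5)
        # only the identical pair (r2=1) survives; third SNP has no neighbor
        assert track.table["mean_r2"].tolist()[:2] == pytest.approx([1.0, 1.0])
        assert np.isnan(track.table["mean_r2"].iloc[2])

    def test_single_neighbor_equals_pair_r2(self):
        G = make_matrix([[0, 1, 2, 0, 1, 2], [0, 1, 1, 0, 2, 2]], positions=[100, 200])
        track = ld_scores(G)
        assert track.table["mean_r2"].tolist() == pytest.approx([0.5625, 0.5625])

    def test_narrow_pair_table_rejected(self):
        G = make_matrix([[0, 1, 2, 0], [0, 1, 2, 0]], positions=[100, 200])
        pairs = pairwise_r2(G, max_bp=1000)
        with pytest.raises(ValidationError, match="max_bp"):
            ld_scores(G, window_bp=1_000_000, pairs=pairs)


class TestExports:
    def test_pair_table_tsv_layout(self, tmp_path):
        G = make_matrix([[0, 1, 2, 0], [0, 1, 2, 0]], positions=[100, 200])
        T = fill_genetic_distance(pairwise_r2(G), GeneticMap(default_ratio=1.0))
        text = T.to_tsv(tmp_path / "pairs.tsv").read_text().splitlines()
        assert text[0].split("\t") == ["CHR", "POS_A", "POS_B", "BP_DIST", "C_MORGAN", "R2"]
        assert text[1].split("\t")[:4] == ["chr1", "100", "200", "100"]

    def test_ld_score_bed_is_zero_based_half_open(self, tmp_path):
        G = make_matrix([[0, 1, 2, 0], [0, 1, 2, 0]], positions=[1000, 2000])
        bed = ld_scores(G).to_bed(tmp_path / "t.bed").read_text().splitlines()
        chrom, start, end, _, score = bed[0].split("\t")
        assert (chrom, start, end) == ("chr1", "999", "1000")
        assert float(score) == pytest.approx(1.0)
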