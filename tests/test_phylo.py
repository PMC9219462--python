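import math

import numpy as np
import pytest

from fishdiv import (
    cophenetic,
    k2p_distance,
    mpd_observed,
    nj_tree,
    nri,
    nri_table,
    null_mpd,
    pdistance,
    read_fasta,
    yule_tree,
)
from fishdiv.assemblage import DissimilarityMatrix
from fishdiv.phylo import NullDistribution, SequenceSet


def _dm(values, labels):
    return DissimilarityMatrix(labels=list(labels), values=np.asarray(values, float))


class TestFastaAndDistances:
    def test_read_fasta_normalizes(self, tmp_path):
        path = tmp_path / "aln.fasta"
        path.write_text(">sp1\nacgtacgtacgt\n>sp2\nACGTACGTACGn\n>sp3\nACGTACGTACGT\n")
        seqs = read_fasta(path)
        assert seqs.n == 3 and seqs.length == 12
        assert seqs.to_strings()["sp2"].endswith("N")

    def test_ragged_alignment_rejected(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a\nACGTACGTAC\n>b\nACGTACGTACGT\n")
        with pytest.raises(ValueError, match="unequal"):
            read_fasta(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">a\nACGT\n>a\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(path)

    def test_pdistance_values(self):
        seqs = SequenceSet.from_strings(["a", "b", "c"], ["ACGT", "GCGT", "ACG-"])
        d = pdistance(seqs).to_frame()
        assert d.loc["a", "b"] == pytest.approx(0.25)
        assert d.loc["a", "c"] == 0.0  # gap excluded pairwise, 3 comparable sites

    def test_k2p_pure_transition(self):
        seqs = SequenceSet.from_strings(["a", "b"], ["ACGT", "GCGT"])  # P=1/4, Q=0
        assert k2p_distance(seqs).values[0, 1] == pytest.approx(0.5 * math.log(2))

    def test_k2p_pure_transversion(self):
        seqs = SequenceSet.from_strings(["a", "b"], ["ACGT", "CCGT"])  # P=0, Q=1/4
        expected = 0.5 * math.log(1 / 0.75) + 0.25 * math.log(2)
        assert k2p_distance(seqs).values[0, 1] == pytest.approx(expected)

    def test_k2p_saturated_pair_rejected(self):
        seqs = SequenceSet.from_strings(["a", "b"], ["AAAA", "GGGG"])
        with pytest.raises(ValueError, match="saturated"):
            k2p_distance(seqs)

    def test_identical_sequences_zero(self):
        seqs = SequenceSet.from_strings(["a", "b"], ["ACGT", "ACGT"])
        assert pdistance(seqs).values[0, 1] == 0.0
        assert k2p_distance(seqs).values[0, 1] == 0.0


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = [[0, 3, 4], [3, 0, 5], [4, 5, 0]]
        tree = nj_tree(_dm(D, "ABC"))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_additive_four_taxon_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4))
        D = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        tree = nj_tree(_dm(D, "ABCD"))
        co = cophenetic(tree).to_frame().loc[list("ABCD"), list("ABCD")]
        assert np.allclose(co.to_numpy(), D)

    def test_exact_on_random_additive_matrices(self):
        # 100 random pure-birth trees, <= 12 leaves: cophenetic -> NJ round trip
        rng = np.random.default_rng(0)
        for rep in range(100):
            n = int(rng.integers(4, 13))
            tree = yule_tree(n, seed=rng.integers(2**31), target_height=0.5)
            D0 = cophenetic(tree)
            rebuilt = nj_tree(D0)
            co = cophenetic(rebuilt).to_frame().loc[D0.labels, D0.labels]
            assert np.allclose(co.to_numpy(), D0.values, atol=1e-9)

    def test_matches_independent_nj_implementation(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        tree = yule_tree(7, seed=11, target_height=0.4)
        D0 = cophenetic(tree)
        theirs = sk_nj(SkDM(D0.values, ids=D0.labels))
        tt = theirs.tip_tip_distances()
        theirs_df = cophenetic(theirs).to_frame().loc[D0.labels, D0.labels]
        mine = cophenetic(nj_tree(D0)).to_frame().loc[D0.labels, D0.labels]
        assert np.allclose(mine.to_numpy(), theirs_df.to_numpy(), atol=1e-6)

    def test_negative_branch_clamped(self, caplog):
        # non-additive matrix known to induce a negative NJ branch estimate
        D = [[0, 0.1, 0.9, 0.9], [0.1, 0, 0.2, 0.9], [0.9, 0.2, 0, 0.1], [0.9, 0.9, 0.1, 0]]
        with caplog.at_level("WARNING"):
            tree = nj_tree(_dm(D, "ABCD"))
        assert all((t.length or 0) >= 0 for t in tree.traverse())

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(_dm([[0, 1], [1, 0]], "AB"))


class TestCophenetic:
    def test_two_leaf_path(self):
        import io

        from skbio import TreeNode

        tree = TreeNode.read(io.StringIO("(A:1,B:2);"))
        assert cophenetic(tree).to_frame().loc["A", "B"] == pytest.approx(3.0)

    def test_symmetry_zero_diagonal_on_random_trees(self):
        tree = yule_tree(9, seed=5)
        d = cophenetic(tree)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)


class TestMpdAndNull:
    D3 = _dm([[0, 2, 4], [2, 0, 6], [4, 6, 0]], ["x", "y", "z"])

    def test_two_species_is_their_distance(self):
        assert mpd_observed(["x", "y"], self.D3) == 2.0

    def test_three_species_mean_of_pairs(self):
        assert mpd_observed(["x", "y", "z"], self.D3) == pytest.approx(4.0)

    def test_single_species_undefined(self, caplog):
        with caplog.at_level("WARNING"):
            assert mpd_observed(["x"], self.D3) is None

    def test_null_support_is_pairwise_distances(self):
        null = null_mpd(2, self.D3, n_rand=3000, seed=0)
        assert set(np.round(null.values, 9)) <= {2.0, 4.0, 6.0}
        assert null.mean == pytest.approx(4.0, abs=0.15)

    def test_null_deterministic_under_seed(self):
        a = null_mpd(2, self.D3, n_rand=99, seed=42)
        b = null_mpd(2, self.D3, n_rand=99, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_degenerate_full_pool_draw(self):
        null = null_mpd(3, self.D3, n_rand=50, seed=0)
        assert null.sd == 0.0
        assert nri(4.0, null).nri is None

    def test_richness_exceeding_pool_rejected(self):
        with pytest.raises(ValueError):
            null_mpd(4, self.D3, n_rand=10)


class TestNri:
    @pytest.mark.parametrize(
        "mean,obs,sd,printed",
        [
            (0.159, 0.149, 0.017, 0.587),  # per-river 2008 row
            (0.188, 0.171, 0.017, 1.002),  # pooled 2008 row
            (0.131, 0.124, 0.014, 0.510),  # pooled 2021 row
        ],
    )
    def test_reported_rows_reproduced_from_printed_inputs(self, mean, obs, sd, printed):
        null = NullDistribution("row", np.array([mean - sd, mean + sd]))
        assert null.mean == pytest.approx(mean)
        assert null.sd == pytest.approx(sd)
        row = nri(obs, null)
        assert row.nri == pytest.approx(printed, abs=0.01 + 1e-12)

    def test_observed_equal_to_mean_is_indeterminate(self):
        null = NullDistribution("c", np.array([1.0, 3.0]))
        row = nri(2.0, null)
        assert row.nri == 0.0 and row.assembly_call == "indeterminate"

    def test_call_is_pure_function_of_sign(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            vals = rng.random(50)
            null = NullDistribution("c", vals)
            row = nri(rng.random(), null)
            if row.nri is None:
                continue
            expected = (
                "environmental_filtering"
                if row.nri > 0
                else "competition"
                if row.nri < 0
                else "indeterminate"
            )
            assert row.assembly_call == expected


class TestNriTable:
    def test_table_layout_and_na_rows(self, default_bundle):
        b = default_bundle
        table = nri_table(b.counts_a, b.distances, n_rand=99, seed=0)
        assert list(table.columns) == [
            "mpd_null_mean",
            "mpd_obs",
            "mpd_null_sd",
            "NRI",
            "assembly_call",
        ]
        assert table.index[-1] == "Total"
        # year-specific pool: pooled community spans the pool -> NA by design
        assert np.isnan(table.loc["Total", "NRI"])

    def test_union_pool_gives_informative_total(self, default_bundle):
        b = default_bundle
        table = nri_table(
            b.counts_a, b.distances, pool=list(b.distances.labels), n_rand=199, seed=0
        )
        assert np.isfinite(table.loc["Total", "NRI"])

    def test_site_with_one_species_gets_na_row(self, default_bundle):
        b = default_bundle
        data = b.counts_a.data.copy()
        keep = data.columns[data.loc[data.index[0]] > 0][:1]
        data.loc[data.index[0], [c for c in data.columns if c not in set(keep)]] = 0
        from fishdiv import CommunityMatrix

        cm = CommunityMatrix(data, year=2008, kind="count")
        table = nri_table(cm, b.distances, n_rand=99, seed=0)
        assert table.loc[data.index[0], "assembly_call"] == "indeterminate"
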