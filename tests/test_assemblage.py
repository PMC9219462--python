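from itertools import combinations, permutations, product

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from fishdiv import (
    CommunityMatrix,
    anosim,
    bray_curtis,
    fourth_root_transform,
    nmds,
    simper,
    upgma,
)
from fishdiv.assemblage import DissimilarityMatrix


def _cm(rows, kind="count"):
    rows = np.asarray(rows)
    return CommunityMatrix(
        pd.DataFrame(
            rows,
            index=[f"site{i}" for i in range(rows.shape[0])],
            columns=[f"sp{j}" for j in range(rows.shape[1])],
        ),
        kind=kind,
    )


def _dm(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"s{i}" for i in range(values.shape[0])]
    return DissimilarityMatrix(labels=labels, values=values)


class TestTransformAndBray:
    def test_fourth_root_values(self):
        cm = _cm([[16, 0], [1, 81]])
        t = fourth_root_transform(cm)
        assert t.data.to_numpy().tolist() == [[2.0, 0.0], [1.0, 3.0]]

    def test_fourth_root_is_monotone(self):
        x = np.sort(np.random.default_rng(0).random(20) * 100)
        t = fourth_root_transform(_cm([x], kind="biomass"))
        assert (np.diff(t.data.to_numpy()[0]) >= 0).all()

    def test_bray_identical_and_disjoint(self):
        d = bray_curtis(_cm([[1, 2, 3], [1, 2, 3]]))
        assert d.values[0, 1] == 0.0
        d = bray_curtis(_cm([[1, 2, 0, 0], [0, 0, 3, 4]]))
        assert d.values[0, 1] == 1.0

    def test_bray_hand_arithmetic(self):
        d = bray_curtis(_cm([[1, 2, 3], [2, 2, 1]]))
        assert d.values[0, 1] == pytest.approx(3 / 11)

    def test_bray_empty_pair_convention(self, caplog):
        with caplog.at_level("WARNING"):
            d = bray_curtis(_cm([[0, 0], [0, 0], [1, 1]]))
        assert d.values[0, 1] == 0.0
        assert any("empty" in r.message for r in caplog.records)

    def test_scale_invariance_only_when_sites_scale_together(self):
        rows = np.array([[1, 4, 0], [2, 0, 3]])
        base = bray_curtis(_cm(rows))
        both = bray_curtis(_cm(rows * 5))
        assert both.values[0, 1] == pytest.approx(base.values[0, 1])
        one = bray_curtis(_cm(np.vstack([rows[0] * 5, rows[1]])))
        assert one.values[0, 1] != pytest.approx(base.values[0, 1])


class TestUpgma:
    def test_two_sites_merge_at_their_distance(self):
        dend = upgma(_dm([[0, 0.4], [0.4, 0]]))
        assert dend.merge_heights.tolist() == [0.4]

    def test_three_site_average_step(self):
        D = [[0, 0.2, 0.8], [0.2, 0, 0.8], [0.8, 0.8, 0]]
        dend = upgma(_dm(D, labels=["A", "B", "C"]))
        assert dend.merge_heights.tolist() == pytest.approx([0.2, 0.8])

    def test_ultrametric_input_reproduced_exactly(self):
        # heights 0.1 (AB), 0.2 (CD), 0.6 (all)
        D = np.array(
            [
                [0, 0.1, 0.6, 0.6],
                [0.1, 0, 0.6, 0.6],
                [0.6, 0.6, 0, 0.2],
                [0.6, 0.6, 0.2, 0],
            ]
        )
        dend = upgma(_dm(D, labels=list("ABCD")))
        assert dend.merge_heights.tolist() == pytest.approx([0.1, 0.2, 0.6])

    def test_newick_round_trip_matches_heights(self):
        import io

        from skbio import TreeNode

        D = np.array(
            [
                [0, 0.1, 0.6, 0.6],
                [0.1, 0, 0.6, 0.6],
                [0.6, 0.6, 0, 0.2],
                [0.6, 0.6, 0.2, 0],
            ]
        )
        dend = upgma(_dm(D, labels=list("ABCD")))
        tree = TreeNode.read(io.StringIO(dend.to_newick()))
        tt = tree.tip_tip_distances()
        back = pd.DataFrame(tt.data, index=tt.ids, columns=tt.ids)
        assert back.loc["A", "B"] == pytest.approx(0.1)
        assert back.loc["A", "C"] == pytest.approx(0.6)

    def test_cut_into_groups(self):
        D = [[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]]
        groups = upgma(_dm(D, labels=["A", "B", "C"])).cut(2)
        assert groups["A"] == groups["B"] != groups["C"]


class TestNmds:
    def test_embeddable_configuration_has_near_zero_stress(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 2))
        res = nmds(_dm(squareform(pdist(pts))), n_restarts=20, seed=0)
        assert res.stress < 0.01
        assert np.allclose(res.configuration.mean(axis=0), 0, atol=1e-8)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 3))
        D = squareform(pdist(pts))
        s1 = nmds(_dm(D), n_restarts=20, seed=0).stress
        s2 = nmds(_dm(np.sqrt(D)), n_restarts=20, seed=0).stress
        assert abs(s1 - s2) < 5e-3

    def test_stress_monotone_in_dimension(self):
        rng = np.random.default_rng(3)
        D = squareform(pdist(rng.random((9, 6))))
        hi = nmds(_dm(D), k=2, n_restarts=20, seed=0).stress
        lo = nmds(_dm(D), k=6, n_restarts=20, seed=0).stress
        assert hi > 0.01  # genuinely unembeddable in the plane
        assert lo <= hi + 1e-3

    def test_non_finite_rejected(self):
        bad = np.array([[0, np.inf], [np.inf, 0]])
        with pytest.raises(ValueError):
            nmds(_dm(bad))


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        # all between-group distances exceed all within-group distances
        D = np.array(
            [
                [0.0, 0.1, 0.9, 0.8],
                [0.1, 0.0, 0.85, 0.95],
                [0.9, 0.85, 0.0, 0.2],
                [0.8, 0.95, 0.2, 0.0],
            ]
        )
        res = anosim(_dm(D), ["g1", "g1", "g2", "g2"], n_permutations=99, seed=0)
        assert res.R == pytest.approx(1.0)
        assert 0 < res.p_value <= 1

    def test_r_matches_skbio(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(4)
        pts = rng.random((8, 3))
        D = squareform(pdist(pts))
        labels = ["a"] * 4 + ["b"] * 4
        mine = anosim(_dm(D), labels, n_permutations=99, seed=0)
        theirs = sk_anosim(SkDM(D), grouping=labels, permutations=0)
        assert mine.R == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_null_centering_of_r(self):
        rng = np.random.default_rng(5)
        D = squareform(pdist(rng.random((8, 2))))
        ranks = rankdata(squareform(D, checks=False))
        ii, jj = np.triu_indices(8, k=1)
        rs = []
        base = np.array(["a"] * 4 + ["b"] * 4)
        m = 8 * 7 / 2
        for _ in range(2000):
            perm = rng.permutation(base)
            w = perm[ii] == perm[jj]
            rs.append((ranks[~w].mean() - ranks[w].mean()) / (m / 2))
        assert abs(np.mean(rs)) < 0.02

    def test_permutation_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        D = squareform(pdist(rng.random((6, 2))))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        dm = _dm(D)
        res = anosim(dm, list(labels), n_permutations=999, seed=1)
        ranks = rankdata(squareform(D, checks=False))
        ii, jj = np.triu_indices(6, k=1)
        m = 6 * 5 / 2

        def r_of(lab):
            lab = np.asarray(lab)
            w = lab[ii] == lab[jj]
            return (ranks[~w].mean() - ranks[w].mean()) / (m / 2)

        exact = np.mean([r_of(p) >= res.R - 1e-12 for p in permutations(labels)])
        assert res.p_value == pytest.approx(exact, abs=0.05)

    def test_single_group_rejected(self):
        D = squareform(pdist(np.random.default_rng(0).random((4, 2))))
        with pytest.raises(ValueError):
            anosim(_dm(D), ["g", "g", "g", "g"], n_permutations=99)


class TestSimper:
    def test_single_species_contributes_everything(self):
        cm = _cm([[5], [3], [8], [1]], kind="count")
        table = simper(cm, ["x", "x", "y", "y"], ("x", "y"))
        assert table["contribution_pct"].iloc[0] == pytest.approx(100.0)

    def test_contributions_sum_to_average_between_group_dissimilarity(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            counts = rng.poisson(2.0, size=(5, 6))
            counts[counts.sum(axis=1) == 0, 0] = 1
            cm = _cm(counts)
            labels = ["g1", "g1", "g2", "g2", "g2"]
            table = simper(cm, labels, ("g1", "g2"))
            bray = bray_curtis(cm).to_frame()
            between = [
                bray.iloc[i, j] for i, j in product(range(2), range(2, 5))
            ]
            assert table["average_dissimilarity"].sum() == pytest.approx(
                np.mean(between), abs=1e-9
            )
            assert table["contribution_pct"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_two_v_two_direct_enumeration(self):
        counts = np.array([[4, 0, 1], [3, 1, 0], [0, 2, 2], [1, 3, 0]])
        cm = _cm(counts)
        table = simper(cm, ["a", "a", "b", "b"], ("a", "b"))
        expected = np.zeros(3)
        for i, j in product([0, 1], [2, 3]):
            expected += np.abs(counts[i] - counts[j]) / (counts[i] + counts[j]).sum()
        expected /= 4
        for k, sp in enumerate(["sp0", "sp1", "sp2"]):
            assert table.loc[sp, "average_dissimilarity"] == pytest.approx(expected[k])

    def test_overlapping_groups_rejected(self):
        cm = _cm([[1, 2], [2, 1]])
        with pytest.raises(ValueError):
            simper(cm, ["g", "g"], ("g", "g"))
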