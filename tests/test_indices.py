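import itertools
import math

import numpy as np
import pytest

from pnb.indices import (
    avepd,
    compute_covariate_table,
    derive_rng,
    index_set,
    minpd,
    null_moments,
    ses,
    totpd,
)
from pnb.neighborhood import NeighborProfile
from pnb.phylogeny import DistanceMatrix, patristic_matrix, read_newick
from pnb.synthetic import yule_newick


def profile(focal, abundance, layer="seedling"):
    return NeighborProfile(focal, layer, abundance, 2020, "q00")


@pytest.fixture(scope="module")
def hand_dmat():
    labels = ["A", "B", "C"]
    d = np.array([[0, 4, 5.5], [4, 0, 3], [5.5, 3, 0]])
    return DistanceMatrix(labels=labels, d=d)


class TestRawIndices:
    def test_totpd_hand_sum(self, hand_dmat):
        assert totpd(profile("A", {"B": 2, "C": 1}), hand_dmat) == pytest.approx(13.5)

    def test_totpd_single_neighbor(self, hand_dmat):
        assert totpd(profile("A", {"B": 1}), hand_dmat) == pytest.approx(4.0)

    def test_empty_profile_missing(self, hand_dmat):
        p = profile("A", {})
        assert math.isnan(totpd(p, hand_dmat))
        assert math.isnan(avepd(p, hand_dmat))
        assert math.isnan(minpd(p, hand_dmat))

    def test_avepd_hand_value(self, hand_dmat):
        assert avepd(profile("A", {"B": 2, "C": 1}), hand_dmat) == pytest.approx(4.5)

    def test_avepd_equidistant_constant(self):
        labels = ["A", "B", "C"]
        d = np.full((3, 3), 7.0)
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(labels=labels, d=d)
        for counts in ({"B": 1, "C": 5}, {"B": 3, "C": 2}):
            assert avepd(profile("A", counts), dm) == pytest.approx(7.0)

    def test_avepd_equals_totpd_at_unit_abundance(self, hand_dmat):
        p = profile("A", {"C": 1})
        assert avepd(p, hand_dmat) == totpd(p, hand_dmat)

    def test_minpd_hand_value(self, hand_dmat):
        assert minpd(profile("A", {"B": 2, "C": 1}), hand_dmat) == pytest.approx(4.0)

    def test_lookup_error_names_species(self, hand_dmat):
        with pytest.raises(KeyError, match="Z"):
            totpd(profile("A", {"Z": 1}), hand_dmat)

    def test_ordering_invariant_random(self):
        """minpd <= avepd <= totpd on random instances; naive-loop oracle agrees."""
        rng = np.random.default_rng(1)
        labels = [f"t{i}" for i in range(15)]
        phy = read_newick(yule_newick(labels, rng, depth=10.0))
        dm = patristic_matrix(phy)
        for _ in range(50):
            k = int(rng.integers(1, 8))
            chosen = rng.choice(labels[1:], size=k, replace=False)
            counts = {s: int(rng.integers(1, 5)) for s in chosen}
            p = profile(labels[0], counts)
            tot, ave, mn = totpd(p, dm), avepd(p, dm), minpd(p, dm)
            # independent naive loops
            o_tot = sum(dm.distance(labels[0], s) * c for s, c in counts.items())
            o_ave = o_tot / sum(counts.values())
            o_min = min(dm.distance(labels[0], s) for s in counts)
            assert tot == pytest.approx(o_tot)
            assert ave == pytest.approx(o_ave)
            assert mn == pytest.approx(o_min)
            assert mn <= ave + 1e-12 <= tot + 1e-9


class TestSES:
    def test_n_null_bound(self, hand_dmat):
        with pytest.raises(ValueError, match="n_null"):
            ses("avepd", profile("A", {"B": 1}), hand_dmat, n_null=1,
                rng=np.random.default_rng(0))

    def test_star_tree_degenerate_null(self):
        labels = list("ABCD")
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(labels=labels, d=d)
        val = ses("avepd", profile("A", {"B": 1, "C": 2}), dm, n_null=99,
                  rng=np.random.default_rng(0))
        assert math.isnan(val)

    def test_null_matches_exhaustive_enumeration(self, toy_dmat):
        """Sampled null mean/SD vs enumeration over all 24 label permutations."""
        p = profile("A", {"B": 1})
        n = 4
        aves, mins = [], []
        for perm in itertools.permutations(range(n)):
            dperm = toy_dmat.d[np.ix_(perm, perm)]
            dm = DistanceMatrix(labels=toy_dmat.labels, d=dperm)
            aves.append(avepd(p, dm))
            mins.append(minpd(p, dm))
        exact_mean, exact_sd = np.mean(aves), np.std(aves, ddof=1)
        n_null = 10_000
        m, s = null_moments("avepd", p, toy_dmat, n_null,
                            np.random.default_rng(7))
        se_mean = exact_sd / math.sqrt(n_null)
        se_sd = exact_sd / math.sqrt(2 * (n_null - 1))
        assert abs(m - exact_mean) < 3 * se_mean
        assert abs(s - exact_sd) < 3 * se_sd
        # minpd == avepd for a single-species unit profile
        assert np.allclose(sorted(aves), sorted(mins))

    def test_scale_invariance(self, toy_dmat):
        p = profile("A", {"B": 1, "C": 2})
        v1 = ses("avepd", p, toy_dmat, n_null=499, rng=np.random.default_rng(3))
        scaled = DistanceMatrix(labels=toy_dmat.labels, d=toy_dmat.d * 10.0)
        v2 = ses("avepd", p, scaled, n_null=499, rng=np.random.default_rng(3))
        assert v1 == pytest.approx(v2, rel=1e-9)

    def test_sign_convention(self):
        """Most-distant neighbors -> SES > 0; closest relatives -> SES < 0."""
        rng = np.random.default_rng(5)
        labels = [f"t{i}" for i in range(12)]
        dm = patristic_matrix(read_newick(yule_newick(labels, rng, depth=30.0)))
        focal = labels[0]
        i = dm.index(focal)
        others = np.argsort(dm.d[i])
        closest = [dm.labels[j] for j in others[1:4]]
        farthest = [dm.labels[j] for j in others[-3:]]
        far_p = profile(focal, {s: 1 for s in farthest})
        near_p = profile(focal, {s: 1 for s in closest})
        assert ses("avepd", far_p, dm, 999, np.random.default_rng(0)) > 0
        assert ses("avepd", near_p, dm, 999, np.random.default_rng(0)) < 0
        assert ses("minpd", far_p, dm, 999, np.random.default_rng(0)) > 0
        assert ses("minpd", near_p, dm, 999, np.random.default_rng(0)) < 0


class TestIndexSet:
    def test_reproducible_given_seed(self, small_sim):
        _, plot, phylo, _ = small_sim
        dmat = patristic_matrix(phylo)
        focal = next(s for s in plot.seedlings if s.is_alive(2020))
        a1 = index_set(focal, plot, dmat, 2020, n_null=199, master_seed=5)
        a2 = index_set(focal, plot, dmat, 2020, n_null=199, master_seed=5)
        for x, y in zip(a1, a2):
            assert x == y

    def test_empty_layer_all_missing(self, hand_dmat, small_sim):
        _, plot, phylo, _ = small_sim
        dmat = patristic_matrix(phylo)
        # fabricate a focal alone in its quadrat with no adults nearby
        from conftest import make_manual_plot, make_seedling

        lone = make_seedling("sx", "q00", phylo.tips[0], ["alive", "alive"])
        mini = make_manual_plot(seedlings=[lone])
        s_set, a_set = index_set(lone, mini, dmat, 2020, n_null=49, master_seed=0)
        assert s_set.empty and a_set.empty
        assert math.isnan(s_set.apd_prime)

    def test_monotone_under_more_distant_neighbors(self):
        rng = np.random.default_rng(9)
        labels = [f"t{i}" for i in range(10)]
        dm = patristic_matrix(read_newick(yule_newick(labels, rng, depth=20.0)))
        focal = labels[0]
        i = dm.index(focal)
        order = np.argsort(dm.d[i])
        near = profile(focal, {dm.labels[j]: 2 for j in order[1:4]})
        far = profile(focal, {dm.labels[j]: 2 for j in order[-3:]})
        assert totpd(far, dm) > totpd(near, dm)
        assert avepd(far, dm) > avepd(near, dm)
        assert minpd(far, dm) >= minpd(near, dm)

    def test_derive_rng_stable_and_distinct(self):
        a = derive_rng(1, "s1", "adult", 2020).random(3)
        b = derive_rng(1, "s1", "adult", 2020).random(3)
        c = derive_rng(1, "s1", "seedling", 2020).random(3)
        assert np.allclose(a, b)
        assert not np.allclose(a, c)


def test_covariate_table_shape(small_sim):
    _, plot, phylo, _ = small_sim
    dmat = patristic_matrix(phylo)
    table = compute_covariate_table(plot, dmat, [2020], master_seed=1, n_null=49)
    n_alive = sum(s.is_alive(2020) for s in plot.seedlings)
    assert len(table) == n_alive
    for col in ["s_totpd", "s_avepd", "s_minpd", "s_apd", "s_ntpd",
                "a_totpd", "a_apd", "s_con", "a_con"]:
        assert col in table.columns
    nonempty = table.dropna(subset=["s_avepd", "s_minpd"])
    assert (nonempty["s_minpd"] <= nonempty["s_avepd"] + 1e-12).all()
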