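import numpy as np
import pytest
import scipy.sparse as sp
from shapely.geometry import box

from parkflux.exposure import ExposureNetwork, build_incidence
from parkflux.geo_core import GROUP_ORDER, Park, Tract
from parkflux.node_metrics import (GroupLabels, assign_parks_to_tracts,
                                   group_crosstabs, homophily,
                                   homophily_summary, label_parks,
                                   label_tracts, neighbor_weighted_average,
                                   park_group_proportions, park_strength,
                                   tract_strength)

from conftest import make_city


def net_from_dense(dense):
    dense = np.asarray(dense)
    nT, nP = dense.shape
    return ExposureNetwork(sp.csr_matrix(dense),
                           [f"t{i}" for i in range(nT)],
                           [f"p{j}" for j in range(nP)])


def random_net(seed, nT=8, nP=12, lam=0.8):
    rng = np.random.default_rng(seed)
    return net_from_dense(rng.poisson(lam, (nT, nP)))


FIG4_NET = [[2, 1, 2]]


class TestStrengths:
    def test_fig4_row_and_column_sums(self):
        net = net_from_dense(FIG4_NET)
        assert tract_strength(net).tolist() == [5]
        assert park_strength(net).tolist() == [2, 1, 2]

    def test_all_zero(self):
        net = net_from_dense(np.zeros((3, 4)))
        assert tract_strength(net).sum() == 0
        assert park_strength(net).sum() == 0

    def test_diagonal(self):
        assert park_strength(net_from_dense(np.diag([3, 4]))).tolist() == [3, 4]

    @pytest.mark.parametrize("seed", range(3))
    def test_random_matches_dense_oracle(self, seed):
        net = random_net(seed)
        dense = net.X.toarray()
        np.testing.assert_array_equal(tract_strength(net), dense.sum(axis=1))
        np.testing.assert_array_equal(park_strength(net), dense.sum(axis=0))


class TestNeighborWeightedAverage:
    def test_constant_attribute(self):
        net = random_net(0)
        out = neighbor_weighted_average(net, np.full(net.n_parks, 3.7), side="park")
        connected = tract_strength(net) > 0
        assert np.allclose(out[connected], 3.7)

    def test_fig4_direct_formula(self):
        net = net_from_dense(FIG4_NET)
        a, b, c = 1.0, 2.0, 4.0
        out = neighbor_weighted_average(net, np.array([a, b, c]), side="park")
        assert out[0] == pytest.approx((2 * a + b + 2 * c) / 5)

    def test_zero_strength_gives_nan_not_zero(self):
        net = net_from_dense([[1, 0], [0, 0]])
        out = neighbor_weighted_average(net, np.array([2.0, 3.0]), side="park")
        assert out[0] == pytest.approx(2.0)
        assert np.isnan(out[1])

    def test_length_mismatch(self):
        net = net_from_dense(FIG4_NET)
        with pytest.raises(ValueError):
            neighbor_weighted_average(net, np.ones(5), side="park")

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_both_sides(self, seed):
        net = random_net(seed)
        rng = np.random.default_rng(seed + 100)
        beta = rng.uniform(0, 10, net.n_parks)
        alpha = rng.uniform(0, 10, net.n_tracts)
        dense = net.X.toarray()
        for i in range(net.n_tracts):
            s = dense[i].sum()
            got = neighbor_weighted_average(net, beta, side="park")[i]
            if s == 0:
                assert np.isnan(got)
            else:
                assert got == pytest.approx((dense[i] * beta).sum() / s)
        for j in range(net.n_parks):
            s = dense[:, j].sum()
            got = neighbor_weighted_average(net, alpha, side="tract")[j]
            if s == 0:
                assert np.isnan(got)
            else:
                assert got == pytest.approx((dense[:, j] * alpha).sum() / s)


def tract_with_counts(tid, counts, geom=box(0, 0, 1, 1)):
    return Tract(tid, geom, dict(zip(GROUP_ORDER, counts)))


class TestLabelTracts:
    def test_simple_argmax(self):
        labels = label_tracts([tract_with_counts("t", (60, 20, 10, 10, 0))])
        assert labels.labels == ["White"]
        assert labels.tie_flag == [False]

    def test_tie_broken_by_group_order(self):
        labels = label_tracts([tract_with_counts("t", (30, 0, 0, 30, 0))])
        assert labels.labels == ["White"]
        assert labels.tie_flag == [True]

    def test_other_predominant_warns_and_unlabels(self):
        with pytest.warns(UserWarning):
            labels = label_tracts([tract_with_counts("t", (1, 1, 1, 1, 10))])
        assert labels.labels == [None]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_argmax_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 100, (20, 5))
        counts[:, 4] = 0  # keep Other from winning
        tracts = [tract_with_counts(f"t{i}", tuple(c)) for i, c in enumerate(counts)]
        labels = label_tracts(tracts)
        for lab, c in zip(labels.labels, counts):
            best = max(c)
            expected = next(g for g, v in zip(GROUP_ORDER, c) if v == best)
            assert lab == expected


class TestLabelParks:
    def test_pure_tract_composition(self):
        net = net_from_dense([[3], [2]])
        tracts = [tract_with_counts("t0", (0, 0, 0, 10, 0)),
                  tract_with_counts("t1", (0, 0, 0, 5, 0))]
        labels = label_parks(net, tracts)
        assert labels.labels == ["Hispanic"]

    def test_even_split_tie_goes_to_group_order(self):
        net = net_from_dense([[1], [1]])
        tracts = [tract_with_counts("t0", (10, 0, 0, 0, 0)),
                  tract_with_counts("t1", (0, 10, 0, 0, 0))]
        labels = label_parks(net, tracts)
        assert labels.labels == ["White"]
        assert labels.tie_flag == [True]

    def test_zero_strength_park_unlabeled(self):
        net = net_from_dense([[1, 0]])
        tracts = [tract_with_counts("t0", (10, 0, 0, 0, 0))]
        labels = label_parks(net, tracts)
        assert labels.labels == ["White", None]

    def test_proportions_sum_to_one_for_connected_parks(self, small_city):
        _, tracts, parks, trajs = small_city
        net, _ = build_incidence(trajs, tracts, parks)
        props = park_group_proportions(net, tracts)
        s = net.park_strengths()
        sums = props.sum(axis=1).to_numpy()
        assert np.allclose(sums[s > 0], 1.0, atol=1e-9)

    def test_matches_bruteforce_weighted_argmax(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 100, (6, 5))
        tracts = [tract_with_counts(f"t{i}", tuple(c)) for i, c in enumerate(counts)]
        dense = rng.poisson(1.0, (6, 9))
        net = net_from_dense(dense)
        labels = label_parks(net, tracts)
        fracs = counts / counts.sum(axis=1, keepdims=True)
        for j in range(9):
            s = dense[:, j].sum()
            if s == 0:
                assert labels.labels[j] is None
                continue
            weighted = (dense[:, j, None] * fracs).sum(axis=0) / s
            best = weighted[:4].max()  # Other never wins
            expected = next(g for g, v in zip(GROUP_ORDER[:4], weighted[:4])
                            if v == best)
            assert labels.labels[j] == expected


def manual_labels(side, labels):
    return GroupLabels(side=side, labels=list(labels),
                       tie_flag=[False] * len(labels))


class TestHomophily:
    def test_uniform_labels_give_one(self):
        net = random_net(1)
        tl = manual_labels("tract", ["White"] * net.n_tracts)
        pl = manual_labels("park", ["White"] * net.n_parks)
        hT, hP = homophily(net, tl, pl)
        assert np.allclose(hT[tract_strength(net) > 0], 1.0)
        assert np.allclose(hP[park_strength(net) > 0], 1.0)

    def test_fully_mismatched_labels_give_zero(self):
        net = net_from_dense([[2, 3]])
        tl = manual_labels("tract", ["Hispanic"])
        pl = manual_labels("park", ["White", "White"])
        hT, hP = homophily(net, tl, pl)
        assert hT[0] == 0.0
        assert hP.tolist() == [0.0, 0.0]

    def test_zero_strength_is_nan(self):
        net = net_from_dense([[1, 0], [0, 0]])
        tl = manual_labels("tract", ["White", "White"])
        pl = manual_labels("park", ["White", "White"])
        hT, hP = homophily(net, tl, pl)
        assert np.isnan(hT[1]) and np.isnan(hP[1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_sum_oracle(self, seed):
        net = random_net(seed)
        rng = np.random.default_rng(seed + 50)
        tl = manual_labels("tract", rng.choice(GROUP_ORDER[:4], net.n_tracts))
        pl = manual_labels("park", rng.choice(GROUP_ORDER[:4], net.n_parks))
        hT, hP = homophily(net, tl, pl)
        dense = net.X.toarray()
        for i in range(net.n_tracts):
            s = dense[i].sum()
            if s == 0:
                assert np.isnan(hT[i])
                continue
            expected = sum(dense[i, j] for j in range(net.n_parks)
                           if tl.labels[i] == pl.labels[j]) / s
            assert hT[i] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_strength_weighted_totals_agree(self, seed):
        # both sides count the same same-label link weight
        net = random_net(seed)
        rng = np.random.default_rng(seed + 70)
        tl = manual_labels("tract", rng.choice(GROUP_ORDER[:4], net.n_tracts))
        pl = manual_labels("park", rng.choice(GROUP_ORDER[:4], net.n_parks))
        hT, hP = homophily(net, tl, pl)
        sT, sP = tract_strength(net), park_strength(net)
        lhs = np.nansum(sT * np.nan_to_num(hT))
        rhs = np.nansum(sP * np.nan_to_num(hP))
        assert lhs == pytest.approx(rhs)

    def test_values_in_unit_interval(self, small_city):
        _, tracts, parks, trajs = small_city
        net, _ = build_incidence(trajs, tracts, parks)
        tl = label_tracts(tracts)
        pl = label_parks(net, tracts)
        hT, hP = homophily(net, tl, pl)
        for h in (hT, hP):
            finite = h[np.isfinite(h)]
            assert ((finite >= 0) & (finite <= 1)).all()


class TestHomophilySummary:
    def test_mean_and_sd_per_group(self):
        labels = manual_labels("tract", ["White", "White", "Black"])
        h = np.array([0.2, 0.6, 1.0])
        summ = homophily_summary(h, labels)
        assert summ.loc["White", "mean"] == pytest.approx(0.4)
        assert summ.loc["White", "sd"] == pytest.approx(np.std([0.2, 0.6], ddof=1))
        assert summ.loc["Black", "n"] == 1


class TestCrosstabs:
    def _layout(self):
        km = 1000.0
        tracts = [
            tract_with_counts("tw", (100, 0, 0, 0, 0), box(0, 0, 2 * km, 2 * km)),
            tract_with_counts("th", (0, 0, 0, 100, 0), box(2 * km, 0, 4 * km, 2 * km)),
        ]
        parks = [
            Park("p0", box(100, 100, 400, 400)),            # in tw
            Park("p1", box(500, 500, 900, 900)),            # in tw
            Park("p2", box(2100, 100, 2500, 500)),          # in th
            Park("p3", box(2600, 600, 3000, 1000)),         # in th
            Park("p4", box(3100, 1100, 3500, 1500)),        # in th
        ]
        park_labels = manual_labels(
            "park", ["White", "Hispanic", "Hispanic", "Hispanic", "White"])
        return tracts, parks, label_tracts(tracts), park_labels

    def test_centroid_assignment(self):
        tracts, parks, _, _ = self._layout()
        hosts = assign_parks_to_tracts(parks, tracts, rule="centroid")
        assert hosts == ["tw", "tw", "th", "th", "th"]

    def test_hand_counted_regional_table(self):
        tracts, parks, tl, pl = self._layout()
        _, regional = group_crosstabs(tracts, parks, tl, pl)
        # tw region: parks p0 (White), p1 (Hispanic) -> 50/50
        assert regional.loc["White", "White_pct"] == pytest.approx(50.0)
        assert regional.loc["White", "Hispanic_pct"] == pytest.approx(50.0)
        assert regional.loc["White", "total"] == 2
        # th region: p2,p3 Hispanic, p4 White -> 66.7/33.3
        assert regional.loc["Hispanic", "Hispanic_pct"] == pytest.approx(200 / 3)
        assert regional.loc["Hispanic", "total"] == 3

    def test_rows_sum_to_100(self):
        tracts, parks, tl, pl = self._layout()
        _, regional = group_crosstabs(tracts, parks, tl, pl)
        pct_cols = [c for c in regional.columns if c.endswith("_pct")]
        sums = regional[pct_cols].sum(axis=1)
        for region, total in regional["total"].items():
            if total > 0:
                assert sums[region] == pytest.approx(100.0, abs=0.01)

    def test_single_group_city(self):
        km = 1000.0
        tracts = [tract_with_counts("t", (100, 0, 0, 0, 0), box(0, 0, km, km))]
        parks = [Park("p", box(100, 100, 300, 300))]
        tl = label_tracts(tracts)
        pl = manual_labels("park", ["White"])
        overview, regional = group_crosstabs(tracts, parks, tl, pl)
        assert overview.loc["White", "tracts"] == 1
        assert overview.loc["White", "pct_city_area"] == pytest.approx(100.0)
        assert regional.loc["White", "White_pct"] == pytest.approx(100.0)

    def test_largest_overlap_rule(self):
        tracts, parks, _, _ = self._layout()
        hosts = assign_parks_to_tracts(parks, tracts, rule="largest-overlap")
        assert hosts == ["tw", "tw", "th", "th", "th"]
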