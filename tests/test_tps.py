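import itertools

import numpy as np
import pytest

from phytonet import (
    PlantCluster,
    best_cluster_for_target,
    build_network,
    extract_subnetwork,
    multi_target_report,
    rank_targets_for_cluster,
    tps_score,
)


def make_net(pc, ct, **kw):
    plants = sorted({p for p, _ in pc})
    return build_network(plants, pc, ct, **kw)


def cluster_of(net, cid, members):
    return PlantCluster.from_network(cid, members, net)


@pytest.fixture
def overlap_net():
    # target t1 -> {c1, c2, c3, c4}; plant p1 -> {c1, c2}; p2 -> {c3}; p3 -> {c5}
    return make_net(
        [("p1", "c1"), ("p1", "c2"), ("p2", "c3"), ("p3", "c5")],
        [("c1", "t1"), ("c2", "t1"), ("c3", "t1"), ("c4", "t1")],
    )


class TestTpsScore:
    def test_full_containment_is_one(self, overlap_net):
        net = overlap_net
        cluster = cluster_of(net, 1, ["p1", "p2"])
        # C_P = {c1,c2,c3}, C_T = {c1..c4}: not containment; build one that is
        small = make_net([("p1", "c1"), ("p1", "c2")], [("c1", "t1"), ("c2", "t1")])
        res = tps_score(cluster_of(small, 1, ["p1"]), "t1", small)
        assert res.tps == 1.0

    def test_disjoint_is_zero(self, overlap_net):
        res = tps_score(cluster_of(overlap_net, 1, ["p3"]), "t1", overlap_net)
        assert res.tps == 0.0 and res.n_overlap == 0

    def test_fraction(self, overlap_net):
        res = tps_score(cluster_of(overlap_net, 1, ["p1"]), "t1", overlap_net)
        assert res.tps == pytest.approx(2 / 4)
        assert res.n_target_chemicals == 4
        assert res.overlap_chemicals == {"c1", "c2"}

    def test_empty_target_fatal(self):
        net = build_network(["p1"], [("p1", "c1")], [], targets=["t0"])
        with pytest.raises(ValueError, match="no connected chemicals"):
            tps_score(cluster_of(net, 1, ["p1"]), "t0", net)

    def test_bounds_and_monotonicity_random(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n_p, n_c, n_t = 6, 8, 3
            pc = [(f"p{i}", f"c{j}") for i in range(n_p) for j in range(n_c)
                  if rng.random() < 0.4]
            ct = [(f"c{j}", f"t{k}") for j in range(n_c) for k in range(n_t)
                  if rng.random() < 0.4]
            if not ct:
                ct = [("c0", "t0")]
            net = build_network([f"p{i}" for i in range(n_p)], pc, ct)
            plants = sorted(net.plants)
            for t in sorted(net.targets):
                prev = -1.0
                for size in range(1, len(plants) + 1):
                    res = tps_score(cluster_of(net, 1, plants[:size]), t, net)
                    assert 0.0 <= res.tps <= 1.0
                    assert res.tps >= prev  # monotone under cluster growth
                    prev = res.tps
                    # set-arithmetic oracle
                    c_p = set().union(*(net.chemical_profile(p) for p in plants[:size]))
                    c_t = net.target_chemicals(t)
                    assert res.tps == pytest.approx(len(c_p & c_t) / len(c_t))


class TestRankTargets:
    def make_sized_net(self):
        # t_big: 20 chemicals; t_small: 19 chemicals; both covered by p1
        pc = [("p1", f"cb{j}") for j in range(20)] + [("p1", f"cs{j}") for j in range(19)]
        ct = [(f"cb{j}", "t_big") for j in range(20)] + [
            (f"cs{j}", "t_small") for j in range(19)
        ]
        return make_net(pc, ct)

    def test_size_filter_excludes_small_targets(self):
        net = self.make_sized_net()
        cluster = cluster_of(net, 1, ["p1"])
        results = rank_targets_for_cluster(cluster, net, tps_min=0.1)
        assert [r.target_id for r in results] == ["t_big"]

    def test_empty_result_allowed(self, overlap_net):
        cluster = cluster_of(overlap_net, 1, ["p3"])
        assert rank_targets_for_cluster(cluster, overlap_net, 0.1) == []

    def test_sorted_descending(self):
        pc = [("p1", f"ca{j}") for j in range(10)] + [("p1", "cb0")]
        ct = [(f"ca{j}", "tA") for j in range(20)] + [(f"cb{j}", "tB") for j in range(25)]
        net = make_net(pc, ct)
        cluster = cluster_of(net, 1, ["p1"])
        results = rank_targets_for_cluster(cluster, net, 0.01, min_target_chemicals=20)
        assert [r.target_id for r in results] == ["tA", "tB"]
        assert results[0].tps == pytest.approx(0.5)
        assert results[1].tps == pytest.approx(1 / 25)


class TestBestCluster:
    def test_single_cluster(self, overlap_net):
        all_plants = sorted(overlap_net.plants)
        res = best_cluster_for_target(
            [cluster_of(overlap_net, 1, all_plants)], "t1", overlap_net
        )
        assert res.tps == pytest.approx(3 / 4)

    def test_argmax(self, overlap_net):
        c1 = cluster_of(overlap_net, 1, ["p3"])
        c2 = cluster_of(overlap_net, 2, ["p1"])
        res = best_cluster_for_target([c1, c2], "t1", overlap_net)
        assert res.cluster_id == 2

    def test_unknown_target_fatal(self, overlap_net):
        with pytest.raises(KeyError):
            best_cluster_for_target(
                [cluster_of(overlap_net, 1, ["p1"])], "tX", overlap_net
            )

    def test_tie_goes_to_smaller_cluster(self, overlap_net):
        # both clusters contain p1 so both have the same overlap {c1, c2}
        big = cluster_of(overlap_net, 1, ["p1", "p3"])
        small = cluster_of(overlap_net, 2, ["p1"])
        res = best_cluster_for_target([big, small], "t1", overlap_net)
        assert res.cluster_id == 2


class TestMultiTarget:
    @pytest.fixture
    def tri_net(self):
        # C_T1 = {a,b,c}, C_T2 = {b,c,d}, C_T3 = {c,d,e}
        ct = [
            ("a", "T1"), ("b", "T1"), ("c", "T1"),
            ("b", "T2"), ("c", "T2"), ("d", "T2"),
            ("c", "T3"), ("d", "T3"), ("e", "T3"),
        ]
        pc = [("p1", "c"), ("p2", "c"), ("p1", "a")]
        return make_net(pc, ct)

    def test_hand_set_arithmetic(self, tri_net):
        report = multi_target_report(["T1", "T2", "T3"], tri_net)
        assert report.pairwise_overlap == {
            ("T1", "T2"): 2, ("T1", "T3"): 1, ("T2", "T3"): 2,
        }
        assert report.common_chemicals == {"c"}
        assert report.chemical_plants == {"c": ["p1", "p2"]}

    def test_identical_sets(self):
        ct = [("a", "T1"), ("b", "T1"), ("a", "T2"), ("b", "T2")]
        net = make_net([("p1", "a")], ct)
        report = multi_target_report(["T1", "T2"], net)
        assert report.pairwise_overlap == {("T1", "T2"): 2}
        assert report.common_chemicals == {"a", "b"}

    def test_disjoint_sets(self):
        ct = [("a", "T1"), ("b", "T2")]
        net = make_net([("p1", "a")], ct)
        report = multi_target_report(["T1", "T2"], net)
        assert report.pairwise_overlap == {("T1", "T2"): 0}
        assert report.common_chemicals == frozenset()

    def test_intersection_subset_invariant(self, tri_net):
        report = multi_target_report(["T1", "T2", "T3"], tri_net)
        for (a, b), n in report.pairwise_overlap.items():
            assert len(report.common_chemicals) <= n

    def test_fewer_than_two_targets_fatal(self, tri_net):
        with pytest.raises(ValueError):
            multi_target_report(["T1"], tri_net)


class TestExtractSubnetwork:
    def test_no_shared_chemistry_gives_empty(self, overlap_net):
        cluster = cluster_of(overlap_net, 1, ["p3"])
        sub = extract_subnetwork(cluster, ["t1"], overlap_net)
        assert sub.n_edges == 0

    def test_full_containment_keeps_all_target_chems(self):
        net = make_net([("p1", "c1"), ("p1", "c2")], [("c1", "t1"), ("c2", "t1")])
        sub = extract_subnetwork(cluster_of(net, 1, ["p1"]), ["t1"], net)
        assert sub.chemicals == net.target_chemicals("t1")

    def test_induced_edges_only(self, overlap_net):
        cluster = cluster_of(overlap_net, 1, ["p1", "p2"])
        sub = extract_subnetwork(cluster, ["t1"], overlap_net)
        # overlap chemicals: {c1, c2, c3}; c4 (target-only) and c5 excluded
        assert sub.chemicals == {"c1", "c2", "c3"}
        assert sub.pc_edges == {("p1", "c1"), ("p1", "c2"), ("p2", "c3")}
        assert sub.ct_edges == {("c1", "t1"), ("c2", "t1"), ("c3", "t1")}
        assert all(sub.node_attrs[c].get("tps_overlap") for c in sub.chemicals)
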