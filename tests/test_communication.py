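import itertools

import networkx as nx
import numpy as np
import pytest

from trajcomm import communication as cm, modes as md, synthetic as syn
from trajcomm.core import TrajectoryEnsemble
from trajcomm.errors import ArgumentError, SchemeError, ThresholdError

from conftest import ca_only_structure


# -- independent oracles ----------------------------------------------------

def brute_mean_min_distance(frames, structure, subset="heavy"):
    mask = structure.selection_mask(subset)
    residues = structure.residue_ids
    groups = [
        np.nonzero(mask & (structure.residue_numbers == r))[0]
        for r in residues
    ]
    n = len(residues)
    acc = np.zeros((n, n))
    for frame in frames:
        for i, j in itertools.combinations(range(n), 2):
            best = min(
                np.linalg.norm(frame[a] - frame[b])
                for a in groups[i] for b in groups[j]
            )
            acc[i, j] += best
            acc[j, i] += best
    return acc / len(frames)


def brute_commute_time(frames_ca):
    n = frames_ca.shape[1]
    ct = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = np.linalg.norm(frames_ca[:, i] - frames_ca[:, j], axis=1)
        ct[i, j] = ct[j, i] = d.var()
    return ct


def _random_fixture(n_residues=10, n_frames=8, seed=0):
    s = syn.make_toy_structure(n_residues, "coil", True)
    rng = np.random.default_rng(seed)
    frames = s.positions[None] + 0.1 * rng.normal(
        size=(n_frames, s.n_atoms, 3))
    ens = TrajectoryEnsemble(replicas=[frames],
                             times=[np.arange(float(n_frames))])
    return s, ens


class TestMeanMinDistance:
    def test_static_equals_single_frame(self):
        s, _ = _random_fixture()
        frames = np.repeat(s.positions[None], 4, axis=0)
        ens = TrajectoryEnsemble(replicas=[frames], times=[np.arange(4.0)])
        mmd = cm.mean_min_distance(ens, s)
        single = brute_mean_min_distance(frames[:1], s)
        assert np.allclose(mmd, single, atol=1e-12)

    def test_oscillating_pair_mean(self):
        s = ca_only_structure([[0.0, 0, 0], [0.3, 0, 0]])
        frames = np.repeat(s.positions[None], 4, axis=0)
        frames[1::2, 1, 0] = 0.5  # alternate 0.3 / 0.5 nm, 50/50
        ens = TrajectoryEnsemble(replicas=[frames], times=[np.arange(4.0)])
        mmd = cm.mean_min_distance(ens, s)
        assert mmd[0, 1] == pytest.approx(0.4, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        s, ens = _random_fixture(seed=seed)
        assert np.allclose(
            cm.mean_min_distance(ens, s),
            brute_mean_min_distance(ens.frames(), s),
            atol=1e-12,
        )


class TestNeighborGraph:
    def test_all_far_empty_graph(self):
        dist = np.full((5, 5), 1.0)
        np.fill_diagonal(dist, 0.0)
        g = cm.neighbor_graph(dist, np.arange(1, 6), d_cut_a=3.6)
        assert g.number_of_edges() == 0

    def test_chain_contacts_make_path(self):
        n = 6
        dist = np.full((n, n), 2.0)
        for i in range(n - 1):
            dist[i, i + 1] = dist[i + 1, i] = 0.30  # 3.0 A
        np.fill_diagonal(dist, 0.0)
        g = cm.neighbor_graph(dist, np.arange(1, n + 1), d_cut_a=3.6)
        assert sorted(g.edges) == [(i, i + 1) for i in range(1, n)]

    def test_edge_count_monotone_in_cutoff(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0.2, 1.0, size=(8, 8))
        dist = (d + d.T) / 2
        np.fill_diagonal(dist, 0.0)
        counts = [
            cm.neighbor_graph(dist, np.arange(8), c).number_of_edges()
            for c in (10.0, 6.0, 4.0, 3.0, 2.0)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_asymmetric_matrix_rejected(self):
        dist = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ArgumentError):
            cm.neighbor_graph(dist, np.arange(2))


class TestContactGraph:
    def _two_residue_frames(self, close_fraction, n_frames=10):
        s = ca_only_structure([[0.0, 0, 0], [0.3, 0, 0], [5.0, 0, 0]])
        frames = np.repeat(s.positions[None], n_frames, axis=0)
        n_far = round((1 - close_fraction) * n_frames)
        frames[:n_far, 1, 0] = 2.0  # break the 1-3 contact in these frames
        ens = TrajectoryEnsemble(replicas=[frames],
                                 times=[np.arange(float(n_frames))])
        return s, ens

    def test_permanent_contact_present(self):
        s, ens = self._two_residue_frames(1.0)
        g = cm.contact_graph(ens, s, contact_dist_a=4.0, persistence=0.5)
        assert g.has_edge(1, 3) is False  # wait: 1-2 adjacent, 1-3 far
        # residues 1 and 2 are sequence-adjacent so excluded; verify that
        assert g.number_of_edges() == 0

    def test_planted_persistent_contact(self):
        s = ca_only_structure([[0.0, 0, 0], [3.0, 0, 0], [0.35, 0, 0]])
        frames = np.repeat(s.positions[None], 10, axis=0)
        ens = TrajectoryEnsemble(replicas=[frames], times=[np.arange(10.0)])
        g = cm.contact_graph(ens, s, contact_dist_a=4.0, persistence=0.5)
        assert g.has_edge(1, 3)

    def test_forty_percent_contact_absent(self):
        s = ca_only_structure([[0.0, 0, 0], [3.0, 0, 0], [0.35, 0, 0]])
        frames = np.repeat(s.positions[None], 10, axis=0)
        frames[:6, 2, 0] = 2.0  # contact in only 4/10 frames
        ens = TrajectoryEnsemble(replicas=[frames], times=[np.arange(10.0)])
        g = cm.contact_graph(ens, s, contact_dist_a=4.0, persistence=0.5)
        assert not g.has_edge(1, 3)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_frame_fraction_oracle(self, seed):
        s, ens = _random_fixture(n_residues=8, n_frames=6, seed=seed)
        cut_a = 5.0
        g = cm.contact_graph(ens, s, contact_dist_a=cut_a, persistence=0.5)
        frames = ens.frames()
        for i, j in itertools.combinations(range(8), 2):
            ri, rj = i + 1, j + 1
            if abs(ri - rj) <= 1:
                assert not g.has_edge(ri, rj)
                continue
            mmd = brute_mean_min_distance(frames, s)
            frac = np.mean([
                brute_mean_min_distance(frames[k:k + 1], s)[i, j] <= cut_a * 0.1
                for k in range(len(frames))
            ])
            assert g.has_edge(ri, rj) == (frac >= 0.5)


class TestCommuteTime:
    def test_rigidly_comoving_zero(self):
        s = ca_only_structure([[0.0, 0, 0], [1.0, 0, 0]])
        rng = np.random.default_rng(0)
        base = np.repeat(s.positions[None], 100, axis=0)
        base += rng.normal(size=(100, 1, 3))  # same offset for both residues
        ens = TrajectoryEnsemble(replicas=[base], times=[np.arange(100.0)])
        _, ct = cm.commute_time(ens, s)
        assert ct[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_independent_jitter_closed_form(self):
        # two residues jittering independently along their separation axis:
        # d = L + x2 - x1, Var(d) = 2 sigma^2
        sigma = 0.05
        s = ca_only_structure([[0.0, 0, 0], [10.0, 0, 0]])
        rng = np.random.default_rng(1)
        frames = np.repeat(s.positions[None], 5000, axis=0)
        frames[:, 0, 0] += sigma * rng.normal(size=5000)
        frames[:, 1, 0] += sigma * rng.normal(size=5000)
        ens = TrajectoryEnsemble(replicas=[frames], times=[np.arange(5000.0)])
        _, ct = cm.commute_time(ens, s)
        assert ct[0, 1] == pytest.approx(2 * sigma ** 2, rel=0.10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_variance_oracle(self, seed):
        s, ens = _random_fixture(seed=seed)
        ca = np.nonzero(s.selection_mask("calpha"))[0]
        _, ct = cm.commute_time(ens, s)
        assert np.allclose(ct, brute_commute_time(ens.frames()[:, ca, :]),
                           atol=1e-12)


class TestChooseCtCut:
    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(0.01, 1.0, size=(20, 20))
        ct = (m + m.T) / 2
        np.fill_diagonal(ct, 0.0)
        a = cm.choose_ct_cut(ct, 0.10)
        b = cm.choose_ct_cut(2.0 * ct, 0.10)
        assert b == pytest.approx(2.0 * a, rel=1e-9)

    def test_target_fraction_one_returns_max(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(0.01, 1.0, size=(10, 10))
        ct = (m + m.T) / 2
        np.fill_diagonal(ct, 0.0)
        assert cm.choose_ct_cut(ct, 1.0) == pytest.approx(
            ct[~np.eye(10, dtype=bool)].max())

    def test_constructed_matrix_threshold_near_point_one(self):
        # pair CTs 0.1 for the first 10% of partners of each residue,
        # much larger otherwise: the chosen cut lands at 0.1
        n = 40
        ct = np.full((n, n), 5.0)
        for i in range(n):
            for j in range(i + 1, min(i + 5, n)):
                ct[i, j] = ct[j, i] = 0.1
        np.fill_diagonal(ct, 0.0)
        cut = cm.choose_ct_cut(ct, 0.10)
        assert cut == pytest.approx(0.1)

    def test_degenerate_matrix_rejected(self):
        ct = np.ones((5, 5))
        np.fill_diagonal(ct, 0.0)
        with pytest.raises(ThresholdError):
            cm.choose_ct_cut(ct)

    def test_partner_rule(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(0.01, 1.0, size=(30, 30))
        ct = (m + m.T) / 2
        np.fill_diagonal(ct, 0.0)
        cut = cm.choose_ct_cut(ct, 0.10)
        target = int(np.ceil(0.10 * 30))
        counts = (ct <= cut).sum(axis=1) - 1
        assert np.percentile(counts, 95) >= target
        # smallest such threshold: the next-lower candidate fails
        off = np.unique(ct[~np.eye(30, dtype=bool)])
        below = off[off < cut]
        if len(below):
            counts_b = (ct <= below[-1]).sum(axis=1) - 1
            assert np.percentile(counts_b, 95) < target


class TestLfaSegments:
    def test_planted_block_recovered(self, helix110, planted_block_110):
        ms = md.pca_modes(planted_block_110, helix110, "calpha", 130)
        k80 = md.modes_for_variance(ms, 0.8)
        sub = TrajectoryEnsemble(
            replicas=[planted_block_110.frames()[:300]],
            times=[np.arange(300.0)])
        mmd = cm.mean_min_distance(sub, helix110)
        ng = cm.neighbor_graph(mmd, helix110.residue_ids)
        _corr, _p_cut, segs = cm.lfa_segments(ms.subset(k80), helix110, ng)
        assert len(segs) == 1
        got = set(segs[0]["residues"])
        planted = set(range(45, 56))
        jaccard = len(got & planted) / len(got | planted)
        assert jaccard >= 0.6

    def test_isotropic_ensemble_no_segments(self, helix110):
        spec = syn.PlantedSpec(n_residues=110, background_sigma=0.03, seed=9)
        ens = syn.sample_ensemble(helix110, spec, 400)
        ms = md.pca_modes(ens, helix110, "calpha", 130)
        k80 = md.modes_for_variance(ms, 0.8)
        sub = TrajectoryEnsemble(replicas=[ens.frames()[:100]],
                                 times=[np.arange(100.0)])
        mmd = cm.mean_min_distance(sub, helix110)
        ng = cm.neighbor_graph(mmd, helix110.residue_ids)
        _corr, _p_cut, segs = cm.lfa_segments(ms.subset(k80), helix110, ng)
        assert segs == []

    def test_quantile_property(self, helix110, planted_block_110):
        ms = md.pca_modes(planted_block_110, helix110, "calpha", 130)
        k80 = md.modes_for_variance(ms, 0.8)
        ng = nx.path_graph(range(1, 111))
        corr, p_cut, _ = cm.lfa_segments(ms.subset(k80), helix110, ng,
                                         keep_fraction=0.01)
        off = np.abs(corr[~np.eye(len(corr), dtype=bool)])
        frac = (off > p_cut).mean()
        cell = 1.0 / len(off)
        assert abs(frac - 0.01) <= cell + 1e-12


class TestGrowCps:
    def _ct(self, n, low_pairs, low=0.01, high=10.0):
        ct = np.full((n, n), high)
        np.fill_diagonal(ct, 0.0)
        for a, b in low_pairs:
            ct[a, b] = ct[b, a] = low
        return ct

    def test_triangle_single_cp(self):
        residues = np.arange(3)
        g = nx.Graph([(0, 1), (1, 2), (0, 2)])
        ct = self._ct(3, [(0, 1), (1, 2), (0, 2)])
        cps = cm.grow_cps(residues, ct, 0.1, g)
        assert cps == [[0, 1, 2]]

    def test_chain_with_far_endpoints_splits(self):
        residues = np.arange(3)
        g = nx.Graph([(0, 1), (1, 2)])
        ct = self._ct(3, [(0, 1), (1, 2)])
        ct[0, 2] = ct[2, 0] = 10.0  # endpoints do not communicate
        cps = cm.grow_cps(residues, ct, 0.1, g)
        assert sorted(map(tuple, cps)) == [(0, 1), (1, 2)]

    def test_planted_fiber_recovered(self):
        # 10 residues, mutual contacts, all pairwise CT below the cutoff
        n = 10
        residues = np.arange(n)
        g = nx.complete_graph(n)
        ct = self._ct(n, itertools.combinations(range(n), 2))
        cps = cm.grow_cps(residues, ct, 0.1, g)
        assert len(cps) == 1
        assert sorted(cps[0]) == list(range(n))

    def test_chains_respect_contact_adjacency_and_ct(self):
        rng = np.random.default_rng(5)
        n = 12
        m = rng.uniform(0.0, 0.2, size=(n, n))
        ct = (m + m.T) / 2
        np.fill_diagonal(ct, 0.0)
        g = nx.gnp_random_graph(n, 0.4, seed=2)
        cps = cm.grow_cps(np.arange(n), ct, 0.08, g)
        for chain in cps:
            for x, y in zip(chain, chain[1:]):
                assert g.has_edge(x, y)
            for x, y in itertools.combinations(chain, 2):
                assert ct[x, y] <= 0.08

    def test_no_contained_duplicates(self):
        rng = np.random.default_rng(6)
        n = 10
        m = rng.uniform(0.0, 0.2, size=(n, n))
        ct = (m + m.T) / 2
        np.fill_diagonal(ct, 0.0)
        g = nx.gnp_random_graph(n, 0.5, seed=3)
        cps = cm.grow_cps(np.arange(n), ct, 0.1, g)
        sets = [frozenset(c) for c in cps]
        for i, a in enumerate(sets):
            for j, b in enumerate(sets):
                if i != j:
                    assert not a < b


class TestNetworkSummary:
    def _net(self, cps, n=30):
        residues = np.arange(1, n + 1)
        ct = np.zeros((n, n))
        g = nx.Graph()
        g.add_nodes_from(residues)
        for chain in cps:
            for x, y in zip(chain, chain[1:]):
                g.add_edge(x, y)
        return cm.CommunicationNetwork(
            residues=residues, retained_modes=3,
            lfa_corr=np.eye(n), p_cut=0.5, ids_list=[],
            mean_min_dist=np.zeros((n, n)), neighbors=nx.Graph(),
            contacts=g, ct_matrix=ct, ct_cut=0.1, cps=cps,
        )

    def test_empty_cp_list_all_zero(self):
        from trajcomm.core import toy_scheme
        net = self._net([])
        summary = cm.network_summary(net, toy_scheme(30), [15])
        assert summary["paths"] == 0
        assert summary["hubs"] == 0
        assert summary["focus_residues"]["15"] == 0

    def test_single_three_residue_cp_three_paths(self):
        from trajcomm.core import toy_scheme
        net = self._net([[4, 5, 6]])
        summary = cm.network_summary(net, toy_scheme(30), [])
        assert summary["paths"] == 3

    def test_region_pair_counts_match_enumeration(self):
        from trajcomm.core import toy_scheme
        scheme = toy_scheme(30)
        cps = [[1, 2, 3, 14], [10, 11, 12], [5, 6, 20]]
        net = self._net(cps)
        summary = cm.network_summary(
            net, scheme, [], region_pairs=[("JM-B", "N-lobe")])
        jmb = set(scheme.residues("JM-B"))
        nlobe = set(scheme.residues("N-lobe"))
        expected = len({
            tuple(sorted((x, y)))
            for chain in cps
            for x, y in itertools.combinations(set(chain), 2)
            if (x in jmb and y in nlobe) or (x in nlobe and y in jmb)
        })
        assert summary["region_pairs"]["JM-B|N-lobe"] == expected

    def test_hub_counting(self):
        net = self._net([[1, 2, 3], [1, 4, 5], [1, 6, 7], [1, 8, 9],
                         [1, 10, 11]])
        assert net.hubs(hub_degree=5) == [1]
        assert net.hubs(hub_degree=6) == []

    def test_missing_region_rejected(self):
        from trajcomm.core import toy_scheme
        net = self._net([[1, 2, 3]])
        with pytest.raises(SchemeError):
            cm.network_summary(net, toy_scheme(30), [],
                               region_pairs=[("Nope", "JM-B")])

    def test_invalid_cp_rejected_by_network_invariant(self):
        n = 30
        residues = np.arange(1, n + 1)
        contacts = nx.Graph([(1, 3), (3, 5)])
        contacts.add_nodes_from(residues)
        with pytest.raises(ArgumentError):
            cm.CommunicationNetwork(
                residues=residues, retained_modes=3,
                lfa_corr=np.eye(n), p_cut=0.5, ids_list=[],
                mean_min_dist=np.zeros((n, n)), neighbors=nx.Graph(),
                contacts=contacts, ct_matrix=np.zeros((n, n)), ct_cut=0.1,
                cps=[[1, 9, 3]],  # 1-9 is not a contact edge
            )


class TestMutationAnalogProperty:
    def test_decorrelation_removes_cross_region_cps(self, helix100):
        """One coherent block spanning two halves produces CPs linking them;
        splitting it into two independent blocks removes every linking CP."""
        # background jitters more than the block residual so the coherent
        # block is the low-commute-time channel
        coupled = syn.PlantedSpec(
            n_residues=100, cluster_blocks=[(40, 60, 0.95, 0.1)],
            background_sigma=0.05, seed=13)
        split = syn.PlantedSpec(
            n_residues=100,
            cluster_blocks=[(40, 49, 0.95, 0.1), (50, 60, 0.95, 0.1)],
            background_sigma=0.05, seed=13)

        def linking_pairs(spec):
            ens = syn.sample_ensemble(helix100, spec, 600)
            residues, ct = cm.commute_time(ens, helix100)
            contacts = cm.contact_graph(ens, helix100, contact_dist_a=7.0,
                                        persistence=0.5)
            cps = cm.grow_cps(residues, ct, 2e-3, contacts)
            left = set(range(40, 50))
            right = set(range(50, 61))
            return {
                (x, y)
                for chain in cps
                for x, y in itertools.combinations(sorted(set(chain)), 2)
                if (x in left and y in right) or (x in right and y in left)
            }

        assert len(linking_pairs(coupled)) > 0
        assert len(linking_pairs(split)) == 0
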