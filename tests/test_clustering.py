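"""SIP clustering, state identification, refinement, top-down hierarchy."""

import numpy as np
import pytest

import trajmap as tm
from trajmap.basis import DihedralBasis
from trajmap.clustering import (
    ClusteringConfig,
    MetastableState,
    cluster_by_sip,
    find_substates,
    identify_states,
    refine_states,
    state_representative,
)
from trajmap.indicators import dwell_segments
from trajmap.mapping import MappedVector, TrajectoryPiece, cut_pieces, map_pieces


def _vec(components, idx=0, length=10):
    comps = np.concatenate(([1.0], np.asarray(components, dtype=float)))
    return MappedVector(TrajectoryPiece("t", idx * length, (idx + 1) * length, 1.0), comps)


class TestClusteringConfig:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            ClusteringConfig(r_l=0.4, overlap_exclusion=0.5)
        with pytest.raises(ValueError):
            ClusteringConfig(min_cluster=1)
        with pytest.raises(ValueError):
            ClusteringConfig(tau_schedule=(100.0, 100.0))


class TestClusterBySip:
    def test_three_tight_groups_cluster_perfectly(self):
        rng = np.random.default_rng(0)
        centers = 5.0 * np.eye(3)
        vectors, owner = [], []
        for g in range(3):
            for k in range(8):
                noise = 0.05 * rng.normal(size=3)
                vectors.append(_vec(centers[g] + noise, idx=len(vectors)))
                owner.append(g)
        clusters = cluster_by_sip(vectors, ClusteringConfig())
        assert len(clusters) == 3
        for cluster in clusters:
            assert len({owner[i] for i in cluster}) == 1
        assert sum(len(c) for c in clusters) == 24

    def test_mutually_dissimilar_vectors_yield_no_clusters(self):
        vectors = [_vec(5.0 * np.eye(4)[k], idx=k) for k in range(4)]
        assert cluster_by_sip(vectors, ClusteringConfig()) == []

    def test_pair_plus_outlier(self):
        a = _vec([5.0, 0.0, 0.0], 0)
        b = _vec([5.0, 0.4, 0.0], 1)  # SIP(a, b) ~ 0.997
        outlier = _vec([0.0, 0.0, 5.0], 2)
        clusters = cluster_by_sip([a, b, outlier], ClusteringConfig())
        assert clusters == [[0, 1]]

    def test_deterministic_given_input_order(self):
        rng = np.random.default_rng(1)
        vectors = [
            _vec(5.0 * np.eye(2)[k % 2] + 0.05 * rng.normal(size=2), idx=k)
            for k in range(12)
        ]
        assert cluster_by_sip(vectors, ClusteringConfig()) == cluster_by_sip(
            vectors, ClusteringConfig()
        )


def _two_basin_system(contaminate=False):
    """Two far-separated torsional basins with deterministic block structure."""
    rng = np.random.default_rng(5)
    T = 2400
    labels = (np.arange(T) // 200) % 2  # alternate 200-frame blocks
    means = np.array([[-1.8, 0.9], [1.2, -2.0]])
    angles = means[labels] + 0.2 * rng.normal(size=(T, 2))
    series = tm.DihedralSeries(angles, 1.0, "tb")
    series_map = {"tb": series}
    basis = DihedralBasis().fit(series.angles)
    pieces = cut_pieces(T, 100, "tb", 1.0)
    piece_labels = [int(labels[p.start]) for p in pieces]
    return series_map, basis, pieces, piece_labels


class TestRefineStates:
    def test_orthogonal_states_unchanged(self):
        series_map, basis, pieces, piece_labels = _two_basin_system()
        sa = MetastableState(1, [p for p, l in zip(pieces, piece_labels) if l == 0], 100.0)
        sb = MetastableState(2, [p for p, l in zip(pieces, piece_labels) if l == 1], 100.0)
        refined, freed = refine_states([sa, sb], ClusteringConfig(), series_map, basis)
        assert len(refined) == 2
        assert freed == []
        assert abs(float(refined[0].representative_ @ refined[1].representative_)) < 0.01

    def test_noise_split_state_pair_is_merged(self):
        series_map, basis, pieces, piece_labels = _two_basin_system()
        same = [p for p, l in zip(pieces, piece_labels) if l == 0]
        sa = MetastableState(1, same[:6], 100.0)
        sb = MetastableState(2, same[6:12], 100.0)
        refined, _ = refine_states([sa, sb], ClusteringConfig(), series_map, basis)
        assert len(refined) == 1
        assert refined[0].n_pieces == 12

    def test_mixed_piece_is_stripped_to_restore_orthogonality(self):
        series_map, basis, pieces, piece_labels = _two_basin_system()
        a_pieces = [p for p, l in zip(pieces, piece_labels) if l == 0]
        b_pieces = [p for p, l in zip(pieces, piece_labels) if l == 1]
        # a piece straddling the basin boundary belongs half to each state
        mixed = TrajectoryPiece("tb", 150, 250, 1.0)
        sa = MetastableState(1, a_pieces, 100.0)
        sb = MetastableState(2, b_pieces[:7] + [mixed], 100.0)
        refined, freed = refine_states([sa, sb], ClusteringConfig(), series_map, basis)
        assert len(refined) == 2
        assert mixed in freed
        reps = np.array([st.representative_ for st in refined])
        assert abs(float(reps[0] @ reps[1])) < 0.01


class TestIdentifyStates:
    def test_strictly_greater_than_min_cluster(self):
        series_map, basis, pieces, _ = _two_basin_system()
        config = ClusteringConfig()
        six, five = [list(range(6)), list(range(6, 11))]
        states, unassigned = identify_states(
            [six, five], [  # six-member cluster qualifies, five does not
                *(map_pieces(pieces[:11], series_map, basis)),
            ], config, 100.0, series_map, basis,
        )
        assert len(states) == 1
        assert states[0].n_pieces == 6
        assert unassigned == list(range(6, 11))

    def test_empty_cluster_list(self):
        series_map, basis, pieces, _ = _two_basin_system()
        states, unassigned = identify_states(
            [], [], ClusteringConfig(), 100.0, series_map, basis
        )
        assert states == [] and unassigned == []


class TestHierarchy:
    def test_three_state_system_recovered_exactly(self, three_state):
        assert three_state.est.n_states_ == 3
        assert sorted(three_state.match.values()) == [0, 1, 2]
        for st in three_state.est.states_:
            assert st.n_pieces > 5

    def test_defining_pieces_partition(self, three_state):
        seen = set()
        for st in three_state.est.states_:
            for p in st.defining_pieces:
                key = (p.source_id, p.start, p.stop)
                assert key not in seen
                seen.add(key)

    def test_refined_states_mutually_near_orthogonal(self, three_state):
        # refinement drives inter-state SIP to near zero; the residual floor
        # (~0.03 here) comes from retained pieces with slight admixture,
        # which only a much more aggressive strip threshold would remove
        reps = three_state.est.representatives_
        S = reps @ reps.T
        off = S[~np.eye(len(S), dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_single_well_gives_one_state_at_first_level(self):
        spec = tm.well_separated_spec(n_states=2, seed=1)
        spec = tm.SyntheticSpec(
            rate_matrix=np.zeros((1, 1)),
            means=spec.means[:1],
            concentrations=spec.concentrations[:1],
            mixing_times=spec.mixing_times[:1],
            total_frames=30_000,
            seed=1,
        )
        series, _ = tm.generate(spec)
        est = tm.TrajectoryMapping(tau_schedule=(500.0, 100.0))
        est.fit(series)
        assert est.n_states_ == 1
        assert est.states_[0].level_tau == 500.0
        assert est.levels_[-1].n_new_states == 0 or len(est.levels_) == 1

    def test_pure_diffusion_yields_no_states(self):
        spec = tm.diffusive_spec(0.0, seed=0)
        series, _ = tm.generate(spec)
        est = tm.TrajectoryMapping(tau_schedule=(150.0,))
        est.fit(series)
        assert est.n_states_ == 0
        assert est.accounted_fraction_ == 0.0

    def test_two_timescale_states_found_at_matching_levels(self, two_timescale):
        fs = two_timescale
        slow_true = {0, 2}  # ring positions of the 5 ns states
        assert fs.est.n_states_ == 4
        assert sorted(fs.match.values()) == [0, 1, 2, 3]  # none duplicated
        for st in fs.est.states_:
            if fs.match[st.state_id] in slow_true:
                assert st.level_tau == 2000.0
            else:
                assert st.level_tau == 150.0

    def test_min_cluster_insensitivity(self, two_timescale):
        # doubling the cluster-size threshold may move states between
        # levels but leaves the final state inventory intact
        from collections import Counter

        est = tm.TrajectoryMapping(tau_schedule=(2000.0, 150.0), min_cluster=10)
        est.fit(two_timescale.series)
        matched = []
        for st in est.states_:
            c = Counter()
            for p in st.defining_pieces:
                c.update(two_timescale.truth.labels[p.start : p.stop].tolist())
            matched.append(c.most_common(1)[0][0])
        assert sorted(matched) == sorted(two_timescale.match.values())

    def test_determinism(self, three_state):
        est = tm.TrajectoryMapping(tau_schedule=(150.0,))
        est.fit(three_state.series)
        ref = three_state.est
        assert est.n_states_ == ref.n_states_
        for a, b in zip(est.states_, ref.states_):
            assert a.state_id == b.state_id
            assert [(p.start, p.stop) for p in a.defining_pieces] == [
                (p.start, p.stop) for p in b.defining_pieces
            ]
            assert a.representative_ == pytest.approx(b.representative_, abs=0)

    def test_sklearn_param_interface(self):
        est = tm.TrajectoryMapping()
        params = est.get_params()
        assert params["r_l"] == 0.95
        est.set_params(r_l=0.9, min_cluster=8)
        assert est.r_l == 0.9
        with pytest.raises(ValueError):
            est.set_params(nonsense=1)


@pytest.fixture(scope="module")
def nested_fit():
    spec, super_of = tm.nested_spec(seed=7)
    series, truth = tm.generate(spec)
    est = tm.TrajectoryMapping(tau_schedule=(24_000.0,))
    est.fit(series)
    return spec, super_of, series, truth, est


class TestNestedSubstates:
    def test_super_states_found_top_down(self, nested_fit):
        spec, super_of, series, truth, est = nested_fit
        assert est.n_states_ == 2
        doms = set()
        for st in est.states_:
            frames = np.concatenate(
                [truth.labels[p.start : p.stop] for p in st.defining_pieces]
            )
            super_frames = super_of[frames]
            dom = np.bincount(super_frames).argmax()
            assert (super_frames == dom).mean() > 0.8
            doms.add(int(dom))
        assert doms == {0, 1}

    def test_focused_search_recovers_substates(self, nested_fit):
        spec, super_of, series, truth, est = nested_fit
        series_map = {series.source_id: series}
        labels = est.predict(series)
        segs = dwell_segments(labels, series.frame_interval, series.source_id)
        for st in est.states_:
            subs = find_substates(st, series_map, (250.0,), segments=segs)
            assert len(subs) >= 2
            largest = sorted(subs, key=lambda s: -s.n_pieces)[:2]
            sub_ids = set()
            for sub in largest:
                frames = np.concatenate(
                    [truth.labels[p.start : p.stop] for p in sub.defining_pieces]
                )
                dom = int(np.bincount(frames).argmax())
                assert (frames == dom).mean() > 0.85
                sub_ids.add(dom)
            # the two dominant sub-states are this super-state's own pair
            assert len(sub_ids) == 2
            assert len({int(super_of[i]) for i in sub_ids}) == 1
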