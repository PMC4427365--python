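"""Lifetimes, stretched-exponential equilibration, rates, relaxation oracle."""

import numpy as np
import pytest

import trajmap as tm
from trajmap.basis import DihedralBasis
from trajmap.indicators import UNASSIGNED, DwellSegment, dwell_segments
from trajmap.kinetics import (
    FokkerPlanckToyModel,
    StretchedExpFit,
    difference_graph,
    estimate_lifetime,
    fit_stretched_exponential,
    lifetimes_from_events,
    pavr_overlap_curve,
    relaxation_curve,
    residence_times,
    tau_eq_from_fit,
    transition_rates,
)
from trajmap.mapping import TrajectoryPiece, cut_pieces


def _segs(durations, state=1):
    segs, t = [], 0
    for d in durations:
        segs.append(DwellSegment(state, "t", t, t + d, 1.0))
        t += d
    return segs


class TestLifetime:
    def test_mean_of_dwells(self):
        mean, se = estimate_lifetime(_segs([10, 20, 30]))
        assert mean == 20.0
        assert se == pytest.approx(10.0 / np.sqrt(3))

    def test_single_segment_has_no_error_bar(self):
        mean, se = estimate_lifetime(_segs([42]))
        assert mean == 42.0 and se is None

    def test_no_segments_raises(self):
        with pytest.raises(ValueError, match="missing lifetime"):
            estimate_lifetime([DwellSegment(UNASSIGNED, "t", 0, 5, 1.0)])

    def test_exponential_dwells_recover_rate(self):
        rng = np.random.default_rng(0)
        lam = 0.02
        durations = np.maximum(1, rng.exponential(1 / lam, 200).astype(int))
        mean, se = estimate_lifetime(_segs(durations.tolist()))
        assert abs(mean - 1 / lam) < 3 * se

    def test_residence_times_from_events(self):
        events = [[(1, 2, 10.0), (2, 1, 25.0), (1, 2, 31.0)]]
        res = residence_times(events)
        assert res == {2: [15.0], 1: [6.0]}
        assert lifetimes_from_events(events) == {2: 15.0, 1: 6.0}


class TestStretchedExponential:
    def test_exact_recovery_single_exponential(self):
        u = np.linspace(1, 100, 60)
        v = 1.0 * (1 - np.exp(-(0.1 * u) ** 1.0))
        fit = fit_stretched_exponential(u, v)
        assert fit.a == pytest.approx(0.1, rel=1e-6)
        assert fit.b == pytest.approx(1.0, rel=1e-6)
        assert fit.c == pytest.approx(1.0, rel=1e-6)

    def test_exact_recovery_stretched(self):
        u = np.geomspace(0.5, 300, 80)
        v = 0.9 * (1 - np.exp(-np.sqrt(0.05 * u)))
        fit = fit_stretched_exponential(u, v)
        assert fit.a == pytest.approx(0.05, rel=1e-4)
        assert fit.b == pytest.approx(0.5, rel=1e-4)
        assert fit.c == pytest.approx(0.9, rel=1e-4)

    def test_noisy_recovery_is_unbiased(self):
        # tau_eq recovered within 15% on average over noisy replicates
        a, b, c = 0.08, 0.7, 0.95
        u = np.geomspace(1, 200, 50)
        truth = c * (1 - np.exp(-((a * u) ** b)))
        true_tau = tau_eq_from_fit(StretchedExpFit(a, b, c, 0.0))
        taus = []
        rng = np.random.default_rng(1)
        for _ in range(100):
            fit = fit_stretched_exponential(u, truth + rng.normal(0, 0.02, u.shape))
            taus.append(tau_eq_from_fit(fit))
        assert np.mean(taus) == pytest.approx(true_tau, rel=0.15)

    def test_validation(self):
        with pytest.raises(ValueError):
            fit_stretched_exponential(np.array([1, 2, 3]), np.array([0.1, 0.2, 0.3]))
        with pytest.raises(ValueError):
            StretchedExpFit(-1.0, 1.0, 1.0, 0.0)

    @pytest.mark.parametrize(
        "a,b,expected", [(1.0, 1.0, 1.0), (2.0, 1.0, 0.5), (1.0, 0.5, 2.0)]
    )
    def test_tau_eq_closed_forms(self, a, b, expected):
        assert tau_eq_from_fit(StretchedExpFit(a, b, 1.0, 0.0)) == pytest.approx(
            expected
        )


class TestTransitionRates:
    def test_worked_rate_arithmetic(self):
        events = [(0, 1, 1.0)] * 3 + [(0, 2, 2.0)]
        net = transition_rates(events, {0: 10.0})
        assert net.rate(0, 1) == pytest.approx(0.075)
        assert net.rate(0, 2) == pytest.approx(0.025)
        assert net.count(0, 1) == 3

    def test_outgoing_rates_sum_to_inverse_lifetime(self):
        rng = np.random.default_rng(2)
        events = [
            (int(rng.integers(4)), int(rng.integers(4, 8)), float(t))
            for t in range(200)
        ]
        lifetimes = {i: float(rng.uniform(5, 50)) for i in range(4)}
        net = transition_rates(events, lifetimes)
        for i in range(4):
            assert net.outgoing_rate_sum(i) == pytest.approx(
                1.0 / lifetimes[i], abs=1e-9
            )

    def test_state_without_events_has_no_outgoing_edges(self):
        net = transition_rates([(0, 1, 1.0)], {0: 5.0, 1: 7.0})
        assert list(net.graph.out_edges(1)) == []

    def test_missing_lifetime_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            transition_rates([(0, 1, 1.0)], {1: 5.0})

    def test_one_directional_edges_preserved(self):
        net = transition_rates([(0, 1, 1.0)], {0: 5.0})
        assert net.graph.has_edge(0, 1) and not net.graph.has_edge(1, 0)

    def test_recovered_rates_match_generator(self, three_state):
        # full pipeline check lives in the acceptance suite; here: the
        # qualitative structure (cycle edges dominate) survives estimation
        fs = three_state
        segs = dwell_segments(fs.labels, 1.0, "synthetic")
        from trajmap.indicators import transition_events

        events = transition_events(segs)
        lifetimes = lifetimes_from_events([events])
        net = transition_rates(events, lifetimes)
        inverse = {v: k for k, v in fs.match.items()}
        for s in range(3):
            i, j = inverse[s], inverse[(s + 1) % 3]
            assert net.count(i, j) > 50


class TestToyRelaxationModel:
    def test_generator_validation(self):
        with pytest.raises(ValueError, match="sum"):
            FokkerPlanckToyModel(np.array([[1.0, 0.0], [0.0, 1.0]]))

    def test_ground_mode_is_stationary_distribution(self, toy_relaxation_model):
        m = toy_relaxation_model
        assert m.eigenvalues[0] == 0.0
        assert np.all(np.diff(m.eigenvalues) >= -1e-12)
        assert m.eigenfunctions[:, 0] ** 2 == pytest.approx(m.stationary, abs=1e-10)

    def test_eigen_propagation_matches_matrix_exponential(self, toy_relaxation_model):
        m = toy_relaxation_model
        p0 = np.array([0.2, 0.0, 0.5, 0.3, 0.0])
        for t in (0.1, 1.0, 7.5):
            assert m.propagate(p0, t) == pytest.approx(
                m.propagate_expm(p0, t), abs=1e-8
            )

    def test_stationary_start_has_flat_overlap(self, toy_relaxation_model):
        m = toy_relaxation_model
        ts = np.geomspace(0.1, 30, 8)
        vals = m.pavr_overlap(m.stationary, ts)
        assert vals == pytest.approx(np.ones_like(ts), abs=1e-10)

    def test_monte_carlo_matches_closed_form(self, toy_relaxation_model):
        m = toy_relaxation_model
        p0 = np.array([1.0, 0, 0, 0, 0])
        ts = np.geomspace(0.2, 60, 10)
        closed = m.pavr_overlap(p0, ts)
        rng = np.random.default_rng(1)
        batches = np.array(
            [m.pavr_overlap_mc(p0, ts, 400, rng) for _ in range(8)]
        )
        mc = batches.mean(axis=0)
        sigma = batches.std(axis=0, ddof=1) / np.sqrt(8)
        assert np.all(np.abs(mc - closed) < 3 * sigma + 1e-3)

    def test_tail_decays_as_inverse_time_squared(self, toy_relaxation_model):
        m = toy_relaxation_model
        p0 = np.array([1.0, 0, 0, 0, 0])
        ts = np.geomspace(20, 200, 10)
        slope = np.polyfit(np.log(ts), np.log(m.pavr_overlap(p0, ts) - 1), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.2)


class TestRelaxationCurves:
    def test_full_prefix_of_single_defining_piece_reaches_one(self):
        rng = np.random.default_rng(4)
        angles = rng.vonmises(0.0, 3.0, size=(300, 2))
        series = tm.DihedralSeries(angles, 1.0, "r")
        basis = DihedralBasis().fit(angles)
        piece = TrajectoryPiece("r", 0, 300, 1.0)
        state = tm.MetastableState(1, [piece], 300.0)
        u, v = relaxation_curve(piece, state, {"r": series}, basis)
        assert u[-1] == 300.0
        assert v[-1] == pytest.approx(1.0, abs=1e-9)
        assert v[0] < 1.0  # a single frame does not cover the state

    def test_curve_reaches_plateau_on_mixing_timescale(self, kinetics_system):
        fs = kinetics_system
        st = fs.est.states_[0]
        curves = [
            relaxation_curve(p, st, fs.series_map, fs.est.basis_)[1]
            for p in st.defining_pieces[:10]
        ]
        u = relaxation_curve(
            st.defining_pieces[0], st, fs.series_map, fs.est.basis_
        )[0]
        mean_curve = np.mean(curves, axis=0)
        u95 = u[np.argmax(mean_curve >= 0.95)]
        # equilibration completes within ~2 decades of the 10 ps mixing time
        assert 10.0 <= u95 <= 1500.0

    def test_tau_eq_below_tau_life_on_metastable_fixture(self, kinetics_system):
        for st in kinetics_system.est.states_:
            assert st.tau_eq is not None and st.tau_life is not None
            margin = 2 * ((st.tau_eq_se or 0.0) + (st.tau_life_se or 0.0))
            assert st.tau_eq <= st.tau_life + margin
            assert st.kappa > 1.0


class TestPavrOverlapCurve:
    def test_equilibrated_ensemble_stays_near_one(self):
        rng = np.random.default_rng(5)
        angles = rng.vonmises(0.7, 4.0, size=(20_000, 2))
        series = tm.DihedralSeries(angles, 1.0, "eq")
        basis = DihedralBasis().fit(angles)
        pieces = cut_pieces(series.n_frames, 500, "eq", 1.0)
        grid = np.array([50, 200, 500])
        # the finite-ensemble noise floor scales as rank/(t * n_pieces)
        vals = pavr_overlap_curve(pieces, {"eq": series}, basis, grid)
        assert vals == pytest.approx(np.ones_like(grid, dtype=float), abs=0.05)
        assert vals[-1] == pytest.approx(1.0, abs=0.01)


class TestDifferenceGraph:
    def test_state_against_itself_is_zero(self):
        rng = np.random.default_rng(6)
        angles = rng.vonmises(0.0, 5.0, size=(100, 3))
        series = tm.DihedralSeries(angles, 1.0, "d")
        st = tm.MetastableState(1, [TrajectoryPiece("d", 0, 100, 1.0)], 10.0)
        assert difference_graph(st, st, {"d": series}) == pytest.approx(
            np.zeros(6), abs=0
        )

    def test_dimension_is_twice_angle_count(self):
        rng = np.random.default_rng(7)
        angles = rng.vonmises(0.0, 5.0, size=(50, 22))
        series = tm.DihedralSeries(angles, 1.0, "d")
        st = tm.MetastableState(1, [TrajectoryPiece("d", 0, 25, 1.0)], 10.0)
        st2 = tm.MetastableState(2, [TrajectoryPiece("d", 25, 50, 1.0)], 10.0)
        assert difference_graph(st, st2, {"d": series}).shape == (44,)

    def test_single_angle_change_is_localized(self):
        rng = np.random.default_rng(8)
        base = np.array([0.5, -1.0, 2.0, 0.0])
        shifted = base.copy()
        shifted[2] += np.pi / 2  # states differ in angle 2 only
        a = rng.vonmises(base, 50.0, size=(4000, 4))
        b = rng.vonmises(shifted, 50.0, size=(4000, 4))
        series = tm.DihedralSeries(np.vstack([a, b]), 1.0, "loc")
        sa = tm.MetastableState(1, [TrajectoryPiece("loc", 0, 4000, 1.0)], 10.0)
        sb = tm.MetastableState(2, [TrajectoryPiece("loc", 4000, 8000, 1.0)], 10.0)
        diff = np.abs(difference_graph(sa, sb, {"loc": series}))
        on_angle = diff[4:6].max()
        off_angle = np.delete(diff, [4, 5]).max()
        assert on_angle > 10 * off_angle
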