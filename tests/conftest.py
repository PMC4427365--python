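"""Shared fixtures: synthetic systems fitted once per session."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pytest

import trajmap as tm
from trajmap.indicators import dwell_segments
from trajmap.kinetics import estimate_state_timescales


@dataclass
class FittedSystem:
    """A generated system plus the fitted estimator and truth matching."""

    spec: tm.SyntheticSpec
    series: tm.DihedralSeries
    truth: tm.GroundTruth
    est: tm.TrajectoryMapping
    labels: np.ndarray  # predicted per-frame state ids
    match: dict  # estimator state_id -> dominant true hidden state

    @property
    def series_map(self):
        return {self.series.source_id: self.series}


def _match_states(est, truth):
    match = {}
    for st in est.states_:
        c = Counter()
        for p in st.defining_pieces:
            c.update(truth.labels[p.start : p.stop].tolist())
        match[st.state_id] = c.most_common(1)[0][0]
    return match


def _fit(spec, **est_kwargs) -> FittedSystem:
    series, truth = tm.generate(spec)
    est = tm.TrajectoryMapping(**est_kwargs)
    est.fit(series)
    return FittedSystem(
        spec, series, truth, est, est.predict(series), _match_states(est, truth)
    )


@pytest.fixture(scope="session")
def three_state() -> FittedSystem:
    """3 well-separated torsional states on a jump cycle, 1e5 frames."""
    return _fit(tm.well_separated_spec(seed=0), tau_schedule=(150.0,))


@pytest.fixture(scope="session")
def two_timescale() -> FittedSystem:
    """Disjoint slow (5 ns) and fast (300 ps) states on a ring."""
    return _fit(tm.two_timescale_spec(seed=5), tau_schedule=(2000.0, 150.0))


@pytest.fixture(scope="session")
def kinetics_system() -> FittedSystem:
    """Slow-mixing states where relaxation curves resolve τ_eq.

    Internal angle decorrelation (10 ps) spans many frames and the basis is
    rich relative to the state count, so a short trajectory prefix overlaps
    its state only partially and the relaxation curve rises from low values
    — the regime in which the stretched-exponential τ_eq estimate is
    meaningful.  Dwells of 9 ns leave a wide τ_eq < τ_life margin.
    """
    spec = tm.well_separated_spec(
        n_angles=4,
        mean_dwell=9000.0,
        mixing_time=10.0,
        total_frames=400_000,
        seed=0,
    )
    fs = _fit(spec, tau_schedule=(3000.0,), half_window=900)
    segs = dwell_segments(fs.labels, 1.0, fs.series.source_id)
    estimate_state_timescales(fs.est.states_, segs, fs.series_map, fs.est.basis_)
    return fs


@pytest.fixture(scope="session")
def toy_relaxation_model():
    """Reversible 5-state birth-death generator with known eigen-structure."""
    rates_up = np.array([1.0, 0.5, 0.8, 0.3])
    rates_dn = np.array([0.7, 0.9, 0.4, 0.6])
    Q = np.zeros((5, 5))
    for i in range(4):
        Q[i, i + 1] = rates_up[i]
        Q[i + 1, i] = rates_dn[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return tm.FokkerPlanckToyModel(Q)
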