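"""State-indicator curves, frame assignment, dwells and transition events.

Once metastable states are identified, a trajectory is projected onto them
as *state-indicator curves*: for each frame t the window [t−Δt, t+Δt] is
mapped to a unit vector and dotted with each state's unit representative,

    f_α(t) = v̂_α^s · v̂[t−Δt, t+Δt].

Inside state α the curve sits near 1 while all others sit near 0; the
curves jump in a step-like way at transitions.  A finite Δt suppresses
statistical noise at the cost of Δt-blurred transition times.  Frames whose
summed indicators exceed a threshold (default 0.9) are assigned to the
argmax state; runs of constant label become dwell segments, and consecutive
distinct-state segments yield transition events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import DihedralBasis, DihedralSeries

__all__ = [
    "UNASSIGNED",
    "IndicatorCurve",
    "DwellSegment",
    "indicator_matrix",
    "indicator_curves",
    "auto_half_windows",
    "assign_frames",
    "dwell_segments",
    "transition_events",
    "accounted_fraction",
]

UNASSIGNED = -1


@dataclass
class IndicatorCurve:
    """f_α(t) along one trajectory for one state."""

    state_id: int
    source_id: str
    values: np.ndarray
    half_window: int


@dataclass(frozen=True)
class DwellSegment:
    """A maximal run of frames with one label (state_id or UNASSIGNED)."""

    state_id: int
    source_id: str
    start: int
    stop: int
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return self.stop - self.start

    @property
    def duration(self) -> float:
        """Dwell duration in ps."""
        return self.n_frames * self.frame_interval


def indicator_matrix(
    series: DihedralSeries,
    representatives: np.ndarray,
    basis: DihedralBasis,
    half_window: int | np.ndarray = 25,
) -> np.ndarray:
    """All state-indicator curves of one trajectory, as a (T, n_states) array.

    ``representatives`` is (n_states, rank+1) of unit state vectors in
    ``basis``.  ``half_window`` (Δt, frames) may be a scalar or one value
    per state: a state identified at piece length τ needs a window long
    enough to average over its internal dynamics, so multi-timescale state
    sets use per-state windows.  Windows are clipped (shrunk) at the
    trajectory ends; half_window=0 uses the single frame.
    """
    reps = np.atleast_2d(np.asarray(representatives, dtype=float))
    T = series.n_frames
    n_states = reps.shape[0]
    if n_states == 0:
        return np.empty((T, 0))
    hw = np.broadcast_to(np.asarray(half_window, dtype=int), (n_states,))
    feats = basis.transform(series.angles)
    csum = np.vstack([np.zeros((1, feats.shape[1])), np.cumsum(feats, axis=0)])
    t = np.arange(T)
    out = np.empty((T, n_states))
    for w in np.unique(hw):
        lo = np.maximum(t - w, 0)
        hi = np.minimum(t + w + 1, T)
        window_means = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
        comps = np.hstack([np.ones((T, 1)), window_means])
        units = comps / np.linalg.norm(comps, axis=1, keepdims=True)
        cols = hw == w
        out[:, cols] = units @ reps[cols].T
    return out


def auto_half_windows(
    states, frame_interval: float, minimum: int = 25, fraction: int = 40
) -> np.ndarray:
    """Per-state indicator half-windows: max(minimum, level_τ/fraction frames).

    A state identified from τ-length pieces equilibrates internally on a
    timescale up to ~τ, so its indicator window must average over a
    matching stretch; short-τ states keep the noise-suppression floor.
    """
    return np.array(
        [
            max(minimum, int(round(st.level_tau / frame_interval / fraction)))
            for st in states
        ],
        dtype=int,
    )


def indicator_curves(
    series: DihedralSeries,
    states,
    basis: DihedralBasis,
    half_window: int | np.ndarray | str = "auto",
) -> list[IndicatorCurve]:
    """Per-state :class:`IndicatorCurve` objects for one trajectory."""
    reps = np.array([st.representative_ for st in states])
    if isinstance(half_window, str):
        half_window = auto_half_windows(states, series.frame_interval)
    hw = np.broadcast_to(np.asarray(half_window, dtype=int), (len(states),))
    mat = indicator_matrix(series, reps, basis, hw)
    return [
        IndicatorCurve(st.state_id, series.source_id, mat[:, k], int(hw[k]))
        for k, st in enumerate(states)
    ]


def assign_frames(curves: np.ndarray, assign_threshold: float = 0.9) -> np.ndarray:
    """Label frames from an indicator matrix (T, n_states).

    A frame gets the argmax state (column index) when the summed indicator
    values exceed ``assign_threshold``, else UNASSIGNED.  Ties break to the
    lowest column index.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    T = curves.shape[0]
    if curves.shape[1] == 0:
        return np.full(T, UNASSIGNED)
    labels = np.argmax(curves, axis=1)
    labels[curves.sum(axis=1) <= assign_threshold] = UNASSIGNED
    return labels


def _runs(labels: np.ndarray):
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [labels.size]])
    return starts, stops


def dwell_segments(
    labels: np.ndarray,
    frame_interval: float,
    source_id: str = "traj",
    bridge_gap: int = 0,
    min_segment: int = 0,
) -> list[DwellSegment]:
    """Maximal constant-label runs; segments tile the trajectory.

    ``min_segment`` (frames): assigned runs shorter than this are
    demoted to UNASSIGNED before anything else — a dwell shorter than the
    indicator window cannot be resolved by it, so such runs are labelling
    flicker, not states.  ``bridge_gap``: UNASSIGNED gaps of at most this
    many frames flanked by the same state on both sides are then absorbed
    into that state.  Both are opt-in (default 0).
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    if min_segment > 0:
        labels = labels.copy()
        starts, stops = _runs(labels)
        for s, e in zip(starts, stops):
            if labels[s] != UNASSIGNED and e - s < min_segment:
                labels[s:e] = UNASSIGNED
    if bridge_gap > 0:
        labels = labels.copy()
        starts, stops = _runs(labels)
        for s, e in zip(starts, stops):
            if (
                labels[s] == UNASSIGNED
                and e - s <= bridge_gap
                and s > 0
                and e < labels.size
                and labels[s - 1] == labels[e]
            ):
                labels[s:e] = labels[s - 1]
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [labels.size]])
    return [
        DwellSegment(int(labels[s]), source_id, int(s), int(e), frame_interval)
        for s, e in zip(starts, stops)
    ]


def transition_events(
    segments: list[DwellSegment],
) -> list[tuple[int, int, float]]:
    """Ordered (from_state, to_state, time ps) between consecutive states.

    An event is recorded between consecutive non-UNASSIGNED segments with
    distinct states; the event time is the start of the destination
    segment.  UNASSIGNED gaps in between do not cancel the event.
    """
    events: list[tuple[int, int, float]] = []
    prev: DwellSegment | None = None
    for seg in segments:
        if seg.state_id == UNASSIGNED:
            continue
        if prev is not None and prev.state_id != seg.state_id:
            events.append(
                (prev.state_id, seg.state_id, seg.start * seg.frame_interval)
            )
        prev = seg
    return events


def accounted_fraction(labels: np.ndarray) -> float:
    """Fraction of frames assigned to any metastable state."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    return float((labels != UNASSIGNED).mean())
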