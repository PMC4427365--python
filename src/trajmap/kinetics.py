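"""Timescales, transition rates and relaxation diagnostics.

Two timescales characterize a metastable state: its lifetime τ_life (mean
duration of a continuous stay) and its local equilibration time τ_eq (how
fast a trajectory loses memory inside it); metastability requires
τ_eq < τ_life.  τ_life is estimated as the mean dwell-segment duration.
τ_eq is estimated from relaxation curves — the SIP between a defining
piece's growing prefix [0, u] and the state representative — fitted with a
stretched exponential c·{1 − exp[−(a·u)^b]}, whence

    τ_eq^est = Γ(1/b) / (a·b)        (= Γ(1 + 1/b)/a by the Γ recurrence).

Observed transitions give directed rates k_ij = N_ij / (τ_life^i · Σ_j N_ij),
so each state's outgoing rates sum to 1/τ_life.  The network is kept as
observed: finite sampling may break detailed balance and single-directional
edges are preserved.

A discrete-state generator-matrix toy model provides an analytic oracle for
the overlap-relaxation diagnostic: with P_ref the equilibrium distribution,

    ⟨P_avr(t)|P_avr(t)⟩ = 1 + (1/t²) Σ_{n>0} (C_n/λ_n)² (e^{−λ_n t} − 1)²,

which decays as 1/t² once the exponentials die — the signature that the
sample inner-product estimate behaves like the true overlap integral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.linalg import expm
from scipy.optimize import curve_fit
from scipy.special import gamma as gamma_fn

from .basis import DihedralBasis, DihedralSeries
from .clustering import MetastableState, state_representative
from .indicators import UNASSIGNED, DwellSegment
from .mapping import TrajectoryPiece

logger = logging.getLogger(__name__)

__all__ = [
    "StretchedExpFit",
    "TransitionNetwork",
    "FokkerPlanckToyModel",
    "estimate_lifetime",
    "residence_times",
    "lifetimes_from_events",
    "relaxation_curve",
    "fit_stretched_exponential",
    "tau_eq_from_fit",
    "estimate_state_timescales",
    "transition_rates",
    "pavr_overlap_curve",
    "difference_graph",
]


@dataclass
class StretchedExpFit:
    """Parameters of c·{1 − exp[−(a·u)^b]} fitted to a relaxation curve."""

    a: float  # inverse-time scale, 1/ps
    b: float  # stretch exponent
    c: float  # plateau amplitude
    residual: float  # RMS fit error

    def __post_init__(self) -> None:
        if not (self.a > 0 and 0 < self.b <= 4 and 0 < self.c <= 1.2):
            raise ValueError("fit parameters out of bounds: a>0, 0<b<=4, 0<c<=1.2")

    def __call__(self, u: np.ndarray) -> np.ndarray:
        return _stretched_exp(np.asarray(u, dtype=float), self.a, self.b, self.c)


def _stretched_exp(u, a, b, c):
    return c * (1.0 - np.exp(-np.power(a * u, b)))


def fit_stretched_exponential(
    u: np.ndarray, values: np.ndarray, n_multistart: int = 5, seed: int = 0
) -> StretchedExpFit:
    """Nonlinear least-squares fit of the stretched-exponential model.

    Initialized at b=1, c=final value, a=1/u_half (u where the curve first
    reaches half its final value); on failure, up to ``n_multistart``
    jittered restarts.  Raises RuntimeError carrying the best attempt if
    all fail.
    """
    u = np.asarray(u, dtype=float)
    values = np.asarray(values, dtype=float)
    if u.shape[0] < 5:
        raise ValueError("need at least 5 points")
    if np.any(np.diff(u) <= 0):
        raise ValueError("u must be strictly increasing")
    c0 = float(np.clip(values[-1], 1e-3, 1.2))
    half_idx = int(np.argmax(values >= 0.5 * c0))
    u_half = u[half_idx] if values[half_idx] >= 0.5 * c0 else u[-1]
    a0 = 1.0 / max(u_half, u[0])
    bounds = ([1e-12, 0.1, 1e-6], [np.inf, 4.0, 1.2])
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray] | None = None
    p0 = np.array([a0, 1.0, c0])
    for attempt in range(n_multistart + 1):
        try:
            popt, _ = curve_fit(
                _stretched_exp, u, values, p0=p0, bounds=bounds, maxfev=20000
            )
            resid = float(np.sqrt(np.mean((_stretched_exp(u, *popt) - values) ** 2)))
            if best is None or resid < best[0]:
                best = (resid, popt)
            break
        except (RuntimeError, ValueError):
            jitter = rng.lognormal(0.0, 0.5, size=3)
            p0 = np.clip(
                np.array([a0, 1.0, c0]) * jitter,
                [1e-10, 0.05, 0.01],
                [1e6, 4.0, 1.2],
            )
    if best is None:
        raise RuntimeError("stretched-exponential fit failed after multistart")
    resid, popt = best
    return StretchedExpFit(float(popt[0]), float(popt[1]), float(popt[2]), resid)


def tau_eq_from_fit(fit: StretchedExpFit) -> float:
    """Equilibration-time estimate Γ(1/b)/(a·b) from a fitted curve, ps."""
    return float(gamma_fn(1.0 / fit.b) / (fit.a * fit.b))


def relaxation_curve(
    piece: TrajectoryPiece,
    state: MetastableState,
    series_map: dict[str, DihedralSeries],
    basis: DihedralBasis,
    n_points: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """SIP of a piece's growing prefix [0, u] against its state.

    Returns (u grid in ps, SIP values) on ~``n_points`` log-spaced prefix
    lengths; the curve rises toward ≈1 on the τ_eq timescale.
    """
    series = series_map[piece.source_id]
    feats = basis.transform(series.angles[piece.start : piece.stop])
    L = feats.shape[0]
    lengths = np.unique(
        np.round(np.geomspace(1, L, min(n_points, L))).astype(int)
    )
    csum = np.cumsum(feats, axis=0)
    means = csum[lengths - 1] / lengths[:, None]
    comps = np.hstack([np.ones((len(lengths), 1)), means])
    units = comps / np.linalg.norm(comps, axis=1, keepdims=True)
    rep = state.representative_
    if rep is None:
        rep = state_representative(state, series_map, basis)
    return lengths * piece.frame_interval, units @ rep


def estimate_lifetime(
    segments: list[DwellSegment],
) -> tuple[float, float | None]:
    """Mean dwell duration (ps) and its standard error (None when n < 3)."""
    durations = np.array(
        [s.duration for s in segments if s.state_id != UNASSIGNED], dtype=float
    )
    if durations.size == 0:
        raise ValueError("missing lifetime: no dwell segments for this state")
    mean = float(durations.mean())
    se = (
        float(durations.std(ddof=1) / np.sqrt(durations.size))
        if durations.size >= 3
        else None
    )
    return mean, se


def residence_times(
    events_per_trajectory: list[list[tuple[int, int, float]]],
) -> dict[int, list[float]]:
    """Visit durations per state, measured between transition events.

    A state's residence runs from the event that enters it to the event
    that leaves it.  Unlike dwell-segment durations, event-to-event times
    include the unassigned boundary gaps symmetrically (the true boundary
    sits somewhere inside each gap) and are unaffected by brief unassigned
    dips inside a stay, so they carry no boundary-blur bias.  Events must
    be grouped per trajectory; the first and last (incomplete) visits of
    each trajectory are excluded.
    """
    out: dict[int, list[float]] = {}
    for events in events_per_trajectory:
        for (_i, j, t1), (_j2, _k, t2) in zip(events, events[1:]):
            out.setdefault(j, []).append(t2 - t1)
    return out


def lifetimes_from_events(
    events_per_trajectory: list[list[tuple[int, int, float]]],
) -> dict[int, float]:
    """Mean event-to-event residence per state (ps)."""
    return {
        s: float(np.mean(r)) for s, r in residence_times(events_per_trajectory).items()
    }


def estimate_state_timescales(
    states: list[MetastableState],
    segments: list[DwellSegment],
    series_map: dict[str, DihedralSeries],
    basis: DihedralBasis,
    n_points: int = 50,
) -> None:
    """Fill tau_life and tau_eq (with standard errors) on each state in place.

    τ_life from the state's dwell segments; τ_eq as the mean of per-piece
    τ_eq^est values over the defining pieces (pieces whose fit fails are
    excluded with a warning).  States with no dwell segment keep
    tau_life=None (reported without error bar downstream).
    """
    by_state: dict[int, list[DwellSegment]] = {}
    for seg in segments:
        by_state.setdefault(seg.state_id, []).append(seg)
    for st in states:
        segs = by_state.get(st.state_id, [])
        if segs:
            st.tau_life, st.tau_life_se = estimate_lifetime(segs)
        else:
            logger.warning("state %d: no dwell segments, lifetime missing", st.state_id)
        taus: list[float] = []
        for piece in st.defining_pieces:
            u, vals = relaxation_curve(piece, st, series_map, basis, n_points)
            if u.shape[0] < 5:
                continue
            try:
                fit = fit_stretched_exponential(u, vals)
            except (RuntimeError, ValueError):
                logger.warning(
                    "state %d: relaxation fit failed for piece %s[%d:%d], excluded",
                    st.state_id,
                    piece.source_id,
                    piece.start,
                    piece.stop,
                )
                continue
            # a fit pinned to a parameter bound or with a large residual has
            # not converged to the model; treat it as failed
            if fit.b <= 0.12 or fit.c >= 1.19 or fit.residual > 0.08:
                logger.warning(
                    "state %d: degenerate relaxation fit for piece %s[%d:%d] "
                    "(a=%.3g b=%.3g c=%.3g resid=%.3g), excluded",
                    st.state_id, piece.source_id, piece.start, piece.stop,
                    fit.a, fit.b, fit.c, fit.residual,
                )
                continue
            taus.append(tau_eq_from_fit(fit))
        if taus:
            arr = np.array(taus)
            st.tau_eq = float(arr.mean())
            st.tau_eq_se = (
                float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size >= 3 else None
            )


@dataclass
class TransitionNetwork:
    """Directed transition network: states as nodes, rates on edges.

    Each edge (i, j) carries the observed jump count N_ij and the rate
    k_ij = N_ij / (τ_life^i Σ_j N_ij) in 1/ps, so a node's outgoing rates
    sum to 1/τ_life^i exactly.  ``groups`` optionally partitions nodes
    (user-supplied labels).
    """

    graph: nx.DiGraph
    groups: dict[int, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    def rate(self, i: int, j: int) -> float:
        return self.graph.edges[i, j]["rate"]

    def count(self, i: int, j: int) -> int:
        return self.graph.edges[i, j]["count"]

    def outgoing_rate_sum(self, i: int) -> float:
        return sum(d["rate"] for _, _, d in self.graph.out_edges(i, data=True))

    def edge_table(self) -> list[tuple[int, int, int, float]]:
        """(i, j, N_ij, k_ij) rows sorted by (i, j)."""
        return sorted(
            (i, j, d["count"], d["rate"])
            for i, j, d in self.graph.edges(data=True)
        )


def transition_rates(
    events: list[tuple[int, int, float]],
    lifetimes: dict[int, float],
    states: list[MetastableState] | None = None,
    groups: dict[int, str] | None = None,
) -> TransitionNetwork:
    """Build the transition network from observed events and lifetimes.

    ``events`` are (from_state, to_state, time) triples; ``lifetimes`` maps
    state_id to τ_life in ps and must cover every state with outgoing
    events.  States with zero outgoing events get no outgoing edges.
    """
    counts: dict[tuple[int, int], int] = {}
    for i, j, _t in events:
        counts[(i, j)] = counts.get((i, j), 0) + 1
    out_totals: dict[int, int] = {}
    for (i, _j), n in counts.items():
        out_totals[i] = out_totals.get(i, 0) + n
    missing = [i for i in out_totals if i not in lifetimes]
    if missing:
        raise ValueError(f"inconsistent input: no lifetime for states {missing}")
    graph = nx.DiGraph()
    node_ids = set(lifetimes) | {j for _i, j in counts}
    if states is not None:
        node_ids |= {st.state_id for st in states}
    meta = {st.state_id: st for st in states} if states else {}
    for i in sorted(node_ids):
        attrs = {"tau_life": lifetimes.get(i, float("nan"))}
        if i in meta:
            attrs.update(
                level_tau=meta[i].level_tau,
                tau_eq=meta[i].tau_eq if meta[i].tau_eq is not None else float("nan"),
            )
        graph.add_node(i, **attrs)
    for (i, j), n in sorted(counts.items()):
        rate = n / (lifetimes[i] * out_totals[i])
        graph.add_edge(i, j, count=n, rate=rate)
    return TransitionNetwork(graph, groups or {})


# ---------------------------------------------------------------------------
# Overlap-relaxation diagnostic and its analytic toy model
# ---------------------------------------------------------------------------


class FokkerPlanckToyModel:
    """Discrete-state generator matrix as an analytic relaxation oracle.

    A reversible rate matrix Q over a small state space stands in for the
    Fokker–Planck operator.  Reversibility makes the symmetrized matrix
    D^{−1/2} Qᵀ D^{1/2} (D = diag stationary distribution) symmetric, so the
    propagator decomposes into orthonormal eigenmodes φ_n with relaxation
    rates λ_n ≥ 0, λ_0 = 0 and φ_0 = √π.  The probability vector evolves as

        p_i(t) = √π_i Σ_n C_n φ_{n,i} e^{−λ_n t},   C_n = Σ_i φ_{n,i} p_i(0)/√π_i.

    ``pavr_overlap`` evaluates the closed-form self-overlap of the
    time-averaged distribution; ``pavr_overlap_mc`` estimates the same
    quantity by simulating jump trajectories and averaging their mapped
    vectors — the pair forms a dual-route check of the inner-product
    estimator.
    """

    def __init__(self, rate_matrix: np.ndarray):
        Q = np.asarray(rate_matrix, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError("rate matrix must be square")
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("generator rows must sum to 0")
        if np.any(Q - np.diag(np.diag(Q)) < -1e-12):
            raise ValueError("off-diagonal rates must be non-negative")
        self.Q = Q
        n = Q.shape[0]
        # stationary distribution: left null vector of Q
        evals, evecs = np.linalg.eig(Q.T)
        k = int(np.argmin(np.abs(evals)))
        pi = np.real(evecs[:, k])
        pi = np.abs(pi) / np.abs(pi).sum()
        if not np.allclose(pi @ Q, 0.0, atol=1e-8):
            raise ValueError("could not find stationary distribution")
        flux = pi[:, None] * Q
        if not np.allclose(flux, flux.T, atol=1e-8):
            raise ValueError("rate matrix must satisfy detailed balance")
        self.stationary = pi
        sqrt_pi = np.sqrt(pi)
        B = (Q.T / sqrt_pi[:, None]) * sqrt_pi[None, :]
        B = 0.5 * (B + B.T)
        lam, phi = np.linalg.eigh(-B)
        order = np.argsort(lam)
        lam, phi = lam[order], phi[:, order]
        lam[0] = 0.0
        if phi[:, 0] @ sqrt_pi < 0:
            phi[:, 0] = -phi[:, 0]
        self.eigenvalues = lam  # λ_n >= 0, ascending
        self.eigenfunctions = phi  # orthonormal columns; φ_0 = √π
        self.n_states = n

    def coefficients(self, p0: np.ndarray) -> np.ndarray:
        """Expansion coefficients C_n of an initial distribution."""
        p0 = np.asarray(p0, dtype=float)
        return self.eigenfunctions.T @ (p0 / np.sqrt(self.stationary))

    def propagate(self, p0: np.ndarray, t: float) -> np.ndarray:
        """P(t) via the eigen-expansion (equals expm(Qᵀ t) @ p0)."""
        C = self.coefficients(p0)
        amps = C * np.exp(-self.eigenvalues * t)
        return np.sqrt(self.stationary) * (self.eigenfunctions @ amps)

    def propagate_expm(self, p0: np.ndarray, t: float) -> np.ndarray:
        """Matrix-exponential propagation, the independent cross-check."""
        return expm(self.Q.T * t) @ np.asarray(p0, dtype=float)

    def pavr_overlap(self, p0: np.ndarray, times: np.ndarray) -> np.ndarray:
        """Closed-form ⟨P_avr(t)|P_avr(t)⟩ with P_ref the equilibrium law."""
        times = np.asarray(times, dtype=float)
        C = self.coefficients(p0)
        lam = self.eigenvalues
        out = np.ones_like(times)
        for n in range(1, self.n_states):
            out += (C[n] / (lam[n] * times)) ** 2 * (
                np.exp(-lam[n] * times) - 1.0
            ) ** 2
        return out

    def sample_paths(
        self, n_paths: int, t_max: float, p0: np.ndarray, rng: np.random.Generator
    ) -> list[tuple[np.ndarray, np.ndarray]]:
        """Gillespie jump paths: (jump times incl. 0 and t_max, state per interval)."""
        paths = []
        p0 = np.asarray(p0, dtype=float)
        exit_rates = -np.diag(self.Q)
        jump_probs = self.Q.copy()
        np.fill_diagonal(jump_probs, 0.0)
        with np.errstate(invalid="ignore"):
            jump_probs = np.where(
                exit_rates[:, None] > 0, jump_probs / exit_rates[:, None], 0.0
            )
        for _ in range(n_paths):
            s = int(rng.choice(self.n_states, p=p0))
            times = [0.0]
            states = []
            t = 0.0
            while t < t_max:
                states.append(s)
                if exit_rates[s] <= 0:
                    break
                t += rng.exponential(1.0 / exit_rates[s])
                if t >= t_max:
                    break
                times.append(t)
                s = int(rng.choice(self.n_states, p=jump_probs[s]))
            times.append(t_max)
            paths.append((np.array(times), np.array(states, dtype=int)))
        return paths

    def occupancies(self, path, t: float) -> np.ndarray:
        """Fraction of [0, t] spent in each state along one path."""
        times, states = path
        occ = np.zeros(self.n_states)
        for k, s in enumerate(states):
            lo = times[k]
            hi = times[k + 1] if k + 1 < len(times) else t
            if lo >= t:
                break
            occ[s] += min(hi, t) - lo
        return occ / t

    def pavr_overlap_mc(
        self,
        p0: np.ndarray,
        times: np.ndarray,
        n_paths: int,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Monte-Carlo ⟨P_avr|P_avr⟩: average mapped vectors over jump paths.

        The basis functions are the exact orthonormal modes Â_n = φ_n/φ_0
        (n ≥ 1); each path's [0, t] occupancy vector gives its time-averaged
        features, paths are ensemble-averaged, and the squared norm of the
        averaged vector (component 0 ≡ 1 included) estimates the overlap.
        """
        times = np.asarray(times, dtype=float)
        paths = self.sample_paths(n_paths, float(times.max()), p0, rng)
        A = self.eigenfunctions[:, 1:] / np.sqrt(self.stationary)[:, None]
        out = np.empty_like(times)
        for k, t in enumerate(times):
            occ = np.array([self.occupancies(p, t) for p in paths])
            v = occ @ A  # (n_paths, n_modes) time-averaged features
            vbar = v.mean(axis=0)
            out[k] = 1.0 + vbar @ vbar
        return out


def pavr_overlap_curve(
    pieces: list[TrajectoryPiece],
    series_map: dict[str, DihedralSeries],
    basis: DihedralBasis,
    t_grid_frames: np.ndarray,
) -> np.ndarray:
    """⟨P_avr(t)|P_avr(t)⟩ from an ensemble of equal-length pieces.

    For each t, each piece's [0, t] prefix is mapped to a vector, the
    vectors are ensemble-averaged, and the squared norm of the average is
    returned (the sample estimate of the self-overlap of the ensemble- and
    time-averaged distribution).  ``basis`` should be orthonormalized under
    the relevant local-equilibrium reference sample.
    """
    t_grid = np.asarray(t_grid_frames, dtype=int)
    prefix_means = []
    for piece in pieces:
        feats = basis.transform(
            series_map[piece.source_id].angles[piece.start : piece.stop]
        )
        csum = np.cumsum(feats, axis=0)
        prefix_means.append(csum[t_grid - 1] / t_grid[:, None])
    stacked = np.stack(prefix_means)  # (n_pieces, n_t, rank)
    vbar = stacked.mean(axis=0)
    return 1.0 + np.sum(vbar**2, axis=1)


def difference_graph(
    state_a: MetastableState,
    state_b: MetastableState,
    series_map: dict[str, DihedralSeries],
) -> np.ndarray:
    """Per-angle averaged (sin, cos) difference vector between two states.

    For each state, sin and cos of each of the D dihedral angles are
    averaged over the defining frames and aligned as 2D values ordered
    (sin θ_1, cos θ_1, sin θ_2, cos θ_2, …); the component-wise difference
    a − b localizes the torsional changes behind the transition.
    """

    def mean_sincos(state: MetastableState) -> np.ndarray:
        total = None
        n = 0
        for p in state.defining_pieces:
            ang = series_map[p.source_id].angles[p.start : p.stop]
            sc = np.empty((ang.shape[0], 2 * ang.shape[1]))
            sc[:, 0::2] = np.sin(ang)
            sc[:, 1::2] = np.cos(ang)
            s = sc.sum(axis=0)
            total = s if total is None else total + s
            n += ang.shape[0]
        if n == 0:
            raise ValueError("state has no defining frames")
        return total / n

    return mean_sincos(state_a) - mean_sincos(state_b)
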