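"""SIP clustering of mapped vectors and the top-down hierarchical driver.

Metastable states are found by grouping trajectory-mapped vectors whose
pairwise SIP exceeds a linkage threshold r_l (default 0.95); clusters with
more than N_ne^std (default 5) members become states, and states are then
refined until every pair is mutually near-orthogonal (SIP < 0.01).  A state
is findable at piece length τ only when τ_eq ≤ τ ≤ τ_life, so the driver
works top-down: it starts from long pieces to catch long-lived states, then
repeatedly cuts the still-unassigned stretches shorter to expose faster
states, excluding pieces that overlap states already found.

:class:`TrajectoryMapping` packages the whole procedure as a scikit-learn
style estimator; the module-level functions expose the individual steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .basis import DihedralBasis, DihedralSeries
from .mapping import MappedVector, TrajectoryPiece, cut_pieces, map_pieces

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringConfig",
    "MetastableState",
    "cluster_by_sip",
    "identify_states",
    "refine_states",
    "hierarchical_tm",
    "find_substates",
    "state_representative",
    "TrajectoryMapping",
]


@dataclass
class ClusteringConfig:
    """Thresholds and the τ schedule controlling state identification.

    r_l : SIP linkage threshold for grouping pieces (default 0.95).
    min_cluster : minimum defining-piece count N_ne^std; a cluster becomes
        a state only when strictly larger (default 5).
    state_orthogonality : maximum allowed inter-state SIP after refinement
        (default 0.01).
    overlap_exclusion : SIP above which a piece is deemed to belong to an
        already-identified state (default 0.5).
    tau_schedule : strictly decreasing piece lengths in ps.
    """

    r_l: float = 0.95
    min_cluster: int = 5
    state_orthogonality: float = 0.01
    overlap_exclusion: float = 0.5
    tau_schedule: tuple[float, ...] = (200_000.0, 20_000.0, 2_000.0)

    def __post_init__(self) -> None:
        if not 0 < self.state_orthogonality < self.overlap_exclusion < self.r_l <= 1:
            raise ValueError(
                "need 0 < state_orthogonality < overlap_exclusion < r_l <= 1"
            )
        if self.min_cluster < 2:
            raise ValueError("min_cluster must be >= 2")
        taus = tuple(self.tau_schedule)
        if any(b >= a for a, b in zip(taus, taus[1:])):
            raise ValueError("tau_schedule must be strictly decreasing")
        self.tau_schedule = taus


@dataclass(eq=False)
class MetastableState:
    """A kinetic metastable state: defining pieces plus timescales.

    The representative vector is the mapped vector of the pooled defining
    frames (equivalently the length-weighted mean of the members' raw
    components), unit-normalized.  It is recomputed whenever the basis
    changes; ``representative_`` caches the most recent value.
    """

    state_id: int
    defining_pieces: list[TrajectoryPiece]
    level_tau: float
    representative_: np.ndarray | None = None
    tau_eq: float | None = None
    tau_eq_se: float | None = None
    tau_life: float | None = None
    tau_life_se: float | None = None

    @property
    def kappa(self) -> float | None:
        """Metastability κ = τ_life / τ_eq (≈1 means diffusive)."""
        if self.tau_eq is None or self.tau_life is None or self.tau_eq <= 0:
            return None
        return self.tau_life / self.tau_eq

    @property
    def n_pieces(self) -> int:
        return len(self.defining_pieces)


def _pooled_components(
    pieces: list[TrajectoryPiece],
    series_map: dict[str, DihedralSeries],
    basis: DihedralBasis,
    feats_cache: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Mapped-vector components of the pooled frames of several pieces."""
    total = None
    n = 0
    for p in pieces:
        if feats_cache is not None and p.source_id in feats_cache:
            feats = feats_cache[p.source_id][p.start : p.stop]
        else:
            feats = basis.transform(series_map[p.source_id].angles[p.start : p.stop])
        s = feats.sum(axis=0)
        total = s if total is None else total + s
        n += feats.shape[0]
    return np.concatenate(([1.0], total / n))


def state_representative(
    state: MetastableState,
    series_map: dict[str, DihedralSeries],
    basis: DihedralBasis,
    feats_cache: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Unit representative vector of a state in the given basis."""
    comps = _pooled_components(state.defining_pieces, series_map, basis, feats_cache)
    return comps / np.linalg.norm(comps)


def cluster_by_sip(
    vectors: list[MappedVector], config: ClusteringConfig
) -> list[list[int]]:
    """Greedy seeded clustering of mapped vectors at SIP > r_l.

    Repeatedly: pick the unassigned vector with the most unassigned
    neighbours at SIP > r_l (ties broken by lowest index) as seed, form a
    provisional cluster of seed plus neighbours, recompute the cluster
    representative from the pooled frames (length-weighted component mean),
    and retain the members whose SIP to the representative exceeds r_l.
    The seed is always assigned (as a singleton if nothing else survives),
    so the loop terminates.  Returns clusters as lists of vector indices.
    """
    n = len(vectors)
    if n == 0:
        return []
    comps = np.array([v.components for v in vectors])
    lengths = np.array([v.piece.n_frames for v in vectors], dtype=float)
    units = comps / np.linalg.norm(comps, axis=1, keepdims=True)
    S = units @ units.T
    adjacency = S > config.r_l
    np.fill_diagonal(adjacency, False)
    unassigned = np.ones(n, dtype=bool)
    clusters: list[list[int]] = []
    while True:
        counts = (adjacency & unassigned).sum(axis=1)
        counts[~unassigned] = -1
        seed = int(np.argmax(counts))  # argmax takes the lowest index on ties
        if counts[seed] < 1:
            break
        members = np.flatnonzero(adjacency[seed] & unassigned).tolist()
        provisional = [seed] + members
        rep_comps = lengths[provisional] @ comps[provisional] / lengths[provisional].sum()
        rep_unit = rep_comps / np.linalg.norm(rep_comps)
        retained = [i for i in provisional if float(units[i] @ rep_unit) > config.r_l]
        if seed not in retained:
            retained = [seed]
        clusters.append(sorted(retained))
        unassigned[retained] = False
    return clusters


def identify_states(
    clusters: list[list[int]],
    vectors: list[MappedVector],
    config: ClusteringConfig,
    level_tau: float,
    series_map: dict[str, DihedralSeries],
    basis: DihedralBasis,
    first_state_id: int = 1,
) -> tuple[list[MetastableState], list[int]]:
    """Promote sufficiently large clusters to metastable states.

    A cluster becomes a state only if its size is strictly larger than
    ``min_cluster`` (excluding occasional concentrations of mapped
    vectors); members of smaller clusters return to the unassigned pool.
    Returns (states, indices of unassigned vectors).
    """
    states: list[MetastableState] = []
    assigned: set[int] = set()
    next_id = first_state_id
    for cluster in clusters:
        if len(cluster) > config.min_cluster:
            pieces = [vectors[i].piece for i in cluster]
            state = MetastableState(next_id, pieces, level_tau)
            state.representative_ = state_representative(state, series_map, basis)
            states.append(state)
            assigned.update(cluster)
            next_id += 1
    unassigned = [i for i in range(len(vectors)) if i not in assigned]
    return states, unassigned


def refine_states(
    states: list[MetastableState],
    config: ClusteringConfig,
    series_map: dict[str, DihedralSeries],
    basis: DihedralBasis,
    feats_cache: dict[str, np.ndarray] | None = None,
) -> tuple[list[MetastableState], list[TrajectoryPiece]]:
    """Refine states to mutual near-orthogonality (SIP < state_orthogonality).

    While some state pair overlaps: merge the pair if their SIP exceeds
    r_l (they are the same state split by noise); otherwise strip, from the
    *smaller* state of the pair only, the defining pieces whose SIP to the
    larger state's representative exceeds ``overlap_exclusion``.  The
    asymmetry matters: an overlapping pair is typically a genuine state
    versus a smaller cluster of mixed pieces that straddle it, and cluster
    size is the method's confidence proxy — stripping symmetrically would
    let the mixed cluster eat the genuine state's pieces.  A pair whose
    overlap persists although no defining piece is individually responsible
    (no piece above ``overlap_exclusion``) carries an irreducible residual
    from the finite basis and finite samples; it is accepted as-is with a
    logged residual rather than ground down.  States dropping below
    ``min_cluster`` pieces dissolve back to the unassigned pool.  Returns
    (refined states, freed pieces).
    """
    states = list(states)
    freed: list[TrajectoryPiece] = []
    for st in states:
        st.representative_ = state_representative(st, series_map, basis, feats_cache)

    def piece_sip(piece: TrajectoryPiece, rep: np.ndarray) -> float:
        comps = _pooled_components([piece], series_map, basis, feats_cache)
        return float(comps / np.linalg.norm(comps) @ rep)

    accepted: set[frozenset] = set()  # pairs with irreducible residual overlap
    while len(states) >= 2:
        reps = np.array([st.representative_ for st in states])
        S = reps @ reps.T
        for i, si in enumerate(states):
            for j, sj in enumerate(states):
                if i == j or frozenset((si.state_id, sj.state_id)) in accepted:
                    S[i, j] = -np.inf
        np.fill_diagonal(S, -np.inf)
        a, b = np.unravel_index(np.argmax(S), S.shape)
        if S[a, b] < config.state_orthogonality:
            break
        a, b = sorted((int(a), int(b)))
        sa, sb = states[a], states[b]
        if S[a, b] > config.r_l:
            logger.info(
                "refine: merging states %d and %d (SIP %.3f)",
                sa.state_id, sb.state_id, S[a, b],
            )
            sa.defining_pieces = sa.defining_pieces + sb.defining_pieces
            sa.representative_ = state_representative(sa, series_map, basis, feats_cache)
            states.pop(b)
            continue
        # strip mixed pieces from the smaller state only; ties break to the
        # later-found state (higher index in the pair ordering)
        small, big = (sa, sb) if len(sa.defining_pieces) < len(sb.defining_pieces) else (sb, sa)
        sips = [piece_sip(p, big.representative_) for p in small.defining_pieces]
        doomed = [i for i, s in enumerate(sips) if s > config.overlap_exclusion]
        if not doomed:
            # residual overlap with no individually responsible piece:
            # a finite-basis/finite-sample floor, kept and reported
            accepted.add(frozenset((sa.state_id, sb.state_id)))
            logger.info(
                "refine: states %d and %d keep residual SIP %.3f "
                "(no defining piece overlaps the partner)",
                sa.state_id, sb.state_id, S[a, b],
            )
            continue
        else:
            logger.info(
                "refine: stripping %d piece(s) from state %d "
                "(overlap %.3f with state %d)",
                len(doomed), small.state_id, S[a, b], big.state_id,
            )
            freed.extend(small.defining_pieces[i] for i in doomed)
            small.defining_pieces = [
                p for i, p in enumerate(small.defining_pieces) if i not in set(doomed)
            ]
        dissolved = [
            st for st in states if len(st.defining_pieces) <= config.min_cluster
        ]
        for st in dissolved:
            logger.info(
                "refine: dissolving state %d (%d pieces left)",
                st.state_id, len(st.defining_pieces),
            )
            freed.extend(st.defining_pieces)
            states.remove(st)
        for st in states:
            st.representative_ = state_representative(st, series_map, basis, feats_cache)
    return states, freed


def _spans_from_pieces(pieces: list[TrajectoryPiece]) -> list[tuple[str, int, int]]:
    """Merge pieces into maximal contiguous (source_id, start, stop) spans."""
    by_src: dict[str, list[TrajectoryPiece]] = {}
    for p in pieces:
        by_src.setdefault(p.source_id, []).append(p)
    spans: list[tuple[str, int, int]] = []
    for src in sorted(by_src):
        ordered = sorted(by_src[src], key=lambda p: p.start)
        cur_start, cur_stop = ordered[0].start, ordered[0].stop
        for p in ordered[1:]:
            if p.start == cur_stop:
                cur_stop = p.stop
            else:
                spans.append((src, cur_start, cur_stop))
                cur_start, cur_stop = p.start, p.stop
        spans.append((src, cur_start, cur_stop))
    return spans


@dataclass
class LevelReport:
    """Bookkeeping for one τ level of the hierarchy."""

    tau: float
    tau_frames: int
    n_pieces: int
    n_excluded: int
    n_new_states: int
    state_ids: list[int] = field(default_factory=list)


class TrajectoryMapping:
    """Top-down trajectory-mapping estimator (scikit-learn style).

    ``fit`` runs the full hierarchy over one or more dihedral-angle series:
    for each τ in the (decreasing) schedule it re-orthonormalizes the basis
    on the frames still in play, cuts them into τ-length pieces, maps the
    pieces, excludes those overlapping states already found, clusters the
    rest by SIP, promotes large clusters to states and refines the whole
    state inventory to mutual orthogonality.  Unassigned stretches carry to
    the next, shorter, τ.

    Parameters
    ----------
    tau_schedule : sequence of float
        Strictly decreasing piece lengths, ps.
    r_l, min_cluster, state_orthogonality, overlap_exclusion
        See :class:`ClusteringConfig`.
    max_order, include_pairs, rank_tolerance
        Raw trigonometric basis construction (see :class:`DihedralBasis`).
    reorthonormalize_per_level : bool
        Rebuild the orthonormal basis on each level's working sample
        (default) or keep the level-0 basis throughout.
    half_window : int or "auto"
        Δt (frames) on either side for state-indicator curves; "auto"
        scales the window with each state's identification timescale
        (max(25, level_τ/40) frames).
    assign_threshold : float
        Summed-indicator threshold above which a frame counts as assigned.

    Attributes
    ----------
    states_ : list of MetastableState
    basis_ : DihedralBasis fit on all input frames (the reporting basis)
    representatives_ : (n_states, rank+1) unit representative vectors in
        ``basis_``
    labels_ : dict source_id -> per-frame state labels (−1 = unassigned)
    accounted_fraction_ : fraction of frames assigned to some state
    levels_ : list of LevelReport
    """

    def __init__(
        self,
        tau_schedule=(200_000.0, 20_000.0, 2_000.0),
        r_l: float = 0.95,
        min_cluster: int = 5,
        state_orthogonality: float = 0.01,
        overlap_exclusion: float = 0.5,
        max_order: int = 2,
        include_pairs: bool = True,
        rank_tolerance: float = 1e-10,
        reorthonormalize_per_level: bool = True,
        half_window: int | str = "auto",
        assign_threshold: float = 0.9,
    ):
        self.tau_schedule = tau_schedule
        self.r_l = r_l
        self.min_cluster = min_cluster
        self.state_orthogonality = state_orthogonality
        self.overlap_exclusion = overlap_exclusion
        self.max_order = max_order
        self.include_pairs = include_pairs
        self.rank_tolerance = rank_tolerance
        self.reorthonormalize_per_level = reorthonormalize_per_level
        self.half_window = half_window
        self.assign_threshold = assign_threshold

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "tau_schedule",
                "r_l",
                "min_cluster",
                "state_orthogonality",
                "overlap_exclusion",
                "max_order",
                "include_pairs",
                "rank_tolerance",
                "reorthonormalize_per_level",
                "half_window",
                "assign_threshold",
            )
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> ClusteringConfig:
        return ClusteringConfig(
            r_l=self.r_l,
            min_cluster=self.min_cluster,
            state_orthogonality=self.state_orthogonality,
            overlap_exclusion=self.overlap_exclusion,
            tau_schedule=tuple(self.tau_schedule),
        )

    @staticmethod
    def _as_series_list(X) -> list[DihedralSeries]:
        if isinstance(X, DihedralSeries):
            return [X]
        if isinstance(X, np.ndarray):
            return [DihedralSeries(X, frame_interval=1.0)]
        return list(X)

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y=None):
        """Run hierarchical trajectory mapping on dihedral series X."""
        trajectories = self._as_series_list(X)
        if not trajectories:
            raise ValueError("need at least one trajectory")
        ids = [t.source_id for t in trajectories]
        if len(set(ids)) != len(ids):
            raise ValueError("trajectory source_ids must be unique")
        config = self._config()
        series_map = {t.source_id: t for t in trajectories}
        frame_interval = trajectories[0].frame_interval
        if any(t.frame_interval != frame_interval for t in trajectories):
            raise ValueError("all trajectories must share one frame_interval")

        states: list[MetastableState] = []
        levels: list[LevelReport] = []
        spans: list[tuple[str, int, int]] = [
            (t.source_id, 0, t.n_frames) for t in trajectories
        ]
        level_basis: DihedralBasis | None = None
        next_id = 1
        for tau in config.tau_schedule:
            tau_frames = max(1, int(round(tau / frame_interval)))
            spans = [s for s in spans if s[2] - s[1] >= tau_frames]
            if not spans:
                break
            if level_basis is None or self.reorthonormalize_per_level:
                # the reference must cover the states refined against, not
                # only the remaining data: a basis whitened on a sample that
                # misses two disjoint states cannot tell them apart
                blocks = [series_map[src].angles[a:b] for src, a, b in spans]
                blocks += [
                    series_map[p.source_id].angles[p.start : p.stop]
                    for st in states
                    for p in st.defining_pieces
                ]
                ref_frames = np.vstack(blocks)
                level_basis = DihedralBasis(
                    max_order=self.max_order,
                    include_pairs=self.include_pairs,
                    rank_tolerance=self.rank_tolerance,
                ).fit(ref_frames, reference_id=f"level-{len(levels)}")
            feats_cache = {
                src: level_basis.transform(series_map[src].angles)
                for src in series_map
            }
            pieces: list[TrajectoryPiece] = []
            for src, a, b in spans:
                pieces.extend(
                    cut_pieces(b - a, tau_frames, src, frame_interval, offset=a)
                )
            vectors = map_pieces(pieces, series_map, level_basis)
            # exclude pieces overlapping states already found
            excluded = 0
            if states:
                reps = np.array(
                    [
                        state_representative(st, series_map, level_basis, feats_cache)
                        for st in states
                    ]
                )
                units = np.array([v.unit for v in vectors])
                max_sip = (units @ reps.T).max(axis=1)
                keep_mask = max_sip <= config.overlap_exclusion
                excluded = int((~keep_mask).sum())
                vectors = [v for v, k in zip(vectors, keep_mask) if k]
            clusters = cluster_by_sip(vectors, config)
            new_states, unassigned_idx = identify_states(
                clusters, vectors, config, tau, series_map, level_basis, next_id
            )
            next_id += len(new_states)
            states, freed = refine_states(
                states + new_states, config, series_map, level_basis, feats_cache
            )
            carried = [vectors[i].piece for i in unassigned_idx] + freed
            spans = _spans_from_pieces(carried) if carried else []
            new_ids = [st.state_id for st in new_states if any(st is s for s in states)]
            levels.append(
                LevelReport(
                    tau, tau_frames, len(pieces), excluded, len(new_ids), new_ids
                )
            )
            logger.info(
                "level tau=%.0f ps: %d pieces, %d excluded as known, %d new states",
                tau,
                len(pieces),
                excluded,
                len(new_ids),
            )

        # final reporting basis on all input frames
        all_frames = np.vstack([t.angles for t in trajectories])
        self.basis_ = DihedralBasis(
            max_order=self.max_order,
            include_pairs=self.include_pairs,
            rank_tolerance=self.rank_tolerance,
        ).fit(all_frames, reference_id="global")
        for st in states:
            st.representative_ = state_representative(st, series_map, self.basis_)
        self.states_ = states
        self.n_states_ = len(states)
        self.levels_ = levels
        self.series_map_ = series_map
        if states:
            self.representatives_ = np.array([st.representative_ for st in states])
        else:
            self.representatives_ = np.empty((0, self.basis_.rank_ + 1))
        from .indicators import accounted_fraction, assign_frames, indicator_matrix

        self.labels_ = {}
        n_assigned = 0
        n_total = 0
        hw = self.half_windows_(frame_interval)
        for t in trajectories:
            curves = indicator_matrix(t, self.representatives_, self.basis_, hw)
            labels = assign_frames(curves, self.assign_threshold)
            self.labels_[t.source_id] = labels
            n_assigned += int((labels >= 0).sum())
            n_total += labels.shape[0]
        self.accounted_fraction_ = n_assigned / n_total if n_total else 0.0
        return self

    def half_windows_(self, frame_interval: float) -> np.ndarray:
        """Per-state indicator half-windows in frames."""
        from .indicators import auto_half_windows

        if isinstance(self.half_window, str):
            return auto_half_windows(self.states_, frame_interval)
        return np.broadcast_to(
            np.asarray(self.half_window, dtype=int), (len(self.states_),)
        )

    def predict(self, X) -> np.ndarray:
        """Per-frame state labels (state_id, or −1 when unassigned)."""
        from .indicators import assign_frames, indicator_matrix

        series = self._as_series_list(X)[0]
        curves = indicator_matrix(
            series,
            self.representatives_,
            self.basis_,
            self.half_windows_(series.frame_interval),
        )
        raw = assign_frames(curves, self.assign_threshold)
        ids = np.array([st.state_id for st in self.states_] + [-1])
        return ids[raw]

    def fit_predict(self, X, y=None) -> np.ndarray:
        self.fit(X)
        first = self._as_series_list(X)[0]
        return self.predict(first)


def find_substates(
    state: MetastableState,
    series_map: dict[str, DihedralSeries],
    tau_schedule,
    segments=None,
    **params,
) -> list[MetastableState]:
    """Focused sub-state search inside one metastable state's own sample.

    Sub-states of a state cannot surface in the top-down pass: their
    pieces overlap the parent and are rightly assigned to it.  Instead the
    state's own sample is re-analysed in isolation — basis and reference
    reset to that sample — at shorter piece lengths.  By default the
    sample is the state's defining pieces; passing the state's dwell
    ``segments`` (the stretches that continuously stay in the state per
    the indicator curves) focuses on a purer sample, since defining pieces
    retain some admixture from straddling other states.  Returned
    sub-states carry pieces re-indexed into the original trajectories'
    frames.
    """
    if segments is not None:
        spans = [
            (seg.source_id, seg.start, seg.stop)
            for seg in segments
            if seg.state_id == state.state_id
        ]
    else:
        spans = _spans_from_pieces(state.defining_pieces)
    sub_series: list[DihedralSeries] = []
    offsets: dict[str, tuple[str, int]] = {}
    for k, (src, a, b) in enumerate(spans):
        sid = f"{src}#s{state.state_id}.{k}"
        parent = series_map[src]
        sub_series.append(
            DihedralSeries(parent.angles[a:b], parent.frame_interval, sid)
        )
        offsets[sid] = (src, a)
    est = TrajectoryMapping(tau_schedule=tuple(tau_schedule), **params)
    est.fit(sub_series)
    for st in est.states_:
        st.defining_pieces = [
            TrajectoryPiece(
                offsets[p.source_id][0],
                p.start + offsets[p.source_id][1],
                p.stop + offsets[p.source_id][1],
                p.frame_interval,
            )
            for p in st.defining_pieces
        ]
        st.representative_ = None  # stale: was computed in the focused basis
    return est.states_


def hierarchical_tm(
    trajectories: list[DihedralSeries],
    config: ClusteringConfig | None = None,
    **basis_kwargs,
) -> list[MetastableState]:
    """Functional wrapper: run the full top-down hierarchy, return states."""
    config = config or ClusteringConfig()
    est = TrajectoryMapping(
        tau_schedule=config.tau_schedule,
        r_l=config.r_l,
        min_cluster=config.min_cluster,
        state_orthogonality=config.state_orthogonality,
        overlap_exclusion=config.overlap_exclusion,
        **basis_kwargs,
    )
    est.fit(trajectories)
    return est.states_
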