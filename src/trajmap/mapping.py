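"""Trajectory pieces, mapped vectors, and the scaled inner product (SIP).

A trajectory is cut into consecutive pieces of equal length τ; each piece i
is mapped to the vector

    v_i = (1, ⟨Â_1⟩_i, …, ⟨Â_n⟩_i),

whose components are the time averages of the orthonormal basis functions
over the piece.  The dot product of two such vectors estimates the overlap
integral ∫ P_i P_j / P_ref dq of the pieces' conformational distributions;
the *scaled inner product* SIP = v̂_i · v̂_j (cosine of the mapped vectors)
is near 1 for pieces equilibrated in the same metastable state and near 0
for pieces visiting disjoint regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .basis import DihedralBasis, DihedralSeries

__all__ = [
    "TrajectoryPiece",
    "MappedVector",
    "cut_pieces",
    "map_piece",
    "map_pieces",
    "sip",
    "sip_matrix",
    "pca_reduce",
    "time_correlation",
    "lag_weighted_correlation_sum",
    "mapped_second_moment",
]


@dataclass(frozen=True)
class TrajectoryPiece:
    """A half-open frame interval [start, stop) of one trajectory."""

    source_id: str
    start: int
    stop: int
    frame_interval: float

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("piece must satisfy stop > start")

    @property
    def n_frames(self) -> int:
        return self.stop - self.start

    @property
    def tau(self) -> float:
        """Piece duration in ps."""
        return self.n_frames * self.frame_interval


@dataclass
class MappedVector:
    """The average-feature vector of one trajectory piece.

    ``components`` has length rank+1: component 0 is exactly 1, components
    1..n are the time averages of the orthonormal features over the piece.
    """

    piece: TrajectoryPiece
    components: np.ndarray
    basis_id: str = "reference"

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components[0] != 1.0:
            raise ValueError("component 0 must equal 1 before normalization")

    @property
    def unit(self) -> np.ndarray:
        """Components scaled to Euclidean norm 1."""
        return self.components / np.linalg.norm(self.components)

    @property
    def rank(self) -> int:
        return self.components.shape[0] - 1


def cut_pieces(
    series_length: int,
    tau_frames: int,
    source_id: str = "traj",
    frame_interval: float = 1.0,
    offset: int = 0,
) -> list[TrajectoryPiece]:
    """Cut a contiguous run of frames into consecutive τ-length pieces.

    Returns floor(series_length / tau_frames) non-overlapping pieces starting
    at ``offset``; the trailing remainder shorter than ``tau_frames`` is
    discarded.  ``tau_frames`` longer than the series yields an empty list.
    """
    if tau_frames < 1:
        raise ValueError("tau_frames must be >= 1")
    n = series_length // tau_frames
    return [
        TrajectoryPiece(
            source_id,
            offset + k * tau_frames,
            offset + (k + 1) * tau_frames,
            frame_interval,
        )
        for k in range(n)
    ]


def map_piece(
    piece: TrajectoryPiece, series: DihedralSeries, basis: DihedralBasis
) -> MappedVector:
    """Map one piece to its average-feature vector (component 0 ≡ 1)."""
    if piece.start < 0 or piece.stop > series.n_frames:
        raise ValueError("piece frames lie outside the series")
    feats = basis.transform(series.angles[piece.start : piece.stop])
    comps = np.concatenate(([1.0], feats.mean(axis=0)))
    return MappedVector(piece, comps, basis_id=basis.reference_id)


def map_pieces(
    pieces: list[TrajectoryPiece],
    series_map: dict[str, DihedralSeries],
    basis: DihedralBasis,
) -> list[MappedVector]:
    """Map many pieces, evaluating features once per source trajectory."""
    out: list[MappedVector] = []
    feats_cache: dict[str, np.ndarray] = {}
    for piece in pieces:
        series = series_map[piece.source_id]
        if piece.source_id not in feats_cache:
            feats_cache[piece.source_id] = basis.transform(series.angles)
        feats = feats_cache[piece.source_id]
        comps = np.concatenate(
            ([1.0], feats[piece.start : piece.stop].mean(axis=0))
        )
        out.append(MappedVector(piece, comps, basis_id=basis.reference_id))
    return out


def sip(a: MappedVector, b: MappedVector) -> float:
    """Scaled inner product: cosine of two mapped vectors.

    Symmetric, in [−1, 1]; small negative values from finite sampling are
    reported as-is (no absolute value, no clamping).
    """
    if a.components.shape != b.components.shape or a.basis_id != b.basis_id:
        raise ValueError("incompatible vectors: mapped under different bases")
    return float(a.unit @ b.unit)


def sip_matrix(vectors: list[MappedVector]) -> np.ndarray:
    """Pairwise SIP matrix of mapped vectors."""
    units = np.array([v.unit for v in vectors])
    return units @ units.T


def pca_reduce(vectors: list[MappedVector], n_dims: int):
    """PCA of mapped vectors (component 0 dropped), for visualization.

    Returns (reduced coordinates, explained variance ratio).  Diagnostic
    only: clustering decisions operate on SIP directly.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 vectors")
    block = np.array([v.components[1:] for v in vectors])
    n_dims = min(n_dims, *block.shape)
    pca = PCA(n_components=n_dims)
    coords = pca.fit_transform(block)
    return coords, pca.explained_variance_ratio_


def time_correlation(
    series_list: list[DihedralSeries] | list[np.ndarray],
    basis: DihedralBasis,
    lag_frames: int,
) -> np.ndarray:
    """Cross time-correlation matrix C_μν(t) of the orthonormal features.

    C_μν(t) is the cross moment of feature μ at a time origin and feature ν
    a lag t later, averaged over all time origins and ensemble members.  At
    lag 0 on the reference sample it is the identity matrix.
    """
    num = None
    count = 0
    for series in series_list:
        angles = series.angles if isinstance(series, DihedralSeries) else series
        feats = basis.transform(angles)
        T = feats.shape[0]
        if lag_frames >= T:
            raise ValueError("lag_frames must be shorter than every series")
        a = feats[: T - lag_frames]
        b = feats[lag_frames:]
        contrib = a.T @ b
        num = contrib if num is None else num + contrib
        count += T - lag_frames
    return num / count


def lag_weighted_correlation_sum(
    series_list: list[DihedralSeries] | list[np.ndarray],
    basis: DihedralBasis,
    piece_frames: int,
) -> np.ndarray:
    """Discrete lag-weighted sum (1/L)Σ_δ w_δ (1−δ/L)[C(δ)+C(δ)ᵀ], w_0 = ½.

    This is the exact discrete counterpart of the relation between the
    covariance of mapped vectors and the feature time-correlation matrix:
    it equals :func:`mapped_second_moment` of the vectors mapped from
    L-frame pieces, to numerical precision.
    """
    L = piece_frames
    total = None
    for delta in range(L):
        C = time_correlation(series_list, basis, delta)
        sym = C + C.T
        weight = (0.5 if delta == 0 else 1.0) * (1.0 - delta / L)
        term = weight * sym
        total = term if total is None else total + term
    return total / L


def mapped_second_moment(vectors: list[MappedVector]) -> np.ndarray:
    """Sample second-moment matrix (1/m)Σ_i v_i v_iᵀ of components 1..n."""
    block = np.array([v.components[1:] for v in vectors])
    return block.T @ block / block.shape[0]
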