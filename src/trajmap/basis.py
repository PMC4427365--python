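"""Trigonometric dihedral basis functions and their orthonormalization.

Trajectory mapping represents a trajectory piece by the time averages of a
fixed set of conformational *basis functions*.  For peptides the natural
coordinates are the backbone torsion angles, and the basis consists of
low-order trigonometric functions of single angles, ``sin(kx)``/``cos(kx)``,
plus products coupling sequentially neighbouring angles,
``{sin,cos}(m x_i) · {sin,cos}(n x_{i+1})`` with ``m, n >= 1``.  The *order*
of a function is ``m + n``; by default orders one and two are used, which for
22 backbone angles yields 172 functions (88 single-angle, 84 neighbour-pair).

Before mapping, the raw functions are orthonormalized under a reference
sample: features are centred (which makes them orthogonal to the constant
function ``A_0 ≡ 1``) and whitened so that their sample second-moment matrix
is the identity.  :class:`DihedralBasis` implements this as a scikit-learn
transformer; :func:`orthonormalize` is the functional entry point.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DihedralSeries",
    "RawBasisDescriptor",
    "ReferenceSample",
    "DihedralBasis",
    "wrap_angles",
    "build_trig_basis",
    "evaluate_raw",
    "orthonormalize",
    "enumerate_backbone_dihedrals",
    "compute_dihedrals",
]

TWO_PI = 2.0 * np.pi


def wrap_angles(angles: np.ndarray) -> np.ndarray:
    """Wrap angles (radians) into the interval (−π, π]."""
    wrapped = np.mod(np.asarray(angles, dtype=float), TWO_PI)
    return np.where(wrapped > np.pi, wrapped - TWO_PI, wrapped)


@dataclass
class DihedralSeries:
    """A trajectory reduced to backbone torsion angles per frame.

    Parameters
    ----------
    angles
        Array of shape (T, D): T frames, D torsion angles in radians.
        Stored wrapped to (−π, π].
    frame_interval
        Time between successive frames, in ps.
    source_id
        Identifier of the originating trajectory.
    """

    angles: np.ndarray
    frame_interval: float
    source_id: str = "traj"

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.angles, dtype=float))
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("angles must be a (T, D) matrix with T >= 1, D >= 1")
        if not np.isfinite(arr).all():
            raise ValueError("angles contain NaN or infinite values")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        self.angles = wrap_angles(arr)

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_angles(self) -> int:
        return self.angles.shape[1]

    @property
    def duration(self) -> float:
        """Total duration in ps."""
        return self.n_frames * self.frame_interval


@dataclass(frozen=True)
class RawBasisDescriptor:
    """One raw (un-orthonormalized) trigonometric basis function.

    ``kind`` is ``"single"`` — a function ``trig(k·x)`` of one angle, with
    ``orders == (k, 0)`` — or ``"pair"`` — a product
    ``trig(m·x_i)·trig(n·x_{i+1})`` of two sequentially adjacent angles with
    ``orders == (m, n)``, ``m, n >= 1``.  ``trig_form`` holds one factor name
    (``"sin"``/``"cos"``) per angle index.
    """

    kind: str
    angle_indices: tuple[int, ...]
    orders: tuple[int, int]
    trig_form: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("single", "pair"):
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        if any(t not in ("sin", "cos") for t in self.trig_form):
            raise ValueError("trig_form entries must be 'sin' or 'cos'")
        m, n = self.orders
        if self.kind == "single":
            if len(self.angle_indices) != 1 or len(self.trig_form) != 1:
                raise ValueError("single descriptor takes one angle and one factor")
            if not (m >= 1 and n == 0):
                raise ValueError("single descriptor needs orders (k, 0), k >= 1")
        else:
            if len(self.angle_indices) != 2 or len(self.trig_form) != 2:
                raise ValueError("pair descriptor takes two angles and two factors")
            if m < 1 or n < 1:
                raise ValueError("pair descriptor needs m >= 1 and n >= 1")
            i, j = self.angle_indices
            if j != i + 1:
                raise ValueError("pair descriptors couple adjacent angles (i, i+1) only")

    @property
    def order(self) -> int:
        return self.orders[0] + self.orders[1]


@dataclass
class ReferenceSample:
    """Frames (possibly pooled across trajectories) defining P_ref.

    The reference distribution under which basis functions are
    orthonormalized is estimated from this finite sample.  Weights, when
    given, must sum to one; the default is uniform.
    """

    frames: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.frames.shape[0],):
                raise ValueError("weights must have one entry per frame")
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("weights must sum to 1")
            self.weights = w

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def build_trig_basis(
    n_angles: int, max_order: int = 2, include_pairs: bool = True
) -> list[RawBasisDescriptor]:
    """Enumerate the trigonometric basis for ``n_angles`` sequential angles.

    Per angle x: sin(kx), cos(kx) for 1 <= k <= max_order.  When
    ``include_pairs``, for each adjacent pair (x_i, x_{i+1}):
    {sin,cos}(m x_i)·{sin,cos}(n x_{i+1}) with m, n >= 1 and m+n <= max_order.
    Ordering is deterministic: angle index, then kind (singles before the
    pair anchored at that angle), then orders, then trig form (sin before
    cos).  For max_order=2 this yields 4·D + 4·(D−1) descriptors.
    """
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    descriptors: list[RawBasisDescriptor] = []
    for i in range(n_angles):
        for k in range(1, max_order + 1):
            for trig in ("sin", "cos"):
                descriptors.append(
                    RawBasisDescriptor("single", (i,), (k, 0), (trig,))
                )
        if include_pairs and i + 1 < n_angles:
            for m in range(1, max_order):
                for n in range(1, max_order - m + 1):
                    for ti in ("sin", "cos"):
                        for tj in ("sin", "cos"):
                            descriptors.append(
                                RawBasisDescriptor("pair", (i, i + 1), (m, n), (ti, tj))
                            )
    return descriptors


_TRIG = {"sin": np.sin, "cos": np.cos}


def evaluate_raw(
    descriptors: list[RawBasisDescriptor], frames: np.ndarray
) -> np.ndarray:
    """Evaluate raw basis functions on frames.

    ``frames`` is (T, D) or (D,); returns (T, P) or (P,) with one column per
    descriptor, all values in [−1, 1].
    """
    arr = np.asarray(frames, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    out = np.empty((arr.shape[0], len(descriptors)))
    for p, d in enumerate(descriptors):
        if d.kind == "single":
            (i,) = d.angle_indices
            out[:, p] = _TRIG[d.trig_form[0]](d.orders[0] * arr[:, i])
        else:
            i, j = d.angle_indices
            m, n = d.orders
            out[:, p] = _TRIG[d.trig_form[0]](m * arr[:, i]) * _TRIG[d.trig_form[1]](
                n * arr[:, j]
            )
    return out[0] if single else out


class DihedralBasis(TransformerMixin, BaseEstimator):
    """Orthonormalized trigonometric dihedral basis (sklearn transformer).

    ``fit(X)`` takes a reference sample of angle frames (T, D), evaluates
    the raw trigonometric functions, centres them and whitens them by a
    symmetric eigendecomposition of the sample second-moment matrix,
    discarding eigendirections with eigenvalue below ``rank_tolerance``
    times the largest.  ``transform(X)`` maps angle frames to the retained
    orthonormal features; on the reference sample they have zero mean and
    identity second-moment matrix.  The constant function A_0 ≡ 1 is carried
    implicitly as component 0 of mapped vectors, not as a feature column.

    Parameters
    ----------
    max_order : int
        Maximum order m+n of the trigonometric functions.
    include_pairs : bool
        Include neighbour-pair product functions.
    rank_tolerance : float
        Relative eigenvalue cutoff for discarding near-degenerate
        directions of the raw feature covariance.
    descriptors : list of RawBasisDescriptor, optional
        Explicit raw basis; when omitted, built from the reference sample's
        angle count via :func:`build_trig_basis`.

    Attributes
    ----------
    descriptors_ : list of RawBasisDescriptor
    mean_ : ndarray (P,)
        Reference mean of the raw features (the centring offset).
    components_ : ndarray (P, rank)
        Whitening matrix; features = (raw − mean_) @ components_.
    rank_ : int
        Number of retained orthonormal functions n.
    reference_id : str
        Identifier of the reference sample used.
    """

    def __init__(
        self,
        max_order: int = 2,
        include_pairs: bool = True,
        rank_tolerance: float = 1e-10,
        descriptors: list[RawBasisDescriptor] | None = None,
    ):
        self.max_order = max_order
        self.include_pairs = include_pairs
        self.rank_tolerance = rank_tolerance
        self.descriptors = descriptors

    def fit(self, X, y=None, sample_weight=None, reference_id: str = "reference"):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] < 2:
            raise ValueError("insufficient reference: need at least 2 frames")
        if not self.rank_tolerance > 0:
            raise ValueError("rank_tolerance must be positive")
        if self.descriptors is not None:
            descriptors = list(self.descriptors)
        else:
            descriptors = build_trig_basis(
                X.shape[1], self.max_order, self.include_pairs
            )
        raw = evaluate_raw(descriptors, X)
        if sample_weight is None:
            w = np.full(X.shape[0], 1.0 / X.shape[0])
        else:
            w = np.asarray(sample_weight, dtype=float)
            w = w / w.sum()
        mean = w @ raw
        centered = raw - mean
        second_moment = (centered * w[:, None]).T @ centered
        evals, evecs = np.linalg.eigh(second_moment)
        largest = evals[-1]
        if largest <= 0:
            raise ValueError("degenerate reference: all features have zero variance")
        keep = evals > self.rank_tolerance * largest
        evals, evecs = evals[keep], evecs[:, keep]
        # descending eigenvalue order, deterministic sign (largest |entry| positive)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        signs = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
        evecs = evecs * signs
        self.descriptors_ = descriptors
        self.mean_ = mean
        self.components_ = evecs / np.sqrt(evals)
        self.rank_ = int(evals.shape[0])
        self.eigenvalues_ = evals
        self.reference_id = reference_id
        return self

    def transform(self, X) -> np.ndarray:
        """Map angle frames (T, D) to orthonormal features (T, rank)."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        raw = evaluate_raw(self.descriptors_, np.atleast_2d(X))
        feats = (raw - self.mean_) @ self.components_
        return feats[0] if single else feats

    @property
    def n_raw_(self) -> int:
        return len(self.descriptors_)


def orthonormalize(
    descriptors: list[RawBasisDescriptor],
    reference: ReferenceSample,
    rank_tolerance: float = 1e-10,
    reference_id: str = "reference",
) -> DihedralBasis:
    """Orthonormalize raw basis functions under a reference sample.

    Returns a fitted :class:`DihedralBasis` whose features satisfy
    ⟨Â_μ Â_ν⟩_ref = δ_μν on the reference to within numerical tolerance.
    """
    basis = DihedralBasis(rank_tolerance=rank_tolerance, descriptors=descriptors)
    return basis.fit(
        reference.frames, sample_weight=reference.weights, reference_id=reference_id
    )


# ---------------------------------------------------------------------------
# Backbone dihedral geometry
# ---------------------------------------------------------------------------

_BACKBONE = ("N", "CA", "C")


def enumerate_backbone_dihedrals(topology) -> list[tuple[int, int, int, int]]:
    """Enumerate φ/ψ atom quadruples of a linear peptide, N- to C-terminus.

    ``topology`` is an ``mdtraj.Topology`` (or any object with ``.chains``
    each having ``.residues`` with named ``.atoms``).  For an R-residue
    chain the defined angles are φ_i = (C'_{i−1}, N_i, CA_i, C'_i) for
    i >= 2 and ψ_i = (N_i, CA_i, C'_i, N_{i+1}) for i <= R−1, interleaved
    per residue — 2(R−1) quadruples in total (22 for a 12-residue peptide).
    """
    chains = list(topology.chains)
    if len(chains) != 1:
        raise ValueError(
            f"unsupported topology: expected a single chain, found {len(chains)}"
        )
    residues = list(chains[0].residues)
    if len(residues) < 2:
        raise ValueError("unsupported topology: need at least 2 residues")
    backbone: list[dict[str, int]] = []
    for res in residues:
        atoms = {a.name: a.index for a in res.atoms}
        missing = [n for n in _BACKBONE if n not in atoms]
        if missing:
            raise ValueError(
                f"malformed topology: residue {res} lacks backbone atoms {missing}"
            )
        backbone.append(atoms)
    quadruples: list[tuple[int, int, int, int]] = []
    R = len(residues)
    for i in range(R):
        if i >= 1:  # φ_i, defined from residue 2 on
            quadruples.append(
                (
                    backbone[i - 1]["C"],
                    backbone[i]["N"],
                    backbone[i]["CA"],
                    backbone[i]["C"],
                )
            )
        if i <= R - 2:  # ψ_i, defined up to residue R−1
            quadruples.append(
                (
                    backbone[i]["N"],
                    backbone[i]["CA"],
                    backbone[i]["C"],
                    backbone[i + 1]["N"],
                )
            )
    return quadruples


def compute_dihedrals(
    coordinates: np.ndarray,
    quadruples: list[tuple[int, int, int, int]],
    frame_interval: float = 1.0,
    source_id: str = "traj",
) -> DihedralSeries:
    """Signed torsion angles for atom quadruples over frames.

    ``coordinates`` is (T, A, 3).  Uses the atan2 construction on the two
    bond-plane normals; result wrapped to (−π, π].  A planar cis arrangement
    gives 0, trans gives π.
    """
    xyz = np.asarray(coordinates, dtype=float)
    if xyz.ndim == 2:
        xyz = xyz[None]
    T = xyz.shape[0]
    quads = np.asarray(quadruples, dtype=int)
    p0, p1, p2, p3 = (xyz[:, quads[:, k], :] for k in range(4))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = np.linalg.norm(b1, axis=-1, keepdims=True)
    if np.any(b1n < 1e-12):
        t, q = np.argwhere(b1n[..., 0] < 1e-12)[0]
        raise ValueError(f"undefined angle: zero central bond at frame {t}, quadruple {q}")
    b1u = b1 / b1n
    v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
    w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
    vn = np.linalg.norm(v, axis=-1)
    wn = np.linalg.norm(w, axis=-1)
    bad = (vn < 1e-12) | (wn < 1e-12)
    if np.any(bad):
        t, q = np.argwhere(bad)[0]
        raise ValueError(
            f"undefined angle: collinear atoms at frame {t}, quadruple {q}"
        )
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1u, v) * w, axis=-1)
    angles = wrap_angles(np.arctan2(y, x))
    angles = angles.reshape(T, len(quadruples))
    return DihedralSeries(angles, frame_interval=frame_interval, source_id=source_id)
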