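"""Readers and writers binding the pipeline stages together.

Dihedral series travel as delimited text (one frame per row, one angle per
column, radians) or as a .npy binary array, each with a JSON sidecar
recording the frame interval (ps) and source id.  Topology + coordinate
trajectories (PDB with DCD or XTC) are read through mdtraj and reduced to
backbone φ/ψ series by this package's own dihedral machinery.  States,
networks, indicator curves, labels and events are written as JSON / TSV /
GraphML, all re-readable by the functions here.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np

from .basis import (
    DihedralSeries,
    compute_dihedrals,
    enumerate_backbone_dihedrals,
)
from .clustering import MetastableState
from .indicators import UNASSIGNED
from .kinetics import TransitionNetwork
from .mapping import TrajectoryPiece

__all__ = [
    "read_dihedral_series",
    "write_dihedral_series",
    "read_trajectory_dihedrals",
    "write_states",
    "read_states",
    "write_network",
    "write_indicator_curves",
    "write_labels",
    "write_events",
]

_TEXT_FMT = "%.9g"  # 9 significant digits for the text round trip


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_dihedral_series(series: DihedralSeries, path: str | Path) -> None:
    """Write a series as .npy (lossless) or delimited text, plus sidecar."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, series.angles)
    else:
        np.savetxt(path, series.angles, fmt=_TEXT_FMT, delimiter="\t")
    _sidecar(path).write_text(
        json.dumps(
            {"frame_interval_ps": series.frame_interval, "source_id": series.source_id}
        )
    )


def read_dihedral_series(
    path: str | Path,
    frame_interval: float | None = None,
    source_id: str | None = None,
) -> DihedralSeries:
    """Read a series from .npy or delimited text (sidecar supplies metadata)."""
    path = Path(path)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    interval = frame_interval or meta.get("frame_interval_ps", 1.0)
    src = source_id or meta.get("source_id", path.stem)
    if path.suffix == ".npy":
        angles = np.load(path)
    else:
        rows = []
        width = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.replace(",", "\t").split()
                if width is None:
                    width = len(fields)
                elif len(fields) != width:
                    raise ValueError(
                        f"{path}: ragged row at line {lineno} "
                        f"({len(fields)} fields, expected {width})"
                    )
                try:
                    rows.append([float(x) for x in fields])
                except ValueError as exc:
                    raise ValueError(f"{path}: parse error at line {lineno}: {exc}")
        angles = np.array(rows)
    if angles.size and not np.isfinite(angles).all():
        raise ValueError(f"{path}: NaN or infinite angles")
    return DihedralSeries(angles, frame_interval=interval, source_id=src)


def read_trajectory_dihedrals(
    topology_path: str | Path,
    trajectory_path: str | Path,
    frame_interval: float,
    source_id: str | None = None,
) -> DihedralSeries:
    """Extract backbone φ/ψ series from a PDB topology + DCD/XTC trajectory."""
    import mdtraj

    traj = mdtraj.load(str(trajectory_path), top=str(topology_path))
    quadruples = enumerate_backbone_dihedrals(traj.topology)
    series = compute_dihedrals(
        traj.xyz,
        quadruples,
        frame_interval=frame_interval,
        source_id=source_id or Path(trajectory_path).stem,
    )
    return series


# ---------------------------------------------------------------------------
# States
# ---------------------------------------------------------------------------


def write_states(states: list[MetastableState], path: str | Path) -> None:
    """Serialize states to JSON (round-trip lossless)."""
    payload = []
    for st in states:
        payload.append(
            {
                "state_id": st.state_id,
                "level_tau": st.level_tau,
                "tau_eq": st.tau_eq,
                "tau_eq_se": st.tau_eq_se,
                "tau_life": st.tau_life,
                "tau_life_se": st.tau_life_se,
                "representative": None
                if st.representative_ is None
                else st.representative_.tolist(),
                "defining_pieces": [
                    {
                        "source_id": p.source_id,
                        "start": p.start,
                        "stop": p.stop,
                        "frame_interval": p.frame_interval,
                    }
                    for p in st.defining_pieces
                ],
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1))


def read_states(path: str | Path) -> list[MetastableState]:
    payload = json.loads(Path(path).read_text())
    states = []
    for rec in payload:
        pieces = [
            TrajectoryPiece(p["source_id"], p["start"], p["stop"], p["frame_interval"])
            for p in rec["defining_pieces"]
        ]
        st = MetastableState(rec["state_id"], pieces, rec["level_tau"])
        st.tau_eq = rec["tau_eq"]
        st.tau_eq_se = rec["tau_eq_se"]
        st.tau_life = rec["tau_life"]
        st.tau_life_se = rec["tau_life_se"]
        if rec["representative"] is not None:
            st.representative_ = np.array(rec["representative"])
        states.append(st)
    return states


# ---------------------------------------------------------------------------
# Network, curves, labels, events
# ---------------------------------------------------------------------------


def write_network(network: TransitionNetwork, out_dir: str | Path) -> None:
    """Write GraphML, an edge-list TSV and a node table TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(network.graph, out_dir / "network.graphml")
    with open(out_dir / "edges.tsv", "w") as fh:
        fh.write("from\tto\tcount\trate_per_ps\n")
        for i, j, n, k in network.edge_table():
            fh.write(f"{i}\t{j}\t{n}\t{k:.9g}\n")
    with open(out_dir / "nodes.tsv", "w") as fh:
        fh.write("state_id\tlevel_tau_ps\ttau_eq_ps\ttau_life_ps\tkappa\tgroup\n")
        for i in network.nodes:
            d = network.graph.nodes[i]
            tau_eq = d.get("tau_eq", float("nan"))
            tau_life = d.get("tau_life", float("nan"))
            kappa = tau_life / tau_eq if tau_eq and tau_eq > 0 else float("nan")
            fh.write(
                f"{i}\t{d.get('level_tau', float('nan')):.9g}\t{tau_eq:.9g}\t"
                f"{tau_life:.9g}\t{kappa:.9g}\t{network.groups.get(i, '')}\n"
            )


def write_indicator_curves(
    times: np.ndarray,
    curves: np.ndarray,
    state_ids: list[int],
    labels: np.ndarray,
    path: str | Path,
) -> None:
    """TSV: time (ps), one indicator column per state, label column."""
    with open(path, "w") as fh:
        header = "time_ps\t" + "\t".join(f"S{j}" for j in state_ids) + "\tlabel\n"
        fh.write(header)
        for t, row, lab in zip(times, np.atleast_2d(curves), labels):
            vals = "\t".join(f"{x:.6g}" for x in row)
            fh.write(f"{t:.9g}\t{vals}\t{int(lab)}\n")


def write_labels(labels: np.ndarray, frame_interval: float, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("time_ps\tlabel\n")
        for t, lab in enumerate(labels):
            fh.write(f"{t * frame_interval:.9g}\t{int(lab)}\n")


def write_events(
    events: list[tuple[int, int, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("time_ps\tfrom\tto\n")
        for i, j, t in events:
            fh.write(f"{t:.9g}\t{i}\t{j}\n")


def read_events(path: str | Path) -> list[tuple[int, int, float]]:
    events = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            t, i, j = line.split()
            events.append((int(i), int(j), float(t)))
    return events
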