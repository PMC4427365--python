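"""End-to-end pipeline: basis → mapping → hierarchy → indicators → kinetics.

:func:`run_pipeline` drives the whole analysis from a :class:`RunConfig`
and writes every artifact (states JSON, network GraphML + TSV, indicator
curves TSV, per-frame labels, transition events, machine-readable report).
All randomness flows from the single configured seed; given fixed inputs
the analysis path is fully deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tmio
from .basis import DihedralSeries
from .clustering import TrajectoryMapping
from .indicators import (
    accounted_fraction,
    assign_frames,
    dwell_segments,
    indicator_matrix,
    transition_events,
)
from .kinetics import (
    estimate_state_timescales,
    lifetimes_from_events,
    transition_rates,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "parse_time_ps"]


def parse_time_ps(text: str) -> float:
    """Parse a time like '200ns', '2500ps' or a bare number (ps)."""
    text = str(text).strip()
    for suffix, factor in (("ns", 1000.0), ("ps", 1.0)):
        if text.endswith(suffix):
            return float(text[: -len(suffix)]) * factor
    return float(text)


@dataclass
class RunConfig:
    """All pipeline settings (mirrors the CLI flags; YAML-loadable)."""

    inputs: list[str] = field(default_factory=list)
    input_format: str = "tsv"  # tsv | npy | pdb+dcd | pdb+xtc
    topology: str | None = None
    frame_interval: float = 1.0  # ps; used when no sidecar metadata exists
    tau_schedule: list[float] = field(
        default_factory=lambda: [200_000.0, 20_000.0, 2_000.0]
    )
    r_l: float = 0.95
    min_cluster: int = 5
    state_orthogonality: float = 0.01
    overlap_exclusion: float = 0.5
    max_order: int = 2
    include_pairs: bool = True
    half_window: int | str = "auto"
    assign_threshold: float = 0.9
    bridge_gap: int = 0
    seed: int = 0
    out_dir: str = "tm_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "tau_schedule" in data:
            data["tau_schedule"] = [parse_time_ps(t) for t in data["tau_schedule"]]
        return cls(**data)

    def validate(self) -> None:
        if not self.inputs:
            raise ValueError("no input trajectories configured")
        for p in self.inputs:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.input_format.startswith("pdb+") and not self.topology:
            raise ValueError("topology PDB required for pdb+dcd / pdb+xtc input")


def _load_inputs(config: RunConfig) -> list[DihedralSeries]:
    series = []
    for k, path in enumerate(config.inputs):
        if config.input_format in ("tsv", "npy"):
            s = tmio.read_dihedral_series(path, frame_interval=None)
            if s.n_frames < 2:
                raise ValueError(f"{path}: trajectory has fewer than 2 frames")
        else:
            s = tmio.read_trajectory_dihedrals(
                config.topology, path, config.frame_interval
            )
        series.append(s)
    return series


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        trajectories = _load_inputs(config)
        stage = "hierarchical-tm"
        est = TrajectoryMapping(
            tau_schedule=tuple(config.tau_schedule),
            r_l=config.r_l,
            min_cluster=config.min_cluster,
            state_orthogonality=config.state_orthogonality,
            overlap_exclusion=config.overlap_exclusion,
            max_order=config.max_order,
            include_pairs=config.include_pairs,
            half_window=config.half_window,
            assign_threshold=config.assign_threshold,
        )
        est.fit(trajectories)
        states = est.states_
        state_ids = [st.state_id for st in states]
        stage = "indicators"
        all_segments = []
        all_events = []
        events_per_traj = []
        per_traj_accounted = {}
        for t in trajectories:
            curves = indicator_matrix(
                t, est.representatives_, est.basis_,
                est.half_windows_(t.frame_interval),
            )
            col_labels = assign_frames(curves, config.assign_threshold)
            ids = np.array(state_ids + [-1])
            labels = ids[col_labels]
            segs = dwell_segments(
                labels, t.frame_interval, t.source_id, config.bridge_gap
            )
            all_segments.extend(segs)
            traj_events = transition_events(segs)
            events_per_traj.append(traj_events)
            all_events.extend(traj_events)
            per_traj_accounted[t.source_id] = accounted_fraction(labels)
            times = np.arange(t.n_frames) * t.frame_interval
            tmio.write_indicator_curves(
                times, curves, state_ids, labels, out / f"curves_{t.source_id}.tsv"
            )
            tmio.write_labels(labels, t.frame_interval, out / f"labels_{t.source_id}.tsv")
        tmio.write_events(all_events, out / "events.tsv")
        stage = "kinetics"
        estimate_state_timescales(states, all_segments, est.series_map_, est.basis_)
        tmio.write_states(states, out / "states.json")
        # network rates use event-to-event residences (boundary-bias free);
        # states without a completed visit fall back to the dwell estimate
        lifetimes = {
            st.state_id: st.tau_life for st in states if st.tau_life is not None
        }
        lifetimes.update(lifetimes_from_events(events_per_traj))
        network = transition_rates(all_events, lifetimes, states)
        tmio.write_network(network, out)
        stage = "report"
        report = {
            "seed": config.seed,
            "n_states": len(states),
            "states_per_level": [
                {"tau_ps": lv.tau, "n_pieces": lv.n_pieces,
                 "n_excluded": lv.n_excluded, "n_new_states": lv.n_new_states,
                 "state_ids": lv.state_ids}
                for lv in est.levels_
            ],
            "accounted_fraction": est.accounted_fraction_,
            "accounted_fraction_per_trajectory": per_traj_accounted,
            "states": [
                {
                    "state_id": st.state_id,
                    "level_tau_ps": st.level_tau,
                    "n_defining_pieces": st.n_pieces,
                    "tau_eq_ps": st.tau_eq,
                    "tau_life_ps": st.tau_life,
                    "kappa": st.kappa,
                }
                for st in states
            ],
            "n_transition_events": len(all_events),
        }
        (out / "report.json").write_text(json.dumps(report, indent=1))
        return report
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise
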