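"""Tail-DNA contact detection, bound/unbound kinetics and derived statistics.

An atomic contact is a heavy-atom pair (one tail atom, one DNA atom) closer
than 4 Angstrom (strict inequality), evaluated at a fixed stride (default
1 ns).  Per-frame contacts roll up into a residue x frame timeline; the full
tail is called *unbound* in a frame when no more than 10% of its residues
keep at least one DNA contact, and maximal constant-state runs of that
sequence are the binding/unbinding events.  Residence-time statistics drop
events shorter than 50 ns (the time needed to establish stable interactions)
while transition counting keeps the full tiling.  The ensemble dissociation
constant is the frame-count ratio Kd = unbound / bound and the standard
binding free energy dG0 = R T ln Kd at the 310 K simulation temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajectory_model import (
    TrajectoryEnsemble,
    SelectionError,
)

__all__ = [
    "GAS_CONSTANT_J",
    "ContactTimeline",
    "BindingEvent",
    "BindingEvents",
    "BindingStats",
    "atomic_contacts",
    "contact_statistics",
    "fraction_bound",
    "call_states",
    "detect_events",
    "binding_stats",
    "radius_of_gyration",
]

#: molar gas constant, J mol^-1 K^-1
GAS_CONSTANT_J = 8.314


@dataclass
class ContactTimeline:
    """Residue x frame atomic-contact counts at a fixed stride.

    ``counts[i, k]`` is the number of heavy-atom contact pairs between tail
    residue i and DNA in sampled frame k; a boolean cell is true iff the
    count is >= 1.  ``bp_counts`` optionally keeps the per-base-pair split
    (residues x base pairs x frames).
    """

    counts: np.ndarray
    residues: np.ndarray
    stride_ns: float
    copy_label: str = ""
    bp_counts: np.ndarray | None = None
    bp_positions: np.ndarray | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be residues x frames")
        if self.stride_ns <= 0:
            raise ValueError("stride must be positive")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")
        self.residues = np.asarray(self.residues)
        if self.residues.shape[0] != self.counts.shape[0]:
            raise ValueError("residues must match count rows")

    @property
    def contacts(self) -> np.ndarray:
        return self.counts >= 1

    @property
    def n_frames(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class BindingEvent:
    state: str  # "bound" | "unbound"
    start_ns: float
    end_ns: float

    @property
    def duration_ns(self) -> float:
        return self.end_ns - self.start_ns


@dataclass
class BindingEvents:
    """Maximal constant-state runs tiling the full timeline.

    ``events`` tile the timeline without gaps; ``passes_filter`` flags the
    events meeting the minimum-duration rule used for residence-time
    statistics.  ``n_transitions`` counts all state changes
    (binding + unbinding); directional counts are kept separately.  The
    duration filter is applied to reported residence times only, never to
    transition counting.
    """

    events: list
    passes_filter: np.ndarray
    min_duration_ns: float
    n_transitions: int
    n_binding: int
    n_unbinding: int

    def durations(self, state: str, filtered: bool = True) -> np.ndarray:
        out = [
            ev.duration_ns
            for ev, ok in zip(self.events, self.passes_filter)
            if ev.state == state and (ok or not filtered)
        ]
        return np.asarray(out)


@dataclass
class BindingStats:
    frames_bound: int
    frames_unbound: int
    kd: float  # dimensionless frame ratio; NaN when undefined
    dG0_kJ_per_mol: float
    temperature_K: float


def _sample_frames(n_frames: int, frame_interval_ns: float, stride_ns: float):
    step = int(round(stride_ns / frame_interval_ns))
    if step < 1 or abs(step * frame_interval_ns - stride_ns) > 1e-9 * stride_ns:
        raise ValueError(
            f"stride {stride_ns} ns is not a multiple of the "
            f"{frame_interval_ns} ns frame interval"
        )
    return np.arange(step - 1, n_frames, step)


def atomic_contacts(
    traj: TrajectoryEnsemble,
    tail_selection,
    dna_selection,
    cutoff_A: float = 4.0,
    stride_ns: float = 1.0,
    copy_label: str = "",
    track_base_pairs: bool = True,
) -> ContactTimeline:
    """Heavy-atom tail-DNA contacts per residue at the sampling stride.

    Candidate pairs come from a KD-tree ball query and are confirmed with the
    exact strict inequality d < cutoff, so a pair at exactly the cutoff does
    not count.  When the ensemble carries a base-pair map and
    ``track_base_pairs`` is set, a per-base-pair count tensor is kept too.
    """
    tail_idx = traj.selection(tail_selection)
    dna_idx = traj.selection(dna_selection)
    heavy = traj.atoms["is_heavy"].to_numpy()
    tail_idx = tail_idx[heavy[tail_idx]]
    dna_idx = dna_idx[heavy[dna_idx]]
    if tail_idx.size == 0 or dna_idx.size == 0:
        raise SelectionError("empty heavy-atom selection")

    tail_res = traj.atoms["resid"].to_numpy()[tail_idx]
    residues = np.unique(tail_res)
    res_row = {r: i for i, r in enumerate(residues)}
    tail_rows = np.array([res_row[r] for r in tail_res])

    bp_map = traj.base_pairs if track_base_pairs else None
    if bp_map is not None:
        dna_res = traj.atoms["resid"].to_numpy()[dna_idx]
        missing = [r for r in np.unique(dna_res) if r not in bp_map]
        if missing:
            raise KeyError(f"DNA residues missing from base-pair map: {missing}")
        bp_positions = np.unique([bp_map[r] for r in np.unique(dna_res)])
        bp_col = {p: j for j, p in enumerate(bp_positions)}
        dna_cols = np.array([bp_col[bp_map[r]] for r in dna_res])

    frames = _sample_frames(traj.n_frames, traj.frame_interval_ns, stride_ns)
    counts = np.zeros((residues.size, frames.size), dtype=np.int32)
    bp_counts = (
        np.zeros((residues.size, bp_positions.size, frames.size), dtype=np.int32)
        if bp_map is not None
        else None
    )
    for k, f in enumerate(frames):
        dna_xyz = traj.coordinates[f][dna_idx]
        tail_xyz = traj.coordinates[f][tail_idx]
        tree = cKDTree(dna_xyz)
        neighbours = tree.query_ball_point(tail_xyz, r=cutoff_A)
        for a, hits in enumerate(neighbours):
            if not hits:
                continue
            d = np.linalg.norm(dna_xyz[hits] - tail_xyz[a], axis=1)
            close = np.asarray(hits)[d < cutoff_A]
            if close.size == 0:
                continue
            counts[tail_rows[a], k] += close.size
            if bp_counts is not None:
                np.add.at(bp_counts[tail_rows[a], :, k], dna_cols[close], 1)
    return ContactTimeline(
        counts=counts,
        residues=residues,
        stride_ns=stride_ns,
        copy_label=copy_label,
        bp_counts=bp_counts,
        bp_positions=bp_positions if bp_map is not None else None,
    )


def contact_statistics(timelines: Sequence[ContactTimeline]) -> dict:
    """Mean contact numbers with SEM across runs/copies (n = len(timelines)).

    Returns per-residue means, per-base-pair means (when base-pair counts
    are tracked) and the residue x base-pair heat-map of mean contact
    numbers, each as a DataFrame.
    """
    if not timelines:
        raise ValueError("need at least one timeline")
    residues = timelines[0].residues
    per_res = np.stack(
        [tl.counts.mean(axis=1) for tl in timelines]
    )  # (n, residues)
    n = per_res.shape[0]
    sem = per_res.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros(
        residues.size
    )
    out = {
        "per_residue": pd.DataFrame(
            {
                "residue": residues,
                "mean_contacts": per_res.mean(axis=0),
                "sem": sem,
            }
        ),
        "n": n,
    }
    if all(tl.bp_counts is not None for tl in timelines):
        bp_positions = timelines[0].bp_positions
        per_bp = np.stack(
            [tl.bp_counts.sum(axis=0).mean(axis=1) for tl in timelines]
        )
        bp_sem = per_bp.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros(
            bp_positions.size
        )
        out["per_base_pair"] = pd.DataFrame(
            {
                "base_pair": bp_positions,
                "mean_contacts": per_bp.mean(axis=0),
                "sem": bp_sem,
            }
        )
        heat = np.stack(
            [tl.bp_counts.mean(axis=2) for tl in timelines]
        ).mean(axis=0)
        out["heat_map"] = pd.DataFrame(
            heat, index=pd.Index(residues, name="residue"), columns=bp_positions
        )
    return out


def fraction_bound(timeline: ContactTimeline) -> np.ndarray:
    """Per-frame fraction of tail residues with at least one DNA contact."""
    if timeline.counts.shape[0] < 1:
        raise ValueError("timeline has no residues")
    return timeline.contacts.mean(axis=0)


def call_states(
    timeline: ContactTimeline, unbound_threshold: float = 0.10
) -> np.ndarray:
    """Boolean per-frame state sequence (True = bound).

    A frame is unbound when *no more than* the threshold fraction of tail
    residues maintain DNA contacts — the comparison is inclusive, so a
    fraction exactly at the threshold is unbound.
    """
    if not 0 < unbound_threshold < 1:
        raise ValueError("unbound_threshold must be in (0, 1)")
    return fraction_bound(timeline) > unbound_threshold


def detect_events(
    states: np.ndarray, stride_ns: float, min_duration_ns: float = 50.0
) -> BindingEvents:
    """Segment a state sequence into events and count transitions.

    Every maximal run becomes an event spanning [start, end) in ns; the
    events tile the timeline.  Events shorter than ``min_duration_ns`` are
    flagged out of the residence-time statistics but stay in the tiling, and
    transition counts ignore the filter entirely.
    """
    states = np.asarray(states, dtype=bool)
    if states.size == 0:
        raise ValueError("empty state sequence")
    change = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate([[0], change, [states.size]])
    events = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        events.append(
            BindingEvent(
                state="bound" if states[s] else "unbound",
                start_ns=s * stride_ns,
                end_ns=e * stride_ns,
            )
        )
    passes = np.array([ev.duration_ns >= min_duration_ns for ev in events])
    n_binding = int(np.sum(~states[change - 1] & states[change]))
    n_unbinding = int(np.sum(states[change - 1] & ~states[change]))
    return BindingEvents(
        events=events,
        passes_filter=passes,
        min_duration_ns=min_duration_ns,
        n_transitions=n_binding + n_unbinding,
        n_binding=n_binding,
        n_unbinding=n_unbinding,
    )


def binding_stats(states: np.ndarray, temperature_K: float = 310.0) -> BindingStats:
    """Frame-count dissociation constant and standard binding free energy.

    Kd = frames unbound / frames bound; dG0 = R T ln Kd in kJ/mol.  When
    either count is zero Kd is undefined and both Kd and dG0 are NaN, with
    the raw counts still reported.
    """
    states = np.asarray(states, dtype=bool)
    if states.size == 0:
        raise ValueError("empty state sequence")
    nb = int(states.sum())
    nu = int(states.size - nb)
    if nb == 0 or nu == 0:
        kd = float("nan")
        dg = float("nan")
    else:
        kd = nu / nb
        dg = GAS_CONSTANT_J * temperature_K * math.log(kd) / 1000.0
    return BindingStats(
        frames_bound=nb,
        frames_unbound=nu,
        kd=kd,
        dG0_kJ_per_mol=dg,
        temperature_K=temperature_K,
    )


def radius_of_gyration(traj: TrajectoryEnsemble, selection) -> np.ndarray:
    """Mass-weighted radius of gyration of a selection, per frame (A)."""
    idx = traj.selection(selection)
    m = traj.masses(idx)
    xyz = traj.coordinates[:, idx, :]
    com = np.sum(xyz * m[None, :, None], axis=1) / m.sum()
    sq = np.sum((xyz - com[:, None, :]) ** 2, axis=2)
    return np.sqrt(np.sum(sq * m[None, :], axis=1) / m.sum())
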