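"""Residue-residue interaction networks from conformational ensembles.

A geometric surrogate for ensemble interaction-network analysis: tail
conformations are extracted at a fixed stride (default 10 ns) from each run,
the two tail copies are pooled, and for every conformation residue pairs are
classified as van der Waals contacts (any heavy-atom pair within the sum of
Bondi radii + 0.5 A) and/or hydrogen bonds (donor-acceptor N/O pair within
3.5 A, with a >= 120 deg donor-H...acceptor angle when hydrogens are
present).  Each observed interaction becomes a graph edge whose probability
score is the fraction of ensemble states containing it; a node's degree is
the sum of its incident edge probabilities.  Contact-probability maps mask
adjacent residues (|i - j| <= 1), whose trivially persistent contacts would
dominate the picture.

Only the hydrogen-bond and van der Waals classes are implemented; ionic and
pi-system classes require charge-group and aromatic-plane geometry outside
this surrogate's scope.  All geometric thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .trajectory_model import TrajectoryEnsemble

__all__ = [
    "BONDI_RADII",
    "Conformation",
    "InteractionGraph",
    "extract_ensemble",
    "frame_edges",
    "edge_probabilities",
    "node_degree",
    "contact_probability_map",
]

#: Bondi van der Waals radii (A)
BONDI_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80}

HBOND = "hydrogen-bond"
VDW = "van-der-Waals"


@dataclass
class Conformation:
    """One extracted tail conformation: coordinates plus atom metadata."""

    coordinates: np.ndarray  # (atoms, 3), A
    atoms: pd.DataFrame  # name, element, resid

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(self.atoms) != self.coordinates.shape[0]:
            raise ValueError("atom table does not match coordinates")


@dataclass
class InteractionGraph:
    """Edges with per-class probabilities over an ensemble of states."""

    edges: pd.DataFrame  # res_i, res_j, kind, probability
    nodes: np.ndarray
    n_states: int
    stride_ns: float | None = None

    def __post_init__(self) -> None:
        probs = self.edges["probability"]
        if len(probs) and (probs.min() < 0 or probs.max() > 1):
            raise ValueError("edge probabilities must be in [0, 1]")
        if len(self.edges) and (self.edges["res_i"] == self.edges["res_j"]).any():
            raise ValueError("self-edges are not allowed")


def extract_ensemble(
    runs: Sequence[TrajectoryEnsemble] | TrajectoryEnsemble,
    copy_selections: Sequence = ("tail_A", "tail_B"),
    stride_ns: float = 10.0,
    combine_copies: bool = True,
):
    """Subsample tail conformations from one or more runs at a fixed stride.

    With the reference protocol (five 2000 ns runs sampled every 10 ns, two
    tail copies pooled) this yields 2000 conformational states.  Returns one
    pooled list, or one list per copy when ``combine_copies`` is false.
    """
    if isinstance(runs, TrajectoryEnsemble):
        runs = [runs]
    per_copy: list[list[Conformation]] = [[] for _ in copy_selections]
    for traj in runs:
        step = int(round(stride_ns / traj.frame_interval_ns))
        if step < 1 or abs(step * traj.frame_interval_ns - stride_ns) > 1e-9 * stride_ns:
            raise ValueError(
                f"stride {stride_ns} ns is finer than or incommensurate with "
                f"the {traj.frame_interval_ns} ns frame interval"
            )
        frames = np.arange(step - 1, traj.n_frames, step)
        for c, sel in enumerate(copy_selections):
            idx = traj.selection(sel)
            atoms = traj.atoms.iloc[idx].reset_index(drop=True)
            for f in frames:
                per_copy[c].append(
                    Conformation(coordinates=traj.coordinates[f][idx], atoms=atoms)
                )
    if combine_copies:
        return [conf for copy in per_copy for conf in copy]
    return per_copy


def _vdw_pairs(conf: Conformation, tolerance_A: float) -> set:
    heavy = conf.atoms["element"] != "H"
    elems = conf.atoms["element"][heavy]
    unknown = sorted(set(elems) - set(BONDI_RADII))
    if unknown:
        raise KeyError(f"no van der Waals radius for elements: {unknown}")
    xyz = conf.coordinates[heavy.to_numpy()]
    radii = elems.map(BONDI_RADII).to_numpy()
    resids = conf.atoms["resid"][heavy].to_numpy()
    d = cdist(xyz, xyz)
    limit = radii[:, None] + radii[None, :] + tolerance_A
    ii, jj = np.nonzero(d <= limit)
    pairs = set()
    for a, b in zip(ii, jj):
        ri, rj = resids[a], resids[b]
        if ri < rj:
            pairs.add((ri, rj))
    return pairs


def _hbond_pairs(
    conf: Conformation, max_dist_A: float, min_angle_deg: float
) -> set:
    atoms = conf.atoms
    polar = atoms["element"].isin(["N", "O"]).to_numpy()
    xyz = conf.coordinates
    p_idx = np.flatnonzero(polar)
    if p_idx.size == 0:
        return set()
    h_idx = np.flatnonzero((atoms["element"] == "H").to_numpy())
    have_h = h_idx.size > 0
    # attach hydrogens to the closest polar atom within covalent range
    donors: dict[int, list[int]] = {}
    if have_h:
        d_hp = cdist(xyz[h_idx], xyz[p_idx])
        for hi, row in zip(h_idx, d_hp):
            j = int(np.argmin(row))
            if row[j] <= 1.25:
                donors.setdefault(int(p_idx[j]), []).append(int(hi))
    resids = atoms["resid"].to_numpy()
    d_pp = cdist(xyz[p_idx], xyz[p_idx])
    pairs = set()
    cos_min = np.cos(np.deg2rad(min_angle_deg))
    for a in range(p_idx.size):
        for b in range(p_idx.size):
            if a == b:
                continue
            i, j = int(p_idx[a]), int(p_idx[b])
            ri, rj = resids[i], resids[j]
            if ri == rj or d_pp[a, b] > max_dist_A:
                continue
            if have_h:
                ok = False
                for hi in donors.get(i, []):
                    dh = xyz[hi] - xyz[i]
                    ha = xyz[j] - xyz[hi]
                    # donor-H...acceptor angle at the hydrogen
                    cosang = -np.dot(dh, ha) / (
                        np.linalg.norm(dh) * np.linalg.norm(ha)
                    )
                    if cosang <= cos_min:
                        ok = True
                        break
                if not ok:
                    continue
            pairs.add((min(ri, rj), max(ri, rj)))
    return pairs


def frame_edges(
    conf: Conformation,
    vdw_tolerance_A: float = 0.5,
    hbond_max_A: float = 3.5,
    hbond_min_angle_deg: float = 120.0,
) -> set:
    """Classified residue-pair edges present in a single conformation.

    Returns (res_i, res_j, kind) tuples with res_i < res_j; adjacent pairs
    are retained here and masked only in reported maps.
    """
    edges = set()
    for ri, rj in _vdw_pairs(conf, vdw_tolerance_A):
        edges.add((ri, rj, VDW))
    for ri, rj in _hbond_pairs(conf, hbond_max_A, hbond_min_angle_deg):
        edges.add((ri, rj, HBOND))
    return edges


def edge_probabilities(
    ensemble: Sequence[Conformation],
    stride_ns: float | None = None,
    **criteria,
) -> InteractionGraph:
    """Edge probability = fraction of ensemble states containing the edge.

    Pairs never observed interacting are simply absent from the graph (a
    sparsity convention, not probability-zero entries).
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    tally: dict = {}
    nodes: set = set()
    for conf in ensemble:
        nodes.update(conf.atoms["resid"].unique())
        for edge in frame_edges(conf, **criteria):
            tally[edge] = tally.get(edge, 0) + 1
    n = len(ensemble)
    rows = [
        {"res_i": ri, "res_j": rj, "kind": kind, "probability": count / n}
        for (ri, rj, kind), count in sorted(tally.items())
    ]
    edges = pd.DataFrame(rows, columns=["res_i", "res_j", "kind", "probability"])
    return InteractionGraph(
        edges=edges,
        nodes=np.array(sorted(nodes)),
        n_states=n,
        stride_ns=stride_ns,
    )


def node_degree(graph: InteractionGraph) -> pd.DataFrame:
    """Cumulative per-residue score: sum of incident edge probabilities.

    Sums across interaction classes and both edge endpoints, returned in
    descending rank order.  Isolated residues score 0.
    """
    score = {int(r): 0.0 for r in graph.nodes}
    for row in graph.edges.itertuples():
        score[int(row.res_i)] = score.get(int(row.res_i), 0.0) + row.probability
        score[int(row.res_j)] = score.get(int(row.res_j), 0.0) + row.probability
    out = pd.DataFrame(
        {"residue": list(score.keys()), "degree": list(score.values())}
    )
    return out.sort_values(
        ["degree", "residue"], ascending=[False, True]
    ).reset_index(drop=True)


def contact_probability_map(
    graph: InteractionGraph, kind: str | None = None
) -> pd.DataFrame | dict:
    """Symmetric residue x residue probability matrix per interaction class.

    Cells with no observed interaction are NaN (rendered white), and the
    diagonal band of adjacent residues (|i - j| <= 1) is masked even when an
    edge exists there.
    """
    if kind is None:
        kinds = sorted(graph.edges["kind"].unique()) if len(graph.edges) else []
        return {k: contact_probability_map(graph, k) for k in kinds}
    nodes = [int(r) for r in graph.nodes]
    mat = pd.DataFrame(np.nan, index=nodes, columns=nodes)
    sub = graph.edges[graph.edges["kind"] == kind]
    for row in sub.itertuples():
        i, j = int(row.res_i), int(row.res_j)
        if abs(i - j) <= 1:
            continue
        mat.loc[i, j] = row.probability
        mat.loc[j, i] = row.probability
    return mat
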