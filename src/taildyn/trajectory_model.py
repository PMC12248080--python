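"""Trajectory substrate: loading, selections, superposition, windowing.

Coordinates are in Angstrom and times in ns throughout.  Frames are indexed
0-based; the time of frame k is k * frame_interval_ns after any equilibration
cut.  Topologies are read from PDB and frames from any binary container
MDAnalysis understands (DCD/XTC/NetCDF-style).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .md_to_nmr import VectorTrajectory

__all__ = [
    "ATOMIC_MASSES",
    "TrajectoryError",
    "TrajectoryFormatError",
    "DegenerateFitError",
    "EmptyTrajectoryError",
    "SelectionError",
    "TrajectoryEnsemble",
    "SuperpositionResult",
    "load_trajectory",
    "write_trajectory",
    "superpose_frames",
    "discard_equilibration",
    "extract_nh_vectors",
]

#: standard atomic masses (u) for the elements a nucleosome model contains
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}


class TrajectoryError(Exception):
    pass


class TrajectoryFormatError(TrajectoryError):
    """Topology/coordinate container mismatch or unparsable file."""


class DegenerateFitError(TrajectoryError):
    """Fewer than three fit atoms, or a collinear fit selection."""


class EmptyTrajectoryError(TrajectoryError):
    """An operation removed every frame."""


class SelectionError(TrajectoryError):
    """A named selection is missing or resolves to no atoms."""


_ATOM_COLUMNS = ("name", "element", "resid", "resname", "chain", "is_heavy")


@dataclass
class TrajectoryEnsemble:
    """Coordinate frames plus the atom table and named selections.

    coordinates : (n_frames, n_atoms, 3) in Angstrom.
    frame_interval_ns : spacing between stored frames.
    atoms : one row per atom with columns name, element, resid, resname,
        chain, is_heavy.
    selections : named index arrays (e.g. "tail_A", "core_ca", "dna").
    base_pairs : maps a DNA residue id (one nucleotide per strand) to its
        integer base-pair position.
    """

    coordinates: np.ndarray
    frame_interval_ns: float
    atoms: pd.DataFrame
    selections: dict = field(default_factory=dict)
    base_pairs: dict | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be positive")
        missing = set(_ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns: {sorted(missing)}")
        if len(self.atoms) != self.coordinates.shape[1]:
            raise ValueError("atom table does not match coordinate atom count")
        for name, idx in self.selections.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_atoms):
                raise SelectionError(f"selection {name!r} refers to missing atoms")
            self.selections[name] = idx

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ns

    def selection(self, key) -> np.ndarray:
        """Resolve a selection name or an explicit index array to indices."""
        if isinstance(key, str):
            if key not in self.selections:
                raise SelectionError(f"no selection named {key!r}")
            idx = self.selections[key]
        else:
            idx = np.asarray(key, dtype=int)
        if idx.size == 0:
            raise SelectionError("selection resolves to no atoms")
        return idx

    def select(
        self,
        chain=None,
        resids=None,
        names=None,
        elements=None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        """Index array of atoms matching all given criteria."""
        mask = np.ones(len(self.atoms), dtype=bool)
        if chain is not None:
            chains = [chain] if isinstance(chain, str) else list(chain)
            mask &= self.atoms["chain"].isin(chains).to_numpy()
        if resids is not None:
            mask &= self.atoms["resid"].isin(list(resids)).to_numpy()
        if names is not None:
            mask &= self.atoms["name"].isin(list(names)).to_numpy()
        if elements is not None:
            mask &= self.atoms["element"].isin(list(elements)).to_numpy()
        if heavy_only:
            mask &= self.atoms["is_heavy"].to_numpy()
        return np.flatnonzero(mask)

    def masses(self, idx=None) -> np.ndarray:
        elems = self.atoms["element"] if idx is None else self.atoms["element"].iloc[idx]
        masses = elems.map(ATOMIC_MASSES)
        if masses.isna().any():
            unknown = sorted(set(elems[masses.isna()]))
            raise SelectionError(f"no mass for elements: {unknown}")
        return masses.to_numpy(dtype=float)


@dataclass
class SuperpositionResult:
    """Superposed ensemble plus per-frame RMSD over the fit selection (A)."""

    ensemble: TrajectoryEnsemble
    rmsd_A: np.ndarray


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "C"
    if stripped[0].upper() == "H":
        return "H"
    two = stripped[:2].capitalize()
    if two in ATOMIC_MASSES:
        return two
    return stripped[0].upper()


def load_trajectory(
    topology_path, coordinates_path, frame_interval_ns: float
) -> TrajectoryEnsemble:
    """Read a PDB topology plus a binary coordinate container.

    Elements come from the topology when present, otherwise they are guessed
    from atom names; the heavy-atom flag is derived from the element.
    """
    import MDAnalysis as mda

    for p in (topology_path, coordinates_path):
        if not Path(p).exists():
            raise IOError(f"cannot read {p}")
    try:
        u = mda.Universe(str(topology_path), str(coordinates_path))
        n_traj_frames = len(u.trajectory)
    except (ValueError, EOFError, IndexError) as exc:
        raise TrajectoryFormatError(
            f"topology and coordinates are inconsistent: {exc}"
        ) from exc

    try:
        elements = [e.capitalize() if e else "" for e in u.atoms.elements]
    except AttributeError:
        elements = [""] * len(u.atoms)
    names = [str(n) for n in u.atoms.names]
    elements = [
        e if e else _guess_element(n) for e, n in zip(elements, names)
    ]
    try:
        chains = [str(c) for c in u.atoms.chainIDs]
    except AttributeError:
        chains = [str(s) for s in u.atoms.segids]
    atoms = pd.DataFrame(
        {
            "name": names,
            "element": elements,
            "resid": u.atoms.resids.astype(int),
            "resname": [str(r) for r in u.atoms.resnames],
            "chain": chains,
            "is_heavy": [e != "H" for e in elements],
        }
    )
    coords = np.empty((n_traj_frames, len(u.atoms), 3))
    for i, _ in enumerate(u.trajectory):
        coords[i] = u.atoms.positions
    return TrajectoryEnsemble(
        coordinates=coords, frame_interval_ns=frame_interval_ns, atoms=atoms
    )


def write_trajectory(
    traj: TrajectoryEnsemble, topology_path, coordinates_path
) -> None:
    """Write the ensemble as a PDB topology plus a DCD coordinate container."""
    import MDAnalysis as mda

    atoms = traj.atoms
    res_keys = list(zip(atoms["chain"], atoms["resid"]))
    codes, uniques = pd.factorize(pd.Series(res_keys))
    n_res = len(uniques)
    seg_labels = pd.unique(atoms["chain"])
    seg_index = {c: i for i, c in enumerate(seg_labels)}
    res_seg = np.array([seg_index[c] for c, _ in uniques])
    u = mda.Universe.empty(
        n_atoms=traj.n_atoms,
        n_residues=n_res,
        n_segments=len(seg_labels),
        atom_resindex=codes,
        residue_segindex=res_seg,
        trajectory=True,
    )
    u.add_TopologyAttr("names", atoms["name"].to_list())
    u.add_TopologyAttr("elements", atoms["element"].to_list())
    first = [res_keys.index(k) for k in uniques]
    u.add_TopologyAttr("resids", [atoms["resid"].iloc[i] for i in first])
    u.add_TopologyAttr("resnames", [atoms["resname"].iloc[i] for i in first])
    u.add_TopologyAttr("segids", [str(c) for c in seg_labels])
    u.add_TopologyAttr("chainIDs", atoms["chain"].to_list())
    u.atoms.positions = traj.coordinates[0]
    u.atoms.write(str(topology_path))
    with mda.Writer(str(coordinates_path), traj.n_atoms) as w:
        for frame in traj.coordinates:
            u.atoms.positions = frame
            w.write(u.atoms)


def _kabsch(mobile: np.ndarray, ref_centered: np.ndarray):
    """Optimal proper rotation (reflections rejected) and translation."""
    mob_mean = mobile.mean(axis=0)
    mob_c = mobile - mob_mean
    H = mob_c.T @ ref_centered
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, mob_mean


def superpose_frames(
    traj: TrajectoryEnsemble, reference_frame: int = 0, fit_selection="core_ca"
) -> SuperpositionResult:
    """Least-squares rigid-body fit of every frame onto a reference frame.

    The fit minimises the RMSD over ``fit_selection`` (closed-form Kabsch
    solution, proper rotations only) and the resulting transform is applied
    to all atoms of each frame.  The reference defaults to the first stored
    frame, the "initial structure".
    """
    idx = traj.selection(fit_selection)
    if idx.size < 3:
        raise DegenerateFitError("superposition needs at least 3 fit atoms")
    ref = traj.coordinates[reference_frame][idx]
    ref_mean = ref.mean(axis=0)
    ref_c = ref - ref_mean
    svals = np.linalg.svd(ref_c, compute_uv=False)
    if svals[1] < 1e-8 * max(svals[0], 1.0):
        raise DegenerateFitError("fit selection is collinear")

    out = np.empty_like(traj.coordinates)
    rmsd = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        R, mob_mean = _kabsch(traj.coordinates[k][idx], ref_c)
        out[k] = (traj.coordinates[k] - mob_mean) @ R.T + ref_mean
        rmsd[k] = np.sqrt(np.mean(np.sum((out[k][idx] - ref) ** 2, axis=1)))
    fitted = replace(traj, coordinates=out)
    return SuperpositionResult(ensemble=fitted, rmsd_A=rmsd)


def discard_equilibration(
    traj: TrajectoryEnsemble, cutoff_ns: float
) -> TrajectoryEnsemble:
    """Drop frames with time < cutoff (equilibration burn-in).

    With the standard settings (2 us runs, 1 ns stride) a 200 ns cutoff
    removes the first 200 frames.  Removing every frame is an error.
    """
    if cutoff_ns < 0:
        raise ValueError("cutoff_ns must be non-negative")
    n_skip = int(np.ceil(cutoff_ns / traj.frame_interval_ns - 1e-12))
    if n_skip >= traj.n_frames:
        raise EmptyTrajectoryError(
            f"cutoff {cutoff_ns} ns removes all {traj.n_frames} frames"
        )
    return replace(traj, coordinates=traj.coordinates[n_skip:])


def extract_nh_vectors(
    traj: TrajectoryEnsemble,
    chain=None,
    resids=None,
    n_name: str = "N",
    h_name: str = "H",
) -> VectorTrajectory:
    """Unit N->H bond vectors per residue, for relaxation prediction.

    Residues lacking either atom (prolines, termini) are skipped.
    """
    atoms = traj.atoms
    mask = np.ones(len(atoms), dtype=bool)
    if chain is not None:
        chains = [chain] if isinstance(chain, str) else list(chain)
        mask &= atoms["chain"].isin(chains).to_numpy()
    if resids is not None:
        mask &= atoms["resid"].isin(list(resids)).to_numpy()
    sub = atoms[mask]
    n_idx, h_idx, residues = [], [], []
    for (ch, resid), grp in sub.groupby(["chain", "resid"], sort=True):
        ns = grp.index[grp["name"] == n_name]
        hs = grp.index[grp["name"] == h_name]
        if len(ns) and len(hs):
            n_idx.append(ns[0])
            h_idx.append(hs[0])
            residues.append(resid if chain is not None else (ch, resid))
    if not residues:
        raise SelectionError("no residues with both N and H atoms")
    vec = traj.coordinates[:, h_idx, :] - traj.coordinates[:, n_idx, :]
    vec /= np.linalg.norm(vec, axis=-1, keepdims=True)
    res_arr = np.empty(len(residues), dtype=object)
    res_arr[:] = residues
    return VectorTrajectory(
        vectors=vec,
        frame_interval_ns=traj.frame_interval_ns,
        residues=res_arr,
    )
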