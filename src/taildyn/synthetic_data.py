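"""Synthetic inputs with known ground truth for every pipeline stage.

The real study inputs are microsecond all-atom trajectories and laboratory
NMR/fluorescence tables, none of which are deposited; these generators
emulate their statistical structure at desk scale so each analysis stage can
be validated against analytic expectations:

* unit NH bond vectors undergoing isotropic rotational diffusion (rank-2
  autocorrelation exactly exp(-t/tau_rot)) with optional restricted internal
  motion (diffusion in a cone whose half-angle matches a prescribed S2);
* hidden two-state Markov bound/unbound timelines with exponential dwell
  times and per-residue Bernoulli contact emission;
* single-exponential peak-intensity decays on the experimental delay
  schedules, with Gaussian noise;
* one- or two-transition sigmoidal melting curves on the 25-95 degC, 1 degC
  instrument grid;
* a toy pseudo-atomic nucleosome (static DNA arc, mobile tail chains with a
  scripted bound/unbound schedule) as an end-to-end fixture for contact and
  network analysis.

Every generator is deterministic under a fixed seed; independent random
streams are spawned from one seed hierarchy.  Each artifact carries its
generating parameters (and seed) as ground truth.  None of this attempts to
mimic real nucleosome energetics, sequence specificity or force-field
physics.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .contact_kinetics import ContactTimeline
from .md_to_nmr import VectorTrajectory
from .thermal_shift import MeltCurve
from .trajectory_model import TrajectoryEnsemble

__all__ = [
    "ResolutionError",
    "R1_DELAYS_0MM_S",
    "R2_DELAYS_0MM_S",
    "R1_DELAYS_100MM_S",
    "R2_DELAYS_100MM_S",
    "gen_rotational_diffusion",
    "gen_internal_motion",
    "gen_two_state_timeline",
    "gen_intensity_decays",
    "gen_melt_curve",
    "gen_toy_nucleosome",
]


class ResolutionError(ValueError):
    """Time step too coarse to resolve the requested motion."""


# experimental relaxation-delay schedules (seconds); "(x2)" repeats retained
R1_DELAYS_0MM_S = (
    0.010, 0.050, 0.050, 0.100, 0.200, 0.400, 0.500, 0.500,
    0.800, 1.000, 1.250, 1.250, 1.500,
)
R2_DELAYS_0MM_S = (
    0.01568, 0.03136, 0.03136, 0.04704, 0.0784, 0.09408, 0.09408,
    0.10976, 0.12544, 0.1568, 0.18816, 0.18816, 0.2034,
)
R1_DELAYS_100MM_S = (0.025, 0.200, 0.400, 0.400, 0.800, 1.250, 1.750)
R2_DELAYS_100MM_S = (
    0.01568, 0.03136, 0.04704, 0.04704, 0.06272, 0.09408, 0.09408, 0.10976,
)


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """One seed hierarchy: dataset seed -> independent per-stream children."""
    return [np.random.Generator(np.random.PCG64(s)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def _sphere_step(u: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """One Brownian step on the unit sphere.

    Displaces each vector by a Gaussian tangent-plane step with per-axis
    standard deviation ``sigma`` (total mean-square angular displacement
    2 sigma^2 = 4 D dt), i.e. a small rotation about a uniformly random axis
    perpendicular to the vector.  This discretization gives rank-l
    autocorrelation exp(-l(l+1) D t) in the small-step limit.
    """
    g = rng.standard_normal(u.shape)
    tang = g - np.sum(g * u, axis=-1, keepdims=True) * u
    v = sigma * tang
    theta = np.linalg.norm(v, axis=-1, keepdims=True)
    safe = np.where(theta > 0, theta, 1.0)
    vhat = v / safe
    out = np.cos(theta) * u + np.sin(theta) * vhat
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def _random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def gen_rotational_diffusion(
    tau_rot_ns: float,
    dt_ns: float,
    n_frames: int,
    n_vectors: int,
    seed: int,
) -> VectorTrajectory:
    """Isotropic rotational Brownian motion of unit vectors.

    Diffusion coefficient D = 1/(6 tau_rot); the expected P2 autocorrelation
    is exp(-t/tau_rot).  ``tau_rot_ns = inf`` freezes the vectors.  The step
    must resolve the motion: dt <= tau_rot / 10.
    """
    if not tau_rot_ns > 0:
        raise ValueError("tau_rot_ns must be positive")
    if math.isfinite(tau_rot_ns) and dt_ns > tau_rot_ns / 10.0:
        raise ResolutionError(
            f"dt = {dt_ns} ns too coarse for tau_rot = {tau_rot_ns} ns "
            "(need dt <= tau_rot/10)"
        )
    rng = _spawn_rngs(seed, 1)[0]
    D = 0.0 if math.isinf(tau_rot_ns) else 1.0 / (6.0 * tau_rot_ns)
    sigma = math.sqrt(2.0 * D * dt_ns)
    u = _random_unit_vectors(n_vectors, rng)
    out = np.empty((n_frames, n_vectors, 3))
    out[0] = u
    for k in range(1, n_frames):
        u = _sphere_step(u, sigma, rng) if sigma > 0 else u
        out[k] = u
    return VectorTrajectory(
        vectors=out,
        frame_interval_ns=dt_ns,
        residues=np.arange(1, n_vectors + 1),
        ground_truth={
            "tau_rot_ns": tau_rot_ns,
            "S2": np.ones(n_vectors),
            "tau_e_ns": None,
            "seed": seed,
        },
    )


def _cone_half_angle(S2: float) -> float:
    """Cone half-angle beta with S2 = [cos(b)(1+cos(b))/2]^2.

    The quadratic in cos(b) has two roots for S2 = 0; the free-diffusion
    branch (b = pi) is chosen there.
    """
    if S2 == 0.0:
        return math.pi
    s = math.sqrt(S2)
    c = (-1.0 + math.sqrt(1.0 + 8.0 * s)) / 2.0
    return math.acos(min(c, 1.0))


def gen_internal_motion(
    S2: float,
    tau_e_ns: float,
    dt_ns: float,
    n_frames: int,
    n_vectors: int,
    seed: int,
) -> VectorTrajectory:
    """Restricted internal wobble: diffusion in a cone matching S2.

    Vectors diffuse on the unit sphere inside a cone about the z axis whose
    half-angle reproduces the requested order parameter through
    S2 = [cos(b)(1+cos(b))/2]^2, with a reflecting boundary; the long-time
    P2 autocorrelation plateau is S2.  The wobble diffusion coefficient is
    D = (1 - S2)/(6 tau_e), exact in the free-diffusion limit (S2 = 0) and
    giving an initial decay time of order tau_e inside the cone.  S2 = 1 is
    static; S2 = 0 is free diffusion with plateau 0.
    """
    if not 0.0 <= S2 <= 1.0:
        raise ValueError("S2 must lie in [0, 1]")
    if not tau_e_ns > 0:
        raise ValueError("tau_e_ns must be positive")
    rng = _spawn_rngs(seed, 1)[0]
    beta = _cone_half_angle(S2)
    D = (1.0 - S2) / (6.0 * tau_e_ns)
    sigma = math.sqrt(2.0 * D * dt_ns)
    cos_beta = math.cos(beta)

    # start from the stationary distribution: uniform on the cone cap
    cos_t = rng.uniform(cos_beta, 1.0, size=n_vectors)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n_vectors)
    sin_t = np.sqrt(1.0 - cos_t**2)
    u = np.column_stack(
        [sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t]
    )
    out = np.empty((n_frames, n_vectors, 3))
    out[0] = u
    reflect = beta < math.pi
    for k in range(1, n_frames):
        if sigma > 0:
            u = _sphere_step(u, sigma, rng)
            if reflect:
                theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
                over = theta > beta
                if np.any(over):
                    theta_r = np.abs(2.0 * beta - theta[over])
                    phi_r = np.arctan2(u[over, 1], u[over, 0])
                    sin_r = np.sin(theta_r)
                    u[over, 0] = sin_r * np.cos(phi_r)
                    u[over, 1] = sin_r * np.sin(phi_r)
                    u[over, 2] = np.cos(theta_r)
        out[k] = u
    return VectorTrajectory(
        vectors=out,
        frame_interval_ns=dt_ns,
        residues=np.arange(1, n_vectors + 1),
        ground_truth={
            "tau_rot_ns": None,
            "S2": float(S2),
            "tau_e_ns": float(tau_e_ns),
            "cone_half_angle_rad": beta,
            "seed": seed,
        },
    )


def gen_two_state_timeline(
    k_bind_per_ns: float,
    k_unbind_per_ns: float,
    n_residues: int,
    p_contact_given_bound: float = 0.5,
    dt_ns: float = 1.0,
    n_frames: int = 10000,
    seed: int = 0,
) -> ContactTimeline:
    """Hidden two-state Markov bound/unbound timeline with contact emission.

    The full tail switches between bound and unbound states with exponential
    dwell times (discretized to geometric frame counts); in the bound state
    each residue contacts DNA independently with probability ``p`` per
    frame, in the unbound state with the 2% background 0.02 p — a nonzero
    noise floor that exercises the 10% state-calling rule.  The hidden state
    sequence is stored as ground truth.
    """
    if k_bind_per_ns <= 0 or k_unbind_per_ns <= 0:
        raise ValueError("rates must be positive")
    if not 0.0 < p_contact_given_bound <= 1.0:
        raise ValueError("p_contact_given_bound must be in (0, 1]")
    rng_state, rng_emit = _spawn_rngs(seed, 2)
    p_leave = {
        True: -math.expm1(-k_unbind_per_ns * dt_ns),   # bound -> unbound
        False: -math.expm1(-k_bind_per_ns * dt_ns),    # unbound -> bound
    }
    p_stationary_bound = k_bind_per_ns / (k_bind_per_ns + k_unbind_per_ns)
    state = bool(rng_state.random() < p_stationary_bound)
    dwell_states, dwell_lens = [], []
    total = 0
    while total < n_frames:
        dwell = int(rng_state.geometric(p_leave[state]))
        dwell_states.append(state)
        dwell_lens.append(dwell)
        total += dwell
        state = not state
    states = np.repeat(dwell_states, dwell_lens)[:n_frames]

    p_emit = np.where(
        states, p_contact_given_bound, 0.02 * p_contact_given_bound
    )
    counts = np.zeros((n_residues, n_frames), dtype=np.int32)
    block = 100_000
    for start in range(0, n_frames, block):
        stop = min(start + block, n_frames)
        draws = rng_emit.random((n_residues, stop - start))
        counts[:, start:stop] = draws < p_emit[None, start:stop]
    return ContactTimeline(
        counts=counts,
        residues=np.arange(1, n_residues + 1),
        stride_ns=dt_ns,
        ground_truth={
            "states": states,
            "k_bind_per_ns": k_bind_per_ns,
            "k_unbind_per_ns": k_unbind_per_ns,
            "p_contact_given_bound": p_contact_given_bound,
            "stationary_bound_fraction": p_stationary_bound,
            "seed": seed,
        },
    )


def gen_intensity_decays(
    true_rates_per_s,
    delays_s: Sequence[float] = R1_DELAYS_0MM_S,
    n_replicates: int = 1,
    noise_sd: float = 0.0,
    I0: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy single-exponential intensity decays on a delay schedule.

    ``true_rates_per_s`` maps residue -> decay rate (a mapping or a
    sequence, numbered from 1).  I(t) = I0 exp(-R t) + N(0, noise_sd);
    duplicate delays receive independent noise.  The default schedule is the
    experimental low-salt R1 delay list (10 ms ... 1.5 s with repeats).
    Returns a long table (residue, replicate, delay_s, intensity) whose
    ``attrs`` carry the ground truth.
    """
    if not isinstance(true_rates_per_s, dict):
        true_rates_per_s = {
            i + 1: float(r) for i, r in enumerate(np.atleast_1d(true_rates_per_s))
        }
    if any(r <= 0 for r in true_rates_per_s.values()):
        raise ValueError("decay rates must be positive")
    delays = np.asarray(delays_s, dtype=float)
    if np.any(delays < 0):
        raise ValueError("delays must be non-negative")
    rng = _spawn_rngs(seed, 1)[0]
    rows = []
    for res, rate in true_rates_per_s.items():
        for rep in range(1, n_replicates + 1):
            clean = I0 * np.exp(-rate * delays)
            noisy = clean + rng.normal(0.0, noise_sd, size=delays.size) if noise_sd else clean
            for d, i in zip(delays, noisy):
                rows.append(
                    {"residue": res, "replicate": rep, "delay_s": d, "intensity": i}
                )
    out = pd.DataFrame(rows)
    out.attrs["ground_truth"] = {
        "rates_per_s": dict(true_rates_per_s),
        "I0": I0,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return out


def gen_melt_curve(
    transition_midpoints_C: Sequence[float],
    steepnesses_C: Sequence[float] | float = 0.8,
    amplitudes: Sequence[float] | None = None,
    temp_grid_C: np.ndarray | None = None,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    baseline: float = 0.0,
    seed: int = 0,
) -> MeltCurve:
    """Sigmoidal melt curves with one or more logistic transitions.

    raw(T) = baseline + sum_k A_k logistic((T - Tm_k)/s_k) + N(0, noise_sd),
    independent noise per replicate and temperature.  Amplitudes default to
    an equal split summing to 1, so ``noise_sd`` reads directly as a
    fraction of the total signal amplitude.  The default grid is the
    instrument protocol: 25-95 degC in 1 degC steps.  Midpoints must lie
    inside the grid.
    """
    temps = (
        np.arange(25.0, 96.0, 1.0)
        if temp_grid_C is None
        else np.asarray(temp_grid_C, dtype=float)
    )
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    mids = np.atleast_1d(np.asarray(transition_midpoints_C, dtype=float))
    if np.any(mids < temps[0]) or np.any(mids > temps[-1]):
        raise ValueError("transition midpoints must lie inside the grid")
    steeps = np.broadcast_to(
        np.atleast_1d(np.asarray(steepnesses_C, dtype=float)), mids.shape
    ).astype(float)
    if amplitudes is None:
        amps = np.full(mids.shape, 1.0 / mids.size)
    else:
        amps = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    rng = _spawn_rngs(seed, 1)[0]
    clean = baseline + np.sum(
        amps[:, None] / (1.0 + np.exp(-(temps[None, :] - mids[:, None]) / steeps[:, None])),
        axis=0,
    )
    raw = np.tile(clean, (n_replicates, 1))
    if noise_sd:
        raw = raw + rng.normal(0.0, noise_sd, size=raw.shape)
    return MeltCurve(
        temps_C=temps,
        raw=raw,
        ground_truth={
            "midpoints_C": mids.tolist(),
            "steepnesses_C": steeps.tolist(),
            "amplitudes": amps.tolist(),
            "baseline": baseline,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


# --- toy nucleosome ----------------------------------------------------------


def _dna_arc(n_dna_beads: int) -> tuple[np.ndarray, np.ndarray]:
    """Two static strands of one bead per nucleotide along an arc."""
    spacing_rad = 7.0 / 45.0  # ~7 A between neighbouring beads at r = 45 A
    angles = np.arange(n_dna_beads) * spacing_rad
    strand1 = np.column_stack(
        [45.0 * np.cos(angles), 45.0 * np.sin(angles), np.zeros(n_dna_beads)]
    )
    strand2 = np.column_stack(
        [45.0 * np.cos(angles), 45.0 * np.sin(angles), np.full(n_dna_beads, 3.5)]
    )
    return strand1, strand2


def gen_toy_nucleosome(
    n_tail_beads: int = 10,
    n_dna_beads: int = 20,
    binding_mode: str = "alternating",
    seed: int = 0,
    n_frames: int = 400,
    frame_interval_ns: float = 1.0,
    n_copies: int = 2,
    block_ns: float = 100.0,
    schedule: np.ndarray | None = None,
    bound_residues: Sequence[int] | None = None,
    intra_tail_contact_frac: float = 0.0,
) -> tuple[TrajectoryEnsemble, dict]:
    """Pseudo-atomic toy fixture: static DNA arc + scripted mobile tails.

    DNA is a static arc of paired nucleotide beads (chains I and J, one bead
    per nucleotide, base-pair index shared across strands).  Each tail copy
    (chains A, B, ...) is a chain of carbon beads that sits 3 A from its
    assigned DNA beads in scripted bound frames and >= 20 A away otherwise.
    Binding modes: "always_bound", "alternating" (``block_ns`` bound /
    ``block_ns`` unbound, starting bound) or "scripted" (explicit boolean
    ``schedule`` per frame, optionally per copy).  ``bound_residues``
    restricts which tail residues approach the DNA when bound (default:
    all).  ``intra_tail_contact_frac`` > 0 folds tail residue 4 of copy A
    onto residue 1 in the first fraction of frames, scripting a persistent
    intra-tail van der Waals contact for network analysis.

    Returns the ensemble and the ground-truth script (the oracle for every
    downstream statistic).
    """
    if n_tail_beads < 2 or n_dna_beads < 2:
        raise ValueError("bead counts must be >= 2")
    strand1, strand2 = _dna_arc(n_dna_beads)

    if schedule is not None:
        schedule = np.atleast_2d(np.asarray(schedule, dtype=bool))
        if schedule.shape[0] == 1:
            schedule = np.repeat(schedule, n_copies, axis=0)
        if schedule.shape != (n_copies, n_frames):
            raise ValueError("schedule must be (n_frames,) or (n_copies, n_frames)")
    elif binding_mode == "always_bound":
        schedule = np.ones((n_copies, n_frames), dtype=bool)
    elif binding_mode == "alternating":
        block = int(round(block_ns / frame_interval_ns))
        pattern = (np.arange(n_frames) // block) % 2 == 0
        schedule = np.repeat(pattern[None, :], n_copies, axis=0)
    else:
        raise ValueError(f"unknown binding mode {binding_mode!r}")

    if bound_residues is None:
        bound_residues = list(range(1, n_tail_beads + 1))
    bound_mask = np.isin(np.arange(1, n_tail_beads + 1), list(bound_residues))

    names, elements, resids, resnames, chains = [], [], [], [], []
    for strand, chain, offset in ((strand1, "I", 1000), (strand2, "J", 2000)):
        for j in range(n_dna_beads):
            names.append("P")
            elements.append("P")
            resids.append(offset + j + 1)
            resnames.append("DA")
            chains.append(chain)
    copy_chains = [chr(ord("A") + c) for c in range(n_copies)]
    for chain in copy_chains:
        for j in range(n_tail_beads):
            names.append("CA")
            elements.append("C")
            resids.append(j + 1)
            resnames.append("GLY")
            chains.append(chain)
    core = np.array(
        [[0.0, 0.0, 20.0], [10.0, 0.0, 25.0], [0.0, 10.0, 25.0], [5.0, 5.0, 32.0]]
    )
    for j in range(4):
        names.append("CA")
        elements.append("C")
        resids.append(9001 + j)
        resnames.append("ALA")
        chains.append("X")
    atoms = pd.DataFrame(
        {
            "name": names,
            "element": elements,
            "resid": resids,
            "resname": resnames,
            "chain": chains,
            "is_heavy": [e != "H" for e in elements],
        }
    )

    n_dna_atoms = 2 * n_dna_beads
    n_atoms = n_dna_atoms + n_copies * n_tail_beads + 4
    coords = np.empty((n_frames, n_atoms, 3))
    coords[:, :n_dna_beads] = strand1
    coords[:, n_dna_beads:n_dna_atoms] = strand2
    coords[:, -4:] = core

    radial = strand1 / np.linalg.norm(strand1, axis=1, keepdims=True)
    n_intra = int(round(intra_tail_contact_frac * n_frames))
    for c in range(n_copies):
        a0 = n_dna_atoms + c * n_tail_beads
        assign = (np.arange(n_tail_beads) + c) % n_dna_beads
        bound_xyz = strand1[assign] + 3.0 * radial[assign]
        unbound_xyz = np.column_stack(
            [
                np.full(n_tail_beads, 80.0 + 10.0 * c),
                np.zeros(n_tail_beads),
                50.0 + 5.0 * np.arange(n_tail_beads),
            ]
        )
        for f in range(n_frames):
            if schedule[c, f]:
                xyz = np.where(bound_mask[:, None], bound_xyz, unbound_xyz)
            else:
                xyz = unbound_xyz
            coords[f, a0 : a0 + n_tail_beads] = xyz
        if c == 0 and n_intra > 0 and n_tail_beads >= 4:
            # fold residue 4 onto residue 1 for the scripted intra-tail contact
            coords[:n_intra, a0 + 3] = coords[:n_intra, a0] + np.array([3.0, 0.0, 0.0])

    selections = {
        "dna": np.arange(n_dna_atoms),
        "core_ca": np.arange(n_atoms - 4, n_atoms),
    }
    for c, chain in enumerate(copy_chains):
        a0 = n_dna_atoms + c * n_tail_beads
        selections[f"tail_{chain}"] = np.arange(a0, a0 + n_tail_beads)
    base_pairs = {}
    for j in range(n_dna_beads):
        base_pairs[1000 + j + 1] = j + 1
        base_pairs[2000 + j + 1] = j + 1

    ensemble = TrajectoryEnsemble(
        coordinates=coords,
        frame_interval_ns=frame_interval_ns,
        atoms=atoms,
        selections=selections,
        base_pairs=base_pairs,
    )
    ground_truth = {
        "schedule": schedule,
        "bound_residues": list(bound_residues),
        "binding_mode": binding_mode,
        "intra_tail_pair": (1, 4) if n_intra > 0 else None,
        "intra_tail_frames": n_intra,
        "copy_chains": copy_chains,
        "seed": seed,
    }
    return ensemble, ground_truth
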