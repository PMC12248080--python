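"""Prediction of NMR spin-relaxation observables from MD-derived NH bond vectors.

Disordered histone tails relax through the dipole-dipole interaction between
the backbone amide 15N and 1H spins plus the 15N chemical-shift anisotropy
(CSA).  Both mechanisms are driven by the reorientation of the NH bond vector,
so the route from a simulation to R1/R2/NOE runs through the rank-2
(second-Legendre) orientational autocorrelation function

    C(t) = < P2( u(s) . u(s+t) ) >_s ,        P2(x) = (3 x^2 - 1) / 2 ,

evaluated on trajectory frames that have been superposed onto the histone
core so that only internal tail motion remains.  The overall tumbling of the
nucleosome core particle is reintroduced analytically by multiplying C(t) by
exp(-t / tau_rot); tau_rot defaults to 163.4 ns, the tumbling time of the
intact particle.  The tumbled correlation function is fitted with (up to)
three exponentials, giving an analytic spectral density

    J(w) = (2/5) * sum_i a_i * tau_i / (1 + (w tau_i)^2)

from which R1, R2 and the heteronuclear NOE follow via the standard
dipolar + CSA expressions.  The per-residue effective correlation time is
then obtained from the same R2/R1 estimator used for the experimental data:

    tau_c = 1 / (4 pi nu_N) * sqrt(6 R2/R1 - 7) .

A numerical cosine-transform route to J(w) is provided as an independent
cross-check of the analytic Lorentzian form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.fft import irfft, next_fast_len, rfft
from scipy.optimize import least_squares, nnls
from scipy.stats import pearsonr

__all__ = [
    "GAMMA_H",
    "GAMMA_N",
    "VectorTrajectory",
    "CorrelationFunction",
    "SpectralDensityModel",
    "FieldParameters",
    "PredictedRelaxation",
    "WindowError",
    "TumblingStateError",
    "InsufficientDataError",
    "nh_autocorrelation",
    "chunk_average",
    "apply_tumbling",
    "fit_exponentials",
    "spectral_density",
    "spectral_density_numeric",
    "relaxation_from_J",
    "predict_relaxation",
    "compare_to_experiment",
]

# --- physical constants (SI) -------------------------------------------------

#: 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_H = 2.6752218744e8
#: 15N gyromagnetic ratio, rad s^-1 T^-1 (negative)
GAMMA_N = -2.7126180436e7
_HBAR = 1.054571817e-34  # J s
_MU0_OVER_4PI = 1.0e-7  # T^2 J^-1 m^3


class WindowError(ValueError):
    """Requested lag window exceeds the frames available."""


class TumblingStateError(RuntimeError):
    """Overall tumbling applied twice to the same correlation function."""


class InsufficientDataError(ValueError):
    """Too few shared residues for a meaningful comparison."""


# --- containers --------------------------------------------------------------


@dataclass
class VectorTrajectory:
    """Unit NH bond vectors for a set of residues over trajectory frames.

    vectors : (n_frames, n_residues, 3), each row a unit vector.
    frame_interval_ns : time between stored frames.
    residues : residue identifiers, one per vector column.
    ground_truth : generating parameters when the data is synthetic
        (true tumbling time, order parameter, internal timescale, seed).
    """

    vectors: np.ndarray
    frame_interval_ns: float
    residues: np.ndarray | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 3:
            raise ValueError("vectors must have shape (frames, residues, 3)")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be positive")
        norms = np.linalg.norm(self.vectors, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("all NH vectors must be unit length (|n|-1| <= 1e-9)")
        if self.residues is None:
            self.residues = np.arange(self.vectors.shape[1])
        else:
            self.residues = np.asarray(self.residues)
            if self.residues.shape[0] != self.vectors.shape[1]:
                raise ValueError("residues must match the vector columns")

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_residues(self) -> int:
        return self.vectors.shape[1]

    def column(self, residue) -> int:
        """Index of ``residue`` in the vector array."""
        key = tuple(residue) if isinstance(residue, (tuple, list)) else residue
        for i, r in enumerate(self.residues):
            if (tuple(r) if isinstance(r, tuple) else r) == key:
                return i
        raise KeyError(f"residue {residue!r} not in trajectory")


@dataclass
class CorrelationFunction:
    """P2 orientational autocorrelation of one residue's NH vector.

    ``sem`` optionally carries the per-lag standard error of the mean
    estimated from chunk-to-chunk scatter; the exponential fit uses it to
    weight lags by their information content.
    """

    lags_ns: np.ndarray
    values: np.ndarray
    n_chunks: int = 1
    residue: object = None
    tumbling_applied: bool = False
    tau_rot_ns: float | None = None
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lags_ns = np.asarray(self.lags_ns, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.values.shape:
                raise ValueError("sem must match values")
        if self.lags_ns.shape != self.values.shape:
            raise ValueError("lags and values must have the same shape")
        if self.lags_ns.size and np.any(np.diff(self.lags_ns) <= 0):
            raise ValueError("lag times must be strictly increasing")
        if (
            not self.tumbling_applied
            and self.lags_ns.size
            and self.lags_ns[0] == 0.0
            and abs(self.values[0] - 1.0) > 1e-6
        ):
            raise ValueError("C(0) must equal 1 before tumbling is applied")


@dataclass
class SpectralDensityModel:
    """Multi-exponential correlation model; evaluates the spectral density.

    Amplitudes are non-negative with sum <= 1 (+1e-3 numerical slack) and
    timescales are sorted ascending.  ``normalization`` records the
    convention: the 2/5 rank-2 factor lives in J(w), and the amplitude sum
    is constrained to <= 1 rather than == 1.
    """

    amplitudes: np.ndarray
    timescales_ns: np.ndarray
    residual_rms: float = 0.0
    poor_fit: bool = False
    normalization: str = "2/5 in J; sum(a) <= 1"

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        self.timescales_ns = np.atleast_1d(
            np.asarray(self.timescales_ns, dtype=float)
        )
        if self.amplitudes.shape != self.timescales_ns.shape:
            raise ValueError("amplitudes and timescales must align")
        if np.any(self.amplitudes < -1e-12):
            raise ValueError("amplitudes must be non-negative")
        if np.any(self.timescales_ns <= 0):
            raise ValueError("timescales must be positive")
        if self.amplitudes.sum() > 1.0 + 1e-3:
            raise ValueError("sum of amplitudes must not exceed 1 (+1e-3)")
        order = np.argsort(self.timescales_ns)
        self.timescales_ns = self.timescales_ns[order]
        self.amplitudes = np.clip(self.amplitudes[order], 0.0, None)

    def correlation(self, t_ns: np.ndarray) -> np.ndarray:
        """Reconstructed C(t) = sum_i a_i exp(-t / tau_i)."""
        t_ns = np.asarray(t_ns, dtype=float)
        return np.sum(
            self.amplitudes * np.exp(-t_ns[..., None] / self.timescales_ns),
            axis=-1,
        )

    def J(self, omega_rad_per_s) -> np.ndarray:
        return spectral_density(self, omega_rad_per_s)


@dataclass(frozen=True)
class FieldParameters:
    """Spectrometer field and spin-pair parameters for relaxation rates."""

    nu_H_hz: float
    nu_N_hz: float
    r_NH_A: float = 1.02
    csa_ppm: float = -170.0

    def __post_init__(self) -> None:
        if self.nu_H_hz <= 0 or self.nu_N_hz <= 0 or self.r_NH_A <= 0:
            raise ValueError("frequencies and bond length must be positive")
        expected = self.nu_H_hz * abs(GAMMA_N / GAMMA_H)
        if abs(self.nu_N_hz - expected) / expected > 0.01:
            raise ValueError(
                "1H/15N frequencies inconsistent with the gyromagnetic ratio"
            )

    @classmethod
    def at_field(
        cls, proton_mhz: float, nu_N_mhz: float | None = None, **kw
    ) -> "FieldParameters":
        """Parameters for a spectrometer named by its 1H frequency (MHz)."""
        nu_H = proton_mhz * 1e6
        nu_N = nu_N_mhz * 1e6 if nu_N_mhz is not None else nu_H * abs(
            GAMMA_N / GAMMA_H
        )
        return cls(nu_H_hz=nu_H, nu_N_hz=nu_N, **kw)

    @property
    def omega_H(self) -> float:
        return 2.0 * math.pi * self.nu_H_hz

    @property
    def omega_N(self) -> float:
        return 2.0 * math.pi * self.nu_N_hz

    @property
    def dipolar_constant(self) -> float:
        """d = (mu0/4pi) hbar gammaH gammaN / r^3, rad/s (magnitude)."""
        r = self.r_NH_A * 1e-10
        return _MU0_OVER_4PI * _HBAR * abs(GAMMA_H * GAMMA_N) / r**3

    @property
    def csa_constant(self) -> float:
        """c = omegaN * |delta_sigma| / sqrt(3), rad/s."""
        return self.omega_N * abs(self.csa_ppm) * 1e-6 / math.sqrt(3.0)


@dataclass
class PredictedRelaxation:
    """Relaxation observables computed from a spectral-density model."""

    R1_per_s: float
    R2_per_s: float
    NOE: float
    tau_c_ns: float  # NaN when 6 R2/R1 - 7 < 0 (fast tumbling)
    residue: object = None


# --- correlation functions ---------------------------------------------------


def _p2_autocorrelation(u: np.ndarray, max_lag_frames: int) -> np.ndarray:
    """FFT-based P2 autocorrelation of one unit-vector time series.

    Uses the identity (u_s . u_t)^2 = sum_ij (u_s u_s^T)_ij (u_t u_t^T)_ij,
    so C(t) is assembled from the autocorrelations of the nine outer-product
    component series (computed in one batched FFT).
    """
    n = u.shape[0]
    if max_lag_frames >= n:
        raise WindowError(
            f"max lag of {max_lag_frames} frames exceeds the {n} frames available"
        )
    comps = (u[:, :, None] * u[:, None, :]).reshape(n, 9)
    size = next_fast_len(2 * n)
    ft = rfft(comps, n=size, axis=0)
    acov = irfft((ft * ft.conj()).real, n=size, axis=0)[: max_lag_frames + 1]
    counts = n - np.arange(max_lag_frames + 1)
    dot_sq = acov.sum(axis=1) / counts
    return 1.5 * dot_sq - 0.5


def nh_autocorrelation(
    vectors: VectorTrajectory, residue=None, max_lag_ns: float | None = None
) -> CorrelationFunction:
    """P2 autocorrelation of one residue's NH vector over all time origins.

    ``residue`` may be omitted for single-residue trajectories.  The default
    lag window is half the trajectory length (variance control at long lags).
    """
    if residue is None:
        if vectors.n_residues != 1:
            raise ValueError("residue must be given for multi-residue data")
        col = 0
    else:
        col = vectors.column(residue)
    dt = vectors.frame_interval_ns
    if max_lag_ns is None:
        max_lag = vectors.n_frames // 2
    else:
        max_lag = int(round(max_lag_ns / dt))
    values = _p2_autocorrelation(vectors.vectors[:, col, :], max_lag)
    lags = np.arange(max_lag + 1) * dt
    return CorrelationFunction(
        lags_ns=lags, values=values, n_chunks=1, residue=residue
    )


def chunk_average(
    vectors: VectorTrajectory,
    residue=None,
    n_chunks: int = 20,
    max_lag_ns: float | None = None,
) -> CorrelationFunction:
    """Average of per-chunk autocorrelations over equal trajectory chunks.

    The trajectory is split into ``n_chunks`` contiguous blocks (default 20;
    any indivisible remainder of at most n_chunks-1 trailing frames is
    dropped), C(t) is computed independently in each block and the blocks are
    averaged pointwise.  This trades long-lag coverage for convergence.  The
    default lag window is half the chunk length.
    """
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    if residue is None:
        if vectors.n_residues != 1:
            raise ValueError("residue must be given for multi-residue data")
        col = 0
    else:
        col = vectors.column(residue)
    dt = vectors.frame_interval_ns
    chunk_len = vectors.n_frames // n_chunks
    if chunk_len < 2:
        raise WindowError("chunks shorter than two frames")
    if max_lag_ns is None:
        max_lag = chunk_len // 2
    else:
        max_lag = int(round(max_lag_ns / dt))
    if max_lag >= chunk_len:
        raise WindowError(
            f"max lag {max_lag} frames exceeds chunk length {chunk_len}"
        )
    u = vectors.vectors[: chunk_len * n_chunks, col, :]
    per_chunk = np.stack(
        [
            _p2_autocorrelation(u[k * chunk_len : (k + 1) * chunk_len], max_lag)
            for k in range(n_chunks)
        ]
    )
    lags = np.arange(max_lag + 1) * dt
    sem = (
        per_chunk.std(axis=0, ddof=1) / math.sqrt(n_chunks)
        if n_chunks > 1
        else None
    )
    return CorrelationFunction(
        lags_ns=lags,
        values=per_chunk.mean(axis=0),
        n_chunks=n_chunks,
        residue=residue,
        sem=sem,
    )


def apply_tumbling(
    corr: CorrelationFunction, tau_rot_ns: float = 163.4
) -> CorrelationFunction:
    """Reintroduce overall tumbling: multiply C(t) by exp(-t / tau_rot).

    The default tumbling time is the 163.4 ns overall rotational correlation
    time of the intact nucleosome core particle.  Applying tumbling twice is
    a state error.
    """
    if corr.tumbling_applied:
        raise TumblingStateError("tumbling already applied to this C(t)")
    if not tau_rot_ns > 0:
        raise ValueError("tau_rot_ns must be positive")
    envelope = np.exp(-corr.lags_ns / tau_rot_ns)
    return replace(
        corr,
        values=corr.values * envelope,
        sem=corr.sem * envelope if corr.sem is not None else None,
        tumbling_applied=True,
        tau_rot_ns=tau_rot_ns,
    )


# --- spectral density --------------------------------------------------------


def _log_subsample(n: int, k: int = 64) -> np.ndarray:
    """Lag indices: lag 0 plus ~k logarithmically spaced points.

    Neighbouring lags of a sampled correlation function carry strongly
    correlated noise; logarithmic subsampling equalises leverage per decade
    instead of letting the dense long-lag region dominate the fit.
    """
    if n <= k + 1:
        return np.arange(n)
    idx = np.unique(np.round(np.geomspace(1, n - 1, k)).astype(int))
    return np.concatenate([[0], idx])


def _fit_n_terms(t, y, w, n_terms, tau_max, n_grid):
    """Best weighted fit with exactly ``n_terms`` exponentials."""
    grid = np.geomspace(0.01, 2.0 * tau_max, n_grid)

    def design(taus):
        return np.exp(-t[:, None] / np.asarray(taus)[None, :])

    starts = []
    for taus in combinations(grid, min(n_terms, len(grid))):
        a, rnorm = nnls(design(taus) * w[:, None], y * w)
        starts.append((rnorm, np.asarray(taus), a))
    starts.sort(key=lambda s: s[0])

    def resid(p):
        a = p[:n_terms]
        taus = np.exp(p[n_terms:])
        r = w * (design(taus) @ a - y)
        # soft barrier keeping sum(a) <= 1
        return np.concatenate([r, [1e4 * max(0.0, a.sum() - 1.0)]])

    lower = np.concatenate([np.zeros(n_terms), np.full(n_terms, np.log(1e-3))])
    upper = np.concatenate(
        [np.ones(n_terms), np.full(n_terms, np.log(2.0 * tau_max))]
    )
    best = None
    for rnorm, taus, a in starts[:4]:
        a0 = np.clip(a, 0.0, 1.0)
        if a0.sum() > 1.0:
            a0 = a0 / a0.sum()
        tau0 = np.clip(taus, 1.1e-3, 1.9 * tau_max)
        sol = least_squares(
            resid,
            np.concatenate([a0, np.log(tau0)]),
            bounds=(lower, upper),
            method="trf",
            xtol=1e-12,
        )
        a_fit = np.clip(sol.x[:n_terms], 0.0, None)
        tau_fit = np.exp(sol.x[n_terms:])
        chi2 = float(np.sum((w * (design(tau_fit) @ a_fit - y)) ** 2))
        if best is None or chi2 < best[0]:
            best = (chi2, a_fit, tau_fit)
    return best


def fit_exponentials(
    corr: CorrelationFunction,
    n_terms: int = 3,
    n_grid: int = 8,
    poor_fit_rms: float = 0.02,
) -> SpectralDensityModel:
    """Constrained multi-exponential fit of an autocorrelation function.

    Fits C(t) ~ sum_i a_i exp(-t/tau_i) with a_i >= 0, tau_i > 0 and
    sum(a) <= 1 by variable projection: candidate timescale tuples from a
    logarithmic grid on [0.01 ns, 2 * tau_max] (tau_max = the applied
    tumbling time, else the longest lag), non-negative least squares for the
    amplitudes, then bounded nonlinear polishing of the best starts.

    Lags are subsampled logarithmically and, when the correlation function
    carries chunk-scatter uncertainties, residuals are weighted by 1/sem so
    the precisely determined short lags anchor the fit.  Model order is
    selected parsimoniously: the smallest number of terms (1..n_terms) whose
    weighted reduced chi-square is <= 1 is accepted, falling back to the
    lowest-chi-square model — statistically insignificant slow components
    would otherwise leak large spurious contributions into J(0).
    Near-duplicate timescales (ratio < 1.05) are collapsed.  A fit whose RMS
    residual exceeds ``poor_fit_rms`` carries a poor-fit flag rather than
    raising.
    """
    if corr.lags_ns.size < 3 * n_terms:
        raise ValueError(
            f"need at least {3 * n_terms} points to fit {n_terms} terms"
        )
    if np.any(corr.values > 1.0 + 1e-6) or np.any(corr.values < -0.5 - 1e-6):
        raise ValueError("correlation values outside [-0.5, 1]")

    idx = _log_subsample(corr.lags_ns.size)
    t = corr.lags_ns[idx]
    y = corr.values[idx]
    calibrated = corr.sem is not None
    if calibrated:
        w = 1.0 / np.maximum(corr.sem[idx], 1e-4)
        if w.size > 1:
            w[t == 0.0] = w[1:].max()  # lag 0 is exact by construction
    else:
        w = np.ones_like(y)
    tau_max = corr.tau_rot_ns if corr.tau_rot_ns else max(t[-1], 1.0)

    chosen = None
    best = None
    for n in range(1, n_terms + 1):
        fit = _fit_n_terms(t, y, w, n, tau_max, n_grid)
        # prefer fewer terms unless more terms genuinely lower chi-square
        if best is None or fit[0] < best[0] * (1.0 - 1e-9) - 1e-12:
            best = fit
        if calibrated and fit[0] / t.size <= 1.0:
            # smallest model already consistent with the measured uncertainty
            chosen = fit
            break
    if chosen is None:
        chosen = best
    _, a, taus = chosen
    if a.sum() > 1.0:
        a = a / a.sum()

    # drop dead terms and collapse near-duplicate timescales
    keep = a > 1e-8
    a, taus = a[keep], taus[keep]
    order = np.argsort(taus)
    a, taus = a[order], taus[order]
    merged_a, merged_tau = [], []
    for ai, ti in zip(a, taus):
        if merged_tau and ti / merged_tau[-1] < 1.05:
            total = merged_a[-1] + ai
            merged_tau[-1] = (merged_a[-1] * merged_tau[-1] + ai * ti) / total
            merged_a[-1] = total
        else:
            merged_a.append(ai)
            merged_tau.append(ti)
    if not merged_a:  # pathological all-zero input
        merged_a, merged_tau = [1e-12], [tau_max]
    model = np.sum(
        np.array(merged_a) * np.exp(-corr.lags_ns[:, None] / np.array(merged_tau)),
        axis=1,
    )
    rms = math.sqrt(float(np.mean((model - corr.values) ** 2)))
    return SpectralDensityModel(
        amplitudes=np.array(merged_a),
        timescales_ns=np.array(merged_tau),
        residual_rms=rms,
        poor_fit=rms > poor_fit_rms,
    )


def spectral_density(model: SpectralDensityModel, omega_rad_per_s) -> np.ndarray:
    """Analytic J(w) = (2/5) sum_i a_i tau_i / (1 + (w tau_i)^2), s/rad."""
    omega = np.asarray(omega_rad_per_s, dtype=float)
    tau_s = model.timescales_ns * 1e-9
    out = 0.4 * np.sum(
        model.amplitudes * tau_s / (1.0 + (omega[..., None] * tau_s) ** 2),
        axis=-1,
    )
    return out if out.ndim else float(out)


def spectral_density_numeric(
    model: SpectralDensityModel,
    omega_rad_per_s,
    t_max_factor: float = 12.0,
) -> np.ndarray:
    """Cosine-transform J(w) of the reconstructed C(t), computed numerically.

    J(w) = (2/5) * integral_0^inf C(t) cos(wt) dt, evaluated by trapezoidal
    quadrature on a grid resolving both the fastest model timescale and the
    highest requested frequency.  Serves as an independent frequency-domain
    cross-check of :func:`spectral_density`.
    """
    omegas = np.atleast_1d(np.asarray(omega_rad_per_s, dtype=float))
    tau_s = model.timescales_ns * 1e-9
    w_max = float(np.max(np.abs(omegas))) if omegas.size else 0.0
    dt = tau_s.min() / 50.0
    if w_max > 0:
        dt = min(dt, 0.05 / w_max)
    t_max = t_max_factor * tau_s.max()
    n = int(t_max / dt) + 1
    out = np.zeros(omegas.shape)
    block = 2_000_000
    for start in range(0, n, block):
        stop = min(start + block, n)
        t = (np.arange(start, stop)) * dt
        c = np.sum(model.amplitudes * np.exp(-t[:, None] / tau_s), axis=1)
        for i, w in enumerate(omegas):
            integrand = c * np.cos(w * t)
            seg = np.trapezoid(integrand, dx=dt)
            if start > 0:
                # re-add the half-weight shared edge between blocks
                prev_t = (start - 1) * dt
                prev_c = np.sum(model.amplitudes * np.exp(-prev_t / tau_s))
                seg += 0.5 * dt * (prev_c * np.cos(w * prev_t) + integrand[0])
            out[i] += seg
    out *= 0.4
    if np.isscalar(omega_rad_per_s) or np.ndim(omega_rad_per_s) == 0:
        return float(out[0])
    return out


# --- relaxation observables --------------------------------------------------


def tau_c_from_ratio(R1: float, R2: float, nu_N_hz: float) -> float:
    """tau_c (seconds) from the R2/R1 ratio; NaN if the discriminant < 0."""
    disc = 6.0 * R2 / R1 - 7.0
    if disc < 0:
        return float("nan")
    return math.sqrt(disc) / (4.0 * math.pi * nu_N_hz)


def relaxation_from_J(
    model: SpectralDensityModel, fieldp: FieldParameters, residue=None
) -> PredictedRelaxation:
    """R1, R2, NOE and the R2/R1-derived tau_c from a fitted J(w).

    Standard dipolar + CSA expressions evaluated at the five canonical
    frequencies {0, wN, wH - wN, wH, wH + wN}; the NOE carries the sign of
    gammaN through the gammaH/gammaN ratio.
    """
    wH, wN = fieldp.omega_H, fieldp.omega_N
    d2 = fieldp.dipolar_constant**2
    c2 = fieldp.csa_constant**2
    J = lambda w: spectral_density(model, w)
    J0, JN, JHmN, JH, JHpN = (J(w) for w in (0.0, wN, wH - wN, wH, wH + wN))
    R1 = d2 / 4.0 * (JHmN + 3.0 * JN + 6.0 * JHpN) + c2 * JN
    R2 = d2 / 8.0 * (4.0 * J0 + JHmN + 3.0 * JN + 6.0 * JH + 6.0 * JHpN) + c2 / 6.0 * (
        4.0 * J0 + 3.0 * JN
    )
    if R1 > 0:
        noe = 1.0 + d2 / (4.0 * R1) * (GAMMA_H / GAMMA_N) * (6.0 * JHpN - JHmN)
        tau_c = tau_c_from_ratio(R1, R2, fieldp.nu_N_hz)
    else:
        noe = float("nan")
        tau_c = float("nan")
    return PredictedRelaxation(
        R1_per_s=float(R1),
        R2_per_s=float(R2),
        NOE=float(noe),
        tau_c_ns=float(tau_c * 1e9) if np.isfinite(tau_c) else float("nan"),
        residue=residue,
    )


def predict_relaxation(
    vectors: VectorTrajectory,
    fieldp: FieldParameters,
    tau_rot_ns: float | None = 163.4,
    n_chunks: int = 20,
    max_lag_ns: float | None = None,
    n_terms: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Full per-residue pipeline: chunked C(t) -> [tumbling] -> fit -> rates.

    Pass ``tau_rot_ns=None`` for data that already contains overall tumbling
    (e.g. free rotational-diffusion synthetics).  Returns a per-residue table
    (residue, R1, R2, NOE, tau_c_ns, fit_rms, poor_fit) and the fitted
    spectral-density models keyed by residue.
    """
    rows = []
    models: dict = {}
    for res in vectors.residues:
        corr = chunk_average(vectors, res, n_chunks=n_chunks, max_lag_ns=max_lag_ns)
        if tau_rot_ns is not None:
            corr = apply_tumbling(corr, tau_rot_ns)
        model = fit_exponentials(corr, n_terms=n_terms)
        rec = relaxation_from_J(model, fieldp, residue=res)
        models[res] = model
        rows.append(
            {
                "residue": res,
                "R1_per_s": rec.R1_per_s,
                "R2_per_s": rec.R2_per_s,
                "NOE": rec.NOE,
                "tau_c_ns": rec.tau_c_ns,
                "fit_rms": model.residual_rms,
                "poor_fit": model.poor_fit,
            }
        )
    return pd.DataFrame(rows), models


def compare_to_experiment(predicted, observed) -> tuple[float, pd.DataFrame]:
    """Pearson r between predicted and observed per-residue values.

    Inputs are mappings or pandas Series indexed by residue; residues missing
    or NaN on either side are excluded pairwise.  Also returns per-residue
    deltas (predicted - observed) for the shared residues.
    """
    pred = pd.Series(predicted, dtype=float)
    obs = pd.Series(observed, dtype=float)
    joined = pd.concat([pred.rename("predicted"), obs.rename("observed")], axis=1)
    joined = joined.dropna()
    if len(joined) < 3:
        raise InsufficientDataError(
            f"only {len(joined)} shared residues; need at least 3"
        )
    r = pearsonr(joined["predicted"], joined["observed"]).statistic
    joined["delta"] = joined["predicted"] - joined["observed"]
    return float(r), joined
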