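"""Thermal-shift (differential scanning fluorimetry) melt-curve analysis.

Raw SYPRO-orange fluorescence traces recorded on a 25-95 degC grid are
normalized per replicate to [0, 1] over that replicate's full temperature
range,

    norm(Ti) = (RFU(Ti) - RFU_min) / (RFU_max - RFU_min) ,

differentiated by a forward difference whose value is assigned to the upper
temperature of each step,

    d norm / dT |_(Ti+1) = (norm(Ti+1) - norm(Ti)) / (Ti+1 - Ti) ,

and the melting temperatures are the temperatures of the derivative peaks.
Nucleosome disassembly typically shows one or two transitions (dimer loss
followed by tetramer loss); peak detection therefore supports both profiles
and suppresses attenuated shoulders via a prominence floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "MeltCurve",
    "GridError",
    "DegenerateRangeError",
    "normalize_curve",
    "derivative_curve",
    "find_tm",
    "aggregate_replicates",
    "analyze_melt",
]


class GridError(ValueError):
    """Temperature grid not strictly ascending, or grids mismatch."""


class DegenerateRangeError(ValueError):
    """A replicate with a constant trace cannot be normalized."""


@dataclass
class MeltCurve:
    """Temperature grid plus raw (and derived) fluorescence per replicate.

    raw : (n_replicates, n_temperatures) RFU.
    normalized / derivative / tm_C are populated by the analysis operations;
    the derivative series is one point shorter than the grid and is indexed
    by ``temps_C[1:]`` (forward-difference values sit at the upper step
    temperature).
    """

    temps_C: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray | None = None
    derivative: np.ndarray | None = None
    tm_C: np.ndarray | None = None
    replicate_mean: np.ndarray | None = None
    replicate_sd: np.ndarray | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temps_C = np.asarray(self.temps_C, dtype=float)
        self.raw = np.atleast_2d(np.asarray(self.raw, dtype=float))
        if np.any(np.diff(self.temps_C) <= 0):
            raise GridError("temperature grid must be strictly ascending")
        if self.raw.shape[1] != self.temps_C.size:
            raise ValueError("raw traces must match the temperature grid")


def normalize_curve(raw: np.ndarray, temps_C: np.ndarray) -> np.ndarray:
    """Min-max normalization per replicate over the full temperature range."""
    temps_C = np.asarray(temps_C, dtype=float)
    if temps_C.size < 3:
        raise ValueError("need at least 3 temperature points")
    if np.any(np.diff(temps_C) <= 0):
        raise GridError("temperature grid must be strictly ascending")
    raw2 = np.atleast_2d(np.asarray(raw, dtype=float))
    lo = raw2.min(axis=1, keepdims=True)
    hi = raw2.max(axis=1, keepdims=True)
    if np.any(hi - lo <= 0):
        raise DegenerateRangeError("constant fluorescence trace")
    out = (raw2 - lo) / (hi - lo)
    return out if np.ndim(raw) == 2 else out[0]


def derivative_curve(
    normalized: np.ndarray, temps_C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-difference derivative, assigned to the upper temperature.

    Returns (derivative, temps_C[1:]); the series is one point shorter than
    the grid.
    """
    temps_C = np.asarray(temps_C, dtype=float)
    if np.any(np.diff(temps_C) <= 0):
        raise GridError("temperature grid must be strictly ascending")
    norm2 = np.atleast_2d(np.asarray(normalized, dtype=float))
    deriv = np.diff(norm2, axis=1) / np.diff(temps_C)[None, :]
    out = deriv if np.ndim(normalized) == 2 else deriv[0]
    return out, temps_C[1:]


def _default_prominence(derivative: np.ndarray) -> float:
    """Noise-aware prominence floor.

    10% of the global derivative maximum, raised to five robust (MAD-based)
    noise standard deviations so replicate noise on a fine grid cannot
    masquerade as a melting transition.
    """
    gmax = float(np.max(derivative))
    sigma = 1.4826 * float(np.median(np.abs(derivative - np.median(derivative))))
    return max(0.10 * gmax, 5.0 * sigma)


def find_tm(
    derivative: np.ndarray,
    deriv_temps_C: np.ndarray,
    min_prominence: float | None = None,
) -> np.ndarray:
    """Melting temperatures: derivative peaks above a prominence floor.

    Local maxima of the forward-difference series with prominence at least
    ``min_prominence`` (default: noise-aware floor, see
    :func:`_default_prominence`) are reported ascending in temperature.  A
    flat profile yields an empty list, not an error.  Because the derivative
    is assigned to the upper step temperature, a detected peak may sit one
    grid step above the true midpoint.
    """
    derivative = np.asarray(derivative, dtype=float)
    if derivative.size == 0:
        raise ValueError("empty derivative series")
    if derivative.ndim != 1:
        raise ValueError("one derivative series at a time")
    if min_prominence is None:
        min_prominence = _default_prominence(derivative)
    peaks, _ = find_peaks(derivative, prominence=min_prominence)
    return np.asarray(deriv_temps_C)[peaks]


def aggregate_replicates(
    curve: "MeltCurve | list[MeltCurve]", min_prominence: float | None = None
) -> MeltCurve:
    """Pointwise replicate mean +- SD; Tm detected on the mean derivative.

    Accepts one multi-replicate curve or a list of curves recorded on a
    shared temperature grid (mismatched grids are an error).
    """
    if not isinstance(curve, MeltCurve):
        curves = list(curve)
        temps = curves[0].temps_C
        for c in curves[1:]:
            if c.temps_C.shape != temps.shape or not np.allclose(c.temps_C, temps):
                raise GridError("replicates recorded on different grids")
        curve = MeltCurve(
            temps_C=temps,
            raw=np.vstack([c.raw for c in curves]),
            ground_truth=curves[0].ground_truth,
        )
    if curve.raw.shape[0] < 2:
        raise ValueError("need at least 2 replicates to aggregate")
    norm = normalize_curve(curve.raw, curve.temps_C)
    mean = norm.mean(axis=0)
    sd = norm.std(axis=0, ddof=1)
    deriv, dtemps = derivative_curve(mean, curve.temps_C)
    tm = find_tm(deriv, dtemps, min_prominence)
    return MeltCurve(
        temps_C=curve.temps_C,
        raw=curve.raw,
        normalized=norm,
        derivative=deriv,
        tm_C=tm,
        replicate_mean=mean,
        replicate_sd=sd,
        ground_truth=curve.ground_truth,
    )


def analyze_melt(
    curve: MeltCurve, min_prominence: float | None = None
) -> MeltCurve:
    """Normalize, differentiate and detect Tm for a single- or multi-replicate
    curve; multi-replicate input is aggregated first."""
    if curve.raw.shape[0] >= 2:
        return aggregate_replicates(curve, min_prominence)
    norm = normalize_curve(curve.raw[0], curve.temps_C)
    deriv, dtemps = derivative_curve(norm, curve.temps_C)
    tm = find_tm(deriv, dtemps, min_prominence)
    return MeltCurve(
        temps_C=curve.temps_C,
        raw=curve.raw,
        normalized=norm[None, :],
        derivative=deriv,
        tm_C=tm,
        replicate_mean=norm,
        replicate_sd=np.zeros_like(norm),
        ground_truth=curve.ground_truth,
    )
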