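"""Experiment-side NMR analysis: CSPs, decay-rate fits, tau_c from R2/R1.

Chemical shift perturbations between two conditions combine the 1H and 15N
displacements of each amide resonance as

    ddelta = sqrt( ddelta_H^2 + 0.154 * ddelta_N^2 )   (ppm),

relaxation rates come from least-squares fits of amide peak intensities to a
single-exponential decay without offset, I(t) = I0 exp(-R t), and the
residue-specific effective rotational correlation time follows from the
R2/R1 ratio,

    tau_c = 1 / (4 pi nu_N) * sqrt( 6 R2/R1 - 7 )   (seconds),

with nu_N the 15N resonance frequency in Hz (60.8 MHz on a 600 MHz
spectrometer).  Uncertainties propagate first-order from (R1, R2) through
the ratio and the square root.  Residues without usable peaks (prolines,
exchange-broadened resonances) are carried as explicit flagged gaps, never
as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CSP_N_WEIGHT",
    "FastTumblingError",
    "AlignmentError",
    "DecayFitError",
    "DecayFit",
    "compute_csp",
    "fit_decay_rate",
    "fit_decay_table",
    "tau_c_from_rates",
    "csp_profile",
    "relaxation_table",
]

#: 15N weight in the combined-shift formula
CSP_N_WEIGHT = 0.154


class FastTumblingError(ValueError):
    """6 R2/R1 - 7 < 0: tau_c undefined by the R2/R1 estimator."""


class AlignmentError(ValueError):
    """Two peak tables share no residues."""


class DecayFitError(RuntimeError):
    """Exponential fit failed to converge."""


def compute_csp(delta_H_ppm, delta_N_ppm):
    """Combined 1H/15N chemical shift change (ppm); vectorised."""
    dh = np.asarray(delta_H_ppm, dtype=float)
    dn = np.asarray(delta_N_ppm, dtype=float)
    out = np.sqrt(dh**2 + CSP_N_WEIGHT * dn**2)
    return float(out) if out.ndim == 0 else out


@dataclass
class DecayFit:
    """Single-exponential decay fit I(t) = I0 exp(-R t), no offset."""

    rate_per_s: float
    sigma_rate: float  # from the fit covariance
    I0: float
    sigma_rate_repeats: float | None = None  # noise floor from repeated delays


def _repeat_noise_sd(delays: np.ndarray, intensities: np.ndarray) -> float | None:
    """Pooled intensity noise estimated from repeated delay points."""
    df = pd.DataFrame({"d": delays, "i": intensities})
    groups = [g["i"].to_numpy() for _, g in df.groupby("d") if len(g) > 1]
    if not groups:
        return None
    ss = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    dof = sum(len(g) - 1 for g in groups)
    return math.sqrt(ss / dof) if dof > 0 and ss > 0 else None


def fit_decay_rate(delays_s, intensities) -> DecayFit:
    """Least-squares single-exponential fit of peak intensities vs delay.

    Duplicate delays are retained as independent observations.  The rate
    uncertainty comes from the fit covariance; when repeated delays exist,
    a second estimate anchored to their scatter is reported alongside.
    Constant intensities give R = 0 exactly.
    """
    t = np.asarray(delays_s, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size < 4 or np.unique(t).size < 4:
        raise ValueError("need at least 4 distinct delay points")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("delays and intensities must be finite")
    if np.ptp(y) == 0:
        return DecayFit(rate_per_s=0.0, sigma_rate=0.0, I0=float(y[0]))

    i0_guess = float(np.max(np.abs(y)))
    positive = y > 0
    if positive.sum() >= 2:
        slope = np.polyfit(t[positive], np.log(y[positive]), 1)[0]
        r_guess = max(-slope, 1e-3)
    else:
        r_guess = 1.0

    model = lambda tt, i0, r: i0 * np.exp(-r * tt)
    try:
        popt, pcov = curve_fit(
            model, t, y, p0=[i0_guess, r_guess], maxfev=10000
        )
    except RuntimeError as exc:
        raise DecayFitError(
            f"exponential fit did not converge (n={t.size}, "
            f"I0 guess {i0_guess:.3g}, R guess {r_guess:.3g})"
        ) from exc
    sigma = float(np.sqrt(pcov[1, 1]))

    sigma_rep = None
    noise = _repeat_noise_sd(t, y)
    if noise is not None:
        try:
            _, pcov_abs = curve_fit(
                model,
                t,
                y,
                p0=popt,
                sigma=np.full_like(y, noise),
                absolute_sigma=True,
                maxfev=10000,
            )
            sigma_rep = float(np.sqrt(pcov_abs[1, 1]))
        except RuntimeError:
            sigma_rep = None
    return DecayFit(
        rate_per_s=float(popt[1]),
        sigma_rate=sigma,
        I0=float(popt[0]),
        sigma_rate_repeats=sigma_rep,
    )


def fit_decay_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-residue decay fits of a long-format table.

    Expects columns residue, delay_s, intensity; returns one row per residue
    with the fitted rate and both uncertainty estimates.
    """
    rows = []
    for res, grp in table.groupby("residue", sort=True):
        fit = fit_decay_rate(grp["delay_s"].to_numpy(), grp["intensity"].to_numpy())
        rows.append(
            {
                "residue": res,
                "rate_per_s": fit.rate_per_s,
                "sigma_rate": fit.sigma_rate,
                "sigma_rate_repeats": fit.sigma_rate_repeats,
                "I0": fit.I0,
            }
        )
    return pd.DataFrame(rows)


def tau_c_from_rates(
    R1: float,
    R2: float,
    sigma_R1: float = 0.0,
    sigma_R2: float = 0.0,
    nu_N_hz: float = 60.8e6,
) -> tuple[float, float]:
    """Effective rotational correlation time from R2/R1, with uncertainty.

    tau_c = 1/(4 pi nu_N) sqrt(6 R2/R1 - 7), in seconds; the uncertainty is
    propagated first-order through the ratio and the square root.  A
    negative discriminant (fast tumbling) raises :class:`FastTumblingError`.
    """
    if R1 <= 0:
        raise ValueError("R1 must be positive")
    ratio = R2 / R1
    disc = 6.0 * ratio - 7.0
    if disc < 0:
        raise FastTumblingError(
            f"6 R2/R1 - 7 = {disc:.4g} < 0: tau_c undefined by this estimator"
        )
    pref = 1.0 / (4.0 * math.pi * nu_N_hz)
    tau = pref * math.sqrt(disc)
    sigma_ratio = abs(ratio) * math.sqrt(
        (sigma_R1 / R1) ** 2 + (sigma_R2 / R2) ** 2
    )
    if disc > 0:
        sigma_tau = pref * 3.0 / math.sqrt(disc) * sigma_ratio
    else:
        sigma_tau = float("inf") if sigma_ratio > 0 else 0.0
    return tau, sigma_tau


def csp_profile(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Per-residue combined shift changes between two peak tables.

    Tables carry columns residue, delta_H_ppm, delta_N_ppm with unique
    residues.  Residues present in only one table are flagged missing and
    carry no value (NaN), mirroring the convention of marking prolines and
    missing peaks explicitly rather than as zeros.
    """
    for name, tbl in (("a", table_a), ("b", table_b)):
        if tbl["residue"].duplicated().any():
            raise ValueError(f"duplicate residues in table {name}")
        if not np.all(np.isfinite(tbl[["delta_H_ppm", "delta_N_ppm"]])):
            raise ValueError(f"non-finite shifts in table {name}")
    a = table_a.set_index("residue")
    b = table_b.set_index("residue")
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise AlignmentError("peak tables share no residues")
    all_res = a.index.union(b.index)
    rows = []
    for res in all_res:
        if res in shared:
            csp = compute_csp(
                a.loc[res, "delta_H_ppm"] - b.loc[res, "delta_H_ppm"],
                a.loc[res, "delta_N_ppm"] - b.loc[res, "delta_N_ppm"],
            )
            flag = "ok"
        else:
            csp = float("nan")
            flag = "missing_in_b" if res in a.index else "missing_in_a"
        rows.append({"residue": res, "csp_ppm": csp, "flag": flag})
    return pd.DataFrame(rows)


def relaxation_table(
    r1_fits: pd.DataFrame, r2_fits: pd.DataFrame, nu_N_hz: float = 60.8e6
) -> pd.DataFrame:
    """Combine per-residue R1 and R2 fits into a relaxation record table.

    Computes R2/R1 and tau_c with propagated uncertainties; residues where
    the estimator is undefined (negative discriminant) carry NaN tau_c with
    a flag instead of failing the whole table.
    """
    a = r1_fits.set_index("residue")
    b = r2_fits.set_index("residue")
    shared = a.index.intersection(b.index)
    rows = []
    for res in shared:
        R1, s1 = a.loc[res, "rate_per_s"], a.loc[res, "sigma_rate"]
        R2, s2 = b.loc[res, "rate_per_s"], b.loc[res, "sigma_rate"]
        ratio = R2 / R1 if R1 > 0 else float("nan")
        sigma_ratio = (
            abs(ratio) * math.sqrt((s1 / R1) ** 2 + (s2 / R2) ** 2)
            if R1 > 0 and R2 > 0
            else float("nan")
        )
        try:
            tau, stau = tau_c_from_rates(R1, R2, s1, s2, nu_N_hz)
            tau_ns, stau_ns, flag = tau * 1e9, stau * 1e9, "ok"
        except (FastTumblingError, ValueError):
            tau_ns, stau_ns, flag = float("nan"), float("nan"), "fast_tumbling"
        rows.append(
            {
                "residue": res,
                "R1_per_s": R1,
                "sigma_R1": s1,
                "R2_per_s": R2,
                "sigma_R2": s2,
                "R2_over_R1": ratio,
                "sigma_R2_over_R1": sigma_ratio,
                "tau_c_ns": tau_ns,
                "sigma_tau_c_ns": stau_ns,
                "nu_N_hz": nu_N_hz,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)
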