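"""Finite-size scaling of the axial hydropathic field and the critical point.

On a scale-invariant interval the axial field magnitude obeys
|m1_z(p, l)| ~ l^gamma(p); around the selectivity filter the exponent
switches sign at the inflection scale — power-law growth (network
expansion, gamma_I > 0) below xi(p) and decay (contraction, gamma_II < 0)
above it.  The atom-packing energy proxy is U(p, l) = |h1_z|/l, modelled per
phase as n(p, l) * l^(gamma-1) with n the selected sigmoid.  The critical
pore point is the SF-region point that best supports the piecewise pattern
(minimal combined mean absolute relative fitting error, MARFE, under the
sign constraint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .packing_cdf import SigmoidFit
from .pore_geometry import PorePath


@dataclass
class PowerLawFit:
    """Log-log least-squares fit of magnitude ~ prefactor * l^gamma on an
    interval (l_lo, l_hi]; MARFE is reported in natural space."""

    p_index: int
    interval: tuple[float, float]
    gamma: float
    prefactor: float
    marfe: float
    marfe_sd: float
    n_points: int
    converged: bool = True

    def predict(self, l: np.ndarray) -> np.ndarray:
        return self.prefactor * np.asarray(l, dtype=float) ** self.gamma


def _failed(p_index: int, interval: tuple[float, float], n: int) -> PowerLawFit:
    return PowerLawFit(
        p_index=p_index, interval=interval, gamma=np.nan, prefactor=np.nan,
        marfe=np.nan, marfe_sd=np.nan, n_points=n, converged=False,
    )


def fit_power_law(
    l_values: np.ndarray,
    magnitudes: np.ndarray,
    interval: tuple[float, float] | None = None,
    p_index: int = -1,
    min_points: int = 5,
) -> PowerLawFit:
    """Ordinary least squares on (ln l, ln magnitude) over (l_lo, l_hi].

    Nonpositive or undefined magnitudes in the interval are filtered with a
    warning; fewer than ``min_points`` survivors flag a fit failure.
    """
    l = np.asarray(l_values, dtype=float)
    y = np.asarray(magnitudes, dtype=float)
    if interval is None:
        interval = (float(np.min(l)) - 1e-12, float(np.max(l)))
    lo, hi = interval
    mask = (l > lo) & (l <= hi) & np.isfinite(y) & np.isfinite(l)
    n_in = int(mask.sum())
    bad = mask & (y <= 0)
    if bad.any():
        warnings.warn(f"filtered {int(bad.sum())} nonpositive magnitudes from power-law fit", stacklevel=2)
        mask &= y > 0
    if int(mask.sum()) < min_points:
        return _failed(p_index, interval, int(mask.sum()))
    X = np.log(l[mask])
    Y = np.log(y[mask])
    slope, intercept = np.polyfit(X, Y, 1)
    model = np.exp(intercept) * l[mask] ** slope
    rel = np.abs(model - y[mask]) / np.abs(y[mask])
    return PowerLawFit(
        p_index=p_index,
        interval=interval,
        gamma=float(slope),
        prefactor=float(np.exp(intercept)),
        marfe=float(np.mean(rel)),
        marfe_sd=float(np.std(rel)),
        n_points=int(mask.sum()),
    )


def piecewise_scaling(
    radii: np.ndarray,
    m1_z: np.ndarray,
    fit: SigmoidFit,
    p_index: int | None = None,
) -> tuple[PowerLawFit, PowerLawFit]:
    """Independent power-law fits of |m1_z| on the pre-inflection (s, xi] and
    post-inflection (xi, o] intervals of the sigmoid partition."""
    if not fit.converged:
        raise ValueError("sigmoid fit did not converge; no partition available")
    idx = fit.p_index if p_index is None else p_index
    mag = np.abs(np.asarray(m1_z, dtype=float))
    part1 = fit_power_law(radii, mag, interval=(fit.s, fit.xi), p_index=idx)
    part2 = fit_power_law(radii, mag, interval=(fit.xi, fit.o), p_index=idx)
    return part1, part2


@dataclass
class EnergyProfile:
    """Atom-packing energy proxy U = |h1_z|/l and its per-phase model."""

    p_index: int
    radii: np.ndarray
    U: np.ndarray
    model: np.ndarray | None = None  # n(l) * l^(gamma-1), per phase, scaled
    marfe_part1: float = np.nan
    marfe_part2: float = np.nan
    marfe_extrap_lag: float = np.nan
    marfe_extrap_asym: float = np.nan


def packing_energy(
    h1_z: np.ndarray,
    radii: np.ndarray,
    sigmoid: SigmoidFit | None = None,
    parts: tuple[PowerLawFit, PowerLawFit] | None = None,
    p_index: int = -1,
) -> EnergyProfile:
    """Elementwise U = |h1_z| / l, with the optional per-phase model curve.

    The model uses the selected sigmoid's n(p, l) times l^(gamma-1) with the
    phase exponents; its multiplicative constant is matched per phase in log
    space.  MARFEs are reported separately inside each phase interval and
    for the extrapolations beyond (s, o] (the latter are diagnostic only).
    """
    l = np.asarray(radii, dtype=float)
    mag = np.abs(np.asarray(h1_z, dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        U = mag / l
    prof = EnergyProfile(p_index=p_index, radii=l, U=U)
    if sigmoid is None or parts is None or not sigmoid.converged:
        return prof
    part1, part2 = parts
    if not (part1.converged and part2.converged):
        return prof
    n_model = sigmoid.predict(l)
    model = np.full_like(l, np.nan)
    pre = l <= sigmoid.xi
    shapes = {True: n_model * l ** (part1.gamma - 1.0), False: n_model * l ** (part2.gamma - 1.0)}

    def scale_for(mask_fit: np.ndarray, shape: np.ndarray) -> float:
        ok = mask_fit & (U > 0) & (shape > 0) & np.isfinite(U)
        if not ok.any():
            return np.nan
        return float(np.exp(np.mean(np.log(U[ok]) - np.log(shape[ok]))))

    in1 = (l > sigmoid.s) & (l <= sigmoid.xi)
    in2 = (l > sigmoid.xi) & (l <= sigmoid.o)
    c1 = scale_for(in1, shapes[True])
    c2 = scale_for(in2, shapes[False])
    model[pre] = c1 * shapes[True][pre]
    model[~pre] = c2 * shapes[False][~pre]
    prof.model = model

    def marfe(mask: np.ndarray) -> float:
        ok = mask & np.isfinite(U) & np.isfinite(model) & (U > 0)
        if not ok.any():
            return np.nan
        return float(np.mean(np.abs(model[ok] - U[ok]) / U[ok]))

    prof.marfe_part1 = marfe(in1)
    prof.marfe_part2 = marfe(in2)
    prof.marfe_extrap_lag = marfe(l <= sigmoid.s)
    prof.marfe_extrap_asym = marfe(l > sigmoid.o)
    return prof


@dataclass
class CriticalPoint:
    """Scaling-critical selectivity-filter pore point, or the explicit
    no-critical-point outcome (``found=False``)."""

    found: bool
    reason: str = ""
    p_index: int = -1
    position: np.ndarray | None = None
    xi_crit: float = np.nan
    gamma_part1: float = np.nan
    gamma_part2: float = np.nan
    marfe_part1: float = np.nan
    marfe_part2: float = np.nan
    marfe_combined: float = np.nan


def locate_critical_point(
    path: PorePath,
    fits: list[SigmoidFit],
    m1_z_grid: np.ndarray,
    radii_grid: np.ndarray,
    sf_center: np.ndarray,
    window: float = 6.0,
) -> CriticalPoint:
    """Select the critical pore point near the selectivity filter.

    Candidates are pore points within an axial window of the SF residues'
    geometric center whose piecewise exponents satisfy the expansion/
    contraction pattern (gamma_I > 0 > gamma_II); among them the winner is
    the point of maximal peak axial-field intensity over its scaling range
    (s, o] — at the critical point both the range and the intensity of the
    axial field maximize.  The combined MARFE of the winner's piecewise fits
    is reported as the fit-quality diagnostic.  No candidate satisfying the
    sign pattern yields an explicit no-critical-point result.
    """
    sf_z = float(np.asarray(sf_center, dtype=float)[2])
    by_p = {f.p_index: f for f in fits}
    best: CriticalPoint | None = None
    best_intensity = -np.inf
    n_candidates = 0
    for i, point in enumerate(path):
        if abs(point.position[2] - sf_z) > window:
            continue
        fit = by_p.get(point.index)
        if fit is None or not fit.converged:
            continue
        n_candidates += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            part1, part2 = piecewise_scaling(radii_grid[i], m1_z_grid[i], fit)
        if not (part1.converged and part2.converged):
            continue
        if not (part1.gamma > 0 > part2.gamma):
            continue
        l = np.asarray(radii_grid[i], dtype=float)
        mag = np.abs(np.asarray(m1_z_grid[i], dtype=float))
        in_range = (l > fit.s) & (l <= fit.o) & np.isfinite(mag)
        intensity = float(np.max(mag[in_range])) if in_range.any() else -np.inf
        if best is None or intensity > best_intensity:
            best_intensity = intensity
            best = CriticalPoint(
                found=True,
                p_index=point.index,
                position=point.position.copy(),
                xi_crit=fit.xi,
                gamma_part1=part1.gamma,
                gamma_part2=part2.gamma,
                marfe_part1=part1.marfe,
                marfe_part2=part2.marfe,
                marfe_combined=0.5 * (part1.marfe + part2.marfe),
            )
    if best is None:
        reason = (
            "no pore point in the SF window" if n_candidates == 0
            else "no candidate satisfies the expansion/contraction sign pattern"
        )
        return CriticalPoint(found=False, reason=reason)
    return best
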