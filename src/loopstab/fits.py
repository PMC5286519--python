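"""Stability and activity curve fitting.

Observables and models:

* **Thermal deactivation** — residual activity after incubation at elevated
  temperature decays first-order; ln(activity) vs time is fit by linear
  regression, giving the deactivation rate constant k_d and the half-life
  t_1/2 = ln 2 / k_d.
* **Thermal unfolding** — intrinsic-fluorescence spectra collapse to the
  barycentric mean wavelength λ_bcm = Σ λ·I(λ) / Σ I(λ); its temperature
  dependence is fit to a two-state van't Hoff transition with linear native
  and unfolded baselines, giving the melting temperature T_m (fraction
  unfolded = 0.5 at T_m).  Temperatures are °C at every interface and Kelvin
  inside the thermodynamic expression.
* **Enzyme kinetics** — initial rates vs substrate concentration are fit by
  non-linear least squares to the Michaelis–Menten equation, giving K_m
  (mM) and k_cat (1/s); catalytic efficiency is k_cat/K_m in s⁻¹·M⁻¹.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DecaySeries",
    "DeactivationFit",
    "SpectralSeries",
    "TwoStateFit",
    "MichaelisMentenFit",
    "fit_deactivation",
    "bcm",
    "bcm_curve",
    "fit_two_state",
    "initial_rate",
    "fit_mm",
    "catalytic_efficiency",
    "fold_change",
]

GAS_CONSTANT_KJ = 8.314462618e-3  # kJ mol^-1 K^-1
_C_TO_K = 273.15


@dataclass
class DecaySeries:
    """Residual activity (fraction of the t=0 value) vs incubation time (min)."""

    times: np.ndarray
    residual_activity: np.ndarray
    normalize_t0: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.residual_activity = np.asarray(self.residual_activity, dtype=float)
        if self.times.shape != self.residual_activity.shape:
            raise ValueError("times and activities must match in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.normalize_t0:
            self.residual_activity = self.residual_activity / self.residual_activity[0]
        if np.any(self.residual_activity <= 0):
            raise ValueError("activities must be positive for log fitting")


@dataclass(frozen=True)
class DeactivationFit:
    """First-order deactivation: k_d (1/min) and t_1/2 = ln 2 / k_d (min)."""

    k_d: float
    half_life: float
    r_squared: float
    stderr_kd: float

    def __post_init__(self):
        if math.isfinite(self.half_life):
            if not math.isclose(self.half_life * self.k_d, math.log(2), rel_tol=1e-12):
                raise ValueError("half_life * k_d must equal ln 2")


def fit_deactivation(series: DecaySeries) -> DeactivationFit:
    """Linear regression of ln(residual activity) vs time; k_d = −slope."""
    if len(series.times) < 3:
        raise ValueError("need at least 3 time points")
    res = stats.linregress(series.times, np.log(series.residual_activity))
    k_d = -res.slope
    if k_d <= 0:
        warnings.warn("non-positive deactivation rate; half-life reported as inf",
                      stacklevel=2)
        return DeactivationFit(k_d, math.inf, res.rvalue ** 2, res.stderr)
    return DeactivationFit(k_d, math.log(2) / k_d, res.rvalue ** 2, res.stderr)


# ---------------------------------------------------------------------------
# Barycentric mean fluorescence and two-state melting

@dataclass
class SpectralSeries:
    """Fluorescence intensities I(λ, T) on strictly increasing grids
    (temperatures in °C, wavelengths in nm)."""

    temperatures: np.ndarray
    wavelengths: np.ndarray
    intensities: np.ndarray  # shape (n_T, n_lambda)

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0) or np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("grids must be strictly increasing")
        if self.intensities.shape != (len(self.temperatures), len(self.wavelengths)):
            raise ValueError("intensity grid shape mismatch")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValueError("intensities must be finite and non-negative")


def bcm(wavelengths: np.ndarray, intensities: np.ndarray) -> float:
    """Barycentric mean wavelength: Σ λ·I(λ) / Σ I(λ)."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    total = intensities.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum has no barycentre")
    return float((wavelengths * intensities).sum() / total)


def bcm_curve(series: SpectralSeries) -> tuple[np.ndarray, np.ndarray]:
    """λ_bcm at every temperature of a spectral series."""
    values = np.array([bcm(series.wavelengths, row) for row in series.intensities])
    return series.temperatures, values


@dataclass(frozen=True)
class TwoStateFit:
    """Two-state van't Hoff melting fit (temperatures in °C)."""

    t_m: float
    vanthoff_dH: float  # kJ/mol
    native_intercept: float
    native_slope: float
    unfolded_intercept: float
    unfolded_slope: float
    residual_norm: float
    temperatures: np.ndarray = field(repr=False, default=None)
    fraction_unfolded: np.ndarray = field(repr=False, default=None)


def _fraction_unfolded(t_celsius: np.ndarray, t_m: float, dH: float) -> np.ndarray:
    t_k = np.asarray(t_celsius, dtype=float) + _C_TO_K
    tm_k = t_m + _C_TO_K
    return 1.0 / (1.0 + np.exp((dH / GAS_CONSTANT_KJ) * (1.0 / t_k - 1.0 / tm_k)))


def _two_state_model(t, t_m, dH, a_n, b_n, a_u, b_u):
    f = _fraction_unfolded(t, t_m, dH)
    return (1.0 - f) * (a_n + b_n * t) + f * (a_u + b_u * t)


def fit_two_state(temperatures: np.ndarray, bcm_values: np.ndarray) -> TwoStateFit:
    """Fit λ_bcm(T) to a two-state transition with linear baselines.

    Model: λ(T) = (1−f)·(a_N + b_N·T) + f·(a_U + b_U·T) with the van't Hoff
    unfolded fraction f(T) = 1 / (1 + exp[(ΔH/R)(1/T − 1/T_m)]), T in Kelvin.
    The T_m initial guess is the temperature of steepest signal change; the
    fitted T_m must lie inside the measured range.
    """
    t = np.asarray(temperatures, dtype=float)
    y = np.asarray(bcm_values, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 temperature points across the transition")
    if np.ptp(y) < 1e-9:
        raise ValueError("flat melting curve: no transition to fit")
    slope = np.gradient(y, t)
    t_m0 = float(t[np.argmax(np.abs(slope))])
    n_edge = max(3, len(t) // 6)
    b_n0, a_n0 = np.polyfit(t[:n_edge], y[:n_edge], 1)
    b_u0, a_u0 = np.polyfit(t[-n_edge:], y[-n_edge:], 1)
    p0 = [t_m0, 300.0, a_n0, b_n0, a_u0, b_u0]
    lower = [t[0], 1.0, -np.inf, -np.inf, -np.inf, -np.inf]
    upper = [t[-1], 1e4, np.inf, np.inf, np.inf, np.inf]
    try:
        popt, _ = optimize.curve_fit(_two_state_model, t, y, p0=p0,
                                     bounds=(lower, upper), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"two-state fit did not converge: {exc}") from exc
    resid = y - _two_state_model(t, *popt)
    frac = _fraction_unfolded(t, popt[0], popt[1])
    return TwoStateFit(
        t_m=float(popt[0]),
        vanthoff_dH=float(popt[1]),
        native_intercept=float(popt[2]),
        native_slope=float(popt[3]),
        unfolded_intercept=float(popt[4]),
        unfolded_slope=float(popt[5]),
        residual_norm=float(np.linalg.norm(resid)),
        temperatures=t,
        fraction_unfolded=frac,
    )


# ---------------------------------------------------------------------------
# Initial rates and Michaelis–Menten kinetics

def initial_rate(
    times: np.ndarray,
    product: np.ndarray,
    max_conversion: float | None = None,
    min_points: int = 3,
) -> float:
    """Slope of the early, linear part of a progress curve.

    ``max_conversion`` keeps only points with product below that level
    (e.g. 10% of the donor concentration); at least ``min_points`` points
    are always retained.
    """
    times = np.asarray(times, dtype=float)
    product = np.asarray(product, dtype=float)
    if max_conversion is not None:
        keep = product <= max_conversion
        if keep.sum() < min_points:
            keep = np.zeros_like(keep)
            keep[:min_points] = True
        times, product = times[keep], product[keep]
    if len(times) < min_points:
        raise ValueError(f"need at least {min_points} points in the linear window")
    res = stats.linregress(times, product)
    return float(res.slope)


@dataclass(frozen=True)
class MichaelisMentenFit:
    k_m: float        # mM
    v_max: float      # rate units of the input
    k_cat: float      # 1/s
    stderr_km: float
    stderr_vmax: float

    def __post_init__(self):
        if self.k_m <= 0 or self.v_max <= 0:
            raise ValueError("Michaelis–Menten parameters must be positive")

    def rate_at(self, s_mM: float) -> float:
        return self.v_max * s_mM / (self.k_m + s_mM)


def fit_mm(
    substrate_mM: np.ndarray,
    rates: np.ndarray,
    enzyme_conc_mg_ml: float | None = None,
    enzyme_molar_mass_g_mol: float | None = None,
    enzyme_molar_M: float | None = None,
    rate_to_per_second: float = 1.0,
) -> MichaelisMentenFit:
    """Non-linear least-squares fit of v = V_max·S / (K_m + S).

    k_cat needs the molar enzyme concentration: give it directly
    (``enzyme_molar_M``) or as mg/mL plus molar mass.  ``rate_to_per_second``
    converts the rate units of the input (e.g. mM/min -> mM/s is 1/60) so
    that k_cat comes out in 1/s; rates in concentration/s with matching
    concentration units need no factor.  The K_m initial guess is the
    substrate level closest to half the maximum observed rate.
    """
    s = np.asarray(substrate_mM, dtype=float)
    v = np.asarray(rates, dtype=float)
    if len(s) < 4:
        raise ValueError("need at least 4 substrate levels")
    if np.any(v <= 0) or np.any(s <= 0):
        raise ValueError("substrate levels and rates must be positive")
    v_max0 = float(v.max())
    k_m0 = float(s[np.argmin(np.abs(v - v_max0 / 2))])
    try:
        popt, pcov = optimize.curve_fit(
            lambda ss, vm, km: vm * ss / (km + ss), s, v,
            p0=[v_max0, k_m0], bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis–Menten fit did not converge: {exc}") from exc
    v_max, k_m = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov))
    if enzyme_molar_M is None and enzyme_conc_mg_ml is not None:
        if not enzyme_molar_mass_g_mol:
            raise ValueError("molar mass required to convert mg/mL to molar")
        enzyme_molar_M = enzyme_conc_mg_ml / enzyme_molar_mass_g_mol  # g/L / (g/mol) = M
    if enzyme_molar_M:
        v_max_M_per_s = (v_max * rate_to_per_second) / 1000.0  # mM -> M
        k_cat = v_max_M_per_s / enzyme_molar_M
    else:
        k_cat = float("nan")
    return MichaelisMentenFit(k_m, v_max, k_cat, float(perr[1]), float(perr[0]))


def catalytic_efficiency(k_cat_per_s: float, k_m_mM: float) -> float:
    """k_cat / K_m in s⁻¹·M⁻¹ (K_m converted from mM to M)."""
    if k_cat_per_s <= 0 or k_m_mM <= 0:
        raise ValueError("k_cat and K_m must be positive")
    return k_cat_per_s / (k_m_mM / 1000.0)


def fold_change(value: float, reference: float) -> float:
    """value / reference (report to one decimal for tables)."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return value / reference
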