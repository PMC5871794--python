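"""First-order mutarotation kinetics and Arrhenius crossover analysis.

The integral intensity of an isomer marker band decays as

    I(t) = A * exp(-k t) + C

during mutarotation toward equilibrium; ``C`` is the model estimate of the
equilibrium intensity I_eq.  Rate constants across temperature follow an
Arrhenius law k = k0 * exp(-Ea/(R T)); a kink in ln k vs 1/T indicates two
activation-energy regimes, resolved by a continuous two-segment fit whose
breakpoint is the kinetic crossover temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .bands import SegmentedFit, segmented_linear_fit
from .dielectric import R_GAS


@dataclass
class KineticsTrace:
    """Marker-band integral intensity vs time at one temperature."""

    temperature: float          # K
    time: np.ndarray            # s, strictly increasing, >= 0
    intensity: np.ndarray       # integral intensity

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.size < 8:
            raise ValueError("kinetics trace needs at least 8 points")
        if self.time[0] < 0 or np.any(np.diff(self.time) <= 0):
            raise ValueError("times must start >= 0 and strictly increase")


@dataclass
class FirstOrderFit:
    A: float
    k: float                    # 1/s
    C: float
    I_eq: float                 # equals the fitted C
    residual: float
    k_stderr: float
    flags: list[str] = field(default_factory=list)


@dataclass
class RateArrheniusFit:
    k0: float                   # pre-exponential, 1/s
    ea_kj_mol: float
    residual: float
    anti_arrhenius: bool = False

    def k(self, T):
        T = np.asarray(T, dtype=float)
        return self.k0 * np.exp(-1e3 * self.ea_kj_mol / (R_GAS * T))


@dataclass
class CrossoverFit:
    Tc: float
    ea_below_kj_mol: float
    ea_above_kj_mol: float
    branch_below: RateArrheniusFit
    branch_above: RateArrheniusFit
    segmented: SegmentedFit
    significant: bool
    success: bool = True
    message: str = ""


# ---------------------------------------------------------------------------

def fit_first_order(trace: KineticsTrace) -> FirstOrderFit:
    """Nonlinear least squares of I = A exp(-k t) + C.

    The equilibrium intensity I_eq is reported as the fitted C (the model
    estimate of the plateau).  Flags mark truncated traces
    (t_max * k < 2) and non-monotone behaviour beyond the noise level;
    an amplitude indistinguishable from zero is an error.
    """
    t, I = trace.time, trace.intensity
    n_tail = max(3, len(I) // 10)
    C0 = float(np.mean(I[-n_tail:]))
    A0 = float(I[0] - C0)
    spread = float(np.ptp(I))
    # rough noise scale from second differences
    noise = float(np.std(np.diff(I, 2)) / np.sqrt(6.0)) if len(I) > 4 else 0.0
    if abs(A0) < max(5.0 * noise, 1e-12 * max(abs(C0), 1.0)):
        raise ValueError("amplitude indistinguishable from zero; "
                         "trace carries no kinetic signal")
    # seed k from the early log-linear decay
    early = I[: max(len(I) // 3, 4)]
    te = t[: len(early)]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (early - C0) / A0
        ok = z > 1e-3
    if ok.sum() >= 2:
        k0 = max(-np.polyfit(te[ok], np.log(z[ok]), 1)[0], 1e-12)
    else:
        k0 = 1.0 / max(t[-1], 1.0)

    def model(t, A, k, C):
        return A * np.exp(-k * t) + C

    popt, pcov = curve_fit(model, t, I, p0=[A0, k0, C0],
                           bounds=([-np.inf, 1e-15, -np.inf],
                                   [np.inf, np.inf, np.inf]),
                           maxfev=20000)
    A, k, C = (float(v) for v in popt)
    resid = I - model(t, *popt)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    k_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan

    flags: list[str] = []
    if t[-1] * k < 2.0:
        flags.append("truncated: trace spans < 2 characteristic times")
    # non-kinetic (non-monotone) traces: fitted decay must explain the data
    if spread > 0 and rms > 0.25 * spread:
        flags.append("non-kinetic: residuals large relative to signal")
        warnings.warn("trace poorly described by first-order decay",
                      stacklevel=2)
    return FirstOrderFit(A=A, k=k, C=C, I_eq=C, residual=rms,
                         k_stderr=k_se, flags=flags)


def linearized_check(trace: KineticsTrace, fit: FirstOrderFit,
                     min_ratio: float | None = None):
    """Linearization diagnostic of first-order character.

    Regresses ln[(I - I_eq)/A] on time; for an exact exponential the slope
    is -k and R^2 = 1.  Points where the ratio drops below ``min_ratio``
    (plateau noise, where the logarithm is noise-dominated) are excluded
    and counted.  The default floor is noise-aware:
    max(1e-3, 3 * residual RMS / |A|).
    """
    if min_ratio is None:
        floor = 3.0 * fit.residual / abs(fit.A) if np.isfinite(fit.residual) \
            else 0.0
        min_ratio = max(1e-3, floor)
    ratio = (trace.intensity - fit.I_eq) / fit.A
    keep = ratio > min_ratio
    n_excluded = int((~keep).sum())
    if keep.sum() < 5:
        raise ValueError("fewer than 5 usable points for linearization")
    x = trace.time[keep]
    y = np.log(ratio[keep])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2), n_excluded


def make_rate_table(fits: dict[float, FirstOrderFit]) -> pd.DataFrame:
    """Assemble a RateTable (temperature_K, k_per_s, k_stderr) DataFrame."""
    rows = [{"temperature_K": T, "k_per_s": f.k, "k_stderr": f.k_stderr}
            for T, f in sorted(fits.items())]
    return pd.DataFrame(rows)


def fit_rate_arrhenius(rates: pd.DataFrame) -> RateArrheniusFit:
    """Arrhenius fit of ln k vs 1/T; Ea = -slope * R, in kJ/mol.

    Weighted by the rate standard errors when present.  Rates decreasing
    with temperature yield a negative Ea with the ``anti_arrhenius`` flag.
    """
    T = np.asarray(rates["temperature_K"], dtype=float)
    k = np.asarray(rates["k_per_s"], dtype=float)
    if len(T) < 3:
        raise ValueError(f"need >= 3 temperatures, got {len(T)}")
    x = 1.0 / T
    y = np.log(k)
    w = None
    if "k_stderr" in rates and np.all(np.isfinite(rates["k_stderr"])) \
            and np.all(np.asarray(rates["k_stderr"]) > 0):
        sigma_ln = np.asarray(rates["k_stderr"], dtype=float) / k
        w = 1.0 / sigma_ln
    slope, intercept = np.polyfit(x, y, 1, w=w)
    rms = float(np.sqrt(np.mean((slope * x + intercept - y) ** 2)))
    ea = -slope * R_GAS / 1e3
    out = RateArrheniusFit(k0=float(np.exp(intercept)), ea_kj_mol=float(ea),
                           residual=rms)
    if ea <= 0:
        out.anti_arrhenius = True
        warnings.warn("rates decrease with temperature (anti-Arrhenius)",
                      stacklevel=2)
    return out


def fit_crossover(rates: pd.DataFrame,
                  min_points_per_side: int = 3) -> CrossoverFit:
    """Two-regime Arrhenius fit with a continuous kink.

    Runs the continuous two-segment regression in (1/T, ln k) space,
    converts the breakpoint back to temperature, and reports per-branch
    activation energies; significance against a single Arrhenius line is
    the segmented fit's F-test.  A breakpoint pinned at the candidate
    boundary is reported as a "no interior crossover" failure state.
    """
    T = np.asarray(rates["temperature_K"], dtype=float)
    k = np.asarray(rates["k_per_s"], dtype=float)
    if len(T) < 2 * min_points_per_side:
        raise ValueError("too few temperatures for a crossover fit")
    x = 1.0 / T
    y = np.log(k)
    seg = segmented_linear_fit(x, y, min_points_per_side=min_points_per_side)
    Tc = 1.0 / seg.breakpoint
    # x < breakpoint corresponds to T > Tc: left segment is the high-T branch
    ea_above = -seg.slope_left * R_GAS / 1e3
    ea_below = -seg.slope_right * R_GAS / 1e3
    branch_above = RateArrheniusFit(k0=float(np.exp(seg.intercept_left)),
                                    ea_kj_mol=float(ea_above),
                                    residual=np.nan)
    branch_below = RateArrheniusFit(k0=float(np.exp(seg.intercept_right)),
                                    ea_kj_mol=float(ea_below),
                                    residual=np.nan)
    xs = np.sort(x)
    success, message = True, ""
    interior_lo = xs[min_points_per_side - 1]
    interior_hi = xs[len(xs) - min_points_per_side]
    if not (interior_lo < seg.breakpoint < interior_hi):
        success = False
        message = "no interior crossover: breakpoint at candidate boundary"
    return CrossoverFit(Tc=float(Tc),
                        ea_below_kj_mol=float(ea_below),
                        ea_above_kj_mol=float(ea_above),
                        branch_below=branch_below,
                        branch_above=branch_above,
                        segmented=seg,
                        significant=seg.significant,
                        success=success, message=message)
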