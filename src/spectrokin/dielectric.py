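"""Dielectric relaxation analysis for supercooled sugar melts.

Broadband dielectric loss spectra are modelled as a superposition of
Havriliak–Negami (HN) relaxation processes plus a dc-conductivity term,

    eps''(omega) = sigma_dc / (eps0 * omega)
                   + sum_j  -Im[ delta_eps_j / (1 + (i omega tau_HN_j)^alpha_j)^beta_j ]

where ``alpha`` and ``beta`` are the symmetric and asymmetric broadening
shapes.  The structural (alpha) relaxation times follow a
Vogel–Fulcher–Tammann (VFT) law, the secondary (gamma) relaxation an
Arrhenius law; their intersection on the log10(tau) vs T plane defines the
dynamic crossover temperature Tc, and the glass transition Tg is the
temperature where tau_alpha reaches 100 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

#: vacuum permittivity, F/m
EPS0 = 8.8541878128e-12
#: gas constant, J/(mol K)
R_GAS = 8.314


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LossSpectrum:
    """One temperature's dielectric loss curve eps''(f)."""

    temperature: float          # K
    frequency: np.ndarray       # Hz, strictly increasing
    loss: np.ndarray            # eps'', dimensionless

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.loss = np.asarray(self.loss, dtype=float)
        if self.frequency.size < 20:
            raise ValueError("loss spectrum needs at least 20 points")
        if np.any(self.frequency <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(self.frequency) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(self.loss)):
            raise ValueError("loss values must be finite")


@dataclass
class HNParams:
    """Parameters of a single Havriliak–Negami relaxation process."""

    delta_eps: float    # dielectric strength, > 0
    tau_hn: float       # HN relaxation time, s
    shape_sym: float    # symmetric broadening alpha in (0, 1]
    shape_asym: float   # asymmetric broadening beta in (0, 1]

    def __post_init__(self) -> None:
        if self.delta_eps <= 0:
            raise ValueError("delta_eps must be > 0")
        if self.tau_hn <= 0:
            raise ValueError("tau_hn must be > 0")
        for name in ("shape_sym", "shape_asym"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class LossModelFit:
    """Result of fitting eps''(f) to HN processes + dc conductivity.

    ``processes`` are ordered by tau descending and labelled (alpha, gamma)
    by rank; processes whose fitted peak lies more than two decades outside
    the measured window are moved to ``refused``.
    """

    processes: list[HNParams]
    sigma_dc: float = 0.0
    residual: float = np.nan            # RMS of log10-loss residuals
    stderr: dict = field(default_factory=dict)
    refused: list[HNParams] = field(default_factory=list)
    success: bool = True
    message: str = ""


@dataclass
class VFTParams:
    """Vogel–Fulcher–Tammann law tau(T) = tau_inf * exp(D_T*T0/(T-T0))."""

    tau_inf: float      # s
    D_T: float          # strength parameter, dimensionless
    T0: float           # Vogel temperature, K
    residual: float = np.nan
    success: bool = True

    def tau(self, T):
        T = np.asarray(T, dtype=float)
        return self.tau_inf * np.exp(self.D_T * self.T0 / (T - self.T0))

    def log10_tau(self, T):
        T = np.asarray(T, dtype=float)
        return (np.log10(self.tau_inf)
                + self.D_T * self.T0 / (np.log(10.0) * (T - self.T0)))


@dataclass
class TauArrheniusParams:
    """Arrhenius law for a relaxation time, tau = tau_inf * exp(Ea/(R*T)).

    ``ea_kj_mol`` is the activation energy in kJ/mol (R = 8.314 J/(mol K)).
    """

    tau_inf: float
    ea_kj_mol: float
    residual: float = np.nan
    success: bool = True
    anti_arrhenius: bool = False

    def tau(self, T):
        T = np.asarray(T, dtype=float)
        return self.tau_inf * np.exp(1e3 * self.ea_kj_mol / (R_GAS * T))

    def log10_tau(self, T):
        return np.log10(self.tau(T))


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def hn_loss_single(frequency, p: HNParams):
    """Dielectric loss of a single HN process at ``frequency`` (Hz)."""
    w = 2.0 * np.pi * np.asarray(frequency, dtype=float)
    z = p.delta_eps / (1.0 + (1j * w * p.tau_hn) ** p.shape_sym) ** p.shape_asym
    return -z.imag


def hn_loss(frequency, fit: LossModelFit):
    """Total loss: dc-conductivity term plus all HN processes."""
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    w = 2.0 * np.pi * f
    out = fit.sigma_dc / (EPS0 * w)
    for p in fit.processes:
        out = out + hn_loss_single(f, p)
    return out


def tau_max_from_hn(p: HNParams) -> float:
    """Convert tau_HN to the loss-peak relaxation time tau_max.

    Uses the standard conversion

        tau_max = tau_HN * sin(pi a/(2+2b))^(-1/a) * sin(pi a b/(2+2b))^(1/a)

    which places 1/tau_max at the angular frequency of the single-process
    loss maximum.  For a Debye process (a = b = 1) and for any b = 1 the
    factor collapses to one.
    """
    a, b = p.shape_sym, p.shape_asym
    s1 = np.sin(np.pi * a / (2.0 + 2.0 * b))
    s2 = np.sin(np.pi * a * b / (2.0 + 2.0 * b))
    return p.tau_hn * s1 ** (-1.0 / a) * s2 ** (1.0 / a)


# ---------------------------------------------------------------------------
# spectrum fitting
# ---------------------------------------------------------------------------

def _pack(theta, n_processes, with_dc):
    """theta -> (sigma_dc, [HNParams...]); tau parametrised as log10."""
    i = 0
    sigma_dc = 0.0
    if with_dc:
        sigma_dc = 10.0 ** theta[0]
        i = 1
    procs = []
    for _ in range(n_processes):
        de, lt, a, b = theta[i:i + 4]
        procs.append(HNParams(10.0 ** de, 10.0 ** lt, a, b))
        i += 4
    return sigma_dc, procs


def _model_log_loss(theta, f, n_processes, with_dc, fixed_loss=0.0):
    sigma_dc, procs = _pack(theta, n_processes, with_dc)
    y = sigma_dc / (EPS0 * 2.0 * np.pi * f) + fixed_loss
    for p in procs:
        y = y + hn_loss_single(f, p)
    return np.log10(np.maximum(y, 1e-300))


def _initial_guesses(s: LossSpectrum, n_processes: int, with_dc: bool):
    """Peak-pick smoothed log-loss for tau seeds; flank seeds otherwise."""
    logf = np.log10(s.frequency)
    logl = np.log10(np.maximum(s.loss, 1e-300))
    smooth = gaussian_filter1d(logl, sigma=2.0)
    idx, _ = find_peaks(smooth)
    # sort peaks by height, keep the most prominent ones
    idx = sorted(idx, key=lambda i: -smooth[i])[:n_processes]
    taus, des = [], []
    for i in sorted(idx):
        taus.append(1.0 / (2.0 * np.pi * s.frequency[i]))
        des.append(2.0 * s.loss[i])
    # processes without an in-window peak: seed just above the window
    while len(taus) < n_processes:
        taus.append(1.0 / (2.0 * np.pi * s.frequency[-1] * 10.0))
        des.append(max(2.0 * s.loss[-1], 1e-3))
    order = np.argsort(taus)[::-1]          # slowest first
    taus = [taus[i] for i in order]
    des = [des[i] for i in order]
    theta = []
    if with_dc:
        sdc = max(s.loss[0] * EPS0 * 2.0 * np.pi * s.frequency[0] * 0.5, 1e-30)
        theta.append(np.log10(sdc))
    for t, d in zip(taus, des):
        theta.extend([np.log10(max(d, 1e-6)), np.log10(t), 0.8, 0.6])
    return np.asarray(theta)


def fit_loss_spectrum(s: LossSpectrum, n_processes: int = 2,
                      with_dc: bool = True, init: LossModelFit | None = None,
                      max_restarts: int = 20, rng=None,
                      rms_target: float = 0.02,
                      fixed_processes: list[HNParams] | None = None
                      ) -> LossModelFit:
    """Fit a loss spectrum to ``n_processes`` HN terms (+ optional dc term).

    Weighted least squares on log10-loss with uniform weights in log f.
    Restarts from jittered seeds until the log-residual RMS drops below
    ``rms_target`` or ``max_restarts`` is exhausted; the best attempt is
    always returned, flagged via ``success``.

    ``fixed_processes`` are HN terms added to the model but not varied —
    e.g. a secondary process pinned to its glassy-state Arrhenius
    extrapolation while the structural process is fitted in the melt.
    """
    if np.all(s.loss <= 0) or np.any(s.loss <= 0):
        raise ValueError("loss spectrum must be strictly positive to fit")
    rng = np.random.default_rng(rng)
    f = s.frequency
    target = np.log10(s.loss)
    fixed_loss = 0.0
    if fixed_processes:
        fixed_loss = np.sum([hn_loss_single(f, p) for p in fixed_processes],
                            axis=0)

    if init is not None:
        theta0 = []
        if with_dc:
            theta0.append(np.log10(max(init.sigma_dc, 1e-30)))
        for p in init.processes:
            theta0.extend([np.log10(p.delta_eps), np.log10(p.tau_hn),
                           p.shape_sym, p.shape_asym])
        theta0 = np.asarray(theta0)
    else:
        if fixed_processes:
            # seed from the data with the pinned contribution removed
            resid_loss = np.maximum(s.loss - fixed_loss, 1e-6 * s.loss)
            s_seed = LossSpectrum(s.temperature, f, resid_loss)
        else:
            s_seed = s
        theta0 = _initial_guesses(s_seed, n_processes, with_dc)

    lo, hi = [], []
    if with_dc:
        lo.append(-30.0)
        hi.append(5.0)
    for _ in range(n_processes):
        lo.extend([-6.0, -16.0, 0.05, 0.05])
        hi.extend([6.0, 8.0, 1.0, 1.0])
    lo, hi = np.asarray(lo), np.asarray(hi)
    theta0 = np.clip(theta0, lo + 1e-9, hi - 1e-9)

    def resid(theta):
        return _model_log_loss(theta, f, n_processes, with_dc,
                               fixed_loss) - target

    best = None
    for attempt in range(max_restarts):
        t0 = theta0 if attempt == 0 else np.clip(
            theta0 + rng.normal(0.0, [0.3] * len(theta0)), lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(resid, t0, bounds=(lo, hi), method="trf",
                                x_scale="jac", max_nfev=4000)
        except Exception:       # pragma: no cover - defensive
            continue
        rms = float(np.sqrt(np.mean(res.fun ** 2)))
        if best is None or rms < best[0]:
            best = (rms, res)
        if rms < rms_target:
            break

    if best is None:
        raise RuntimeError("optimizer failed on every restart")
    rms, res = best
    sigma_dc, procs = _pack(res.x, n_processes, with_dc)

    # covariance proxy from the jacobian at the optimum
    stderr: dict = {}
    try:
        J = res.jac
        dof = max(len(res.fun) - len(res.x), 1)
        cov = np.linalg.pinv(J.T @ J) * (2.0 * res.cost / dof)
        diag = np.diag(cov)
        # a singular jacobian (parameter at a bound, degenerate process)
        # means the parameter is undetermined, not perfectly determined
        se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.inf)
        i = 1 if with_dc else 0
        for j in range(n_processes):
            stderr[f"p{j}_log10_delta_eps"] = se[i]
            stderr[f"p{j}_log10_tau"] = se[i + 1]
            stderr[f"p{j}_shape_sym"] = se[i + 2]
            stderr[f"p{j}_shape_asym"] = se[i + 3]
            i += 4
    except Exception:           # pragma: no cover
        pass

    # order by tau descending, then apply the 2-decade reporting rule
    order = np.argsort([p.tau_hn for p in procs])[::-1]
    stderr = {_relabel(k, order): v for k, v in stderr.items()}
    procs = [procs[i] for i in order]
    fmin, fmax = f[0], f[-1]
    kept, refused = [], []
    for p in procs:
        fpeak = 1.0 / (2.0 * np.pi * tau_max_from_hn(p))
        if fmin / 100.0 <= fpeak <= fmax * 100.0:
            kept.append(p)
        else:
            refused.append(p)
    success = rms < rms_target * 5
    msg = "" if success else f"residual RMS {rms:.3g} above target"
    return LossModelFit(processes=kept, sigma_dc=sigma_dc, residual=rms,
                        stderr=stderr, refused=refused, success=success,
                        message=msg)


def _relabel(key: str, order) -> str:
    if not key.startswith("p"):
        return key
    j = int(key[1])
    rank = int(np.where(np.asarray(order) == j)[0][0])
    return f"p{rank}" + key[2:]


# ---------------------------------------------------------------------------
# relaxation map and temperature laws
# ---------------------------------------------------------------------------

def fit_vft(relax_map, label: str = "alpha",
            stderr_floor: float = 0.01) -> VFTParams:
    """Fit a VFT law to the ``label`` rows of a relaxation map.

    ``relax_map`` is a DataFrame with columns ``temperature_K``, ``process``
    and ``tau_s``.  The fit is least squares in (1/T, log10 tau) space; a
    profiled linear solve over candidate T0 values seeds the nonlinear
    refinement.  When a ``log10_tau_stderr`` column is present the fit is
    inverse-variance weighted (stderr floored at ``stderr_floor`` so no
    single point dominates) — relaxation times fitted near the edge of
    the frequency window carry visibly larger uncertainties and would
    otherwise tilt the extrapolation.  Fewer than 4 points, or a T0
    estimate at or above the lowest fitted temperature, yields a failure
    state.
    """
    sub = relax_map[relax_map["process"] == label]
    T = np.asarray(sub["temperature_K"], dtype=float)
    tau = np.asarray(sub["tau_s"], dtype=float)
    if len(T) < 4:
        raise ValueError(f"need >= 4 temperatures for VFT fit, got {len(T)}")
    y = np.log10(tau)
    if "log10_tau_stderr" in sub:
        se = np.asarray(sub["log10_tau_stderr"], dtype=float)
        w = 1.0 / np.maximum(np.nan_to_num(se, nan=np.inf), stderr_floor)
    else:
        w = np.ones_like(y)
    Tmin = T.min()

    def linear_at_T0(T0):
        X = np.column_stack([np.ones_like(T), 1.0 / (T - T0)])
        coef, res, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
        ssr = float(np.sum((w * (X @ coef - y)) ** 2))
        return coef, ssr

    candidates = np.linspace(1.0, Tmin - 2.0, 200)
    ssrs = [linear_at_T0(t0)[1] for t0 in candidates]
    T0_seed = candidates[int(np.argmin(ssrs))]
    coef, _ = linear_at_T0(T0_seed)

    def resid(theta):
        lt_inf, dtt0, T0 = theta
        return w * (lt_inf + dtt0 / (np.log(10.0) * (T - T0)) - y)

    theta0 = [coef[0], coef[1] * np.log(10.0), T0_seed]
    res = least_squares(resid, theta0,
                        bounds=([-40, 1e-6, 0.0], [10, 1e6, Tmin - 1e-3]),
                        x_scale="jac", max_nfev=5000)
    lt_inf, dtt0, T0 = res.x
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    out = VFTParams(tau_inf=10.0 ** lt_inf, D_T=dtt0 / T0, T0=T0, residual=rms)
    if T0 >= Tmin:
        out.success = False
    return out


def fit_tau_arrhenius(relax_map, label: str = "gamma") -> TauArrheniusParams:
    """Arrhenius fit of ln tau vs 1/T; Ea = slope * R in kJ/mol.

    A negative slope (tau increasing with temperature) is unphysical for a
    relaxation time and is flagged via ``anti_arrhenius`` / ``success``.
    """
    sub = relax_map[relax_map["process"] == label]
    T = np.asarray(sub["temperature_K"], dtype=float)
    tau = np.asarray(sub["tau_s"], dtype=float)
    if len(T) < 3:
        raise ValueError(f"need >= 3 temperatures for Arrhenius fit, got {len(T)}")
    x = 1.0 / T
    y = np.log(tau)
    slope, intercept = np.polyfit(x, y, 1)
    rms = float(np.sqrt(np.mean((slope * x + intercept - y) ** 2)))
    ea = slope * R_GAS / 1e3
    out = TauArrheniusParams(tau_inf=float(np.exp(intercept)), ea_kj_mol=ea,
                             residual=rms)
    if ea <= 0:
        out.anti_arrhenius = True
        out.success = False
        warnings.warn("relaxation time increases with temperature "
                      "(anti-Arrhenius); flagged", stacklevel=2)
    return out


def glass_transition_temperature(v: VFTParams, tau_ref: float = 100.0) -> float:
    """Tg from a fitted VFT law: the temperature where tau = tau_ref (100 s).

    Closed form T = T0 + D_T*T0 / ln(tau_ref/tau_inf).
    """
    if tau_ref <= v.tau_inf:
        raise ValueError("tau_ref must exceed tau_inf (no solution)")
    return v.T0 + v.D_T * v.T0 / np.log(tau_ref / v.tau_inf)


def crossover_temperature(v: VFTParams, a: TauArrheniusParams,
                          bracket: tuple[float, float]) -> tuple[float, float]:
    """Intersection of the VFT (alpha) and Arrhenius (gamma) time laws.

    Returns ``(Tc, log10_tau_at_Tc)``; the root of
    log10 tau_VFT(T) - log10 tau_Arr(T) is bracketed in ``bracket``
    (tolerance 1e-3 K).  A missing sign change raises, naming both
    endpoint values.
    """
    lo, hi = bracket
    if lo <= v.T0:
        lo = v.T0 + 1e-3

    def f(T):
        return float(v.log10_tau(T) - a.log10_tau(T))

    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            "no crossover in bracket: delta log10 tau = "
            f"{flo:.4g} at {lo:.1f} K and {fhi:.4g} at {hi:.1f} K")
    Tc = brentq(f, lo, hi, xtol=1e-3)
    return float(Tc), float(v.log10_tau(Tc))
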