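"""Theoretical Raman spectra from computed vibrational modes.

Harmonic frequencies and Raman scattering activities (quantum-chemistry
outputs, consumed as tables) are converted to observable Stokes
intensities via

    I_i = 1e-12 * (nu0 - nu_i)^4 * S_i / (nu_i * B_i),
    B_i = 1 - exp(-h c nu_i / (kB T)),

where nu0 = 1e7 / lambda0[nm] is the excitation wavenumber and B_i the
Boltzmann temperature factor accounting for excited vibrational states.
Computed frequencies are scaled by an empirical harmonic-correction factor
(default 0.976) before use; line spectra are broadened to continuous
curves, and mixtures of isomer basis spectra are fitted to experimental
data by non-negative least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.special import voigt_profile

from .bands import Spectrum

#: h*c/kB in cm*K — converts a wavenumber to an equivalent temperature
HC_OVER_KB = 1.438777


@dataclass
class ComputedMode:
    """One computed normal mode: harmonic wavenumber + Raman activity."""

    frequency: float            # cm^-1, unscaled harmonic
    activity: float             # Raman scattering activity S_i, >= 0
    ir_intensity: float | None = None

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("mode frequency must be > 0")
        if self.activity < 0:
            raise ValueError("Raman activity must be >= 0")


@dataclass
class RamanConditions:
    """Excitation and temperature conditions for intensity conversion."""

    laser_wavelength: float = 532.0     # nm
    temperature: float = 298.15         # K

    def __post_init__(self) -> None:
        if self.laser_wavelength <= 0:
            raise ValueError("laser wavelength must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def nu0(self) -> float:
        """Excitation wavenumber, cm^-1 (1e7 / lambda[nm])."""
        return 1e7 / self.laser_wavelength


@dataclass
class TheoreticalSpectrum:
    wavenumber: np.ndarray
    intensity: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass
class MixtureFit:
    weights: np.ndarray
    fractions: np.ndarray
    residual: float
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------

def boltzmann_factor(nu, cond: RamanConditions):
    """Temperature factor B = 1 - exp(-h c nu / (kB T)), strictly in (0, 1)."""
    nu = np.asarray(nu, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("wavenumber must be > 0")
    return 1.0 - np.exp(-HC_OVER_KB * nu / cond.temperature)


def raman_intensity(mode: ComputedMode, cond: RamanConditions) -> float:
    """Stokes Raman intensity of one mode (arbitrary overall scale).

    I = 1e-12 * (nu0 - nu_i)^4 * S_i / (nu_i * B_i); linear in the
    scattering activity.  Modes at or above the excitation wavenumber
    (anti-Stokes side) are rejected.
    """
    nu0 = cond.nu0
    if mode.frequency >= nu0:
        raise ValueError(
            f"mode at {mode.frequency} cm^-1 not on the Stokes side of "
            f"nu0 = {nu0:.1f} cm^-1")
    B = float(boltzmann_factor(mode.frequency, cond))
    return 1e-12 * (nu0 - mode.frequency) ** 4 * mode.activity / (
        mode.frequency * B)


def scale_frequencies(modes: list[ComputedMode],
                      factor: float = 0.976) -> list[ComputedMode]:
    """Apply the empirical harmonic scale factor to mode frequencies."""
    if not 0.8 < factor < 1.05:
        raise ValueError("scale factor outside sanity interval (0.8, 1.05)")
    return [ComputedMode(frequency=m.frequency * factor, activity=m.activity,
                         ir_intensity=m.ir_intensity) for m in modes]


def broaden(modes: list[ComputedMode], cond: RamanConditions,
            shape: str = "lorentzian", fwhm: float = 8.0,
            grid=None, normalize: bool = False) -> TheoreticalSpectrum:
    """Render a line spectrum as a continuous curve.

    Each mode contributes an area-normalized Gaussian or Lorentzian of the
    given FWHM scaled by its Raman intensity, so the integrated spectrum
    equals the summed mode intensities.  ``normalize=True`` rescales to a
    unit maximum for shape comparisons.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    if not modes:
        raise ValueError("empty mode list")
    if shape not in ("gaussian", "lorentzian"):
        raise ValueError(f"unknown line shape: {shape}")
    if grid is None:
        fmin = min(m.frequency for m in modes)
        fmax = max(m.frequency for m in modes)
        grid = np.arange(max(fmin - 10 * fwhm, 1.0), fmax + 10 * fwhm, 1.0)
    grid = np.asarray(grid, dtype=float)
    y = np.zeros_like(grid)
    for m in modes:
        inten = raman_intensity(m, cond)
        if shape == "gaussian":
            sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            y += inten * voigt_profile(grid - m.frequency, sigma, 0.0)
        else:
            y += inten * voigt_profile(grid - m.frequency, 0.0, fwhm / 2.0)
    if normalize and y.max() > 0:
        y = y / y.max()
    return TheoreticalSpectrum(
        wavenumber=grid, intensity=y,
        provenance={"shape": shape, "fwhm_cm1": fwhm,
                    "laser_nm": cond.laser_wavelength,
                    "temperature_K": cond.temperature,
                    "normalized": normalize})


def fit_isomer_populations(experimental: Spectrum,
                           basis: list[TheoreticalSpectrum],
                           region: tuple[float, float],
                           normalize: bool = False) -> MixtureFit:
    """Non-negative least-squares unmixing of an experimental spectrum.

    All spectra are resampled to the experimental grid restricted to
    ``region``; weights are the NNLS solution, fractions their normalized
    values.  A relative residual above 10% flags a basis that cannot
    represent the data.
    """
    if len(basis) < 2:
        raise ValueError("need at least 2 basis spectra")
    lo, hi = region
    mask = (experimental.wavenumber >= lo) & (experimental.wavenumber <= hi)
    grid = experimental.wavenumber[mask]
    if grid.size < 2:
        raise ValueError("experimental spectrum does not cover the region")
    target = experimental.intensity[mask].astype(float)
    cols = []
    for b in basis:
        if b.wavenumber[0] > hi or b.wavenumber[-1] < lo:
            raise ValueError("basis spectrum does not overlap the region")
        cols.append(np.interp(grid, b.wavenumber, b.intensity))
    A = np.column_stack(cols)
    if not np.any(A):
        raise ValueError("all-zero basis")
    if normalize:
        scales = A.max(axis=0)
        scales[scales == 0] = 1.0
        A = A / scales
        tmax = target.max() if target.max() > 0 else 1.0
        target = target / tmax
    w, rnorm = nnls(A, target)
    tnorm = float(np.linalg.norm(target))
    rel_resid = rnorm / tnorm if tnorm > 0 else np.inf
    total = w.sum()
    fractions = w / total if total > 0 else np.zeros_like(w)
    flags = []
    if rel_resid > 0.1:
        flags.append(f"large residual ({rel_resid:.2g}): basis does not "
                     "represent the experimental spectrum")
    return MixtureFit(weights=w, fractions=fractions,
                      residual=float(rel_resid), flags=flags)
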