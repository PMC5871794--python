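# Methods

This package reconstructs, as a tested analysis chain, the spectroscopic
case for a dynamic crossover in supercooled L-sorbose and its effect on
the kinetics of mutarotation.  Because no raw spectra are deposited for
this system, the chain runs on synthetic data whose generative truth is
calibrated to the published headline values; every analysis stage is
exercised end to end against that truth.

## Dielectric relaxation mapping

Loss spectra ε″(f) are modelled as

    ε″(ω) = σ_dc/(ε0 ω) + Σ_j −Im[ Δε_j / (1 + (iωτ_HN,j)^α_j)^β_j ]

with Havriliak–Negami shape parameters α (symmetric) and β (asymmetric)
in (0, 1].  The static permittivity offset ε∞ belongs to the real part
and is excluded from the loss.  Fits run on log10 ε″ with uniform
weighting in log f, bounded trust-region least squares, peak-picked
initialization and jittered restarts.  Per-process loss-peak times come
from the standard conversion

    τ_max = τ_HN · sin(πα/(2+2β))^(−1/α) · sin(παβ/(2+2β))^(1/α).

Fitted processes whose peak lies more than two decades outside the
measured window (10⁻²–10⁶ Hz) are refused; surviving rows additionally
need a log10 τ standard-error proxy below 0.15, because flank-limited
fits are nearly scale/time degenerate and their covariance blows up by
one to two orders of magnitude exactly when the estimate is meaningless.

The stage protocol follows standard practice for systems whose secondary
process exits the window above the glass transition: the γ relaxation is
fitted in the glassy state, where its peak is in-window, giving the γ
Arrhenius law (Ea = slope·R with R = 8.314 J mol⁻¹ K⁻¹); in the melt the
γ contribution is pinned to that law's extrapolation and only the α
process and the dc term are fitted.  An unconstrained two-process fit in
the melt is not identifiable — the γ flank is a near power law whose
amplitude and time trade off freely — and measurably corrupts the α
parameters.

The α branch is fitted with the VFT law τ(T) = τ∞·exp(D_T·T0/(T−T0)) in
(1/T, log10 τ) space, inverse-variance weighted by the per-row stderr
(floored at 0.01 decades so no point dominates).  Weighting matters:
edge-of-window α times carry ~10–30× larger uncertainty, and unweighted
fits occasionally tilt the extrapolated crossover by more than 10 K.
Tg is the closed-form solution of τ(Tg) = 100 s,

    Tg = T0 + D_T·T0 / ln(τ_ref/τ∞),

and the crossover Tc is the bracketed root (Brent, 10⁻³ K) of
log10 τ_VFT(T) − log10 τ_Arr(T) in (Tg+10, Tg+150) K.

## Band analysis

Vibrational bands are deconvolved as area-scaled Voigt profiles
(`scipy.special.voigt_profile`) over a linear per-window baseline.
Integral intensity is the fitted Voigt area, so overlapping bands
separate cleanly; a raw-trapezoid mode exists for cross-checks.  Voigt
FWHM uses the Olivero–Longbothum approximation (relative error < 0.02%).
Bands whose fitted area falls below three standard errors are flagged as
consistent with zero.

Temperature trends of position/area are tested for a kink with a
continuous two-segment linear fit: the breakpoint is grid-searched over
midpoints of consecutive abscissae (≥ 3 points per side) and refined by
bounded scalar minimization; significance against a single line is an
F-test with 2 extra parameters at level 0.05.  A single line fitting to
machine precision short-circuits the F-test (it would otherwise fire on
rounding noise).  Trend fits stop at 410 K, below the caramelization
regime; the generator supports an optional second kink there but no
dedicated analysis is attached.

Difference spectra are computed after linear resampling onto the first
spectrum's grid restricted to the OH region (3000–3600 cm⁻¹ default),
Δ_i = s_i − s_1 ("/" in series notation is enumeration, not division; a
ratio mode exists behind a flag).  Signed extrema are located with a
prominence threshold of 5% of max |Δ|.

## Mutarotation kinetics

Marker-band areas follow I(t) = A·exp(−kt) + C; the equilibrium
intensity I_eq is reported as the fitted C, the model estimate of the
plateau.  The linearization diagnostic regresses ln[(I−I_eq)/A] on time
(slope −k for a first-order process; the decaying convention keeps the
argument positive).  Points within max(10⁻³, 3·RMS/|A|) of the plateau
are excluded — their logarithm is noise — and the exclusion count is
reported.  Rate constants across temperature are fitted as
k = k0·exp(−Ea/RT) (ln k vs 1/T, weighted by rate stderr); rates
decreasing with temperature are flagged anti-Arrhenius rather than
silently sign-flipped.  The crossover fit reuses the continuous
two-segment regression in (1/T, ln k); the breakpoint maps to Tc and the
segment slopes to the two activation energies, with the same F-test
significance flag.

## Theoretical Raman spectra

Computed modes (wavenumber + Raman scattering activity, consumed as CSV
tables; quantum-chemistry runs themselves are out of scope) are
converted to Stokes intensities by

    I_i = 10⁻¹² (ν0 − ν_i)⁴ S_i / (ν_i B_i),   B_i = 1 − exp(−hcν_i/kT),

with ν0 = 10⁷/λ0[nm] (532 nm default) and hc/k = 1.438777 cm·K.  The
10⁻¹² prefactor is an arbitrary overall scale; intensities are relative.
Frequencies are scaled by 0.976 before the (ν0−ν)⁴ factor — the scaled
frequency is the physical prediction.  Broadening uses area-normalized
Lorentzians (FWHM 8 cm⁻¹ default, Gaussian optional); isomer populations
are recovered by non-negative least squares on a common grid, with
fractions normalized to unit sum.  The per-isomer mode tables shipped in
`synthetic_mode_tables` are synthetic stand-ins built on the isomers'
fingerprint band positions; their activities are invented but fixed.

## Synthetic scenario: what it emulates

`paper_scenario` encodes the study conditions as analytic truth:

* α relaxation: VFT with τ∞ = 10⁻¹⁴ s (typical phonon prefactor); T0 ≈
  260.3 K and D_T ≈ 4.63 solve τ(293 K) = 100 s and log10 τ(365 K) = −9.
* γ relaxation: Arrhenius, Ea = 45.6 kJ/mol, prefactor ≈ 3.0·10⁻¹⁶ s
  anchored at τ(365 K) = 10⁻⁹ s, so both laws intersect at Tc = 365 K.
* HN shapes (0.85, 0.6) for α and (0.75, 1.0) for γ, Δε 20 and 1.5,
  constant in temperature; dc amplitude tied to 1/τ_α in the melt so the
  conductivity wing sits ~2 decades below each α peak.
* Dielectric grids: 203–263 K (glass, γ peak in-window) and 303–453 K
  (melt, 10 K steps) on 10⁻²–10⁶ Hz at 10 points/decade.  The truth
  itself dictates this split: with τ_γ(365 K) = 10⁻⁹ s the γ peak leaves
  the measured window above ~270 K, so γ is measurable only in the
  glass, as in the real experiment.  Temperatures where no process has
  τ inside [1/(2π f_max·10³), 10³/(2π f_min)] are rejected with warning
  records (423–453 K under the defaults).
* Band trends: CCO markers at 815 and 885 cm⁻¹ drifting to lower
  wavenumber with slopes steepening at 365 K (−0.05 → −0.20 cm⁻¹/K for
  the 815 band); OH stretch at 3375 cm⁻¹ drifting upward (+0.4 → +0.9
  cm⁻¹/K, ~100 cm⁻¹ over the full range); intensities decline with
  matching kinks.  The VFT/Arrhenius truths describe loss-peak times, so
  the generator back-converts them to τ_HN through the shape factor.
* Kinetics: two-branch Arrhenius continuous at 365 K with Ea = 57.5 and
  184.5 kJ/mol (midpoints of the reported 53–62 and 177–192 kJ/mol
  ranges) and k(365 K) = 10⁻³ s⁻¹ so traces equilibrate on desk-scale
  horizons.  Marker pair: β at 815 cm⁻¹ decaying, α at 876 cm⁻¹ growing,
  areas summing to a constant.  Sampling is adaptive (horizon 6/k(T), 80
  points), which honours "horizon ≥ 3 characteristic times" at every
  temperature across the ~80× range in k.
* OH rearrangement during reaction above Tc: population transfer from an
  H-bonded sub-band at 3334 cm⁻¹ to one +144 cm⁻¹ higher, sub-band FWHM
  ~80 cm⁻¹ so difference spectra resolve the two lobes at the band
  positions.
* Noise: multiplicative Gaussian, σ_rel = 1% (additive available); one
  RNG stream per generated file keyed by (seed, stage, temperature), so
  any subset regenerates bit-identically.

What the generator does **not** emulate: instrument baselines and drift,
detector nonlinearity, temperature-dependent HN shapes and Δε, the
excess-wing β process, caramelization chemistry, anharmonic mode
couplings, and correlated (non-white) noise.  Passing recovery tests
therefore demonstrates that the estimators are correct and well
conditioned under the stated statistical structure — not that they are
robust to every artefact of real instruments.

## Problem sizes and numerical choices

The recovery experiments use 5 seeds × 19 dielectric spectra, 10 seeds ×
11 kinetic traces, and one 10-point band trend — sizes chosen so the
whole chain, including the acceptance script, completes in minutes on
one CPU while leaving the stochastic tolerances comfortably resolved.
Fit tolerances and restart policies: HN fits restart up to 20× (5× in
the batch stage) with log-normal jitter and stop early below RMS 0.02 in
log10; band fits jitter centers; first-order fits seed k from the early
log-linear decay; the segmented-fit breakpoint refines to 10⁻⁶ of the
x-range.  Degenerate inputs (all-zero spectra, constant traces,
both-zero Voigt widths, anti-Stokes modes) raise errors rather than
returning numbers.

## Known limitations

* The α branch of the relaxation map spans only ~30 K (303–333 K) before
  the peak leaves the window, so Tc rests on a genuine extrapolation —
  exactly as in the underlying experiment — and inherits its variance
  (±1–2 K per replicate at 1% noise, seed-averaged in the reports).
* The γ pinning transfers the glassy Arrhenius law into the melt; if a
  real system's secondary process changed strength or shape above Tg,
  that assumption would bias the α fits.
* The stderr quality gate uses a pseudo-inverse covariance proxy; it
  separates determined from degenerate fits by orders of magnitude but
  is not a calibrated confidence interval.
* Mixture unmixing assumes the basis spans the experimental spectrum up
  to white noise; structured residuals (unmodelled bands) are only
  flagged, not decomposed.
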