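# spectrokin

Spectroscopic inference of the dynamic crossover and mutarotation
kinetics in supercooled L-sorbose.

## The problem

When a melted sugar is supercooled, its ring isomers keep
interconverting (mutarotation, here β → α in L-sorbose) while the
liquid's own dynamics slow toward the glass transition.  Around
T ≈ 1.2 Tg the structural (α) and secondary (γ) relaxations merge — the
dynamic crossover Tc — and the mutarotation rate constant was reported
to change its activation energy abruptly at the same temperature, from
~53–62 to ~177–192 kJ/mol.  Establishing that coincidence takes three
independent spectroscopic analyses:

1. **Dielectric relaxation mapping** — loss spectra are fitted to
   Havriliak–Negami processes plus a dc-conductivity term,

       ε″(ω) = σ_dc/(ε0ω) + Σ −Im[Δε/(1 + (iωτ_HN)^α)^β],

   relaxation times are mapped against temperature, the α branch is
   fitted with VFT, τ(T) = τ∞·exp(D_T·T0/(T−T0)), the γ branch with an
   Arrhenius law; Tg is defined by τ_α = 100 s and Tc by the
   intersection of the two time laws.
2. **Vibrational band trends** — FTIR bands are deconvolved with Voigt
   profiles; kinks in position/intensity vs temperature are located by
   continuous two-segment regression with an F-test.
3. **Mutarotation kinetics** — isomer marker-band areas follow
   I(t) = A·e^(−kt) + C; ln k vs 1/T is fitted with a continuous
   two-branch Arrhenius law whose breakpoint is the kinetic crossover.

A fourth stage converts computed Raman activities into theoretical
spectra, I ∝ (ν0−ν)⁴·S/(ν·B) with the Boltzmann factor
B = 1 − e^(−hcν/kT), and unmixes isomer populations by non-negative
least squares.

No raw spectra are deposited for this system, so the package ships a
first-class synthetic-data module whose generative truth is calibrated
to the published values (Tg = 293 K, Tc = 365 K, log10 τ(Tc) = −9,
Ea_γ = 45.6 kJ/mol, kinetic branch energies 57.5/184.5 kJ/mol); every
stage is validated by recovering that truth from noisy data.  The
package is aimed at physical chemists analysing broadband dielectric
and FTIR/Raman data of supercooled molecular liquids — the stages are
generic even though the calibration is specific.

## Worked example

The numbered drivers under `analysis/` run the whole study on a
generated experiment:

```
$ python analysis/01_simulate.py --seed 1
wrote synthetic experiment to results/synthetic
truth: Tg = 293.0 K, Tc = 365.0 K, log10 tau(Tc) = -9.00, Ea_gamma = 45.6 kJ/mol

$ python analysis/02_dielectric_maps.py
fitting 19 loss spectra (203-413 K)
Tg = 293.0 K (tau_alpha = 100 s)
Ea_gamma = 45.60 kJ/mol
Tc = 365.1 K at log10 tau = -9.00

$ python analysis/03_band_trends.py
position kink at 365.1 K (significant: True, p = 1.66e-14)
slopes: -0.050 -> -0.201 cm^-1/K

$ python analysis/04_mutarotation_kinetics.py
kinetic crossover at Tc = 365.2 K (significant: True)
Ea below/above: 57.6 / 186.6 kJ/mol

$ python analysis/06_full_report.py
crossover estimates (dielectric, bands, kinetics): 365.1 K, 365.1 K, 365.2 K
spread: 0.1 K -> coincide: True
overall: PASS
```

Reading: the three independent routes to the crossover — extrapolated
relaxation-time intersection, vibrational band-trend kink, and the kink
in log k of the reaction — land on the same temperature within a
fraction of a kelvin on this synthetic replicate, which is the study's
central claim; the recovered activation energies bracket the change from
the ~57 kJ/mol regime below Tc to the ~185 kJ/mol regime above it.
`analysis/05_raman_theory.py` adds the isomer-population readout
(fractions recovered to ±0.001 at 1% noise on a 4-isomer basis).

The same machinery is scriptable through a CLI
(`spectrokin simulate|dielectric|bands|kinetics|ramancalc|mixture|full|score`)
and, primarily, as a library — see `spectrokin.pipeline` for the stage
entry points and `spectrokin.experiments` for the seed-replicated
recovery experiments.

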