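# Methods

This note records the models implemented in `phipchip`, their assumptions,
the defaults that matter, and what the synthetic data do and do not emulate.

## The system being modelled

A lab-on-a-chip device produces a hyperpolarized, 13C-labelled metabolite
(fumarate) continuously: parahydrogen diffuses from pressurized gas channels
through a PDMS membrane into a liquid stream carrying an acetylene
dicarboxylate precursor and a Ru catalyst; trans-hydrogenation installs the
two parahydrogen protons as a nuclear singlet pair; in the detection chamber a
pulse sequence converts that singlet order into observable 13C magnetization,
which is quantified against thermal references. The package models each stage
at desk scale: a 1-D reaction–transport model of the chip, an exact
density-matrix simulation of the three-spin product, and the quantification
arithmetic.

## Chip geometry (`geometry`)

A chip is an ordered list of straight channel segments (length, width, depth,
membrane-contact width, effective membrane thickness, number of gas-contact
sides) plus a well-mixed detection chamber. Two named fixtures are shipped:

* `beta_chip()` — fluid path flanked by gas channels on both sides
  (`n_gas_sides = 2`), 18 mm × 0.5 mm × 0.5 mm path (4.5 µL), 2.5 µL chamber,
  7.0 µL total;
* `alpha_chip()` — the earlier one-sided layout, path shorter by the factor
  1.3 (the two-sided design extended the membrane path by ~30%), same
  cross-section and chamber.

The published record fixes only aggregates (7 µL total, 2.5 µL chamber,
two-sided vs one-sided, ~30% longer path); the cross-section (0.5 mm square,
matching the 0.5 mm middle device layer) and the single-segment idealisation
are this package's choices, and every dimension can be overridden through a
TOML geometry file. Residence times assume plug flow; dispersion is absorbed
into the mass-transfer coefficient below.

## Membrane uptake and kinetics (`transport`)

The steady-state dissolved-H2 balance along the path is reduced to

    dc/dt = kLa(x) (c_sat − c) − r(c, …),   t = residence-time coordinate,

with Henry's law `c_sat = H · p(H2)` and a series-resistance volumetric
mass-transfer coefficient per segment,

    kLa = [ L_m/(D_m K_m) + d_f/D_l ]⁻¹ · (w_contact · n_sides)/(w · d).

Defaults (all overridable, provenance in `constants.py`): H = 3.96 mM/bar
(H2 in methanol, 298 K), D_l = 5×10⁻⁹ m²/s, D_m = 1.4×10⁻⁸ m²/s (H2 in PDMS),
K_m = 0.5, effective membrane path 0.5 mm.

**Calibration.** The one free parameter is the liquid-film depth `d_f`. It is
fixed once by requiring the two-sided chip effluent to reach 97.5% of
saturation at 2 µL/min and 5 bar — the flow rate at which the measured
effluent is experimentally indistinguishable from saturated ("fully
saturated" within typical spectral noise) — and then frozen for every other
prediction, including the one-sided chip. With the shipped fixtures the
calibrated depth is 0.375 mm, comfortably inside the 0.5 mm channel depth.
Without reaction the per-segment balance is linear, so segments are
propagated with their exact exponential solution (A-stable, no overshoot, and
identical to the closed form the tests check against); a membrane-free
well-mixed chamber passes the inlet concentration through at steady state.

Known, deliberately preserved deficiency: like the original full simulation,
the reduced model overestimates uptake at high flow rates (membrane
deformation is not modelled); no correction is applied.

**Kinetics.** Hydrogenation is modelled with first-order catalyst activation
and rate laws bilinear in substrate/product and dissolved H2:

    d[cat*]/dt = k_act ([cat]_tot − [cat*])
    d[A]/dt = −k_hyd [cat*][A][H2]
    d[P]/dt = +k_hyd [cat*][A][H2] − k_over [cat*][P][H2]
    d[X]/dt = +k_over [cat*][P][H2]

with one H2 consumed per event, integrated per segment with LSODA
(rtol 1e-8, atol 1e-9 mM); the chamber steady state solves the well-mixed
tank balance. The carbon skeleton [A]+[P]+[X] is conserved by construction.
The original rate constants are not public; two named defaults are shipped:
`propargyl_kinetics()` (room temperature, the regime of the what-if
scenarios: the hydrogenation capacity is about twice the membrane supply
capacity at the comparison point, i.e. H2-supply-limited) and
`fumarate_kinetics()` (58 °C chamber, k_hyd scaled ~8× ≈ ×2 per 10 °C).
In this supply-limited regime the scenario comparison reproduces the expected
ordering of design levers: doubling H2 pressure (×1.9 yield) beats doubling
all rate constants (×1.2) beats 10× faster activation (×1.01). Note that
with activation independent of [H2] the model is linear in the H2 scale, so a
pressure doubling can give at most a twofold yield gain; a larger gain would
require H2-dependent activation, which this rate law intentionally omits.

## Spin dynamics (`spin`)

The product is treated as three spins (Ha, Hb, 13C) in the Zeeman product
basis, each isotope in its own rotating frame: offsets enter as 2πν Iz,
homonuclear couplings keep the full scalar form (strong coupling), and
heteronuclear couplings are truncated to their secular 2πJ Iz Sz part.
Propagation is exact (eigendecomposition of the 8×8 Hamiltonian); pulses are
ideal zero-duration rotations (the probe's finite 12.5 kHz nutation is
metadata only).

The bundled J network for the labelled fumarate dianion is J_HH = 15.9 Hz,
J(C–Ha) = 3.2 Hz, J(C–Hb) = 6.8 Hz. The proton pair is chemically
equivalent; the ~3.6 Hz difference of the carbon couplings is the symmetry
breaking the transfer sequence exploits. The numerical values are
transcriptions within the literature ranges for this molecule, fixed by
requiring the simulated sequence optimum below to match the published
operating point (τ = 15.7 ms at n1 = n2 = 7).

**Transfer sequence.** The purge + singlet-to-heteronuclear-magnetization
sequence is implemented as

    90x(1H) — [τ 180x(13C) τ]×n1 — τ — 90x(13C) — [τ 180x(13C) τ]×n2 — 90y(13C)

The echo spacing 2τ is matched to the singlet–triplet splitting
(τ ≈ 1/(4 J_HH)): each 13C π pulse flips the sign of the
coupling-difference term, which then resonantly drives |S0⟩→|T0⟩ coherence
correlated with the carbon state; the junction 90° converts it to a
transverse-carbon form, the second train rephases it into net carbon
magnetization, and the final 90°, phase-shifted by 90°, stores it along +z.
Two layout details matter and were fixed by simulation: the junction pulse
must come a full echo period after the last refocusing pulse, and the final
pulse must be 90°-shifted relative to the junction pulse — otherwise the
efficiency maximum splits into two lobes displaced ±0.85 ms from resonance.
With the shipped couplings the grid optimum is τ = 15.7 ms at n1 = n2 = 7
with efficiency 0.99 (normalized so 1 = complete conversion of singlet order
into carbon polarization, i.e. 2⟨Iz(13C)⟩ from a pure singlet).

**Singlet–triplet mixing.** The catalyst-hydride pathway that leaks singlet
into |T0⟩ is modelled as optional coherent evolution of the pair under a
chemical-shift-difference Hamiltonian π·Δδ·(I1z−I2z) for a contact time (the
two-level Rabi formula for J = 0), not as a kinetic exchange model. The purge
pulse empties |T0⟩ into |T±⟩, where it cannot cancel the transferred signal;
the tests verify both the closed form and the purge rescue.

**Relaxation** is phenomenological, not Lindbladian: during every delay the
carbon Zeeman order decays with T1 and every other deviation from the
maximally mixed state — the stored singlet order and the proton-coherence
intermediates the echo train works through — decays with the singlet
lifetime T_S. This captures the two lifetimes the analysis reasons with and
has the right limits (T_S → 0 kills the transfer; T_S → ∞ recovers the
unitary result). Defaults: T_S = 45 s, T1(13C) = 30 s.

## Quantification (`quant`)

* Peak areas: trapezoidal integration after subtracting a linear baseline
  through the window edges (mean of the outer 5% of points per edge).
* Concentrations: area ratio against an internal standard, corrected by the
  nuclei-per-molecule counts (Cp* ligand 15, vinylic product 2, acetate 3,
  H2 2).
* SNR: peak maximum over rms of a least-squares-detrended signal-free window
  (the common spectrometer convention; pinned because published "9:1" ratios
  rarely state their estimator). Note this estimator is upward-biased when
  the true SNR is low (the maximum over n noise samples is ~2–2.5σ for
  n ≈ 10–80), which is why low-SNR round-trip tests compare means and the
  synthetic polarization recovery uses a well-conditioned reference.
* Enhancement: E = (SNR_hyper/(SNR_ref/√N))·(c_ref/c_hyper); thermal
  polarization tanh(ħγB0/2k_BT) with CODATA constants (the exact tanh form,
  not its linearization); percent polarization = 100·E·P_thermal; percent
  yield = 100·[P]/[A]0. Reference temperature defaults to 298 K.

With the experiment's printed inputs (SNR 9 single scan at 3 mM vs SNR 2 at
32 scans and 1 M, 11.7 T, 298 K) the chain gives E ≈ 8.49×10³ and 8.56% 13C
polarization.

## Synthetic data (`synth`)

Generators emit sums of Lorentzian lines on an evenly spaced ppm axis with
i.i.d. Gaussian point noise; areas are proportional to
concentration × nuclei × scans and multi-scan noise grows as √N, so the √N
SNR law holds by construction. All generators take explicit seeds and return
their ground truth alongside the data. They emulate: the 1H uptake series
(H2 line at 4.55 ppm + 20 mM acetate standard at 1.90 ppm, per flow rate),
single-scan hyperpolarized 13C spectra across flow rates (amplitude =
product × transfer efficiency × exp(−t_transit/T_S), noise scaled so the
strongest spectrum has SNR 9), and a multi-scan thermal 13C reference.

They do **not** emulate: FID-domain effects (phase errors, apodization,
truncation wiggles), lineshape distortions, baseline roll, solvent
backgrounds, field drift, or radiation damping. Passing round-trip tests
therefore demonstrates the correctness of the quantification chain on clean
Lorentzian data, not robustness to real-spectrum artefacts.

## Numerical choices

* Transport ODE: LSODA, rtol 1e-8, atol 1e-9 mM; uptake-only segments use the
  exact exponential; chamber steady state by Powell hybrid root-finding from
  the plug-flow outlet; film-depth calibration by bisection to 1e-12 m.
* Spin propagation: Hermitian eigendecomposition (unitary to machine
  precision); density matrices validated for trace 1, Hermiticity, and
  positive semidefiniteness at 1e-10/−1e-9 tolerances.
* Grid optimizer tie-break: smallest τ, then smallest n1+n2 (deterministic).
* Degenerate inputs raise typed errors (non-positive dimensions, flow ≤ 0,
  zero-rms noise windows, unsupported spin topologies) rather than returning
  NaN.

## Problem sizes

The shipped defaults keep everything at desk scale: 8×8 density matrices
(251-point τ grids complete in about a second), 50 path points per channel
segment, flow sweeps of 8–10 points, and 20-seed statistical round trips on
8k–32k-point spectra.

## Known limitations

* The chip fixtures are plausible stand-ins constrained by published
  aggregates, not measured channel drawings; the ±20% band on the chamber
  concentration prediction reflects this.
* The kinetics defaults are calibrated to the stated regime, not transcribed
  rate constants; only regime-level (ordering, shape) conclusions should be
  drawn from them.
* The reduced uptake model cannot simultaneously reproduce full α-chip
  saturation at 2 µL/min and the measured factor-2 uptake ratio at
  10 µL/min; the calibration anchors the β chip and accepts ~76% α-chip
  saturation at the anchor flow.
* Relaxation during the pulse sequence is a two-lifetime phenomenological
  model; cross-correlated relaxation and chemical exchange are out of scope.
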