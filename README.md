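# phipchip

Desk-scale models of continuous parahydrogen-induced **¹³C hyperpolarization
in a membrane microfluidic chip**: membrane H₂ uptake coupled to
hydrogenation kinetics, density-matrix simulation of singlet-to-¹³C
polarization transfer, the NMR quantification chain, and deterministic
synthetic-spectrum generators so every stage is testable without
spectrometer data.

Intended users: NMR/hyperpolarization researchers and lab-on-a-chip
developers who want quantitative, reproducible versions of the back-of-device
calculations — how much H₂ a channel design dissolves, what a pulse-sequence
operating point should be, and what a measured SNR means in percent
polarization — without a finite-element package or a spin-dynamics suite.

## The models

**Membrane uptake (reduced order).** Dissolved H₂ along the fluid path obeys
a plug-flow balance in residence time `t`,

    dc/dt = kLa (c_sat − c),        c_sat = H · p(H₂)      (Henry's law)

with a series-resistance volumetric mass-transfer coefficient per channel
segment,

    kLa = [ L_m/(D_m K_m) + d_f/D_l ]⁻¹ · (w_contact · n_sides)/(w · d).

The single calibration knob, the liquid-film depth `d_f`, is fixed once so
the two-sided chip saturates at the lowest experimental flow rate, then
frozen for all other predictions. Hydrogenation adds first-order catalyst
activation and rate laws bilinear in substrate and H₂
(`d[P]/dt = k_hyd [cat*][A][H₂] − k_over [cat*][P][H₂]`).

**Spin dynamics.** The product [1-¹³C]fumarate is a three-spin system
(Hₐ, H_b, C): the parahydrogen-derived proton pair starts in the nuclear
singlet |S₀⟩, and the unequal ¹³C–H couplings (ΔJ ≈ 3.6 Hz against
J_HH = 15.9 Hz) are the symmetry breaking that an echo train exploits. The
purge + singlet-to-heteronuclear-magnetization sequence

    90x(¹H) — [τ 180x(¹³C) τ]×n₁ — τ — 90x(¹³C) — [τ 180x(¹³C) τ]×n₂ — 90y(¹³C)

is propagated exactly (8×8 density matrices, ideal pulses), with the echo
spacing matched to the singlet–triplet splitting, τ ≈ 1/(4 J_HH).

**Quantification.** Peak areas against an internal standard give
concentrations; enhancement `E = (SNR_hyp/(SNR_ref/√N)) · (c_ref/c_hyp)`
times the thermal polarization `tanh(ħγB₀/2k_BT)` gives absolute percent
polarization; `100·[P]/[A]₀` gives percent yield.

## Worked example

```python
import numpy as np
from phipchip import *

# 1. Calibrate the transport model: beta chip saturated at 2 uL/min, 5 bar
params = calibrate_film_depth(beta_chip(), TransportParams(), pressure_bar=5.0)

# 2. Predict chamber H2 for both chip designs at 10 uL/min
c_beta  = h2_profile(beta_chip(), 10, 5, params).chamber_concentration_mM
c_alpha = h2_profile(alpha_chip(), 10, 5, params).chamber_concentration_mM

# 3. Find the transfer-sequence operating point for labelled fumarate
taus = [t * 1e-3 for t in np.arange(5, 30.0001, 0.1)]
best, records = optimize_sequence(fumarate_13c1(), taus, [(7, 7)])

# 4. Run the quantification chain on measured SNRs
enh = enhancement_factor(9, 2, 32, 3, 1000)           # SNRs, scans, mM, mM
pol = percent_polarization(enh, thermal_polarization("13C", 11.7, 298))
```

Output of the session above:

```
calibrated film depth: 0.375 mm
chamber [H2] at 10 uL/min: beta 10.3 mM, alpha 4.9 mM, ratio 2.11
transfer optimum: tau = 15.7 ms (n1 = n2 = 7), efficiency = 0.989
enhancement = 8485, 13C polarization = 8.56%
yields: 24.5% at 25 C, 35.0% at 37 C
```

Reading the numbers: the two-sided membrane layout roughly doubles the
dissolved H₂ reaching the detection chamber at working flow rates (10.3 vs
4.9 mM against a 19.8 mM saturation ceiling); the echo delay that best
converts singlet order to carbon magnetization is 15.7 ms with seven echoes
per train, converting 99% of the singlet order; and a single-scan SNR of 9
from a 3 mM sample, referenced to an SNR-2, 32-scan spectrum of a 1 M
sample, corresponds to an ~8.5×10³ signal enhancement, i.e. 8.6% ¹³C
polarization at 11.7 T.

The same stages are available from the shell:

```bash
phipchip geometry --chip beta
phipchip uptake --chip beta --pressure 5 --flows 2:20:2 --out curve.csv
phipchip spin --tau-scan 5:30:0.1 --n1 7 --n2 7 --out efficiency.csv
phipchip quant polarization --snr-hyper 9 --snr-ref 2 --n-scans-ref 32
phipchip synth --what uptake --seed 1 --out synthetic/
phipchip run --out results/
```

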