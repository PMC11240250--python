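"""Synthetic-spectrum generators emulating every measurement the analysis uses.

All generators are deterministic under an explicit seed (no global random
state), emit Lorentzian lines on an evenly spaced ppm axis with i.i.d.
Gaussian point noise, and return the ground-truth parameters alongside the
data so that every downstream quantification stage can be tested as a
parameter-recovery problem.

Peak areas are proportional to concentration x contributing nuclei x scan
count; multi-scan noise grows as sqrt(n_scans), reproducing the sqrt(N) SNR
law the quantification chain relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import ChipGeometry, residence_time
from .quant import Spectrum
from .transport import (
    KineticParams,
    TransportParams,
    h2_profile,
    hydrogenation_profile,
)

#: Arbitrary intensity-area units per (mM x proton x scan).
AREA_PER_MM_NUCLEUS = 1.0

# canonical chemical shifts used by the generators, ppm
H2_SHIFT = 4.55
ACETATE_SHIFT = 1.90
FUMARATE_13C_SHIFT = 175.4
GLUCOSE_13C_SHIFT = 96.0


@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian line: position, width, concentration and nuclei count."""

    center_ppm: float
    linewidth_hz: float
    concentration_mM: float
    nuclei: int = 1

    def __post_init__(self) -> None:
        if self.linewidth_hz <= 0:
            raise ValueError("linewidth must be > 0")
        if self.concentration_mM < 0:
            raise ValueError("concentration must be >= 0")
        if self.nuclei < 1:
            raise ValueError("nuclei count must be >= 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Axis layout, noise level and seed for the spectrum generator."""

    seed: int = 0
    noise_sigma: float = 0.0
    frequency_mhz: float = 500.0
    points: int = 8192
    sweep_ppm: tuple[float, float] = (-2.0, 12.0)

    def __post_init__(self) -> None:
        if self.points < 64:
            raise ValueError("points must be >= 64")
        if self.sweep_ppm[0] >= self.sweep_ppm[1]:
            raise ValueError("sweep must be a non-degenerate (low, high) ppm range")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.frequency_mhz <= 0:
            raise ValueError("spectrometer frequency must be > 0")


def _lorentzian(ppm: np.ndarray, center: float, fwhm_ppm: float, area: float) -> np.ndarray:
    half = fwhm_ppm / 2.0
    return area / np.pi * half / ((ppm - center) ** 2 + half**2)


def synth_spectrum(
    peaks: Sequence[PeakSpec],
    config: GeneratorConfig,
    nucleus: str = "1H",
    n_scans: int = 1,
    metadata: Optional[dict] = None,
) -> Spectrum:
    """Sum of Lorentzian lines plus i.i.d. Gaussian noise on a descending ppm axis.

    The area of each line is ``concentration x nuclei x n_scans`` (arbitrary
    units); noise is drawn per point with sigma ``noise_sigma x sqrt(n_scans)``,
    so co-adding scans improves SNR as sqrt(N).
    """
    lo, hi = config.sweep_ppm
    ppm = np.linspace(hi, lo, config.points)  # descending, NMR convention
    intensity = np.zeros_like(ppm)
    for peak in peaks:
        if not lo <= peak.center_ppm <= hi:
            raise ValueError(
                f"peak at {peak.center_ppm} ppm lies outside the sweep {config.sweep_ppm}"
            )
        area = AREA_PER_MM_NUCLEUS * peak.concentration_mM * peak.nuclei * n_scans
        fwhm_ppm = peak.linewidth_hz / config.frequency_mhz
        intensity += _lorentzian(ppm, peak.center_ppm, fwhm_ppm, area)
    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        intensity = intensity + rng.normal(
            0.0, config.noise_sigma * np.sqrt(n_scans), size=ppm.shape
        )
    meta = {"generator": "synth_spectrum", "noise_sigma": config.noise_sigma}
    if metadata:
        meta.update(metadata)
    return Spectrum(ppm=ppm, intensity=intensity, nucleus=nucleus, n_scans=n_scans, metadata=meta)


def synth_uptake_experiment(
    geometry: ChipGeometry,
    transport: TransportParams,
    flow_rates_uL_min: Sequence[float],
    pressure_bar: float = 5.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    acetate_mM: float = 20.0,
    linewidth_hz: float = 2.0,
) -> tuple[list[Spectrum], dict]:
    """Emulate the H2-uptake measurement: one 1H spectrum per flow rate.

    Each spectrum contains the dissolved-H2 line at 4.55 ppm (2 nuclei) at the
    chamber concentration predicted by the transport model, plus the acetate
    concentration standard (3 methyl protons).  Ground truth is returned as a
    sidecar dict.
    """
    spectra = []
    truth = {
        "pressure_bar": pressure_bar,
        "acetate_mM": acetate_mM,
        "flow_rates_uL_min": [],
        "c_h2_mM": [],
    }
    for i, flow in enumerate(flow_rates_uL_min):
        c_h2 = h2_profile(geometry, flow, pressure_bar, transport).chamber_concentration_mM
        cfg = GeneratorConfig(
            seed=seed + i, noise_sigma=noise_sigma, sweep_ppm=(-2.0, 12.0)
        )
        spec = synth_spectrum(
            [
                PeakSpec(H2_SHIFT, linewidth_hz, c_h2, nuclei=2),
                PeakSpec(ACETATE_SHIFT, linewidth_hz, acetate_mM, nuclei=3),
            ],
            cfg,
            nucleus="1H",
            metadata={"flow_uL_min": float(flow), "chip": geometry.label},
        )
        spectra.append(spec)
        truth["flow_rates_uL_min"].append(float(flow))
        truth["c_h2_mM"].append(float(c_h2))
    return spectra, truth


def synth_thermal_reference_13c(
    concentration_mM: float = 1000.0,
    n_scans: int = 32,
    target_snr: float = 2.0,
    seed: int = 0,
    linewidth_hz: float = 2.0,
    frequency_mhz: float = 125.7,
    points: int = 8192,
) -> tuple[Spectrum, dict]:
    """Multi-scan thermal 13C spectrum of a concentrated reference compound.

    The noise sigma is chosen so that the true peak height over rms noise in
    the final co-added spectrum equals ``target_snr``.
    """
    cfg0 = GeneratorConfig(
        seed=seed, noise_sigma=0.0, frequency_mhz=frequency_mhz, points=points,
        sweep_ppm=(-10.0, 190.0),
    )
    peak = PeakSpec(GLUCOSE_13C_SHIFT, linewidth_hz, concentration_mM, nuclei=1)
    clean = synth_spectrum([peak], cfg0, nucleus="13C", n_scans=n_scans)
    height = float(clean.intensity.max())
    sigma_total = height / target_snr
    cfg = GeneratorConfig(
        seed=seed, noise_sigma=sigma_total / np.sqrt(n_scans),
        frequency_mhz=frequency_mhz, points=points, sweep_ppm=(-10.0, 190.0),
    )
    spec = synth_spectrum(
        [peak], cfg, nucleus="13C", n_scans=n_scans,
        metadata={"concentration_mM": concentration_mM, "target_snr": target_snr},
    )
    truth = {
        "concentration_mM": concentration_mM,
        "n_scans": n_scans,
        "target_snr": target_snr,
        "clean_peak_height": height,
        "noise_sigma_total": sigma_total,
    }
    return spec, truth


def synth_flow_sweep_13c(
    geometry: ChipGeometry,
    transport: TransportParams,
    kinetics: KineticParams,
    transfer_efficiency: float,
    t_singlet_s: float,
    flow_rates_uL_min: Sequence[float],
    pressure_bar: float = 6.0,
    seed: int = 0,
    target_snr_max: float = 9.0,
    linewidth_hz: float = 2.0,
    frequency_mhz: float = 125.7,
) -> tuple[list[Spectrum], dict]:
    """Emulate the single-scan hyperpolarized 13C series across flow rates.

    Per flow rate the hyperpolarized amplitude is
    ``product concentration x transfer efficiency x exp(-t_transit / T_S)``:
    the product is made along the path, its proton singlet order decays with
    lifetime T_S during transit, and what survives is converted to carbon
    magnetization in the detection chamber.  Spectra are rendered with a
    common noise sigma chosen so the strongest spectrum of the series has peak
    SNR ``target_snr_max``.
    """
    flows = [float(f) for f in flow_rates_uL_min]
    amplitudes = []
    products = []
    transits = []
    for flow in flows:
        prof = hydrogenation_profile(geometry, flow, pressure_bar, transport, kinetics)
        product = prof.chamber["product"]
        t_transit = residence_time(geometry, flow)
        amplitudes.append(product * transfer_efficiency * np.exp(-t_transit / t_singlet_s))
        products.append(product)
        transits.append(t_transit)
    amplitudes = np.asarray(amplitudes)

    # noise level: strongest line of the series reaches target_snr_max
    fwhm_ppm = linewidth_hz / frequency_mhz
    peak_height = lambda amp: (AREA_PER_MM_NUCLEUS * amp) * 2.0 / (np.pi * fwhm_ppm)
    sigma = peak_height(amplitudes.max()) / target_snr_max if amplitudes.max() > 0 else 1.0

    spectra = []
    for i, (flow, amp) in enumerate(zip(flows, amplitudes)):
        cfg = GeneratorConfig(
            seed=seed + i, noise_sigma=sigma, frequency_mhz=frequency_mhz,
            points=8192, sweep_ppm=(-10.0, 190.0),
        )
        spectra.append(
            synth_spectrum(
                [PeakSpec(FUMARATE_13C_SHIFT, linewidth_hz, amp, nuclei=1)],
                cfg,
                nucleus="13C",
                n_scans=1,
                metadata={"flow_uL_min": flow, "chip": geometry.label},
            )
        )
    truth = {
        "flow_rates_uL_min": flows,
        "product_mM": [float(p) for p in products],
        "transit_s": [float(t) for t in transits],
        "hyper_amplitude_mM": [float(a) for a in amplitudes],
        "transfer_efficiency": transfer_efficiency,
        "t_singlet_s": t_singlet_s,
        "noise_sigma": float(sigma),
    }
    return spectra, truth
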