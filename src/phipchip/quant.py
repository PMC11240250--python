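"""NMR quantification chain: peak areas, concentrations, SNR, enhancement,
thermal polarization, percent polarization and percent yield.

The hyperpolarized signal is quantified against ordinary thermal-equilibrium
references: an internal concentration standard fixes absolute concentrations
through proton-count-weighted peak areas, and a multi-scan thermal spectrum of
a concentrated reference compound fixes the signal-per-spin scale.  The
enhancement factor (hyperpolarized signal per spin over thermal signal per
spin) times the thermal equilibrium polarization gives the absolute
polarization of the hyperpolarized nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import tanh

import numpy as np

from .constants import GYROMAGNETIC_RATIO, HBAR, K_BOLTZMANN


@dataclass
class Spectrum:
    """A 1-D NMR spectrum: ppm axis (ascending or descending) and intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    nucleus: str = "1H"
    n_scans: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm axis and intensity must be equal-length 1-D arrays")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")


@dataclass(frozen=True)
class PeakRegion:
    """An integration window: centre +- half_width, both in ppm."""

    center_ppm: float
    half_width_ppm: float

    def __post_init__(self) -> None:
        if self.half_width_ppm <= 0:
            raise ValueError("half_width must be > 0")

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.center_ppm - self.half_width_ppm, self.center_ppm + self.half_width_ppm)

    def overlaps(self, other: "PeakRegion") -> bool:
        lo1, hi1 = self.bounds
        lo2, hi2 = other.bounds
        return lo1 < hi2 and lo2 < hi1


def _region_slice(spectrum: Spectrum, region: PeakRegion) -> np.ndarray:
    lo, hi = region.bounds
    mask = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if mask.sum() < 4:
        raise ValueError(
            f"region {region.bounds} ppm covers fewer than 4 points of the axis"
        )
    return np.where(mask)[0]


def _edge_baseline(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Linear baseline through the mean of the outer 5% of points at each edge."""
    k = max(1, len(x) // 20)
    x0, y0 = x[:k].mean(), y[:k].mean()
    x1, y1 = x[-k:].mean(), y[-k:].mean()
    slope = (y1 - y0) / (x1 - x0) if x1 != x0 else 0.0
    return y0 + slope * (x - x0)


def integrate_peak(spectrum: Spectrum, region: PeakRegion) -> float:
    """Trapezoidal peak area over the region after edge-fitted linear baseline
    subtraction.  The area sign follows the peak, not the axis direction."""
    idx = _region_slice(spectrum, region)
    x = spectrum.ppm[idx]
    y = spectrum.intensity[idx]
    order = np.argsort(x)
    x, y = x[order], y[order]
    y = y - _edge_baseline(x, y)
    return float(np.trapezoid(y, x))


def concentration_by_reference(
    analyte_area: float,
    ref_area: float,
    ref_concentration_mM: float,
    analyte_protons: int,
    ref_protons: int,
) -> float:
    """Concentration from area ratio against an internal standard,
    correcting for the number of contributing nuclei per molecule."""
    if ref_area <= 0:
        raise ValueError("reference area must be > 0")
    if analyte_protons < 1 or ref_protons < 1:
        raise ValueError("proton counts must be >= 1")
    return ref_concentration_mM * (analyte_area / ref_area) * (ref_protons / analyte_protons)


def snr(spectrum: Spectrum, signal_region: PeakRegion, noise_region: PeakRegion) -> float:
    """Peak height over rms noise.

    The estimator is the maximum of the baseline-subtracted intensity in the
    signal window divided by the root-mean-square of the least-squares-detrended
    intensity in a signal-free noise window.  Published signal-to-noise ratios
    of the form "9:1" rarely state their estimator; peak-over-rms is the
    common spectrometer-software convention and is pinned here so the
    quantification chain is deterministic.
    """
    if signal_region.overlaps(noise_region):
        raise ValueError("signal and noise regions must be disjoint")
    s_idx = _region_slice(spectrum, signal_region)
    xs, ys = spectrum.ppm[s_idx], spectrum.intensity[s_idx]
    order = np.argsort(xs)
    ys = ys[order] - _edge_baseline(xs[order], ys[order])
    peak = float(ys.max())

    n_idx = _region_slice(spectrum, noise_region)
    xn, yn = spectrum.ppm[n_idx], spectrum.intensity[n_idx]
    coeffs = np.polyfit(xn, yn, 1)
    resid = yn - np.polyval(coeffs, xn)
    rms = float(np.sqrt(np.mean(resid**2)))
    if rms == 0:
        raise ZeroDivisionError("noise region has zero rms; cannot form an SNR")
    return peak / rms


def enhancement_factor(
    snr_hyper: float,
    snr_ref: float,
    n_scans_ref: int,
    conc_hyper_mM: float,
    conc_ref_mM: float,
) -> float:
    """Signal enhancement per spin of the hyperpolarized sample.

    The multi-scan reference SNR is reduced to a single-scan equivalent by
    dividing by sqrt(n_scans); the concentration ratio converts signal to
    signal per spin:

        E = (SNR_hyper / (SNR_ref / sqrt(N))) * (c_ref / c_hyper)
    """
    if min(snr_hyper, snr_ref, n_scans_ref, conc_hyper_mM, conc_ref_mM) <= 0:
        raise ValueError("all enhancement inputs must be > 0")
    return (snr_hyper / (snr_ref / np.sqrt(n_scans_ref))) * (conc_ref_mM / conc_hyper_mM)


def thermal_polarization(isotope: str, field_T: float, temperature_K: float) -> float:
    """Thermal-equilibrium polarization tanh(hbar gamma B0 / (2 kB T)).

    The exact tanh form is kept rather than its high-temperature linearization
    (the difference is negligible at NMR energies, but the form is exact).
    """
    if field_T <= 0 or temperature_K <= 0:
        raise ValueError("field and temperature must be > 0")
    try:
        gamma = GYROMAGNETIC_RATIO[isotope]
    except KeyError:
        raise KeyError(f"unknown isotope {isotope!r}; have {sorted(GYROMAGNETIC_RATIO)}")
    return tanh(HBAR * gamma * field_T / (2.0 * K_BOLTZMANN * temperature_K))


def percent_polarization(enhancement: float, thermal: float) -> float:
    """Absolute polarization in percent: 100 * enhancement * thermal level."""
    if enhancement <= 0 or thermal <= 0:
        raise ValueError("enhancement and thermal polarization must be > 0")
    return 100.0 * enhancement * thermal


def percent_yield(product_mM: float, precursor_mM: float) -> float:
    """Reaction yield in percent of the precursor converted to product."""
    if precursor_mM <= 0:
        raise ValueError("precursor concentration must be > 0")
    if product_mM < 0:
        raise ValueError("product concentration must be >= 0")
    return 100.0 * product_mM / precursor_mM


#: Proton counts used for internal-standard referencing.  The
#: pentamethylcyclopentadienyl (Cp*) ligand of the Ru catalyst carries 15
#: equivalent methyl protons; the vinylic product resonance integrates 2
#: protons; the acetate methyl standard integrates 3; molecular H2 two.
PROTON_COUNTS = {
    "fumarate_vinyl": 2,
    "cp_star": 15,
    "acetate_methyl": 3,
    "h2": 2,
}
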