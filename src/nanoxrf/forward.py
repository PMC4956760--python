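"""Analytic fundamental-parameter forward model for energy-dispersive XRF.

Expected per-pixel spectra are built line by line: detected line-group
counts per unit concentration and time (the *sensitivity*) follow

    S_e = flux * (Omega/4pi) * eps(E_line) * k_e(E0) * rho*t * A_e

where ``k_e`` is the element's fluorescence-production factor at the
excitation energy, ``rho*t`` the areal density, ``eps`` the detector-window
transmission and ``A_e`` the thin-slab self-absorption factor

    A = (1 - exp(-chi * rho * t)) / (chi * rho * t),
    chi = mu(E0)/sin(psi_in) + mu(E_line)/sin(psi_out).

Lines are spread as bin-integrated Gaussians with an energy-dependent FWHM
(electronic noise + Fano broadening); a smooth continuum plus Rayleigh and
Compton scatter peaks complete the expectation, and acquisition is an
independent Poisson draw per channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from . import constants as C
from .phantom import GroundTruthMaps, ReferenceSample


@dataclass(frozen=True)
class InstrumentConfig:
    """Beam, detector and digitizer parameters of the simulated nano-probe."""

    E0_keV: float = 17.5
    flux: float = 2.0e11                  # photons/s
    spot_nm: tuple[float, float] = (50.0, 50.0)
    detector_angle_deg: float = 77.0      # between beam axis and detector
    solid_angle_fraction: float = 0.04    # Omega/4pi, both SDD arrays merged
    fwhm_ref_ev: float = 130.0            # at e_ref_ev
    fano_ev: float = 2.46                 # FWHM^2 slope vs energy, eV per eV
    e_ref_ev: float = 5900.0
    n_channels: int = 2048
    gain_ev: float = 10.0
    offset_ev: float = 0.0
    scatter_scale: float = 1.0
    window_be_um: float = 25.0

    def __post_init__(self):
        if self.flux < 0 or self.solid_angle_fraction <= 0 or self.gain_ev <= 0:
            raise ValueError("flux, solid angle and gain must be positive")
        if self.n_channels * self.gain_ev <= self.E0_keV * 1000:
            raise ValueError("energy axis does not cover the excitation energy")

    @property
    def energy_axis_kev(self) -> np.ndarray:
        """Channel-center energies in keV."""
        return (self.offset_ev + self.gain_ev * (np.arange(self.n_channels) + 0.5)) / 1000.0

    @property
    def bin_edges_kev(self) -> np.ndarray:
        return (self.offset_ev + self.gain_ev * np.arange(self.n_channels + 1)) / 1000.0

    def fwhm_ev(self, energy_kev):
        e = np.asarray(energy_kev, dtype=float) * 1000.0
        fw2 = self.fwhm_ref_ev**2 + self.fano_ev * (e - self.e_ref_ev)
        return np.sqrt(np.maximum(fw2, 40.0**2))

    @property
    def sin_psi_in(self) -> float:
        return 1.0  # beam normal to the section plane

    @property
    def sin_psi_out(self) -> float:
        return math.cos(math.radians(self.detector_angle_deg))


@dataclass(frozen=True)
class SampleModel:
    """Slab sample: thickness, density and a 2-term matrix attenuation law."""

    thickness_um: float = 2.0
    density: float = 1.0                  # g/cm^3
    matrix: str = "organic"
    mu_pe: float = C.MATRIX_MU_PE         # mu/rho = mu_pe*E^-3 + mu_inc
    mu_inc: float = C.MATRIX_MU_INCOHERENT

    def __post_init__(self):
        if self.thickness_um <= 0 or self.density <= 0:
            raise ValueError("thickness and density must be positive")

    @property
    def areal_density(self) -> float:
        """rho * t in g/cm^2."""
        return self.density * self.thickness_um * 1.0e-4

    def mu(self, energy_kev):
        e = np.asarray(energy_kev, dtype=float)
        return self.mu_pe * e**-3 + self.mu_inc

    @staticmethod
    def from_reference(ref: ReferenceSample) -> "SampleModel":
        return SampleModel(thickness_um=ref.thickness_um, density=ref.density,
                           matrix="reference")


@dataclass(frozen=True)
class EmissionLine:
    element: str
    series: str
    energy_kev: float
    rel_intensity: float     # group-normalized


@dataclass
class Spectrum:
    counts: np.ndarray
    gain_ev: float = 10.0
    offset_ev: float = 0.0
    live_time_s: float = 1.0

    @property
    def energy_axis_kev(self) -> np.ndarray:
        n = len(self.counts)
        return (self.offset_ev + self.gain_ev * (np.arange(n) + 0.5)) / 1000.0


@dataclass
class MapCube:
    counts: np.ndarray                   # rows x cols x n_channels
    dwell_s: float
    step_nm: float
    instrument: InstrumentConfig
    sample: SampleModel
    truth: GroundTruthMaps | None = None

    @property
    def shape(self):
        return self.counts.shape

    @property
    def n_pixels(self) -> int:
        return self.counts.shape[0] * self.counts.shape[1]


class UnsupportedElementError(KeyError):
    pass


def emission_lines(element: str) -> list[EmissionLine]:
    """Group-normalized emission lines (K-series, or L-series for Pt)."""
    if element not in C.SUPPORTED_ELEMENTS:
        raise UnsupportedElementError(element)
    return [EmissionLine(element, s, e, r)
            for s, e, r in C.group_normalized_lines(element)]


def compton_energy(E0_keV: float, theta_deg: float) -> float:
    """Compton-scattered photon energy at scattering angle theta."""
    if not 0 <= theta_deg <= 180:
        raise ValueError("theta must be in [0, 180] degrees")
    k = E0_keV / C.ELECTRON_REST_ENERGY_KEV
    return E0_keV / (1.0 + k * (1.0 - math.cos(math.radians(theta_deg))))


def detector_efficiency(energy_kev, instrument: InstrumentConfig):
    """Transmission of the detector Be window."""
    e = np.asarray(energy_kev, dtype=float)
    mu_be = C.BE_MU_PE * e**-3 + C.BE_MU_INCOHERENT
    t_cm = instrument.window_be_um * 1.0e-4
    return np.exp(-mu_be * C.BE_DENSITY * t_cm)


def self_absorption(energy_kev, instrument: InstrumentConfig, sample: SampleModel):
    """Thin-slab self-absorption factor A(E_line) in (0, 1]."""
    chi = (sample.mu(instrument.E0_keV) / instrument.sin_psi_in
           + sample.mu(energy_kev) / instrument.sin_psi_out)
    x = chi * sample.areal_density
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        a = np.where(x > 1e-12, -np.expm1(-x) / np.maximum(x, 1e-12), 1.0)
    return a


def line_sensitivities(element: str, instrument: InstrumentConfig,
                       sample: SampleModel) -> tuple[list[EmissionLine], np.ndarray]:
    """Per-line detected counts per (wt-fraction * s)."""
    lines = emission_lines(element)
    energies = np.array([l.energy_kev for l in lines])
    rel = np.array([l.rel_intensity for l in lines])
    s = (instrument.flux * instrument.solid_angle_fraction
         * detector_efficiency(energies, instrument)
         * C.K_PRODUCTION[element] * rel
         * sample.areal_density
         * self_absorption(energies, instrument, sample))
    return lines, s


def element_sensitivity(element: str, instrument: InstrumentConfig,
                        sample: SampleModel) -> float:
    """Total detected line-group counts per (wt-fraction * s)."""
    _, s = line_sensitivities(element, instrument, sample)
    return float(s.sum())


def _binned_gaussian(instrument: InstrumentConfig, energy_kev: float,
                     fwhm_scale: float = 1.0) -> np.ndarray:
    """Unit-area line profile integrated over channel bins."""
    sigma = fwhm_scale * float(instrument.fwhm_ev(energy_kev)) / 2.3548 / 1000.0
    edges = instrument.bin_edges_kev
    z = (edges - energy_kev) / (math.sqrt(2.0) * sigma)
    cdf = 0.5 * (1.0 + erf(z))
    return np.diff(cdf)


# Continuum shape constants: exp decay + pedestal, scaled by beam, areal
# density and scatter_scale. Chosen once for a few counts/channel/0.1 s in
# tissue; fidelity of the continuum is explicitly not load-bearing.
_CONT_BETA = 5.0e-5
_CONT_DECAY_KEV = 6.0
_CONT_PEDESTAL = 0.1
_RAYLEIGH_XS = 2.0e-3
_COMPTON_XS = 4.0e-3
_COMPTON_WIDTH = 2.0  # Doppler broadening vs detector response


def background_expectation(instrument: InstrumentConfig, sample: SampleModel,
                           dwell_s: float) -> np.ndarray:
    """Continuum + Rayleigh/Compton scatter-peak expectation, counts/channel."""
    e = instrument.energy_axis_kev
    beam = instrument.flux * instrument.solid_angle_fraction * sample.areal_density
    cont = (instrument.scatter_scale * beam * _CONT_BETA
            * (np.exp(-e / _CONT_DECAY_KEV) + _CONT_PEDESTAL)
            * detector_efficiency(e, instrument))
    cont = cont * (e < instrument.E0_keV * 1.02)
    ray = (instrument.scatter_scale * beam * _RAYLEIGH_XS
           * _binned_gaussian(instrument, instrument.E0_keV))
    e_c = compton_energy(instrument.E0_keV, instrument.detector_angle_deg)
    com = (instrument.scatter_scale * beam * _COMPTON_XS
           * _binned_gaussian(instrument, e_c, fwhm_scale=_COMPTON_WIDTH))
    return (cont + ray + com) * dwell_s


def expected_spectrum(pixel_conc: dict, instrument: InstrumentConfig,
                      sample: SampleModel, dwell_s: float) -> Spectrum:
    """Expectation (real-valued) spectrum for one pixel's concentrations."""
    total = background_expectation(instrument, sample, dwell_s).copy()
    for el, conc in pixel_conc.items():
        conc = float(conc)
        if conc < 0:
            raise ValueError(f"negative concentration for {el}")
        if conc == 0:
            continue
        lines, sens = line_sensitivities(el, instrument, sample)
        for line, s in zip(lines, sens):
            total += s * conc * dwell_s * _binned_gaussian(instrument, line.energy_kev)
    return Spectrum(total, instrument.gain_ev, instrument.offset_ev, dwell_s)


def _line_system(elements, instrument, sample):
    """Stacked per-line profiles and sensitivities for vectorized simulation."""
    profiles, sens, owner = [], [], []
    for i, el in enumerate(elements):
        lines, s = line_sensitivities(el, instrument, sample)
        for line, sl in zip(lines, s):
            profiles.append(_binned_gaussian(instrument, line.energy_kev))
            sens.append(sl)
            owner.append(i)
    return np.array(profiles), np.array(sens), np.array(owner)


def expected_cube(truth: GroundTruthMaps, instrument: InstrumentConfig,
                  sample: SampleModel, dwell_s: float) -> np.ndarray:
    """Per-pixel expectation spectra as an (rows, cols, n_channels) array."""
    elements = list(truth.conc)
    shapes = {truth.conc[el].shape for el in elements}
    if len(shapes) != 1:
        raise ValueError(f"truth maps have mismatched shapes: {shapes}")
    rows, cols = shapes.pop()
    conc = np.stack([truth.conc[el].ravel() for el in elements], axis=1)
    profiles, sens, owner = _line_system(elements, instrument, sample)
    amp = conc[:, owner] * (sens * dwell_s)          # (npix, nlines)
    exp = amp @ profiles
    exp += background_expectation(instrument, sample, dwell_s)
    return exp.reshape(rows, cols, instrument.n_channels)


def simulate_cube(truth: GroundTruthMaps, instrument: InstrumentConfig | None = None,
                  sample: SampleModel | None = None, dwell_s: float = 0.1,
                  seed: int = 0) -> MapCube:
    """Poisson-sampled scan of a ground-truth phantom."""
    instrument = instrument or InstrumentConfig()
    sample = sample or SampleModel()
    exp = expected_cube(truth, instrument, sample, dwell_s)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(exp).astype(np.int32)
    return MapCube(counts, dwell_s, truth.label_map.pixel_size_nm,
                   instrument, sample, truth=truth)


def expected_reference_spectrum(ref: ReferenceSample, instrument: InstrumentConfig,
                                live_time_s: float = 500.0) -> Spectrum:
    sample = SampleModel.from_reference(ref)
    return expected_spectrum(ref.certified, instrument, sample, live_time_s)


def simulate_reference_spectrum(ref: ReferenceSample,
                                instrument: InstrumentConfig | None = None,
                                live_time_s: float = 500.0,
                                seed: int = 0) -> Spectrum:
    """Poisson draw of a homogeneous reference-standard acquisition."""
    if live_time_s <= 0:
        raise ValueError("live_time must be positive")
    instrument = instrument or InstrumentConfig()
    exp = expected_reference_spectrum(ref, instrument, live_time_s)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(exp.counts).astype(np.int64)
    return Spectrum(counts, instrument.gain_ev, instrument.offset_ev, live_time_s)
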