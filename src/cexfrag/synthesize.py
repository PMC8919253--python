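"""Synthetic ion-yield datasets with known ground truth.

No measured spectra ship with this package, so the spectroscopy layer is
exercised on synthetic data that emulates a sulfur L-edge photon-energy scan
of a trapped ion: a grid of photon energies stepped 40-70 meV, and at each
energy a unit-resolution TOF mass spectrum whose fragment peaks carry
areas drawn from per-fragment resonance profiles (three bound resonances,
a broad feature, and an edge step at the ionization threshold).  The
injected per-fragment areas are returned alongside the spectra, so partial
ion yields extracted by the analysis can be compared with truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import MassSpectrum, TofCalibration

#: (center eV, Gaussian sigma eV) of the bound resonances and broad feature,
#: plus the edge-step onset, loosely emulating an S L-edge region
#: (~160-178 eV).  Amplitudes are per-fragment below.
RESONANCES = {
    "A": (164.3, 0.35),
    "B": (165.4, 0.40),
    "C": (166.6, 0.45),
    "D": (170.0, 1.60),
}
EDGE_ONSET_EV = 173.0
EDGE_WIDTH_EV = 0.5

#: Default fragment set: label -> (nominal m/z, {resonance: amplitude},
#: edge-step amplitude).  Disulfide-containing fragments favour the higher
#: resonances and the edge; the low-energy resonance favours fragments that
#: require rupture of the disulfide bridge.
DEFAULT_FRAGMENTS = {
    "45": (45.0, {"A": 0.9, "B": 1.1, "C": 1.0, "D": 0.8}, 1.2),
    "64": (64.0, {"A": 0.1, "B": 0.5, "C": 0.6, "D": 0.4}, 0.7),
    "74": (74.0, {"A": 0.8, "B": 0.9, "C": 0.4, "D": 0.3}, 0.6),
    "55": (55.0, {"A": 0.1, "B": 0.4, "C": 0.5, "D": 0.3}, 0.3),
    "57": (57.0, {"A": 0.5, "B": 0.6, "C": 0.2, "D": 0.2}, 0.2),
}


def resonance_profile(
    energies_eV, amplitudes: dict, edge_amplitude: float
) -> np.ndarray:
    """Sum of Gaussian resonances plus a sigmoidal edge step."""
    e = np.asarray(energies_eV, float)
    out = np.zeros_like(e)
    for name, amp in amplitudes.items():
        c, s = RESONANCES[name]
        out += amp * np.exp(-0.5 * ((e - c) / s) ** 2)
    out += edge_amplitude / (1.0 + np.exp(-(e - EDGE_ONSET_EV) / EDGE_WIDTH_EV))
    return out


def stepped_energy_grid(
    lo_eV: float,
    hi_eV: float,
    rng: np.random.Generator,
    step_bounds=(0.040, 0.070),
) -> np.ndarray:
    """Strictly increasing grid with uniform-random steps inside the bounds."""
    energies = [lo_eV]
    while energies[-1] < hi_eV:
        energies.append(energies[-1] + rng.uniform(*step_bounds))
    return np.array(energies[:-1] if energies[-1] > hi_eV else energies)


@dataclass
class SyntheticScan:
    energies_eV: np.ndarray
    spectra: list  # MassSpectrum per energy (m/z domain)
    tof_spectra: list  # same spectra on the flight-time axis
    true_piy: dict  # label -> injected peak areas over the energy grid
    calibration: TofCalibration
    fragment_mz: dict  # label -> nominal m/z


def synthetic_ion_yield_scan(
    seed: int = 0,
    lo_eV: float = 160.0,
    hi_eV: float = 178.0,
    fragments: dict = DEFAULT_FRAGMENTS,
    mz_sigma: float = 0.08,
    mz_step: float = 0.02,
    noise: float = 0.0,
    calibration: TofCalibration = TofCalibration(t0=2.0, k=0.75),
) -> SyntheticScan:
    """Generate a full synthetic photon-energy scan.

    Each mass spectrum is a dense m/z grid with a narrow Gaussian peak per
    fragment whose area equals the fragment's resonance profile at that
    photon energy (plus optional multiplicative noise).  ``tof_spectra``
    gives the same data on the flight-time axis via the forward calibration
    t = t0 + k*sqrt(m/z), for exercising the calibration round trip.
    """
    rng = np.random.default_rng(seed)
    energies = stepped_energy_grid(lo_eV, hi_eV, rng)
    true_piy = {
        label: resonance_profile(energies, amps, edge)
        for label, (mz0, amps, edge) in fragments.items()
    }
    if noise > 0:
        for label in true_piy:
            true_piy[label] = true_piy[label] * (
                1.0 + noise * rng.standard_normal(len(energies))
            )
            true_piy[label] = np.clip(true_piy[label], 0.0, None)
    mz_axis = np.arange(30.0, 120.0, mz_step)
    t_axis = calibration.mz_to_time(mz_axis)
    spectra, tof_spectra = [], []
    for k in range(len(energies)):
        intensity = np.zeros_like(mz_axis)
        for label, (mz0, _, _) in fragments.items():
            area = true_piy[label][k]
            intensity += (
                area
                / (mz_sigma * np.sqrt(2.0 * np.pi))
                * np.exp(-0.5 * ((mz_axis - mz0) / mz_sigma) ** 2)
            )
        spectra.append(MassSpectrum(mz_axis, intensity))
        tof_spectra.append(MassSpectrum(t_axis, intensity))
    return SyntheticScan(
        energies,
        spectra,
        tof_spectra,
        true_piy,
        calibration,
        {label: f[0] for label, f in fragments.items()},
    )
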