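"""Ion-yield spectroscopy utilities.

Covers the experiment-side bookkeeping around a photon-energy scan over a
core-level edge of a trapped molecular ion:

* time-of-flight (TOF) mass calibration with the standard linear-TOF law
  t = t0 + k*sqrt(m/z), anchored on reference peaks;
* peak integration of mass spectra (dense grids or peak lists);
* partial ion yields (PIY: integrated intensity of one fragment peak as a
  function of photon energy) and their sum (SIY), which approximates the
  absorption (NEXAFS) spectrum;
* Gaussian broadening + rigid energy shift of computed stick spectra for
  comparison with measured yields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default photon-energy step bounds (eV) accepted by the scan validator —
#: monochromator scans over an L-edge typically step 40-70 meV.
DEFAULT_STEP_BOUNDS_EV = (0.040, 0.070)

#: Default Gaussian broadening FWHM (eV) and rigid shift (eV) applied to
#: stick spectra when comparing with a measured summed ion yield.  Both are
#: match parameters, not physical constants.
DEFAULT_FWHM_EV = 0.7
DEFAULT_SHIFT_EV = 7.23


@dataclass
class StickSpectrum:
    """Computed electronic transitions as (energy eV, strength) bars."""

    energies_eV: np.ndarray
    strengths: np.ndarray

    def __post_init__(self) -> None:
        self.energies_eV = np.asarray(self.energies_eV, float)
        self.strengths = np.asarray(self.strengths, float)
        if self.energies_eV.shape != self.strengths.shape:
            raise ValueError("energies and strengths must align")
        if not np.isfinite(self.energies_eV).all():
            raise ValueError("non-finite stick energy")
        if np.any(self.strengths < 0):
            raise ValueError("negative stick strength")

    @classmethod
    def from_text(cls, path) -> "StickSpectrum":
        """Two-column text: energy_eV strength, '#' comments allowed."""
        arr = np.loadtxt(path, comments="#", ndmin=2)
        return cls(arr[:, 0], arr[:, 1])

    def to_text(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.energies_eV, self.strengths]),
            header="energy_eV strength",
        )


@dataclass
class MassSpectrum:
    """Either a dense (m/z axis, intensity) grid or a discrete peak list."""

    mz: np.ndarray
    intensity: np.ndarray
    kind: str = "dense"  # "dense" | "peaks"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.kind not in ("dense", "peaks"):
            raise ValueError("kind must be 'dense' or 'peaks'")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("axis/intensity mismatch")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")


@dataclass(frozen=True)
class TofCalibration:
    """t = t0 + k*sqrt(m/z); k in time units per sqrt(u/e)."""

    t0: float
    k: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("calibration slope must be positive")

    def mz_to_time(self, mz) -> np.ndarray:
        return self.t0 + self.k * np.sqrt(np.asarray(mz, float))


def tof_calibrate(reference_peaks) -> TofCalibration:
    """Fit (t0, k) from (flight time, known m/z) reference pairs.

    Exact solve for two references; least squares for more.  In practice two
    well-separated fragment peaks of known composition suffice.
    """
    refs = list(reference_peaks)
    if len(refs) < 2:
        raise ValueError("need at least 2 reference peaks")
    mzs = np.array([mz for _, mz in refs], float)
    ts = np.array([t for t, _ in refs], float)
    if np.any(mzs <= 0):
        raise ValueError("reference m/z must be positive")
    if len(np.unique(mzs)) != len(mzs):
        raise ValueError("duplicate reference m/z")
    a = np.column_stack([np.ones_like(mzs), np.sqrt(mzs)])
    (t0, k), *_ = np.linalg.lstsq(a, ts, rcond=None)
    return TofCalibration(float(t0), float(k))


def tof_to_mz(times, calib: TofCalibration):
    """Invert the calibration: m/z = ((t - t0)/k)^2."""
    t = np.asarray(times, float)
    if np.any(t < calib.t0):
        raise ValueError("flight time earlier than calibration offset t0")
    out = ((t - calib.t0) / calib.k) ** 2
    return float(out) if np.isscalar(times) else out


def integrate_peak(spectrum: MassSpectrum, window) -> float:
    """Integrated intensity in [lo, hi]: trapezoid on dense grids, plain sum
    of peak intensities for peak lists."""
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    inside = (spectrum.mz >= lo) & (spectrum.mz <= hi)
    if not inside.any():
        return 0.0
    if spectrum.kind == "peaks":
        return float(spectrum.intensity[inside].sum())
    return float(np.trapezoid(spectrum.intensity[inside], spectrum.mz[inside]))


@dataclass
class IonYieldScan:
    """Photon-energy grid + per-fragment PIY curves + their SIY sum."""

    energies_eV: np.ndarray
    piy: dict  # fragment label -> np.ndarray over the energy grid
    siy: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.energies_eV = np.asarray(self.energies_eV, float)
        if np.any(np.diff(self.energies_eV) <= 0):
            raise ValueError("photon-energy grid must be strictly increasing")
        for label, curve in self.piy.items():
            self.piy[label] = np.asarray(curve, float)
            if self.piy[label].shape != self.energies_eV.shape:
                raise ValueError(f"PIY {label!r} does not match the energy grid")
        if not self.piy:
            raise ValueError("need at least one PIY curve")
        self.siy = siy(self)

    def validate_step(self, bounds=DEFAULT_STEP_BOUNDS_EV) -> None:
        steps = np.diff(self.energies_eV)
        if len(steps) and not ((steps >= bounds[0] - 1e-12) & (steps <= bounds[1] + 1e-12)).all():
            raise ValueError(
                f"photon-energy steps outside {bounds[0]*1e3:.0f}-"
                f"{bounds[1]*1e3:.0f} meV"
            )

    def to_frame(self) -> pd.DataFrame:
        cols = {"energy_eV": self.energies_eV}
        cols.update({f"piy_{k}": v for k, v in self.piy.items()})
        cols["siy"] = self.siy
        return pd.DataFrame(cols)


def siy(scan: IonYieldScan) -> np.ndarray:
    """Summed ion yield: the exact elementwise sum of the stored PIYs.

    Summation runs in sorted label order so the result is bit-identical
    under permutation of the fragment dictionary.
    """
    labels = sorted(scan.piy)
    out = scan.piy[labels[0]].copy()
    for k in labels[1:]:
        out += scan.piy[k]
    return out


def piy_scan(
    energies_eV,
    spectra,
    fragment_windows: dict,
    step_bounds=DEFAULT_STEP_BOUNDS_EV,
) -> IonYieldScan:
    """Build an ion-yield scan from per-energy mass spectra.

    ``spectra`` is one MassSpectrum per photon energy (shared calibration
    assumed); ``fragment_windows`` maps a fragment label to its integration
    window (lo, hi) in m/z.  Windows must not overlap between labels —
    otherwise intensity would be double counted in the SIY.
    """
    energies_eV = np.asarray(energies_eV, float)
    if len(energies_eV) != len(spectra):
        raise ValueError("one mass spectrum required per photon energy")
    wins = sorted(fragment_windows.items(), key=lambda kv: kv[1][0])
    for (la, wa), (lb, wb) in zip(wins, wins[1:]):
        if wa[1] > wb[0]:
            raise ValueError(f"windows {la!r} and {lb!r} overlap")
    piy = {
        label: np.array([integrate_peak(s, win) for s in spectra])
        for label, win in fragment_windows.items()
    }
    scan = IonYieldScan(energies_eV, piy)
    if step_bounds is not None:
        scan.validate_step(step_bounds)
    return scan


def nominal_windows(nominal_mz_values, half_width: float = 0.5) -> dict:
    """±half_width integration windows around nominal m/z peak positions."""
    return {str(m): (m - half_width, m + half_width) for m in nominal_mz_values}


def broaden_sticks(
    sticks: StickSpectrum,
    fwhm_eV: float = DEFAULT_FWHM_EV,
    shift_eV: float = DEFAULT_SHIFT_EV,
    energy_grid=None,
    grid_step: float | None = None,
    pad_sigmas: float = 6.0,
):
    """Convolve a stick spectrum with a unit-area Gaussian and shift it.

    S(E) = sum_k f_k * G(E - E_k - shift; sigma = fwhm / sqrt(8 ln 2)).
    The kernel is unit-area, so the integrated dense spectrum equals the
    summed stick strength (to quadrature accuracy; the default grid step of
    fwhm/20 keeps that error well below 0.1%).

    Returns (energy grid, dense spectrum).
    """
    if fwhm_eV <= 0:
        raise ValueError("FWHM must be positive")
    sigma = fwhm_eV / np.sqrt(8.0 * np.log(2.0))
    centers = sticks.energies_eV + shift_eV
    if energy_grid is None:
        step = grid_step if grid_step is not None else fwhm_eV / 20.0
        lo = centers.min() - pad_sigmas * sigma
        hi = centers.max() + pad_sigmas * sigma
        energy_grid = np.arange(lo, hi + step, step)
    else:
        energy_grid = np.asarray(energy_grid, float)
    dense = np.zeros_like(energy_grid)
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    for e_k, f_k in zip(centers, sticks.strengths):
        dense += f_k * norm * np.exp(-0.5 * ((energy_grid - e_k) / sigma) ** 2)
    return energy_grid, dense
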