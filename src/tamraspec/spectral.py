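"""Gaussian-broadened UV-vis absorption spectra from vertical excitations.

A TD-DFT calculation reports, per excited state, a vertical excitation
energy ``E_k`` (eV) and a dimensionless oscillator strength ``f_k``.  The
absorption band shape is modelled as a sum of Gaussians composed in the
*energy* domain,

    I(E) = sum_k f_k * exp(-(E - E_k)^2 / (2 sigma^2)),

with ``sigma`` derived from a half-width-at-half-maximum of 0.1 eV by
default, and evaluated on a wavelength grid (nm) through ``E = hc/lambda``.
Intensities are in arbitrary units proportional to oscillator strength; no
molar-absorptivity prefactor is applied, since ensemble analyses compare
band positions and shapes, not absolute extinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, DomainError, GridError, NoPeakError

__all__ = [
    "HC_EV_NM",
    "VerticalExcitation",
    "ExcitationSet",
    "BroadeningParams",
    "Spectrum",
    "energy_to_wavelength",
    "wavelength_to_energy",
    "hwhm_to_sigma",
    "broaden",
    "average_spectra",
    "resample_spectrum",
    "find_lambda_max",
    "band_shift",
    "normalize_spectrum",
]

#: Planck constant times speed of light, eV*nm (CODATA-derived).
HC_EV_NM = 1239.84193


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VerticalExcitation:
    """One electronic excited state of one conformer.

    Parameters
    ----------
    state_index : int
        1-based index; states are numbered in order of increasing energy.
    energy_eV : float
        Vertical excitation energy in eV, > 0.
    oscillator_strength : float
        Dimensionless transition intensity, >= 0.
    character : str, optional
        Free-form label such as ``"pi-pi*"``, ``"CT"`` or ``"pCT"``.
    mo_contributions : tuple of (int, int, float), optional
        (occupied MO, unoccupied MO, percent) pairs; percents in (0, 100].
    """

    state_index: int
    energy_eV: float
    oscillator_strength: float
    character: str | None = None
    mo_contributions: tuple[tuple[int, int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.state_index < 1:
            raise DomainError(f"state_index must be >= 1, got {self.state_index}")
        if not self.energy_eV > 0:
            raise DomainError(f"energy_eV must be positive, got {self.energy_eV}")
        if self.oscillator_strength < 0:
            raise DomainError(
                f"oscillator_strength must be >= 0, got {self.oscillator_strength}"
            )
        for occ, unocc, pct in self.mo_contributions:
            if not 0 < pct <= 100:
                raise DomainError(f"MO contribution percent {pct} not in (0, 100]")

    @property
    def wavelength_nm(self) -> float:
        return energy_to_wavelength(self.energy_eV)


@dataclass(frozen=True)
class ExcitationSet:
    """Energy-ordered excited states of a single conformer.

    An empty state list is legal and represents "no transitions": such a
    conformer contributes a zero spectrum, which lets all-dark snapshots
    participate in ensemble averages.
    """

    conformer_id: str
    states: tuple[VerticalExcitation, ...]

    def __post_init__(self) -> None:
        states = tuple(self.states)
        object.__setattr__(self, "states", states)
        energies = [s.energy_eV for s in states]
        if any(b < a for a, b in zip(energies, energies[1:])):
            raise DomainError(
                f"states of {self.conformer_id!r} are not energy-ordered"
            )

    def __len__(self) -> int:
        return len(self.states)

    @staticmethod
    def from_pairs(
        conformer_id: str, pairs: Iterable[tuple[float, float]]
    ) -> "ExcitationSet":
        """Build from (energy_eV, oscillator_strength) pairs, sorting by energy."""
        ordered = sorted(pairs, key=lambda p: p[0])
        states = tuple(
            VerticalExcitation(i + 1, e, f) for i, (e, f) in enumerate(ordered)
        )
        return ExcitationSet(conformer_id, states)


@dataclass(frozen=True)
class BroadeningParams:
    """Gaussian band-broadening settings.

    ``hwhm_eV`` is the half-width at half-maximum of each band in energy;
    the Gaussian standard deviation is ``hwhm / sqrt(2 ln 2)``.  The default
    grid (300-800 nm at 0.5 nm) covers the visible band system of
    rhodamine-family dyes.
    """

    hwhm_eV: float = 0.1
    lineshape: str = "gaussian"
    grid_min_nm: float = 300.0
    grid_max_nm: float = 800.0
    grid_step_nm: float = 0.5

    def __post_init__(self) -> None:
        if not self.hwhm_eV > 0:
            raise ConfigError(f"hwhm_eV must be positive, got {self.hwhm_eV}")
        if self.lineshape != "gaussian":
            raise ConfigError(f"unsupported lineshape {self.lineshape!r}")
        if not (self.grid_min_nm > 0 and self.grid_max_nm > self.grid_min_nm):
            raise ConfigError(
                f"invalid grid range [{self.grid_min_nm}, {self.grid_max_nm}]"
            )
        if not self.grid_step_nm > 0:
            raise ConfigError(f"grid_step_nm must be positive, got {self.grid_step_nm}")

    @property
    def sigma_eV(self) -> float:
        return hwhm_to_sigma(self.hwhm_eV)

    def wavelength_grid(self) -> np.ndarray:
        n = int(round((self.grid_max_nm - self.grid_min_nm) / self.grid_step_nm)) + 1
        return self.grid_min_nm + self.grid_step_nm * np.arange(n)


@dataclass(frozen=True)
class Spectrum:
    """Intensity sampled on a strictly increasing wavelength grid (nm)."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", inten)
        if wl.ndim != 1 or inten.ndim != 1 or wl.size != inten.size:
            raise GridError("wavelengths and intensities must be 1-D and equal length")
        if wl.size == 0:
            raise GridError("empty spectrum grid")
        if not np.all(np.diff(wl) > 0):
            raise GridError("wavelength grid must be strictly increasing")
        if np.any(inten < 0):
            raise DomainError("spectrum intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.wavelengths_nm)

    def with_meta(self, **kwargs) -> "Spectrum":
        return replace(self, meta={**self.meta, **kwargs})


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------

def energy_to_wavelength(energy_eV: float) -> float:
    """Convert photon energy (eV) to vacuum wavelength (nm).

    Strictly decreasing; uses hc = 1239.84193 eV nm.
    """
    energy = np.asarray(energy_eV, dtype=float)
    if np.any(energy <= 0):
        raise DomainError(f"energy must be positive, got {energy_eV}")
    out = HC_EV_NM / energy
    return float(out) if out.ndim == 0 else out


def wavelength_to_energy(wavelength_nm: float) -> float:
    """Inverse of :func:`energy_to_wavelength` (the map is an involution)."""
    wl = np.asarray(wavelength_nm, dtype=float)
    if np.any(wl <= 0):
        raise DomainError(f"wavelength must be positive, got {wavelength_nm}")
    out = HC_EV_NM / wl
    return float(out) if out.ndim == 0 else out


def hwhm_to_sigma(hwhm: float) -> float:
    """Gaussian standard deviation for a given half-width at half-maximum."""
    if not hwhm > 0:
        raise DomainError(f"hwhm must be positive, got {hwhm}")
    return hwhm / np.sqrt(2.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# Broadening and spectrum algebra
# ---------------------------------------------------------------------------

def broaden(
    excitations: ExcitationSet, params: BroadeningParams | None = None
) -> Spectrum:
    """Sum of oscillator-strength-scaled Gaussians on the wavelength grid.

    Composition happens in the energy domain: each grid wavelength is mapped
    to ``E = hc/lambda`` and the Gaussian sum is evaluated there.  An empty
    excitation set yields the all-zero spectrum on the full grid.
    """
    params = params or BroadeningParams()
    grid_nm = params.wavelength_grid()
    if not excitations.states:
        intens = np.zeros_like(grid_nm)
    else:
        grid_eV = HC_EV_NM / grid_nm
        energies = np.array([s.energy_eV for s in excitations.states])
        strengths = np.array([s.oscillator_strength for s in excitations.states])
        sigma = params.sigma_eV
        # (n_grid, n_states) residuals; vectorized double loop
        resid = grid_eV[:, None] - energies[None, :]
        intens = (strengths[None, :] * np.exp(-resid**2 / (2.0 * sigma**2))).sum(axis=1)
    meta = {
        "source": excitations.conformer_id,
        "n_states": len(excitations),
        "hwhm_eV": params.hwhm_eV,
    }
    return Spectrum(grid_nm, intens, meta)


def average_spectra(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of spectra sharing one grid.

    Mismatched grids raise; resample first with :func:`resample_spectrum`.
    """
    if len(spectra) == 0:
        raise DomainError("cannot average an empty list of spectra")
    grid = spectra[0].wavelengths_nm
    for s in spectra[1:]:
        if len(s) != len(grid) or not np.array_equal(s.wavelengths_nm, grid):
            raise GridError("spectra must share an identical wavelength grid")
    # extended-precision accumulation keeps the mean of k identical spectra
    # bit-identical to the input
    stacked = np.array([s.intensities for s in spectra])
    mean = np.mean(stacked, axis=0, dtype=np.longdouble).astype(np.float64)
    return Spectrum(grid.copy(), mean, {"n_conformers": len(spectra)})


def resample_spectrum(spectrum: Spectrum, target_grid_nm) -> Spectrum:
    """Linear interpolation onto a new grid; zero outside the source support."""
    target = np.asarray(target_grid_nm, dtype=float)
    if target.size == 0:
        raise DomainError("target grid is empty")
    if not np.all(np.diff(target) > 0):
        raise GridError("target grid must be strictly increasing")
    values = np.interp(
        target, spectrum.wavelengths_nm, spectrum.intensities, left=0.0, right=0.0
    )
    return Spectrum(target, values, dict(spectrum.meta))


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex abscissa of the parabola through points i-1, i, i+1 (clamped)."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(x[i])
    # uniform-grid vertex offset in units of the local spacing
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = 0.5 * (x[i + 1] - x[i - 1])
    return float(x[i] + delta * step)


def find_lambda_max(
    spectrum: Spectrum, window_nm: tuple[float, float] | None = None
) -> float:
    """Wavelength of the global intensity maximum, parabolically refined.

    Ties at the grid resolution are broken toward longer wavelength.  An
    all-zero spectrum (within the window) has no peak and raises.
    """
    wl = spectrum.wavelengths_nm
    inten = spectrum.intensities
    if window_nm is not None:
        lo, hi = window_nm
        mask = (wl >= lo) & (wl <= hi)
        if not mask.any():
            raise NoPeakError(f"window {window_nm} contains no grid points")
        wl, inten = wl[mask], inten[mask]
    if np.all(inten == 0):
        raise NoPeakError("spectrum is identically zero; no peak to locate")
    peak = inten.max()
    # ties -> longest wavelength
    i = int(np.flatnonzero(inten == peak)[-1])
    return _parabolic_refine(wl, inten, i)


def band_shift(
    spec_a: Spectrum,
    spec_b: Spectrum,
    window_nm: tuple[float, float] | None = None,
) -> float:
    """lambda_max(b) - lambda_max(a); positive means b is red-shifted vs a."""
    return find_lambda_max(spec_b, window_nm) - find_lambda_max(spec_a, window_nm)


def normalize_spectrum(spectrum: Spectrum, mode: str = "max") -> Spectrum:
    """Scale to unit peak (``max``) or unit trapezoidal area (``area``).

    Pure scaling, so the peak position is invariant.
    """
    inten = spectrum.intensities
    if np.all(inten == 0):
        raise DomainError("cannot normalize an all-zero spectrum")
    if mode == "max":
        scale = inten.max()
    elif mode == "area":
        scale = np.trapezoid(inten, spectrum.wavelengths_nm)
    else:
        raise DomainError(f"unknown normalization mode {mode!r}")
    return Spectrum(
        spectrum.wavelengths_nm.copy(),
        inten / scale,
        {**spectrum.meta, "normalized": mode},
    )
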