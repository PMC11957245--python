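"""Synthetic conformer ensembles and the experimental-style reference band.

Real inputs for this analysis would be snapshots from classical MD of the
solvated dye (and, for the dimethylamine torsion, ab initio dynamics of a
reduced model).  Neither trajectory type is deposited anywhere, so this
module generates dihedral-deviation ensembles with the statistical
structure those simulations exhibit:

* classical-MD-like deviations from the optimized geometry — phenyl stays
  within ~20 degrees of perpendicular, the carboxylate twists 10-15
  degrees, and the dimethylamine groups are floppy with a density peak
  near 40 degrees and support out to 100 degrees;
* BOMD-like dimethylamine deviations from planarity — most probable value
  near 20 degrees, support up to 90 degrees.

All distributions are truncated normals (optionally mixtures thereof)
parameterized by mode, spread and truncation bounds; draws are fully
reproducible from the spec's seed.  The generators emulate marginal
dihedral distributions only: snapshots are drawn independently, with no
autocorrelation in time and no coupling between groups, both of which real
trajectories have.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError
from .geometry import DihedralSample, fold_deviation
from .spectral import BroadeningParams, Spectrum, broaden
from .surrogate import SurrogateModel, conformer_to_excitations

__all__ = [
    "TruncatedNormal",
    "Mixture",
    "EnsembleSpec",
    "Snapshot",
    "MD_DEFAULTS",
    "BOMD_DEFAULT",
    "sample_md_ensemble",
    "sample_bomd_ensemble",
    "ensemble_to_spectra",
    "make_experimental_reference",
]


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mode, sigma) truncated to [lo, hi], in degrees.

    The mode parameter is the location of the untruncated normal; as long
    as it lies inside the bounds it is also the density mode of the
    truncated law.
    """

    mode_deg: float
    sigma_deg: float
    lo_deg: float
    hi_deg: float

    def __post_init__(self) -> None:
        if not self.lo_deg <= self.mode_deg <= self.hi_deg:
            raise DomainError(
                f"mode {self.mode_deg} outside truncation [{self.lo_deg}, {self.hi_deg}]"
            )
        if not self.sigma_deg > 0:
            raise DomainError(f"sigma must be positive, got {self.sigma_deg}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        a = (self.lo_deg - self.mode_deg) / self.sigma_deg
        b = (self.hi_deg - self.mode_deg) / self.sigma_deg
        return stats.truncnorm.rvs(
            a, b, loc=self.mode_deg, scale=self.sigma_deg, size=n, random_state=rng
        )


@dataclass(frozen=True)
class Mixture:
    """Weighted mixture of truncated normals (weights need not be normalized)."""

    components: tuple[tuple[float, TruncatedNormal], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise DomainError("mixture needs at least one component")
        if any(w <= 0 for w, _ in self.components):
            raise DomainError("mixture weights must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        weights = np.array([w for w, _ in self.components], dtype=float)
        weights /= weights.sum()
        choice = rng.choice(len(weights), size=n, p=weights)
        out = np.empty(n)
        for k, (_, comp) in enumerate(self.components):
            mask = choice == k
            out[mask] = comp.sample(rng, int(mask.sum()))
        return out


#: Classical-MD-like deviation distributions per rotor group (degrees).
MD_DEFAULTS: dict[str, TruncatedNormal] = {
    "Ph": TruncatedNormal(5.0, 7.0, 0.0, 20.0),
    "COO": TruncatedNormal(12.5, 5.0, 0.0, 45.0),
    "NMe2": TruncatedNormal(40.0, 22.0, 0.0, 100.0),
}

#: BOMD-like dimethylamine deviation-from-planarity distribution (degrees).
BOMD_DEFAULT = TruncatedNormal(20.0, 18.0, 0.0, 90.0)


@dataclass(frozen=True)
class EnsembleSpec:
    """Generator settings: ensemble size, seed and per-group distributions."""

    n_snapshots: int = 100
    seed: int = 0
    groups: Mapping[str, TruncatedNormal | Mixture] = field(
        default_factory=lambda: dict(MD_DEFAULTS)
    )

    def __post_init__(self) -> None:
        if self.n_snapshots < 1:
            raise DomainError(f"n_snapshots must be >= 1, got {self.n_snapshots}")
        if not self.groups:
            raise DomainError("at least one group distribution is required")


@dataclass(frozen=True)
class Snapshot:
    """One synthetic conformer: id plus per-group dihedral deviations (deg)."""

    snapshot_id: str
    deviations: Mapping[str, float]


def sample_md_ensemble(spec: EnsembleSpec | None = None) -> list[Snapshot]:
    """Draw an MD-like ensemble of per-group dihedral deviations.

    Deviations are reported on each distribution's native range (the
    dimethylamine default extends to 100 degrees); folding to the
    surrogate's [0, 90] domain happens at spectrum time.
    """
    spec = spec or EnsembleSpec()
    rng = np.random.default_rng(spec.seed)
    draws = {
        group: dist.sample(rng, spec.n_snapshots)
        for group, dist in spec.groups.items()
    }
    return [
        Snapshot(f"snap{i:04d}", {g: float(draws[g][i]) for g in spec.groups})
        for i in range(spec.n_snapshots)
    ]


def sample_bomd_ensemble(
    n: int = 5000, seed: int = 0, dist: TruncatedNormal | Mixture = BOMD_DEFAULT
) -> DihedralSample:
    """Draw BOMD-like dimethylamine deviations from planarity."""
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return DihedralSample("d_NMe2", dist.sample(rng, n), source="bomd")


def ensemble_to_spectra(
    ensemble: Sequence[Snapshot],
    model: SurrogateModel,
    params: BroadeningParams | None = None,
) -> list[Spectrum]:
    """Per-snapshot broadened spectra via the rotation surrogate.

    Each deviation is folded into [0, 90] (two-fold rotor symmetry) before
    surrogate evaluation; snapshot order is preserved.
    """
    params = params or BroadeningParams()
    out = []
    for snap in ensemble:
        folded = {
            g: fold_deviation(d, 0.0, 180.0) for g, d in snap.deviations.items()
        }
        excitations = conformer_to_excitations(model, folded, snap.snapshot_id)
        out.append(broaden(excitations, params))
    return out


# --- experimental-style reference band --------------------------------------

#: Width of the main (550 nm) band, nm.
REF_SIGMA_MAIN_NM = 18.0
#: Width of the secondary (510 nm) band, nm; broad enough that the envelope
#: decays into the ~400 nm region.
REF_SIGMA_SECONDARY_NM = 33.0
#: Secondary/main peak ratio.
REF_SECONDARY_RATIO = 0.6


def make_experimental_reference(
    params: BroadeningParams | None = None,
    main_nm: float = 550.0,
    secondary_nm: float = 510.0,
    ratio: float = REF_SECONDARY_RATIO,
    sigma_main_nm: float = REF_SIGMA_MAIN_NM,
    sigma_secondary_nm: float = REF_SIGMA_SECONDARY_NM,
) -> Spectrum:
    """Two-Gaussian stand-in for the measured dye absorption band.

    Synthetic: models the measured band system of the dye in buffer — a
    strong band at 550 nm with a less intense shoulder near 510 nm and a
    tail reaching roughly 400 nm — as two Gaussians in wavelength,
    peak-normalized.  Because the bands overlap, placing the main Gaussian
    exactly at 550 nm would drag the *composite* maximum a few nm to the
    blue; the main-band center is therefore calibrated (fixed-point
    iteration on a fine grid) so the composite global maximum sits at
    ``main_nm``.
    """
    params = params or BroadeningParams()

    def composite(center: float, wl: np.ndarray) -> np.ndarray:
        return np.exp(-((wl - center) ** 2) / (2 * sigma_main_nm**2)) + ratio * np.exp(
            -((wl - secondary_nm) ** 2) / (2 * sigma_secondary_nm**2)
        )

    fine = np.arange(main_nm - 30.0, main_nm + 30.0, 0.01)
    center = main_nm
    for _ in range(20):
        peak = fine[np.argmax(composite(center, fine))]
        if abs(peak - main_nm) < 5e-3:
            break
        center += main_nm - peak

    grid = params.wavelength_grid()
    intens = composite(center, grid)
    intens /= intens.max()
    return Spectrum(
        grid,
        intens,
        {
            "source": "experimental_reference(synthetic)",
            "main_nm": main_nm,
            "secondary_nm": secondary_nm,
        },
    )
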