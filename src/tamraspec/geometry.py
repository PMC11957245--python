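"""Dihedral-angle analysis of conformer snapshots.

The dye's flexibility lives in three rotatable groups: the pendant
dicarboxyphenyl ring (d_Ph), the carboxylate on that ring (d_COO), and the
two dimethylamine groups on the xanthene core (d_NMe2).  Snapshots from
dynamics are reduced to per-group torsion angles, folded into deviations
from a reference geometry using the rotor's symmetry period, and summarized
by kernel density estimates (Scott's-rule bandwidth) and rotamer-bin
populations.

Angles follow the IUPAC torsion convention: looking along the central bond
from atom 2 to atom 3, a clockwise rotation of the far bond relative to the
near bond is positive; values lie in (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, CoverageError, DomainError, GeometryError

__all__ = [
    "ConformerStructure",
    "DihedralSpec",
    "DihedralSample",
    "KdeResult",
    "dihedral_angle",
    "fold_deviation",
    "kde_scott",
    "rotamer_populations",
    "deviation_summary",
]

#: Bandwidth floor (degrees) guarding near-degenerate samples.
KDE_BANDWIDTH_FLOOR_DEG = 0.5
#: KDE evaluation-grid spacing (degrees).
KDE_GRID_STEP_DEG = 0.25
#: Grid padding beyond the sample range, in bandwidths.
KDE_GRID_PAD_BW = 5.0


@dataclass(frozen=True)
class ConformerStructure:
    """Cartesian snapshot: element symbols plus (n, 3) coordinates in Angstrom."""

    atom_names: tuple[str, ...]
    coordinates: np.ndarray
    frame_id: int = 0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "atom_names", tuple(self.atom_names))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError("coordinates must have shape (n_atoms, 3)")
        if len(self.atom_names) != coords.shape[0]:
            raise GeometryError("atom_names and coordinates length mismatch")
        if coords.shape[0] < 4:
            raise GeometryError("a structure needs at least 4 atoms")
        if not np.all(np.isfinite(coords)):
            raise GeometryError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)


@dataclass(frozen=True)
class DihedralSpec:
    """Four 0-based atom indices defining a torsion, plus rotor symmetry.

    ``symmetry_period_deg`` is 180 for two-fold symmetric rotors (phenyl,
    carboxylate, dimethylamine: a half-turn is chemically equivalent) and
    360 otherwise.
    """

    name: str
    atom_indices: tuple[int, int, int, int]
    symmetry_period_deg: float = 360.0

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.atom_indices)
        object.__setattr__(self, "atom_indices", idx)
        if len(set(idx)) != 4:
            raise ConfigError(f"dihedral {self.name!r}: indices must be distinct")
        if any(i < 0 for i in idx):
            raise ConfigError(f"dihedral {self.name!r}: indices must be >= 0")
        period = self.symmetry_period_deg
        if not period > 0 or 360.0 % period != 0:
            raise ConfigError(
                f"dihedral {self.name!r}: period {period} must divide 360"
            )


@dataclass(frozen=True)
class DihedralSample:
    """A set of torsion observations (degrees, in (-180, 180])."""

    name: str
    angles_deg: np.ndarray
    source: str = "synthetic"  # md | bomd | synthetic

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles_deg, dtype=float)
        object.__setattr__(self, "angles_deg", angles)
        if angles.ndim != 1:
            raise DomainError("angles_deg must be one-dimensional")
        if angles.size and (angles.min() <= -180.0 or angles.max() > 180.0):
            raise DomainError("angles must lie in (-180, 180]")

    def __len__(self) -> int:
        return len(self.angles_deg)


@dataclass(frozen=True)
class KdeResult:
    """Scott's-rule Gaussian KDE on a regular grid, with the refined mode."""

    grid_deg: np.ndarray
    density: np.ndarray
    mode_deg: float
    bandwidth_deg: float
    degenerate: bool = False


def dihedral_angle(structure: ConformerStructure, spec: DihedralSpec) -> float:
    """Signed torsion (degrees) of four atoms, IUPAC sign convention.

    Invariant under rigid rotation and translation; the sign flips under
    reflection.  Raises :class:`GeometryError` when a consecutive atom
    triplet is collinear (the torsion plane is undefined).
    """
    idx = spec.atom_indices
    if max(idx) >= structure.n_atoms:
        raise ConfigError(
            f"dihedral {spec.name!r}: index {max(idx)} out of range "
            f"for {structure.n_atoms} atoms"
        )
    p0, p1, p2, p3 = structure.coordinates[list(idx)]
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2_norm = np.linalg.norm(b2)
    scale = max(np.linalg.norm(b1), 1.0) * max(np.linalg.norm(b3), 1.0) * max(b2_norm, 1.0)
    if np.linalg.norm(n1) < 1e-10 * scale or np.linalg.norm(n2) < 1e-10 * scale:
        raise GeometryError(
            f"dihedral {spec.name!r}: collinear consecutive atoms, torsion undefined"
        )
    angle = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2) / b2_norm, np.dot(n1, n2)))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def fold_deviation(angle_deg, reference_deg: float, period_deg: float):
    """Minimal absolute circular distance modulo the rotor period.

    The result lies in ``[0, period/2]``; e.g. with a 180-degree period an
    angle of 110 off a reference of 0 folds to 70.  Accepts scalars or
    arrays.
    """
    if not period_deg > 0:
        raise DomainError(f"period must be positive, got {period_deg}")
    diff = np.mod(np.asarray(angle_deg, dtype=float) - reference_deg, period_deg)
    folded = np.minimum(diff, period_deg - diff)
    return float(folded) if folded.ndim == 0 else folded


def kde_scott(
    sample: DihedralSample, eval_grid_deg: np.ndarray | None = None
) -> KdeResult:
    """Gaussian-kernel density estimate with Scott's-rule bandwidth.

    Bandwidth ``h = sigma_hat * n^(-1/5)`` with ``sigma_hat`` the plain
    sample standard deviation (ddof=1), floored at 0.5 degrees.  The default
    evaluation grid spans the sample range padded by 5 bandwidths at 0.25
    degree spacing.  The mode is the grid argmax refined by a 3-point
    parabola.  A zero-variance sample returns a degenerate point-mass
    result with its value as the mode.
    """
    values = np.asarray(sample.angles_deg, dtype=float)
    if values.size < 2:
        raise DomainError("KDE requires at least 2 observations")
    if not np.all(np.isfinite(values)):
        raise DomainError("KDE sample contains non-finite values")
    std = float(np.std(values, ddof=1))
    if std == 0.0:
        grid = np.array([values[0]])
        return KdeResult(grid, np.array([np.inf]), float(values[0]),
                         KDE_BANDWIDTH_FLOOR_DEG, degenerate=True)
    h = max(std * len(values) ** (-1.0 / 5.0), KDE_BANDWIDTH_FLOOR_DEG)
    if eval_grid_deg is None:
        lo = values.min() - KDE_GRID_PAD_BW * h
        hi = values.max() + KDE_GRID_PAD_BW * h
        n = int(np.ceil((hi - lo) / KDE_GRID_STEP_DEG)) + 1
        grid = lo + KDE_GRID_STEP_DEG * np.arange(n)
    else:
        grid = np.asarray(eval_grid_deg, dtype=float)
    resid = (grid[:, None] - values[None, :]) / h
    density = np.exp(-0.5 * resid**2).sum(axis=1) / (
        len(values) * h * np.sqrt(2.0 * np.pi)
    )
    i = int(np.argmax(density))
    mode = _refine_mode(grid, density, i)
    return KdeResult(grid, density, mode, h)


def _refine_mode(x: np.ndarray, y: np.ndarray, i: int) -> float:
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    delta = float(np.clip(0.5 * (y[i - 1] - y[i + 1]) / denom, -0.5, 0.5))
    return float(x[i] + delta * (x[i + 1] - x[i]))


def rotamer_populations(
    sample: DihedralSample, bin_edges_deg: Sequence[float]
) -> np.ndarray:
    """Fraction of observations per angular bin.

    Bins are half-open ``[lo, hi)`` with the last bin closed; the edges must
    cover every observation.  Fractions sum to 1.
    """
    edges = np.asarray(bin_edges_deg, dtype=float)
    if edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise DomainError("bin edges must be strictly increasing, length >= 2")
    values = np.asarray(sample.angles_deg, dtype=float)
    if values.size == 0:
        raise DomainError("cannot bin an empty sample")
    if values.min() < edges[0] or values.max() > edges[-1]:
        raise CoverageError(
            f"sample range [{values.min():g}, {values.max():g}] exceeds "
            f"bin coverage [{edges[0]:g}, {edges[-1]:g}]"
        )
    counts, _ = np.histogram(values, bins=edges)  # numpy: last bin closed
    return counts / values.size


@dataclass(frozen=True)
class DeviationSummary:
    """Per-group deviation statistics: KDE mode, central 50% interval, max."""

    name: str
    mode_deg: float
    q25_deg: float
    q75_deg: float
    max_deg: float
    n: int


def deviation_summary(
    samples: Sequence[DihedralSample],
    reference: Mapping[str, float],
    period_deg: float | Mapping[str, float] = 180.0,
) -> dict[str, DeviationSummary]:
    """Fold each sample against its reference angle and summarize.

    ``reference`` must provide an entry for every sample name.  Deviations
    are folded by :func:`fold_deviation` with the given period (scalar or
    per-name mapping), then summarized by the Scott's-rule KDE mode,
    quartiles and maximum.
    """
    out: dict[str, DeviationSummary] = {}
    for sample in samples:
        if sample.name not in reference:
            raise ConfigError(f"no reference angle supplied for {sample.name!r}")
        period = (
            period_deg[sample.name]
            if isinstance(period_deg, Mapping)
            else period_deg
        )
        dev = fold_deviation(sample.angles_deg, reference[sample.name], period)
        dev = np.atleast_1d(dev)
        if dev.size >= 2 and np.std(dev, ddof=1) > 0:
            mode = kde_scott(DihedralSample(sample.name, dev, sample.source)).mode_deg
        else:
            mode = float(dev[0])
        q25, q75 = np.percentile(dev, [25.0, 75.0])
        out[sample.name] = DeviationSummary(
            sample.name, mode, float(q25), float(q75), float(dev.max()), dev.size
        )
    return out
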