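"""Conformation-to-excitation surrogate built from constrained rotation scans.

Re-running TD-DFT for every snapshot of an ensemble is expensive; instead,
the package interpolates a printed table of constrained-rotation results:
for each rotatable group (phenyl, carboxylate, dimethylamine) the table
gives, at a handful of rotation angles away from the planar optimum, the
two lowest vertical excitations (energy in eV, oscillator strength).

Between nodes, energy and oscillator strength are interpolated per state
with shape-preserving monotone piecewise cubics (PCHIP), which reproduce
every node exactly and never overshoot — so oscillator strengths cannot go
negative between nodes.

For a snapshot where several groups deviate simultaneously the surrogate
uses a first-order independence heuristic relative to the shared planar
reference: energy shifts add, oscillator-strength ratios multiply.  The
underlying scans rotate one group at a time, so this combination rule is a
documented approximation, not a fitted model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import DomainError, IntegrityError
from .spectral import ExcitationSet, VerticalExcitation

__all__ = [
    "GROUPS",
    "RotationScanTable",
    "SurrogateModel",
    "load_packaged_scan",
    "build_surrogate",
    "interpolate_group",
    "conformer_to_excitations",
]

GROUPS = ("Ph", "COO", "NMe2")

_SCAN_RESOURCE = "rotation_scan.tsv"
_SCAN_SHA256 = "7fa7c4ece51c5c79aa19aefcd0fc46aafaec051f89f430f9587361e895f0b9b1"


@dataclass(frozen=True)
class RotationScanTable:
    """Per-group rotation-scan nodes.

    ``nodes[group]`` maps to ``(angles, records)`` where ``angles`` is a
    strictly increasing array starting at 0 and ``records[i]`` is a tuple of
    ``(excit_no, energy_eV, f)`` per state at ``angles[i]``.  The planar
    reference node (delta = 0) is shared by all groups.
    """

    nodes: Mapping[str, tuple[np.ndarray, tuple[tuple[tuple[int, float, float], ...], ...]]]

    def __post_init__(self) -> None:
        for group, (angles, records) in self.nodes.items():
            if angles[0] != 0.0 or not np.all(np.diff(angles) > 0):
                raise DomainError(
                    f"scan for {group!r}: node angles must start at 0 and increase"
                )
            for recs in records:
                for _, energy, f in recs:
                    if not energy > 0 or f < 0:
                        raise DomainError(f"scan for {group!r}: invalid node record")

    @property
    def reference(self) -> tuple[tuple[int, float, float], ...]:
        first = next(iter(self.nodes))
        return self.nodes[first][1][0]


@dataclass(frozen=True)
class SurrogateModel:
    """PCHIP interpolants of (E, f) vs rotation angle for each group/state."""

    scan: RotationScanTable
    _interp: Mapping[str, tuple]  # group -> ((E_interp, f_interp) per state)

    @property
    def reference_excitations(self) -> ExcitationSet:
        states = tuple(
            VerticalExcitation(no, energy, f)
            for no, energy, f in self.scan.reference
        )
        return ExcitationSet("planar_reference", states)

    @property
    def max_angle(self) -> dict[str, float]:
        return {g: float(angles[-1]) for g, (angles, _) in self.scan.nodes.items()}


def load_packaged_scan() -> RotationScanTable:
    """Load the packaged constrained-rotation calibration table.

    The file is checksum-verified; a mismatch means the installation is
    corrupted and raises :class:`IntegrityError`.
    """
    raw = resources.files("tamraspec").joinpath("data", _SCAN_RESOURCE).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _SCAN_SHA256:
        raise IntegrityError(
            f"packaged rotation scan failed checksum ({digest[:12]}...)"
        )
    import io

    import pandas as pd

    df = pd.read_csv(io.BytesIO(raw), sep="\t")
    ref = df[df["group"] == "ref"].sort_values("state")
    ref_records = tuple(
        (int(r.state), float(r.energy_eV), float(r.f)) for r in ref.itertuples()
    )
    nodes: dict[str, tuple[np.ndarray, tuple]] = {}
    for group in GROUPS:
        sub = df[df["group"] == group]
        angles = [0.0]
        records = [ref_records]
        for delta in sorted(sub["delta_deg"].unique()):
            rows = sub[sub["delta_deg"] == delta].sort_values("state")
            angles.append(float(delta))
            records.append(
                tuple(
                    (int(r.state), float(r.energy_eV), float(r.f))
                    for r in rows.itertuples()
                )
            )
        nodes[group] = (np.asarray(angles), tuple(records))
    return RotationScanTable(nodes)


def build_surrogate(scan: RotationScanTable | None = None) -> SurrogateModel:
    """Construct the interpolating surrogate from a scan table."""
    scan = scan or load_packaged_scan()
    interp: dict[str, tuple] = {}
    for group, (angles, records) in scan.nodes.items():
        n_states = len(records[0])
        per_state = []
        for k in range(n_states):
            energies = np.array([recs[k][1] for recs in records])
            strengths = np.array([recs[k][2] for recs in records])
            per_state.append(
                (PchipInterpolator(angles, energies), PchipInterpolator(angles, strengths))
            )
        interp[group] = tuple(per_state)
    return SurrogateModel(scan, interp)


def interpolate_group(
    model: SurrogateModel, group: str, delta_deg: float
) -> list[tuple[float, float]]:
    """Interpolated (energy_eV, f) per state at a single-group rotation.

    ``delta_deg`` is a folded deviation in [0, 90]; angles beyond a group's
    last scan node clamp to that node.  Oscillator strengths are floored at
    zero (PCHIP cannot overshoot, so the floor only clips rounding noise).
    """
    if group not in model._interp:
        raise DomainError(f"unknown rotor group {group!r}; expected one of {GROUPS}")
    if delta_deg < 0:
        raise DomainError(f"delta_deg must be >= 0 (folded), got {delta_deg}")
    angles, records = model.scan.nodes[group]
    x = min(float(delta_deg), float(angles[-1]))
    hit = np.flatnonzero(angles == x)
    if hit.size:  # node-exactness, bit for bit
        return [(energy, f) for _, energy, f in records[int(hit[0])]]
    out = []
    for e_interp, f_interp in model._interp[group]:
        out.append((float(e_interp(x)), max(float(f_interp(x)), 0.0)))
    return out


def conformer_to_excitations(
    model: SurrogateModel,
    deviations: Mapping[str, float],
    conformer_id: str = "snapshot",
) -> ExcitationSet:
    """Excitations for a snapshot with several simultaneously rotated groups.

    Relative to the planar reference, per state: energy shifts from each
    group add; oscillator-strength ratios multiply (floored at 0).  States
    are re-sorted by energy after combination.  An all-planar snapshot
    returns the reference set exactly.
    """
    if not deviations:
        raise DomainError("at least one group deviation is required")
    ref = model.scan.reference
    energies = np.array([r[1] for r in ref])
    strengths = np.array([r[2] for r in ref])
    for group, delta in deviations.items():
        vals = interpolate_group(model, group, delta)
        for k, (e_k, f_k) in enumerate(vals):
            energies[k] += e_k - ref[k][1]
            if ref[k][2] > 0:
                strengths[k] *= f_k / ref[k][2]
            else:
                strengths[k] = f_k
    strengths = np.maximum(strengths, 0.0)
    return ExcitationSet.from_pairs(conformer_id, zip(energies, strengths))
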