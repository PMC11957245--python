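"""File formats: neutral excitation tables, QC log blocks, XYZ, spectrum CSV.

The neutral interchange format for excitations is delimited text (TSV by
default) with one row per state or per orbital-pair contribution:

    conformer_id  state  energy_eV  f  [character  occ_mo  unocc_mo  percent]

Energies are stored in eV; wavelengths are always derived on demand from
``hc/E`` so there is a single source of truth and no rounding drift.
Dihedral atom indices used elsewhere in the package are 0-based — note
that most chemistry tools print 1-based atom numbers.

Readers reject structurally invalid input rather than repairing it; the
one documented exception is spectrum rows arriving unsorted, which are
sorted ascending on read.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, SchemaError
from .geometry import ConformerStructure
from .spectral import ExcitationSet, Spectrum, VerticalExcitation

__all__ = [
    "read_excitation_table",
    "write_excitation_table",
    "parse_qc_excited_state_block",
    "read_xyz",
    "write_xyz",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

_REQUIRED_COLUMNS = ("conformer_id", "state", "energy_eV", "f")
_OPTIONAL_COLUMNS = ("character", "occ_mo", "unocc_mo", "percent")


def _detect_sep(path: Path) -> str:
    header = path.read_text().splitlines()[0] if path.read_text() else ""
    return "\t" if "\t" in header else ","


def read_excitation_table(path: str | Path, sep: str | None = None) -> list[ExcitationSet]:
    """Read a neutral excitation table into one ExcitationSet per conformer.

    States are energy-sorted within each conformer; conformers appear in
    file order.  Missing required columns raise :class:`SchemaError`;
    non-numeric energies or oscillator strengths raise :class:`ParseError`
    naming the offending line.
    """
    path = Path(path)
    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")

    out: list[ExcitationSet] = []
    for conformer_id, group in df.groupby("conformer_id", sort=False):
        states: dict[int, dict] = {}
        for idx, row in group.iterrows():
            line_no = idx + 2  # header is line 1
            try:
                state = int(row["state"])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{line_no}: bad state index") from exc
            rec = states.setdefault(state, {"mo": []})
            if row["energy_eV"] != "":
                try:
                    rec["energy_eV"] = float(row["energy_eV"])
                    rec["f"] = float(row["f"])
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name}:{line_no}: non-numeric energy or f"
                    ) from exc
            if row.get("character", ""):
                rec["character"] = row["character"]
            if row.get("occ_mo", "") and row.get("unocc_mo", ""):
                try:
                    rec["mo"].append(
                        (int(row["occ_mo"]), int(row["unocc_mo"]), float(row["percent"]))
                    )
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name}:{line_no}: bad MO contribution"
                    ) from exc
        ordered = sorted(states.values(), key=lambda r: r["energy_eV"])
        excitations = tuple(
            VerticalExcitation(
                i + 1,
                rec["energy_eV"],
                rec["f"],
                rec.get("character"),
                tuple(rec["mo"]),
            )
            for i, rec in enumerate(ordered)
        )
        out.append(ExcitationSet(str(conformer_id), excitations))
    return out


def write_excitation_table(
    sets: Sequence[ExcitationSet], path: str | Path, sep: str = "\t"
) -> None:
    """Write ExcitationSets in the neutral format (full float precision)."""
    rows = []
    for es in sets:
        for s in es.states:
            base = {
                "conformer_id": es.conformer_id,
                "state": s.state_index,
                "energy_eV": repr(float(s.energy_eV)),
                "f": repr(float(s.oscillator_strength)),
                "character": s.character or "",
            }
            if s.mo_contributions:
                for occ, unocc, pct in s.mo_contributions:
                    rows.append({**base, "occ_mo": occ, "unocc_mo": unocc, "percent": pct})
                    base = {**base, "energy_eV": "", "f": ""}  # continuation rows
            else:
                rows.append({**base, "occ_mo": "", "unocc_mo": "", "percent": ""})
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS) + list(_OPTIONAL_COLUMNS)).to_csv(
        path, sep=sep, index=False
    )


_STATE_RE = re.compile(
    r"Excited\s+State\s+(\d+)\s*[:.]?\s*(\S*)\s+"
    r"(\d+(?:\.\d+)?)\s*eV(?:\s+(\d+(?:\.\d+)?)\s*nm)?(.*)$"
)
_F_RE = re.compile(r"f\s*=\s*(\d+(?:\.\d+)?)")
_MO_RE = re.compile(r"^\s*(\d+)\s*->\s*(\d+)\s+(-?\d+\.\d+)\s*$")


def parse_qc_excited_state_block(
    text: str, conformer_id: str = "qc_block"
) -> ExcitationSet:
    """Parse "Excited State n: ... x.xx eV ... f=..." blocks from a TD log.

    Best-effort and dialect-limited: one common block style, tolerant of
    interleaved lines.  Orbital-pair lines ``occ -> unocc  coeff`` are
    converted to percents as ``2 * coeff^2 * 100`` (closed-shell CI
    coefficients).  States missing an oscillator strength are dropped with
    a warning; zero parseable states raise :class:`ParseError`.
    """
    states: list[dict] = []
    current: dict | None = None
    for line in text.splitlines():
        m = _STATE_RE.search(line)
        if m:
            rest = m.group(5) or ""
            fm = _F_RE.search(rest)
            current = {
                "state": int(m.group(1)),
                "energy_eV": float(m.group(3)),
                "f": float(fm.group(1)) if fm else None,
                "character": m.group(2) or None,
                "mo": [],
            }
            states.append(current)
            continue
        mo = _MO_RE.match(line)
        if mo and current is not None:
            coeff = float(mo.group(3))
            pct = min(200.0 * coeff * coeff, 100.0)
            if pct > 0:
                current["mo"].append((int(mo.group(1)), int(mo.group(2)), pct))
    if not states:
        raise ParseError("no excited-state lines recognized in block")
    kept = [s for s in states if s["f"] is not None]
    for s in states:
        if s["f"] is None:
            warnings.warn(
                f"excited state {s['state']} has no oscillator strength; dropped",
                stacklevel=2,
            )
    if not kept:
        raise ParseError("no excited state carried an oscillator strength")
    kept.sort(key=lambda s: s["energy_eV"])
    excitations = tuple(
        VerticalExcitation(
            i + 1, s["energy_eV"], s["f"], s["character"], tuple(s["mo"])
        )
        for i, s in enumerate(kept)
    )
    return ExcitationSet(conformer_id, excitations)


def read_xyz(path: str | Path) -> list[ConformerStructure]:
    """Read a single- or multi-frame XYZ file (coordinates in Angstrom).

    Every frame must have the same atom count and ordering; a mismatch
    raises :class:`FormatError` naming the frame index.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[ConformerStructure] = []
    i = 0
    names0: tuple[str, ...] | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(
                f"{path.name}: frame {len(frames)}: expected atom count, "
                f"got {lines[i]!r}"
            ) from exc
        records = lines[i + 2 : i + 2 + n_atoms]
        if len(records) < n_atoms:
            raise FormatError(
                f"{path.name}: frame {len(frames)}: declared {n_atoms} atoms, "
                f"found {len(records)} records"
            )
        names, coords = [], []
        for rec in records:
            parts = rec.split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path.name}: frame {len(frames)}: malformed record {rec!r}"
                )
            names.append(parts[0])
            try:
                coords.append([float(x) for x in parts[1:4]])
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}: frame {len(frames)}: non-numeric coordinate "
                    f"in {rec!r}"
                ) from exc
        if names0 is None:
            names0 = tuple(names)
        elif tuple(names) != names0:
            raise FormatError(
                f"{path.name}: frame {len(frames)}: atom ordering differs "
                f"from frame 0"
            )
        frames.append(ConformerStructure(tuple(names), np.array(coords), len(frames)))
        i += 2 + n_atoms
    if not frames:
        raise FormatError(f"{path.name}: no frames found")
    return frames


def write_xyz(structures: Sequence[ConformerStructure], path: str | Path) -> None:
    """Write structures as multi-frame XYZ with full float precision."""
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f"{s.n_atoms}\n")
            fh.write(f"frame {s.frame_id}\n")
            for name, (x, y, z) in zip(s.atom_names, s.coordinates):
                fh.write(f"{name} {x:.10f} {y:.10f} {z:.10f}\n")


def read_spectrum_csv(path: str | Path, sep: str | None = None) -> Spectrum:
    """Read a two-column wavelength/intensity file (header required).

    Rows arriving unsorted are sorted ascending by wavelength; duplicate
    wavelengths are ambiguous and raise :class:`FormatError`.
    """
    path = Path(path)
    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.shape[1] < 2:
        raise SchemaError(f"{path.name}: expected two columns, found {df.shape[1]}")
    try:
        wl = df.iloc[:, 0].astype(float).to_numpy()
        inten = df.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path.name}: non-numeric spectrum values") from exc
    order = np.argsort(wl, kind="stable")
    wl, inten = wl[order], inten[order]
    if np.any(np.diff(wl) == 0):
        raise FormatError(f"{path.name}: duplicate wavelengths")
    return Spectrum(wl, inten, {"source": str(path)})


def write_spectrum_csv(spectrum: Spectrum, path: str | Path, sep: str = ",") -> None:
    """Write a spectrum as two-column text; round-trip stable."""
    pd.DataFrame(
        {
            "wavelength_nm": spectrum.wavelengths_nm,
            "intensity": [repr(float(v)) for v in spectrum.intensities],
        }
    ).to_csv(path, sep=sep, index=False)
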