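"""End-to-end orchestration: snapshots -> dihedrals -> surrogate excitations
-> broadened spectra -> ensemble average -> comparison report.

A run is driven by a single :class:`RunConfig` with exactly one input mode:

* ``ensemble`` — generate synthetic snapshots from an :class:`EnsembleSpec`;
* ``trajectory`` — read an XYZ trajectory and measure configured dihedrals;
* ``excitation_table`` — skip geometry entirely and broaden per-conformer
  excitations read from a neutral table.

Everything downstream of the config is deterministic: snapshot subset
selection is seeded sampling without replacement, and reports are written
with sorted keys and no timestamps, so a config maps to byte-identical
outputs across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .ensemble import (
    EnsembleSpec,
    Snapshot,
    TruncatedNormal,
    ensemble_to_spectra,
    sample_md_ensemble,
)
from .errors import ConfigError, DomainError, TamraspecError
from .geometry import (
    DihedralSample,
    DihedralSpec,
    deviation_summary,
    dihedral_angle,
    fold_deviation,
    rotamer_populations,
)
from .io import (
    read_excitation_table,
    read_spectrum_csv,
    read_xyz,
    write_spectrum_csv,
)
from .spectral import (
    BroadeningParams,
    Spectrum,
    average_spectra,
    band_shift,
    broaden,
    find_lambda_max,
    normalize_spectrum,
    resample_spectrum,
)
from .surrogate import build_surrogate, conformer_to_excitations

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "compare_to_reference",
    "subset_average",
]

logger = logging.getLogger("tamraspec")

#: Dihedral-name -> surrogate rotor-group mapping.
GROUP_BY_DIHEDRAL = {"d_Ph": "Ph", "d_COO": "COO", "d_COO'": "COO",
                     "d_NMe2": "NMe2", "d_NMe2'": "NMe2"}
#: Rotamer bins (degrees, folded) used in the report.
ROTAMER_EDGES = (0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0)


@dataclass(frozen=True)
class DihedralConfig:
    """One tracked dihedral: spec plus its reference angle (degrees)."""

    spec: DihedralSpec
    reference_deg: float


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one pipeline run."""

    output_dir: Path
    ensemble: EnsembleSpec | None = None
    trajectory: Path | None = None
    excitation_table: Path | None = None
    dihedrals: tuple[DihedralConfig, ...] = ()
    broadening: BroadeningParams = field(default_factory=BroadeningParams)
    subset_size: int | None = None
    seed: int = 0
    reference_spectrum: Path | None = None
    peak_window_nm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        modes = [
            m for m in (self.ensemble, self.trajectory, self.excitation_table)
            if m is not None
        ]
        if len(modes) != 1:
            raise ConfigError(
                "exactly one input mode (ensemble | trajectory | excitation_table) "
                f"must be set, got {len(modes)}"
            )
        if self.trajectory is not None and not self.dihedrals:
            raise ConfigError("trajectory mode requires dihedral specs")

    @staticmethod
    def from_yaml(path: str | Path, seed: int | None = None) -> "RunConfig":
        """Load a config file; ``seed`` overrides the file's seed."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {"output_dir": Path(raw.get("output_dir", "tamraspec_out"))}
        if "ensemble" in raw:
            ens = raw["ensemble"]
            groups = {
                name: TruncatedNormal(
                    p["mode_deg"], p["sigma_deg"], p["lo_deg"], p["hi_deg"]
                )
                for name, p in ens.get("groups", {}).items()
            }
            kwargs["ensemble"] = EnsembleSpec(
                n_snapshots=ens.get("n_snapshots", 100),
                seed=ens.get("seed", raw.get("seed", 0)),
                **({"groups": groups} if groups else {}),
            )
        if "trajectory" in raw:
            kwargs["trajectory"] = Path(raw["trajectory"])
        if "excitation_table" in raw:
            kwargs["excitation_table"] = Path(raw["excitation_table"])
        kwargs["dihedrals"] = tuple(
            DihedralConfig(
                DihedralSpec(
                    d["name"],
                    tuple(d["atom_indices"]),
                    d.get("symmetry_period_deg", 180.0),
                ),
                d["reference_deg"],
            )
            for d in raw.get("dihedrals", [])
        )
        if "broadening" in raw:
            kwargs["broadening"] = BroadeningParams(**raw["broadening"])
        for key in ("subset_size", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "reference_spectrum" in raw:
            kwargs["reference_spectrum"] = Path(raw["reference_spectrum"])
        if "peak_window_nm" in raw:
            kwargs["peak_window_nm"] = tuple(raw["peak_window_nm"])
        if seed is not None:
            kwargs["seed"] = seed
            if "ensemble" in kwargs:
                kwargs["ensemble"] = dataclasses.replace(kwargs["ensemble"], seed=seed)
        return RunConfig(**kwargs)


@dataclass(frozen=True)
class RunReport:
    """All headline numbers of a run plus the file manifest."""

    per_snapshot_lambda_max: tuple[float, ...]
    ensemble_lambda_max: float
    planar_lambda_max: float
    band_shift_nm: float
    dihedral_summary: dict
    rotamer_table: dict
    comparison: dict | None
    manifest: tuple[str, ...]
    config_echo: dict

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=2, sort_keys=True)


def subset_average(spectra: Sequence[Spectrum], k: int, seed: int = 0) -> Spectrum:
    """Average a seeded random subset of ``k`` spectra, without replacement.

    ``k`` equal to the ensemble size reproduces the full average regardless
    of seed; ``k = 1`` returns one input spectrum verbatim.
    """
    if k < 1 or k > len(spectra):
        raise DomainError(f"subset size {k} not in [1, {len(spectra)}]")
    if k == len(spectra):
        chosen = list(spectra)
    else:
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(spectra), size=k, replace=False))
        chosen = [spectra[i] for i in idx]
    return average_spectra(chosen)


def compare_to_reference(
    ensemble_spectrum: Spectrum,
    reference_spectrum: Spectrum,
    window_nm: tuple[float, float] | None = None,
) -> dict:
    """Peak displacement and band overlap between simulation and reference.

    The reference is resampled onto the simulated grid and both are
    peak-normalized; the overlap statistic is the trapezoidal integral of
    the pointwise minimum after area-normalization (1 for identical band
    shapes, 0 for disjoint support).  Mutual normalization of measured and
    simulated spectra is a convention, recorded in the output record.
    """
    ref = resample_spectrum(reference_spectrum, ensemble_spectrum.wavelengths_nm)
    a = normalize_spectrum(ensemble_spectrum, "max")
    b = normalize_spectrum(ref, "max")
    delta = band_shift(a, b, window_nm)
    wl = a.wavelengths_nm
    a_area = a.intensities / np.trapezoid(a.intensities, wl)
    b_area = b.intensities / np.trapezoid(b.intensities, wl)
    overlap = float(np.trapezoid(np.minimum(a_area, b_area), wl))
    return {
        "delta_lambda_max_nm": float(delta),
        "overlap": overlap,
        "normalization": "peak (positions) / area (overlap)",
    }


def _stage(name: str):
    """Context wrapper turning stage failures into stage-named diagnostics."""
    import contextlib

    @contextlib.contextmanager
    def ctx():
        logger.info("stage: %s", name)
        try:
            yield
        except TamraspecError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    return ctx()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis described by ``config``.

    Returns the report and writes, under ``config.output_dir``: every
    per-snapshot spectrum, the ensemble average, the planar reference
    spectrum, and ``report.json``.  Deterministic given the config.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "spectra").mkdir(exist_ok=True)
    manifest: list[str] = []
    model = build_surrogate()

    deviations_by_group: dict[str, np.ndarray] = {}
    dihedral_sum: dict = {}
    rotamer_table: dict = {}

    with _stage("input"):
        if config.ensemble is not None:
            snapshots = sample_md_ensemble(config.ensemble)
            excitation_sets = None
            for group in config.ensemble.groups:
                deviations_by_group[group] = np.array(
                    [s.deviations[group] for s in snapshots]
                )
        elif config.trajectory is not None:
            frames = read_xyz(config.trajectory)
            samples = []
            references = {}
            for dc in config.dihedrals:
                angles = np.array(
                    [dihedral_angle(fr, dc.spec) for fr in frames]
                )
                samples.append(DihedralSample(dc.spec.name, angles, source="md"))
                references[dc.spec.name] = dc.reference_deg
            snapshots = []
            for i, _ in enumerate(frames):
                dev = {}
                for dc, sample in zip(config.dihedrals, samples):
                    group = GROUP_BY_DIHEDRAL.get(dc.spec.name)
                    if group is None:
                        continue
                    dev[group] = fold_deviation(
                        sample.angles_deg[i],
                        dc.reference_deg,
                        dc.spec.symmetry_period_deg,
                    )
                snapshots.append(Snapshot(f"frame{i:04d}", dev))
            excitation_sets = None
            per = {
                dc.spec.name: dc.spec.symmetry_period_deg for dc in config.dihedrals
            }
            dihedral_sum = {
                name: dataclasses.asdict(s)
                for name, s in deviation_summary(samples, references, per).items()
            }
            for dc, sample in zip(config.dihedrals, samples):
                group = GROUP_BY_DIHEDRAL.get(dc.spec.name)
                if group is not None:
                    deviations_by_group[group] = fold_deviation(
                        sample.angles_deg, dc.reference_deg,
                        dc.spec.symmetry_period_deg,
                    )
        else:
            excitation_sets = read_excitation_table(config.excitation_table)
            snapshots = None

    with _stage("geometry-summary"):
        if config.ensemble is not None and snapshots is not None:
            samples = [
                DihedralSample(f"d_{g}" if not g.startswith("d_") else g,
                               v, source="synthetic")
                for g, v in deviations_by_group.items()
            ]
            refs = {s.name: 0.0 for s in samples}
            dihedral_sum = {
                name: dataclasses.asdict(s)
                for name, s in deviation_summary(samples, refs, 180.0).items()
            }
        for group, dev in deviations_by_group.items():
            folded = fold_deviation(dev, 0.0, 180.0)
            fracs = rotamer_populations(
                DihedralSample(group, np.atleast_1d(folded)), ROTAMER_EDGES
            )
            rotamer_table[group] = {
                f"[{ROTAMER_EDGES[i]:g},{ROTAMER_EDGES[i+1]:g})": float(fr)
                for i, fr in enumerate(fracs)
            }

    with _stage("spectra"):
        if snapshots is not None:
            spectra = ensemble_to_spectra(snapshots, model, config.broadening)
            ids = [s.snapshot_id for s in snapshots]
        else:
            spectra = [broaden(es, config.broadening) for es in excitation_sets]
            ids = [es.conformer_id for es in excitation_sets]
        planar = broaden(model.reference_excitations, config.broadening)
        for sid, sp in zip(ids, spectra):
            p = out_dir / "spectra" / f"{sid}.csv"
            write_spectrum_csv(sp, p)
            manifest.append(str(p.relative_to(out_dir)))

    with _stage("average"):
        k = config.subset_size or len(spectra)
        ensemble_avg = subset_average(spectra, k, config.seed)
        avg_path = out_dir / "ensemble_average.csv"
        write_spectrum_csv(ensemble_avg, avg_path)
        manifest.append(str(avg_path.relative_to(out_dir)))
        planar_path = out_dir / "planar_reference.csv"
        write_spectrum_csv(planar, planar_path)
        manifest.append(str(planar_path.relative_to(out_dir)))

    with _stage("analysis"):
        window = config.peak_window_nm
        per_snapshot = tuple(
            round(find_lambda_max(sp, window), 6) for sp in spectra
        )
        ens_lmax = round(find_lambda_max(ensemble_avg, window), 6)
        planar_lmax = round(find_lambda_max(planar, window), 6)
        shift = round(ens_lmax - planar_lmax, 6)
        comparison = None
        if config.reference_spectrum is not None:
            ref = read_spectrum_csv(config.reference_spectrum)
            comparison = compare_to_reference(ensemble_avg, ref, window)

    report = RunReport(
        per_snapshot_lambda_max=per_snapshot,
        ensemble_lambda_max=ens_lmax,
        planar_lambda_max=planar_lmax,
        band_shift_nm=shift,
        dihedral_summary=dihedral_sum,
        rotamer_table=rotamer_table,
        comparison=comparison,
        manifest=tuple(sorted(manifest)),
        config_echo={
            "seed": config.seed,
            "subset_size": config.subset_size,
            "n_spectra": len(spectra),
            "hwhm_eV": config.broadening.hwhm_eV,
        },
    )
    (out_dir / "report.json").write_text(report.to_json() + "\n")
    return report
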