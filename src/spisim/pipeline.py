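"""Study orchestration: noise cases x dataset sizes -> EMC -> R -> resolution.

A study sweeps snapshot counts for each detector-noise case, reconstructs
each dataset with EMC, registers the result against the ideal reciprocal-
space map, computes the R-factor curve and the R = 0.2 resolution, and
writes per-run artifacts plus a combined CSV (one row per case/size/seed).
Completed runs are recorded in a manifest keyed by a config hash so a study
can resume after interruption; a changed config is refused with a diff.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .diffraction import AtomicModel, build_ideal_volume, voxel_size_for
from .emc import EMCConfig, run_emc
from .geometry import BeamParameters, DetectorGeometry, build_qmap
from .metrics import r_factor, register_rotation, resolution_at_threshold
from .synthetic import PhantomSpec, fluence_for_occupancy, make_dataset, make_phantom

__all__ = ["StudyConfig", "StudyReport", "run_study", "resume_study"]

NOISE_CASES = ("poisson_only", "standard", "low_noise")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a resolution-vs-snapshots study.

    ``dataset_sizes`` and ``noise_cases`` span the sweep; ``emc_seeds``
    lists independent EMC repeats per (case, size) used for error bars.
    ``target_occupancy`` rescales the fluence so snapshots sit in the
    photon-sparse regime (~0.1 photons/pixel).
    """

    phantom: PhantomSpec = PhantomSpec()
    geometry: DetectorGeometry = None
    beam: BeamParameters = None
    dataset_sizes: tuple[int, ...] = (600, 1200)
    noise_cases: tuple[str, ...] = ("poisson_only", "low_noise")
    emc: EMCConfig = None
    emc_seeds: tuple[int, ...] = (0,)
    d_grid_nm: tuple[float, ...] = ()
    threshold: float = 0.2
    target_occupancy: float = 0.1
    data_seed: int = 1234
    custom_noise: dict | None = None  #: NoiseModel kwargs for case "custom"

    def __post_init__(self) -> None:
        from .synthetic import desk_beam, desk_geometry

        if self.geometry is None:
            object.__setattr__(self, "geometry", desk_geometry())
        if self.beam is None:
            object.__setattr__(self, "beam", desk_beam())
        if self.emc is None:
            object.__setattr__(self, "emc", EMCConfig())
        if not self.dataset_sizes or not self.noise_cases:
            raise ValueError("need at least one dataset size and one noise case")
        for case in self.noise_cases:
            if case not in NOISE_CASES + ("custom",):
                raise ValueError(f"unknown noise case {case!r}")
        if "custom" in self.noise_cases and not self.custom_noise:
            raise ValueError("custom noise case requires custom_noise parameters")

    def config_dict(self) -> dict:
        return json.loads(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.config_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def _voxel_size(self) -> float:
        return self.emc.voxel_size or voxel_size_for(
            self.geometry, self.emc.grid_edge
        )

    def beamstop_voxel_radius(self) -> float:
        """Beamstop radius converted from detector pixels to grid voxels."""
        q_bs = self.geometry.q_at_radius(self.geometry.beamstop_radius)
        return float(q_bs / self._voxel_size())

    def resolved_d_grid(self) -> np.ndarray:
        if self.d_grid_nm:
            return np.asarray(self.d_grid_nm, dtype=float)
        # default: from ~particle size (or the coarsest shell that clears
        # the excluded beamstop sphere) down to 1.2x the edge resolution
        vox = self._voxel_size()
        coarse_grid = 2 * np.pi / ((self.beamstop_voxel_radius() + 2.0) * vox) / 10.0
        coarse = min(self.phantom.extent_nm * 1.5, coarse_grid)
        fine = self.geometry.edge_resolution() * 1.2
        return np.geomspace(coarse, fine, 25)


@dataclass
class RunResult:
    case: str
    size: int
    emc_seed: int
    resolution_nm: float | None
    flag: str
    registration_corr: float | None = None
    error: str | None = None


@dataclass
class StudyReport:
    config_hash: str
    runs: list[RunResult] = field(default_factory=list)

    def rows(self) -> list[dict]:
        return [dataclasses.asdict(r) for r in self.runs]

    def resolution_table(self) -> dict[tuple[str, int], dict]:
        """Median/std of resolution over EMC seeds per (case, size)."""
        table: dict[tuple[str, int], dict] = {}
        for (case, size) in {(r.case, r.size) for r in self.runs}:
            vals = [
                r.resolution_nm
                for r in self.runs
                if r.case == case and r.size == size and r.resolution_nm is not None
            ]
            if vals:
                table[(case, size)] = {
                    "median_nm": float(np.median(vals)),
                    "std_nm": float(np.std(vals)),
                    "n": len(vals),
                }
        return table


def _run_one(
    config: StudyConfig,
    qmap,
    model: AtomicModel,
    ideal,
    flu: float,
    case: str,
    size: int,
    emc_seed: int,
) -> RunResult:
    from .noise import NoiseModel

    data_seed = (
        config.data_seed
        + 7919 * config.noise_cases.index(case)
        + 104729 * config.dataset_sizes.index(size)
    ) % 2**31
    noise_model = None
    noise_case = case
    if case == "custom":
        noise_model = NoiseModel(**config.custom_noise)
    patterns = make_dataset(
        model,
        qmap,
        config.beam,
        size,
        noise_case=noise_case,
        noise_model=noise_model,
        fluence_override=flu,
        seed=data_seed,
    )
    emc_cfg = dataclasses.replace(config.emc, seed=emc_seed)
    result = run_emc(patterns, qmap, emc_cfg)
    _, registered = register_rotation(result.volume, ideal)
    curve = r_factor(
        registered,
        ideal,
        config.resolved_d_grid(),
        exclude_beamstop=config.beamstop_voxel_radius(),
    )
    est = resolution_at_threshold(curve, config.threshold)
    return RunResult(
        case=case,
        size=size,
        emc_seed=emc_seed,
        resolution_nm=est.resolution_nm,
        flag=est.flag,
    )


def run_study(config: StudyConfig, out_dir=None, resume: bool = False) -> StudyReport:
    """Execute (or resume) the full study; failures are recorded per run.

    When ``out_dir`` is given, per-run JSON artifacts, a manifest and a
    combined ``study.csv`` are written there.
    """
    out = Path(out_dir) if out_dir is not None else None
    chash = config.config_hash()
    manifest_path = out / "manifest.json" if out else None
    done: dict[str, dict] = {}
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        if manifest_path.exists():
            manifest = json.loads(manifest_path.read_text())
            if manifest.get("config_hash") != chash:
                old = manifest.get("config", {})
                new = config.config_dict()
                diff = [
                    f"  {k}: {old.get(k)!r} -> {new.get(k)!r}"
                    for k in sorted(set(old) | set(new))
                    if old.get(k) != new.get(k)
                ]
                raise ValueError(
                    "output directory holds a different study; "
                    "changed fields:\n" + "\n".join(diff)
                )
            if resume:
                for key, row in manifest.get("runs", {}).items():
                    run_file = out / f"run-{key}.json"
                    if run_file.exists():
                        done[key] = json.loads(run_file.read_text())
        elif resume:
            pass  # nothing to resume; run everything

    model = make_phantom(config.phantom)
    qmap = build_qmap(config.geometry)
    flu = fluence_for_occupancy(
        model, qmap, config.beam, config.target_occupancy, seed=config.data_seed
    )
    vox = config.emc.voxel_size or voxel_size_for(config.geometry, config.emc.grid_edge)
    ideal = build_ideal_volume(model, config.emc.grid_edge, vox)

    report = StudyReport(config_hash=chash)
    for case in config.noise_cases:
        for size in config.dataset_sizes:
            for emc_seed in config.emc_seeds:
                key = f"{case}-{size}-{emc_seed}"
                if key in done:
                    report.runs.append(RunResult(**done[key]))
                    continue
                try:
                    run = _run_one(
                        config, qmap, model, ideal, flu, case, size, emc_seed
                    )
                except Exception as exc:  # record and continue the sweep
                    run = RunResult(
                        case=case,
                        size=size,
                        emc_seed=emc_seed,
                        resolution_nm=None,
                        flag="failed",
                        error=f"{type(exc).__name__}: {exc}",
                    )
                report.runs.append(run)
                if out is not None:
                    (out / f"run-{key}.json").write_text(
                        json.dumps(dataclasses.asdict(run), indent=2)
                    )
                    _write_manifest(manifest_path, chash, report, config)
    if out is not None:
        _write_manifest(manifest_path, chash, report, config)
        _write_csv(out / "study.csv", report)
    return report


def _write_manifest(
    path: Path, chash: str, report: StudyReport, config: StudyConfig | None = None
) -> None:
    runs = {
        f"{r.case}-{r.size}-{r.emc_seed}": dataclasses.asdict(r)
        for r in report.runs
    }
    doc = {"config_hash": chash, "runs": runs}
    if config is not None:
        doc["config"] = config.config_dict()
    path.write_text(json.dumps(doc, indent=2))


def _write_csv(path: Path, report: StudyReport) -> None:
    fields = ["case", "size", "emc_seed", "resolution_nm", "flag", "error"]
    with open(path, "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=fields, extrasaction="ignore")
        writer.writeheader()
        for r in sorted(
            report.rows(), key=lambda d: (d["case"], d["size"], d["emc_seed"])
        ):
            writer.writerow(r)


def resume_study(out_dir, config: StudyConfig) -> StudyReport:
    """Re-run a study directory, skipping completed (case, size, seed) runs.

    Refuses with a diff-style error if the stored manifest hash does not
    match the given config.
    """
    return run_study(config, out_dir=out_dir, resume=True)
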