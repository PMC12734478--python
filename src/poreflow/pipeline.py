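"""End-to-end pipeline orchestration: config, seeding, artifacts, manifest.

A :class:`PipelineConfig` is a plain serializable record of every stage
toggle and parameter plus one master seed; :func:`run_pipeline`
executes the enabled stages in dependency order —

    generate → foul/calibrate → render → align → enhance → segment →
    morphometry → flow → challenge → report

— writing each stage's artifacts under the output directory and
returning a manifest that lists every artifact with its SHA-256 hash
and the resolved per-stage seed.  Runs with the same config and master
seed produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import morphometry as morph
from . import stokes as stk
from .render import RenderSpec, render_stack
from .stacks import align_stack, enhance_and_correct, save_stack, segment_two_zone
from .structure import VoxelStructure, load_structure, save_structure
from .synthetic import (
    FoulingSpec,
    MembraneProfile,
    apply_fouling,
    calibrate_fouling,
    generate_membrane,
    substream,
)
from .transport import ChallengeConfig, capture_depth_profile, run_batch_challenge

__all__ = ["PipelineConfig", "run_pipeline", "roundtrip_structure"]

log = logging.getLogger("poreflow.pipeline")

_STAGES = (
    "generate",
    "foul",
    "render",
    "align",
    "enhance",
    "segment",
    "morphometry",
    "flow",
    "challenge",
    "report",
)


@dataclass
class PipelineConfig:
    """Resolved parameters for a reproducible pipeline run."""

    master_seed: int = 0
    out_dir: str = "poreflow_run"
    precision: int = 2  # reporting decimals for ratios/LRV
    stages: dict = field(
        default_factory=lambda: {s: False for s in _STAGES}
    )

    # generate
    dims: tuple[int, int, int] = (96, 96, 96)
    voxel_size_nm: float = 7.0
    porosity_inlet: float = 0.40
    porosity_exit: float = 0.35
    correlation_inlet_nm: float = 14.0
    correlation_exit_nm: float = 7.0

    # foul
    foul_mode: str = "spec"  # "spec" | "calibrate"
    deposit_fraction: float = 0.3
    size_weight: float = 4.0
    depth_weight: float = 1.0
    target_flux_ratio: float = 0.6
    calibration_tol: float = 0.05

    # render
    noise_sd: float = 6.0
    drift_max_px: int = 5
    gradient_span: tuple[float, float] = (1.0, 1.5)

    # segment
    zone_boundary: int | None = None

    # morphometry
    slab_nm: float = 250.0

    # flow
    delta_p_kpa: float = 210.0
    viscosity_pa_s: float = 1.0e-3
    solver_rtol: float = 1e-8
    solver_method: str = "mg"

    # challenge
    n_batches: int = 30
    batch_size: int = 25
    ghosts_per_batch: int = 0
    particle_diameter_nm: float = 20.0
    blocking_threshold: float = 0.5
    seed_offset_nm: float = 100.0

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        self.stages = {s: bool(self.stages.get(s, False)) for s in _STAGES}

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dims"] = list(self.dims)
        d["gradient_span"] = list(self.gradient_span)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "dims" in d:
            d["dims"] = tuple(d["dims"])
        if "gradient_span" in d:
            d["gradient_span"] = tuple(d["gradient_span"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def paper_mini(cls, **overrides) -> "PipelineConfig":
        """Full-chain configuration on a 96³ membrane."""
        cfg = cls(
            stages={s: True for s in _STAGES},
            dims=(96, 96, 96),
            foul_mode="calibrate",
            target_flux_ratio=0.6,
        )
        return dataclasses.replace(cfg, **overrides)

    def membrane_profile(self) -> MembraneProfile:
        thick = self.dims[2] * self.voxel_size_nm * 1e-3
        z = np.linspace(0.0, thick, 25)
        frac = z / thick
        return MembraneProfile(
            depth_um=z,
            porosity=self.porosity_inlet + (self.porosity_exit - self.porosity_inlet) * frac**2,
            correlation_nm=self.correlation_inlet_nm
            + (self.correlation_exit_nm - self.correlation_inlet_nm) * frac,
        )


def _sha256(path: Path) -> str:
    hsh = hashlib.sha256()
    hsh.update(path.read_bytes())
    return hsh.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the run manifest.

    The manifest records the resolved config, every artifact path with
    its SHA-256 hash, the per-stage derived seeds, and per-stage
    diagnostics (solver residuals and iteration counts).  A stage
    failure writes the partial manifest and re-raises, naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "artifacts": {}, "stages": {}}
    seeds = {s: int(np.asarray(substream(config.master_seed, f"stage/{s}").integers(0, 2**31 - 1)))
             for s in _STAGES}

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    cfg_path = config.to_yaml(out / "resolved_config.yaml")
    record("resolved_config", cfg_path)

    structure: VoxelStructure | None = None
    fouled: VoxelStructure | None = None
    protein: np.ndarray | None = None
    segmented = None
    stack = None
    stage = "none"
    try:
        if config.stages.get("generate"):
            stage = "generate"
            log.info("generate: dims=%s seed=%d", config.dims, seeds[stage])
            structure = generate_membrane(
                config.membrane_profile(), config.dims, config.voxel_size_nm, seed=seeds[stage]
            )
            p = save_structure(out / "membrane_clean.nrrd", structure)
            record("membrane_clean", p)
            manifest["stages"][stage] = {"seed": seeds[stage], "porosity": structure.porosity()}

        if config.stages.get("foul"):
            stage = "foul"
            if structure is None:
                raise RuntimeError("foul stage requires generate")
            spec = FoulingSpec(
                deposit_fraction=config.deposit_fraction,
                size_weight=config.size_weight,
                depth_weight=config.depth_weight,
            )
            if config.foul_mode == "calibrate":
                spec, fouled, rec = calibrate_fouling(
                    structure,
                    config.target_flux_ratio,
                    tol=config.calibration_tol,
                    spec_template=spec,
                    seed=seeds[stage],
                    solver_kwargs={"rtol": config.solver_rtol, "method": config.solver_method},
                )
                manifest["stages"][stage] = {
                    "seed": seeds[stage],
                    "deposit_fraction": spec.deposit_fraction,
                    "achieved_flux_ratio": rec.achieved_flux_ratio,
                    "iterations": len(rec.history),
                }
            else:
                fouled = apply_fouling(structure, spec, seed=seeds[stage])
                manifest["stages"][stage] = {
                    "seed": seeds[stage],
                    "deposit_fraction": spec.deposit_fraction,
                }
            protein = structure.grid & ~fouled.grid
            p = save_structure(out / "membrane_fouled.nrrd", fouled)
            record("membrane_fouled", p)

        if config.stages.get("render"):
            stage = "render"
            target = fouled if fouled is not None else structure
            if target is None:
                raise RuntimeError("render stage requires a structure")
            rng = substream(seeds[stage], "drift")
            drift = rng.integers(
                -config.drift_max_px, config.drift_max_px + 1, size=(target.shape[0], 2)
            )
            drift[0] = 0
            gradient = np.linspace(*config.gradient_span, target.shape[0])
            rspec = RenderSpec(
                drift=drift, noise_sd=config.noise_sd, depth_gradient=gradient,
                pad_px=max(8, config.drift_max_px + 2),
            )
            stack, truth = render_stack(target, rspec, protein_mask=protein, seed=seeds[stage])
            p = save_stack(out / "stack_raw.tiff", stack)
            record("stack_raw", p)
            np.save(out / "true_drift.npy", truth["drift"])
            record("true_drift", out / "true_drift.npy")
            manifest["stages"][stage] = {"seed": seeds[stage], "n_slices": stack.n_slices}

        if config.stages.get("align"):
            stage = "align"
            if stack is None:
                raise RuntimeError("align stage requires render")
            stack, trace = align_stack(stack)
            trace.to_frame().to_csv(out / "drift_trace.csv", index=False)
            record("drift_trace", out / "drift_trace.csv")
            manifest["stages"][stage] = {
                "max_dx": int(np.abs(trace.dx).max()),
                "max_dy": int(np.abs(trace.dy).max()),
            }

        if config.stages.get("enhance"):
            stage = "enhance"
            if stack is None:
                raise RuntimeError("enhance stage requires render")
            stack = enhance_and_correct(stack)
            manifest["stages"][stage] = {"done": True}

        if config.stages.get("segment"):
            stage = "segment"
            if stack is None:
                raise RuntimeError("segment stage requires render")
            segmented = segment_two_zone(stack, zone_boundary=config.zone_boundary)
            p = save_structure(out / "membrane_segmented.nrrd", segmented.structure)
            record("membrane_segmented", p)
            manifest["stages"][stage] = {
                "thresholds": list(segmented.thresholds),
                "zone_boundary": segmented.zone_boundary,
            }

        analysis_structure = (
            segmented.structure if segmented is not None
            else (fouled if fouled is not None else structure)
        )

        if config.stages.get("morphometry"):
            stage = "morphometry"
            if analysis_structure is None:
                raise RuntimeError("morphometry requires a structure")
            prof = morph.porosity_profile(analysis_structure, slab_nm=config.slab_nm)
            prof.to_frame().to_csv(out / "porosity_profile.csv", index=False)
            record("porosity_profile", out / "porosity_profile.csv")
            psd = morph.pore_size_distribution(analysis_structure)
            psd.to_frame().to_csv(out / "pore_size_distribution.csv", index=False)
            record("pore_size_distribution", out / "pore_size_distribution.csv")
            summary = {
                "mean_diameter_nm": float(psd.diameters_nm.mean()),
                "p50_nm": float(np.median(psd.diameters_nm)),
                "p90_nm": float(np.quantile(psd.diameters_nm, 0.9)),
            }
            (out / "psd_summary.json").write_text(json.dumps(summary, indent=2))
            record("psd_summary", out / "psd_summary.json")
            manifest["stages"][stage] = summary

        if config.stages.get("flow"):
            stage = "flow"
            if analysis_structure is None:
                raise RuntimeError("flow requires a structure")
            field_ = stk.solve_stokes(
                analysis_structure,
                delta_p_kpa=config.delta_p_kpa,
                viscosity_pa_s=config.viscosity_pa_s,
                rtol=config.solver_rtol,
                method=config.solver_method,
            )
            kres = stk.permeability(field_, analysis_structure)
            ok, achieved = stk.verify_pressure_match(field_, config.delta_p_kpa)
            payload = {
                "kappa_lmh_per_kpa": kres.kappa,
                "delta_p_kpa": achieved,
                "pressure_match": bool(ok),
                "max_divergence": field_.max_divergence,
                "iterations": field_.cg_iterations,
            }
            (out / "permeability.json").write_text(json.dumps(payload, indent=2))
            record("permeability", out / "permeability.json")
            manifest["stages"][stage] = payload

        if config.stages.get("challenge"):
            stage = "challenge"
            if analysis_structure is None:
                raise RuntimeError("challenge requires a structure")
            ccfg = ChallengeConfig(
                n_batches=config.n_batches,
                batch_size=config.batch_size,
                ghosts_per_batch=config.ghosts_per_batch,
                particle_diameter_nm=config.particle_diameter_nm,
                blocking_threshold=config.blocking_threshold,
                seed_offset_nm=config.seed_offset_nm,
            )
            res = run_batch_challenge(
                analysis_structure, ccfg, delta_p_kpa=config.delta_p_kpa,
                seed=seeds[stage], solver_rtol=config.solver_rtol,
                solver_method=config.solver_method,
            )
            lrv = res.lrv()
            caps = res.all_capture_positions()
            np.savetxt(
                out / "capture_positions_nm.csv", caps, delimiter=",",
                header="x_nm,y_nm,z_nm", comments="",
            )
            record("capture_positions", out / "capture_positions_nm.csv")
            depth = capture_depth_profile(res)
            payload = {
                "n_in": res.n_in,
                "n_out": res.n_out,
                "lrv": lrv.report(config.precision),
                "lrv_is_lower_bound": lrv.lower_bound,
                "captured_real_per_batch": res.captured_real,
                "permeability_per_batch": res.permeability_per_batch,
                "mean_capture_depth_um": depth.mean_um,
            }
            (out / "challenge.json").write_text(json.dumps(payload, indent=2))
            record("challenge", out / "challenge.json")
            manifest["stages"][stage] = {"seed": seeds[stage], "lrv": payload["lrv"]}

        if config.stages.get("report"):
            stage = "report"
            report = {
                "stages_run": [s for s in _STAGES if config.stages.get(s)],
                "stage_summaries": manifest["stages"],
            }
            (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
            record("report", out / "report.json")

    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    manifest["artifacts"]["manifest"] = {"path": str(out / "manifest.json")}
    return manifest


def roundtrip_structure(path: str | Path) -> VoxelStructure:
    """Load a persisted structure, insisting on complete metadata."""
    return load_structure(path)
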