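"""Config-driven end-to-end runs.

One YAML config drives the full chain: samples (or a precomputed
probability map, or a synthetic-scene recipe) -> probability map -> entropy
map -> percentile segmentations -> voxel physics -> characteristic
distribution.  Every run writes a manifest listing each produced file, the
config hash, the seed and per-stage wall times, with machine-readable
warnings (non-monotonicity, fit downgrade, clamping).

The config schema is strict: unknown keys are rejected, since a silently
ignored misspelling is the main hazard in an uncertainty pipeline.  A
completed run is idempotent — re-running with an unchanged config and seed
skips execution and changes no output bytes; a non-monotone quantity table
downgrades the distribution fit to the empirical family with a warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import distfit, percentile, physics_voxel, probmap, synth, uncertainty

__all__ = ["RunConfig", "PhysicsSpec", "DistFitSpec", "SynthRecipe",
           "run_pipeline", "load_config"]

log = logging.getLogger("seguq")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthRecipe(_Strict):
    generator: Literal["planar_interface", "blob_microstructure"]
    shape: tuple[int, int, int] = (32, 32, 32)
    # planar
    x0: float = 16.0
    w: float = 2.0
    # blobs
    phi: float = 0.5
    ell: float = 3.0
    noise_amplitude: float = 0.05
    # sampling
    sampler: Literal["threshold_jitter", "noise_then_threshold"] = "threshold_jitter"
    n_samples: int = 64


class PhysicsSpec(_Strict):
    quantities: list[Literal["volume_fraction", "effective_conductivity",
                             "tortuosity"]] = ["volume_fraction"]
    axis: Literal["z", "y", "x"] = "z"
    k_in: float | tuple[float, float, float] = 1.0
    k_out: float | tuple[float, float, float] = 1e-6


class DistFitSpec(_Strict):
    family: Literal["normal", "beta", "half_cauchy", "empirical"] = "normal"
    tolerance: float = 0.05


class RunConfig(_Strict):
    """Validated configuration for one end-to-end run."""

    samples: Optional[list[str]] = None
    probability_map: Optional[str] = None
    synth: Optional[SynthRecipe] = None
    classes: list[int] = [1]
    percentiles: list[float] = [15.9, 50.0, 84.1]
    physics: PhysicsSpec = Field(default_factory=PhysicsSpec)
    distfit: DistFitSpec = Field(default_factory=DistFitSpec)
    output_dir: str = "seguq_run"
    seed: int = 0
    write_stl: bool = False
    verbosity: Literal["debug", "info", "warning"] = "info"

    @model_validator(mode="after")
    def _one_input(self):
        given = [x is not None for x in (self.samples, self.probability_map,
                                         self.synth)]
        if sum(given) != 1:
            raise ValueError("exactly one input source required: samples, "
                             "probability_map or synth")
        if self.samples is not None:
            missing = [p for p in self.samples if not Path(p).exists()]
            if missing:
                raise ValueError(f"sample file(s) not found: {missing}")
        if self.probability_map is not None and \
                not Path(self.probability_map).exists():
            raise ValueError(f"probability map not found: "
                             f"{self.probability_map}")
        for P in self.percentiles:
            percentile.percentile_to_threshold(P)  # raises outside (0, 100)
        return self


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _build_probability_map(config: RunConfig):
    if config.synth is not None:
        r = config.synth
        if r.generator == "planar_interface":
            scene = synth.make_planar_interface(r.shape, r.x0, r.w)
        else:
            scene = synth.make_blob_microstructure(
                r.shape, r.phi, r.ell, seed=config.seed,
                noise_amplitude=r.noise_amplitude)
        stack = synth.sample_segmentations(scene, r.n_samples,
                                           sampler=r.sampler,
                                           seed=config.seed + 1)
        return probmap.compute_probability_map(stack)
    if config.samples is not None:
        stack = probmap.load_samples(config.samples)
        return probmap.compute_probability_map(stack)
    return probmap.load_probability_map(config.probability_map)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest.

    The manifest lists all written files, the config hash, seed, per-stage
    timings and any warnings.  A completed run (matching manifest on disk,
    all files present) is returned as-is without re-execution.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)

    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            old = json.load(fh)
        if old.get("config_hash") == chash and \
                all((out / f).exists() for f in old.get("files", [])):
            log.info("run already complete (config hash %s); skipping", chash)
            return old

    level = getattr(logging, config.verbosity.upper())
    log.setLevel(level)
    fh_log = logging.FileHandler(out / "run.log", mode="w")
    fh_log.setLevel(level)
    log.addHandler(fh_log)

    files: list[str] = []
    warnings: list[dict] = []
    timings: dict[str, float] = {}
    try:
        t0 = time.perf_counter()
        pmap = _build_probability_map(config)
        timings["probmap"] = time.perf_counter() - t0
        probmap.save_probability_map(pmap, out / "probability_map.npy")
        files.append("probability_map.npy")
        log.info("probability map built: grid %s, classes %s",
                 pmap.grid_shape, pmap.classes)

        t0 = time.perf_counter()
        umap = uncertainty.entropy_map(pmap)
        umap.save(out / "entropy_map.npy")
        uncertainty.write_entropy_summary(umap, out / "entropy_summary.json")
        files += ["entropy_map.npy", "entropy_summary.json"]
        timings["uncertainty"] = time.perf_counter() - t0

        class_i = config.classes[0] if config.classes[0] in pmap.classes \
            else pmap.classes[-1]

        t0 = time.perf_counter()
        for P in config.percentiles:
            seg = percentile.threshold_map(pmap, class_i, P)
            name = f"mask_p{P:g}.npy"
            np.save(out / name, seg.mask)
            files.append(name)
            if config.write_stl:
                try:
                    mesh = percentile.extract_surface(pmap, class_i, P)
                    sname = f"surface_p{P:g}.stl"
                    percentile.save_surface_stl(mesh, out / sname)
                    files.append(sname)
                except percentile.EmptySurfaceError as exc:
                    warnings.append({"stage": "percentile",
                                     "kind": "empty_surface",
                                     "detail": str(exc), "percentile": P})
        timings["percentile"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        results = physics_voxel.run_physics_sweep(
            pmap, class_i, config.percentiles, config.physics.quantities,
            axis=config.physics.axis, k_in=config.physics.k_in,
            k_out=config.physics.k_out)
        table_df = physics_voxel.results_to_table(results)
        table_df.to_csv(out / "physics.csv", index=False)
        files.append("physics.csv")
        timings["physics"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        for quantity in config.physics.quantities:
            table = distfit.QuantityTable.from_results(results, quantity)
            dist = _fit_with_guard(table, config.distfit, warnings)
            if dist is not None:
                dname = f"distribution_{quantity}.json"
                dist.to_json(out / dname)
                files.append(dname)
        timings["distfit"] = time.perf_counter() - t0
    except Exception as exc:
        log.error("pipeline halted: %s", exc)
        # preserve partial outputs; report the failed stage via the exception
        raise
    finally:
        log.removeHandler(fh_log)
        fh_log.close()
    files.append("run.log")

    manifest = {
        "config": config.model_dump(mode="json"),
        "config_hash": chash,
        "seed": config.seed,
        "files": files,
        "warnings": warnings,
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _fit_with_guard(table: distfit.QuantityTable, spec: DistFitSpec,
                    warnings: list):
    """Fit the configured family, downgrading to empirical when non-monotone."""
    if len(table) >= 3:
        report = distfit.check_monotonicity(table)
        if not report.monotone:
            warnings.append({
                "stage": "distfit", "kind": "non_monotone",
                "detail": f"quantity {table.quantity!r} is non-monotone in "
                          f"percentile; downgraded to empirical CDF",
                "violations": report.violations,
                "band_escapes": report.band_escapes,
            })
            try:
                vals = np.sort(table.values)
                return distfit.CharacteristicDistribution(
                    family="empirical",
                    params={"values": vals,
                            "probs": table.percentiles / 100.0},
                    diagnostics={"downgraded": True},
                )
            except Exception as exc:  # pragma: no cover
                warnings.append({"stage": "distfit", "kind": "fit_failure",
                                 "detail": str(exc)})
                return None
    try:
        if spec.family == "normal":
            dist = distfit.fit_characteristic_normal(table)
        elif spec.family == "empirical":
            dist = distfit.fit_alternative(table, "empirical")
        else:
            dist = distfit.fit_alternative(table, spec.family)
        if len(table) > 3 and spec.family == "normal":
            dist.diagnostics["held_out"] = distfit.assess_characteristic_fit(
                dist, table, tol=spec.tolerance)
            if not dist.diagnostics["held_out"]["passed"]:
                warnings.append({
                    "stage": "distfit", "kind": "poor_characteristic_fit",
                    "detail": f"held-out CDF discrepancy "
                              f"{dist.diagnostics['held_out']['max_discrepancy']:.3g}"
                              f" exceeds {spec.tolerance}",
                })
        return dist
    except (ValueError, distfit.FitError) as exc:
        warnings.append({"stage": "distfit", "kind": "fit_failure",
                         "detail": str(exc)})
        return None
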