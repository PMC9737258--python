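"""End-to-end pipeline: simulate → zonate → score → phenotype → correlate → survive.

A :class:`RunConfig` (usually parsed from YAML) drives one fully seeded run:
synthetic wells are generated per population, quantified into zone profiles,
scored and ranked, phenotype tables are generated from the ground-truth
spatial scores and ranked, rank concordance is measured, and a two-group
survival comparison (internal vs external subgroup) is performed.  All
randomness derives from the single top-level seed through per-stage
substreams, so every stage is individually reproducible and rerunning with
the same config reproduces all numeric outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import ConfigError, DataError, config_hash, provenance_meta, write_image, write_report, write_table
from .phenotypes import compute_phenotype_metrics, concordance, rank_and_split
from .scoring import classify_configuration, rank_populations, score_profiles
from .survival import km_estimate, logrank_test
from .synthetic import (
    PhenotypeCoupling,
    PopulationSpec,
    RadialPlacementModel,
    SimulationConfig,
    generate_aggregate_image,
    generate_phenotype_tables,
    generate_survival,
)
from .zonation import WellGeometry, quantify_zones

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_run_config", "derive_seed"]

log = logging.getLogger("hma")


class PipelineError(Exception):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def derive_seed(seed: int, stream: int) -> int:
    """A reproducible per-stage child seed (< 2³¹) from the top-level seed."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration for one end-to-end run on synthetic data."""

    seed: int = 0
    geometry: WellGeometry = field(default_factory=WellGeometry)
    populations: list[PopulationSpec] = field(default_factory=list)
    z_slices: int = 1
    noise_sd: float = 0.05
    ref_inner: str | None = None  # label of the internal reference line
    ref_outer: str | None = None
    threshold: str = "otsu"
    coupling: PhenotypeCoupling = field(default_factory=PhenotypeCoupling)
    hazard_ratio: float = 3.0
    baseline_median: float = 24.0
    censor_prob: float = 0.2
    n_per_group: int = 25
    timestamp: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = dataclasses.asdict(self.geometry)
        d["populations"] = [dataclasses.asdict(p) for p in self.populations]
        d["coupling"] = dataclasses.asdict(self.coupling)
        return d


def load_run_config(path, seed: int | None = None) -> RunConfig:
    """Parse a YAML run configuration; an explicit ``seed`` overrides the file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        geom = WellGeometry(**raw.get("geometry", {}))
        image = raw.get("image", {})
        pops = []
        for spec in raw.get("populations", []):
            spec = dict(spec)
            if "zone_probs" in spec:
                placement = RadialPlacementModel.from_zone_probs(spec.pop("zone_probs"))
            elif "core_shell" in spec:
                cs = spec.pop("core_shell")
                placement = RadialPlacementModel.core_shell_model(
                    cs["core_fraction"], cs["shell_bias"]
                )
            else:
                raise ConfigError(
                    f"population {spec.get('label')!r}: give zone_probs or core_shell"
                )
            pops.append(
                PopulationSpec(
                    label=spec["label"],
                    channel=spec.get("channel", spec["label"]),
                    n_cells=int(spec.get("n_cells", 400)),
                    cell_radius_um=float(
                        spec.get("cell_radius_um", image.get("cell_radius_um", 6.0))
                    ),
                    placement=placement,
                )
            )
        refs = raw.get("references", {}) or {}
        coupling_raw = raw.get("coupling", {}) or {}
        survival_raw = raw.get("survival", {}) or {}
        cfg = RunConfig(
            seed=int(seed if seed is not None else raw.get("seed", 0)),
            geometry=geom,
            populations=pops,
            z_slices=int(image.get("z_slices", 1)),
            noise_sd=float(image.get("noise_sd", 0.05)),
            ref_inner=refs.get("inner"),
            ref_outer=refs.get("outer"),
            threshold=str(raw.get("threshold", "otsu")),
            coupling=PhenotypeCoupling(
                direction=coupling_raw.get("direction", "resistant_when_external"),
                noise_sd=float(coupling_raw.get("noise_sd", 0.0)),
            ),
            hazard_ratio=float(survival_raw.get("hazard_ratio", 3.0)),
            baseline_median=float(survival_raw.get("baseline_median", 24.0)),
            censor_prob=float(survival_raw.get("censor_prob", 0.2)),
            n_per_group=int(survival_raw.get("n_per_group", 25)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: invalid configuration: {exc}") from exc
    if len(cfg.populations) < 2:
        raise ConfigError(f"{path}: at least two populations required")
    return cfg


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage, writing all outputs under ``out_dir``.

    Returns the summary dictionary (also written as ``summary.json``).  On a
    stage failure, partial outputs are retained, a manifest naming the
    failing stage is written, and :class:`PipelineError` is raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config.to_dict())
    meta = lambda: provenance_meta(config.seed, cfg_hash, timestamp=config.timestamp)
    manifest: dict = {"stages_completed": [], "outputs": []}
    summary: dict = {
        "seed": config.seed,
        "config_sha256": cfg_hash,
        "hma_version": __version__,
    }

    def _write_manifest(failed: str | None = None):
        manifest["failed_stage"] = failed
        write_report(manifest, out / "manifest.json")

    stage = "simulate"
    try:
        t0 = _time.perf_counter()
        wells_dir = out / "wells"
        wells_dir.mkdir(exist_ok=True)
        true_scores = {}
        stacks = {}
        for i, pop in enumerate(config.populations):
            sim = SimulationConfig(
                geometry=config.geometry,
                populations=(pop,),
                z_slices=config.z_slices,
                noise_sd=config.noise_sd,
                seed=derive_seed(config.seed, i),
            )
            stacks[pop.label] = generate_aggregate_image(sim)
            write_image(stacks[pop.label], wells_dir / f"{pop.label}.ome.tif")
            manifest["outputs"].append(str(wells_dir / f"{pop.label}.ome.tif"))
            expected = pop.placement.expected_zone_profile(
                config.geometry.n_zones, config.geometry.radius_um
            )
            true_scores[pop.label] = float(
                np.arange(1, config.geometry.n_zones + 1) @ expected
            )
        non_ref = [
            p.label
            for p in config.populations
            if p.label not in (config.ref_inner, config.ref_outer)
        ]
        doses, growth, invasion = generate_phenotype_tables(
            {l: true_scores[l] for l in non_ref},
            PhenotypeCoupling(
                direction=config.coupling.direction,
                noise_sd=config.coupling.noise_sd,
                seed=derive_seed(config.seed, 1001),
            ),
        )
        for name, df in (("doses", doses), ("growth", growth), ("invasion", invasion)):
            write_table(df, out / f"{name}.csv", meta())
            manifest["outputs"].append(str(out / f"{name}.csv"))
        manifest["stages_completed"].append(stage)
        log.info("simulate: %d wells in %.1fs", len(stacks), _time.perf_counter() - t0)

        stage = "zonate"
        t0 = _time.perf_counter()
        frames = []
        for label, stack in stacks.items():
            profile = quantify_zones(stack, config.geometry, threshold=config.threshold)
            frames.append(profile.to_frame(well_id=label))
        profiles = pd.concat(frames, ignore_index=True)
        write_table(profiles, out / "zone_profiles.csv", meta())
        manifest["outputs"].append(str(out / "zone_profiles.csv"))
        manifest["stages_completed"].append(stage)
        log.info("zonate: %d profiles in %.1fs", len(frames), _time.perf_counter() - t0)

        stage = "score"
        scored = score_profiles(profiles)
        scores = dict(zip(scored["label"], scored["score"]))
        write_table(scored, out / "scores.csv", meta())
        spatial_ranks = rank_populations({l: scores[l] for l in non_ref})
        write_table(spatial_ranks, out / "rank_table.csv", meta())
        manifest["outputs"] += [str(out / "scores.csv"), str(out / "rank_table.csv")]
        if config.ref_inner and config.ref_outer:
            calls = pd.DataFrame(
                {
                    "label": non_ref,
                    "call": [
                        classify_configuration(
                            scores[l], scores[config.ref_inner], scores[config.ref_outer]
                        )
                        for l in non_ref
                    ],
                }
            )
            write_table(calls, out / "configuration_calls.csv", meta())
            manifest["outputs"].append(str(out / "configuration_calls.csv"))
        manifest["stages_completed"].append(stage)

        stage = "phenotype"
        metrics = compute_phenotype_metrics(doses, growth, invasion)
        write_table(metrics, out / "phenotype_metrics.csv", meta())
        resistance_ranks = rank_and_split(
            dict(zip(metrics["label"], metrics["resistance"]))
        )
        write_table(resistance_ranks, out / "phenotype_ranks.csv", meta())
        manifest["outputs"] += [
            str(out / "phenotype_metrics.csv"),
            str(out / "phenotype_ranks.csv"),
        ]
        manifest["stages_completed"].append(stage)

        stage = "correlate"
        rho, agreement = concordance(spatial_ranks, resistance_ranks)
        summary["spearman_rho"] = rho
        summary["group_agreement"] = agreement
        manifest["stages_completed"].append(stage)

        stage = "survive"
        groups = dict(zip(spatial_ranks["label"], spatial_ranks["subgroup"]))
        records = generate_survival(
            groups,
            hazard_ratio=config.hazard_ratio,
            baseline_median=config.baseline_median,
            censor_prob=config.censor_prob,
            n_per_group=config.n_per_group,
            seed=derive_seed(config.seed, 2001),
        )
        write_table(records, out / "survival.csv", meta())
        km_frames = []
        for gname, grp in records.groupby("group"):
            curve = km_estimate(grp["time"], grp["event"]).to_frame()
            curve.insert(0, "group", gname)
            km_frames.append(curve)
        write_table(pd.concat(km_frames, ignore_index=True), out / "km_curves.csv", meta())
        lr = logrank_test(records["time"], records["event"], records["group"])
        write_report(
            {"chi_square": lr.chi_square, "p_value": lr.p_value, **meta()},
            out / "logrank.json",
        )
        manifest["outputs"] += [
            str(out / "survival.csv"),
            str(out / "km_curves.csv"),
            str(out / "logrank.json"),
        ]
        manifest["stages_completed"].append(stage)
        summary["logrank_chi_square"] = lr.chi_square
        summary["logrank_p_value"] = lr.p_value
        summary["spatial_scores"] = {k: float(v) for k, v in scores.items()}
    except Exception as exc:  # noqa: BLE001 — stage name must reach the caller
        _write_manifest(failed=stage)
        raise PipelineError(stage, exc) from exc

    _write_manifest(failed=None)
    write_report(summary, out / "summary.json")
    return summary
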