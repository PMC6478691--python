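"""End-to-end orchestration: phantom -> morphometry -> model prep -> flow
-> sensitivity/statistics, with reproducible seeded configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from pulmolymph import io as plio
from pulmolymph.core import FluidParameters
from pulmolymph.microflow import assemble, export_fields, solve
from pulmolymph.model_prep import identify_vessel_openings, prepare_model_volume
from pulmolymph.morphometry import (
    classify_rois,
    measure_voi,
    pleural_distance_map,
    sample_rois,
    voi_covering,
)
from pulmolymph.stats_report import run_sensitivity
from pulmolymph.synthetic import SyntheticSpec, generate_voi, intralobular_spec

log = logging.getLogger("pulmolymph")


@dataclass
class PipelineConfig:
    """All stage parameters; defaults reproduce the reference settings."""

    out_dir: str = "pulmolymph_out"
    seed: int = 0
    # stage toggles
    run_synth: bool = True
    run_morpho: bool = True
    run_prep: bool = True
    run_flow: bool = True
    run_sensitivity: bool = False
    # synthetic spec (None -> intralobular default at the configured seed)
    synthetic: SyntheticSpec | None = None
    # sampling
    n_rois: int = 25
    roi_side_um: float = 830.0
    depth_um: float = 500.0
    threshold_um: float = 830.0
    max_iter: int = 500
    # model prep (reference settings: x3 upsampling, 3^3 median window)
    upsample: int = 3
    median_window: int = 3
    shrinkage_scale: float = 1.0
    # solver
    params: FluidParameters = field(default_factory=FluidParameters)
    tol: float = 1e-10
    max_backflow_iters: int = 20

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("params") is not None and not isinstance(
                d["params"], FluidParameters):
            d["params"] = FluidParameters(**d["params"])
        if d.get("synthetic") is not None and not isinstance(
                d["synthetic"], SyntheticSpec):
            syn = dict(d["synthetic"])
            from pulmolymph.synthetic import BloodTreeSpec, LymphNetworkSpec
            if isinstance(syn.get("blood_tree"), dict):
                syn["blood_tree"] = BloodTreeSpec(**syn["blood_tree"])
            if isinstance(syn.get("lymph_network"), dict):
                ln = dict(syn["lymph_network"])
                if isinstance(ln.get("radius_um_range"), list):
                    ln["radius_um_range"] = tuple(ln["radius_um_range"])
                syn["lymph_network"] = LymphNetworkSpec(**ln)
            if isinstance(syn.get("shape"), list):
                syn["shape"] = tuple(syn["shape"])
            if isinstance(syn.get("openings"), list):
                syn["openings"] = tuple(
                    (f, tuple(c)) for f, c in syn["openings"])
            d["synthetic"] = SyntheticSpec(**syn)
        return cls(**d)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)   # the hash identifies the computation, not
        # where its artifacts land
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the artifact directory.

    Every output carries the config hash and seed; a stage failure raises
    a stage-named error while earlier artifacts stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    (out / "config.json").write_text(
        json.dumps({**config.to_dict(), **stamp}, indent=1, default=str))

    volume = None
    if config.run_synth:
        try:
            spec = config.synthetic or intralobular_spec(seed=config.seed)
            volume, truth = generate_voi(spec)
            plio.write_volume(volume, out / "phantom.tif")
            plio.write_truth_csv(
                [{"bin": i,
                  "depth_lo_um": truth.depth_bin_edges_um[i],
                  "depth_hi_um": truth.depth_bin_edges_um[i + 1],
                  "target_vf": truth.target_vf_per_bin[i],
                  "realized_vf": truth.realized_vf_per_bin[i],
                  **stamp}
                 for i in range(len(truth.target_vf_per_bin))],
                out / "phantom_truth.csv")
        except Exception as exc:
            raise RuntimeError(f"stage synth failed: {exc}") from exc

    vois = None
    if config.run_morpho:
        try:
            if volume is None:
                raise RuntimeError("morpho stage needs a volume (enable synth "
                                   "or load one explicitly)")
            dist = pleural_distance_map(volume)
            sampled = sample_rois(volume, z_plane=volume.shape[0] // 2,
                                  roi_side_um=min(
                                      config.roi_side_um,
                                      volume.shape[1] * volume.voxel_pitch / 2),
                                  n_target=min(config.n_rois, 4),
                                  max_iter=config.max_iter, seed=config.seed)
            vois = classify_rois(sampled.rois, volume, dist,
                                 threshold_um=config.threshold_um,
                                 depth_um=min(config.depth_um,
                                              volume.shape[0]
                                              * volume.voxel_pitch / 2))
            records = [measure_voi(volume, v) for v in vois]
            frame = plio.morphometry_to_frame(records, vois)
            for k, v in stamp.items():
                frame[k] = v
            frame.to_csv(out / "morphometry.csv", index=False)
        except Exception as exc:
            raise RuntimeError(f"stage morpho failed: {exc}") from exc

    model = boundaries = None
    if config.run_prep:
        try:
            if volume is None:
                raise RuntimeError("prep stage needs a volume")
            model = prepare_model_volume(volume, voi=None,
                                         upsample=config.upsample,
                                         median_window=config.median_window,
                                         shrinkage_scale=config.shrinkage_scale)
            boundaries = identify_vessel_openings(
                model, volume.pleural_direction or "-z")
            (out / "boundaries.json").write_text(json.dumps({
                "distal_faces": list(boundaries.distal_faces),
                "counts": {c: list(v) for c, v in boundaries.counts().items()},
                "warnings": boundaries.warnings, **stamp}, indent=1))
        except Exception as exc:
            raise RuntimeError(f"stage prep failed: {exc}") from exc

    solution = None
    if config.run_flow:
        try:
            if model is None:
                raise RuntimeError("flow stage needs a prepared model")
            system = assemble(model, boundaries, config.params)
            solution = solve(system, tol=config.tol,
                             max_backflow_iters=config.max_backflow_iters)
            flux = solution.fluxes
            (out / "flow.json").write_text(json.dumps({
                "Q_L_in": flux.Q_L_in, "Q_B_out": flux.Q_B_out,
                "inlet_flux": flux.inlet_flux,
                "outlet_flux": flux.outlet_flux,
                "interstitial_exchange_in": flux.interstitial_exchange_in,
                "balance_defect": flux.balance_defect,
                "residuals": solution.residuals,
                "suppressed_outlet_faces": solution.suppressed_outlet_faces,
                **stamp}, indent=1))
            export_fields(solution, model, out / "fields.vtk")
        except Exception as exc:
            raise RuntimeError(f"stage flow failed: {exc}") from exc

    if config.run_sensitivity:
        try:
            if model is None:
                raise RuntimeError("sensitivity stage needs a prepared model")
            rep = run_sensitivity(model, boundaries, config.params,
                                  tol=config.tol)
            (out / "sensitivity.json").write_text(json.dumps({
                "base_Q_L_in": rep.base_Q_L_in,
                "discretization_error": rep.discretization_error,
                "rows": rep.rows, **stamp}, indent=1, default=float))
        except Exception as exc:
            raise RuntimeError(f"stage sensitivity failed: {exc}") from exc

    log.info("pipeline artifacts written to %s", out)
    return out
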