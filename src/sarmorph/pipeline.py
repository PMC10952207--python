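"""End-to-end study orchestration: phantoms -> registration -> fields ->
CP-mode and random-shim SAR -> VOP -> agreement reports.

A single global seed fans out to named per-stage substreams (recorded in
the manifest) so any stage can be re-run in isolation bit-identically.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coilfields import CoilModel, combine_fields, efield_sq_difference, simulate_channel_fields
from .core import AffineTransform, TissueTable, default_tissue_table
from .dosimetry import cp_mode, cp_shim
from .phantoms import (
    PhantomSpec,
    apply_transform_to_model,
    make_phantom,
    perturb_segmentation,
    reference_spec,
    subject_spec,
    synthesize_t1,
)
from .registration import dice, extract_brain_mask, property_difference_maps, register_affine, register_nonlinear
from .shimming import ShimSet, build_q_matrices, compress_vop, generate_shims, max10g_exact, max10g_vop
from .stats import ComparisonReport, b1_rmse, uncertainty_comparison

__all__ = ["RunConfig", "run_morphometry_study", "run_uncertainty_study", "stage_seed"]

REGISTRATION_METHODS = ("none", "rigid", "affine", "nonlinear")

DEFAULT_UNCERTAINTY_OPS = [
    {"op": "split_tissue", "tissue": "skull", "inner": "cancellous_bone",
     "outer": "cortical_bone", "depth": 1},
    {"op": "insert_layer", "outer": "csf", "inner": "gray_matter", "new": "dura",
     "thickness": 1},
    {"op": "boundary_flip", "p": 0.2},
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (global seed + stage name)."""
    ss = np.random.SeedSequence([global_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % 2**31)


@dataclass
class RunConfig:
    """All knobs of a reproducible study run."""

    voxel_size_mm: float = 4.0
    reference: str = "reference"
    targets: tuple = ("subject_a",)
    neck_slab: bool = False
    tissue_table_path: str | None = None
    registration_methods: tuple = ("none", "affine", "nonlinear")
    noise_sd: float | None = None
    n_shims: int = 5000
    shim_total_power_w: float = 5.0
    vop_lambda: float = 0.05
    vop_enabled: bool = True
    target_mass_g: float = 10.0
    max_half_width: int = 7
    cp_target_b1_ut: float = 2.0
    coil: dict = field(default_factory=dict)
    field_sim: dict = field(default_factory=dict)
    uncertainty_ops: list = field(default_factory=lambda: list(DEFAULT_UNCERTAINTY_OPS))
    seed: int = 0
    outdir: str = "out"

    def __post_init__(self):
        for m in self.registration_methods:
            if m not in REGISTRATION_METHODS:
                raise ValueError(f"unknown registration method {m!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        data = {k: tuple(v) if k in ("targets", "registration_methods") else v
                for k, v in data.items()}
        return cls(**data)

    def tissue_table(self) -> TissueTable:
        if self.tissue_table_path:
            return TissueTable.from_csv(self.tissue_table_path)
        return default_tissue_table()

    def coil_model(self) -> CoilModel:
        return CoilModel(**self.coil)

    def phantom_spec(self, name: str) -> PhantomSpec:
        if name == "reference":
            return reference_spec(self.neck_slab)
        return subject_spec(name, self.neck_slab)


class _Manifest:
    def __init__(self, config: RunConfig):
        self.data = {
            "software_version": __version__,
            "config": asdict(config),
            "stages": [],
        }
        self._t0 = None
        self._name = None

    def start(self, name: str):
        self._t0 = time.time()
        self._name = name

    def done(self, **info):
        self.data["stages"].append(
            {"stage": self._name, "wall_s": round(time.time() - self._t0, 3), **info}
        )

    def write(self, path: Path):
        path.write_text(json.dumps(self.data, indent=2, default=str))


def _estimate_transform(config, ref_img, tgt_img, ref_model, tgt_model, method):
    if method == "none":
        return None
    ref_brain = extract_brain_mask(ref_img, ref_model)
    tgt_brain = extract_brain_mask(tgt_img, tgt_model)
    dof = 6 if method == "rigid" else 12
    aff = register_affine(ref_img, tgt_img, moving_mask=ref_brain, fixed_mask=tgt_brain, dof=dof)
    if method in ("rigid", "affine"):
        return aff
    # whole-head data drive the nonlinear stage
    return register_nonlinear(ref_img, tgt_img, init=aff)


def _model_sar_bundle(config, coil, model, shims, manifest, tag, with_vop):
    """Fields, CP summary, Q set, exact (and optional VOP-bound) series."""
    manifest.start(f"fields[{tag}]")
    fields = simulate_channel_fields(coil, model, **config.field_sim)
    manifest.done()
    cp = cp_mode(fields, coil, model, target_b1_ut=config.cp_target_b1_ut,
                 target_mass_g=config.target_mass_g, max_half_width=config.max_half_width)
    manifest.start(f"qmatrices[{tag}]")
    qset = build_q_matrices(fields, model, target_mass_g=config.target_mass_g,
                            max_half_width=config.max_half_width)
    exact = max10g_exact(qset, shims)
    manifest.done(n_regions=len(qset))
    bound = None
    n_vops = None
    if with_vop:
        manifest.start(f"vop[{tag}]")
        vops = compress_vop(qset, config.vop_lambda)
        bound = max10g_vop(vops, shims)
        n_vops = len(vops)
        manifest.done(n_vops=n_vops)
    return {"fields": fields, "cp": cp, "qset": qset, "exact": exact,
            "bound": bound, "n_vops": n_vops}


def run_morphometry_study(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Full study for every target and registration method; writes reports.

    Returns a results dict keyed (target, method) holding the per-method
    ComparisonReport, DSC table, CP summaries and shim series.
    """
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    table = config.tissue_table()
    coil = config.coil_model()

    manifest.start("phantoms")
    ref_model = make_phantom(config.phantom_spec(config.reference), table, config.voxel_size_mm)
    ref_img = synthesize_t1(ref_model, config.noise_sd, seed=stage_seed(config.seed, "t1:reference"))
    manifest.done()

    manifest.start("shims")
    shims = generate_shims(config.n_shims, coil.n_channels, config.shim_total_power_w,
                           seed=stage_seed(config.seed, "shims"))
    shims.to_csv(outdir / "shims.csv")
    manifest.done(n=len(shims))

    results = {}
    for target in config.targets:
        tgt_model = make_phantom(config.phantom_spec(target), table, config.voxel_size_mm)
        tgt_img = synthesize_t1(tgt_model, config.noise_sd,
                                seed=stage_seed(config.seed, f"t1:{target}"))
        native = _model_sar_bundle(config, coil, tgt_model, shims, manifest,
                                   f"{target}:native", with_vop=False)
        native["cp"].to_json(outdir / f"cp_{target}_native.json")
        for method in config.registration_methods:
            manifest.start(f"register[{target}:{method}]")
            transform = _estimate_transform(config, ref_img, tgt_img, ref_model, tgt_model, method)
            manifest.done()
            warped = apply_transform_to_model(ref_model, transform, tgt_model)
            dsc = dice(tgt_model, warped)
            props = property_difference_maps(warped, tgt_model)
            bundle = _model_sar_bundle(config, coil, warped, shims, manifest,
                                       f"{target}:{method}", with_vop=config.vop_enabled)
            mask = warped.head_mask() | tgt_model.head_mask()
            rmse = b1_rmse(bundle["cp"].b1p_norm, native["cp"].b1p_norm, mask)
            ediff = efield_sq_difference(bundle["fields"], native["fields"], warped,
                                         tgt_model, cp_shim(coil))
            report = ComparisonReport(
                bundle["exact"], native["exact"],
                label_a=f"warped_{config.reference}_{method}", label_b=target,
                extras={
                    "dsc": dsc.to_dict(),
                    "dsc_mean": dsc.mean(),
                    "b1_rmse_ut": rmse,
                    "mean_abs_e2_diff": ediff["mean_abs_diff"],
                    "mean_conductivity_diff": props["mean_conductivity_diff"],
                    "mean_density_diff": props["mean_density_diff"],
                    "head_mass_warped_kg": props["head_mass_a_kg"],
                    "head_mass_target_kg": props["head_mass_b_kg"],
                    "n_vops": bundle["n_vops"],
                },
            )
            if bundle["bound"] is not None:
                over = bundle["bound"] / bundle["exact"] - 1.0
                report.extras["vop_max_overestimation_pct"] = float(100 * over.max())
                report.extras["vop_underestimates"] = bool((over < -1e-9).any())
            stem = f"{target}_{method}"
            report.to_json(outdir / f"report_{stem}.json")
            report.pairs_to_csv(outdir / f"pairs_{stem}.csv")
            pd.DataFrame(
                sorted(dsc.per_group.items()), columns=["dsc_group", "dsc"]
            ).to_csv(outdir / f"dsc_{stem}.csv", index=False)
            bundle["cp"].to_json(outdir / f"cp_{stem}.json")
            if isinstance(transform, AffineTransform):
                transform.save(outdir / f"affine_{stem}.txt")
            results[(target, method)] = {"report": report, "dsc": dsc, "cp": bundle["cp"],
                                         "cp_native": native["cp"], "exact": bundle["exact"],
                                         "exact_native": native["exact"],
                                         "bound": bundle["bound"], "b1_rmse": rmse}
    manifest.write(outdir / "manifest.json")
    return results


def run_uncertainty_study(config: RunConfig, outdir: str | Path | None = None) -> ComparisonReport:
    """Segmentation-uncertainty mode: perturb one target's labels, re-simulate
    fields, evaluate the same shim list on both variants (morphometry fixed)."""
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    table = config.tissue_table()
    coil = config.coil_model()
    target = config.targets[0]

    manifest.start("phantom")
    model = make_phantom(config.phantom_spec(target), table, config.voxel_size_mm)
    manifest.done()
    manifest.start("perturb")
    variant = perturb_segmentation(model, config.uncertainty_ops,
                                   seed=stage_seed(config.seed, "perturb"))
    manifest.done()
    shims = generate_shims(config.n_shims, coil.n_channels, config.shim_total_power_w,
                           seed=stage_seed(config.seed, "shims"))
    shims.to_csv(outdir / "shims.csv")
    base = _model_sar_bundle(config, coil, model, shims, manifest, "uncert:v2", with_vop=False)
    pert = _model_sar_bundle(config, coil, variant, shims, manifest, "uncert:v1", with_vop=False)
    report = uncertainty_comparison(pert["qset"], base["qset"], shims)
    report.to_json(outdir / "uncertainty_report.json")
    report.pairs_to_csv(outdir / "uncertainty_pairs.csv")
    manifest.write(outdir / "manifest_uncertainty.json")
    return report
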