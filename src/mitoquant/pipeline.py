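"""End-to-end simulated-division experiments.

Each replicate builds a ground-truthed synthetic cell, simulates the
acquisition of a bleaching two-channel timeseries across a division,
pushes the two endpoint stacks (metaphase, post-cytokinesis) through the
processing chain (align on the red channel, re-apply to green, subtract
bleedthrough, crop, Richardson-Lucy), and measures:

* normalised fluorescence (integrated density post/meta) for multi-step
  and two-step acquisition schedules,
* normalised globally-thresholded segmented quantity (foreground voxels
  post/meta),
* fixed- and relative-mode histograms of the processed stacks and the
  class position of the threshold in each.

Across replicates these feed the invariance statistics: fluorescence drops
with bleaching, segmented quantity does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import histanalysis, preprocess, segmentation, synthgen, tseries
from .optics import PSFModel, gaussian_psf, theoretical_psf
from .rois import ROISet

__all__ = [
    "DivisionMeasurement",
    "ExperimentConfig",
    "run_division_replicate",
    "run_two_step_replicate",
    "run_invariance_battery",
    "process_division_with_intermediates",
    "bleach_trace_replicate",
    "summarise_battery",
]


@dataclass
class ExperimentConfig:
    """Study conditions for one simulated division experiment."""

    scene: synthgen.SceneSpec = field(default_factory=synthgen.SceneSpec)
    schedule: synthgen.BleachSchedule = field(default_factory=synthgen.BleachSchedule)
    bleedthrough_fraction: float = 0.08
    subtract_fraction: float = 0.12
    rl_iterations: int = 20
    jitter: Optional[synthgen.JitterModel] = field(default_factory=synthgen.JitterModel)
    noise: Optional[synthgen.NoiseModel] = field(default_factory=synthgen.NoiseModel)
    psf_shape: tuple[int, int, int] = (13, 33, 33)
    acquisition_psf_shape: tuple[int, int, int] = (9, 17, 17)
    roi_margin_um: float = 0.3
    threshold_algorithm: str = "isodata"
    fixed_x_max: float = histanalysis.FIXED_XMAX_PROCESSED

    def deconvolution_psf(self) -> np.ndarray:
        """Theoretical diffraction PSF at the green emission peak (RL input)."""
        model = PSFModel(
            emission_wavelength=510.0, voxel_size=self.scene.voxel_size
        )
        return theoretical_psf(model, self.psf_shape)

    def acquisition_psf(self) -> np.ndarray:
        """Compact processed-acquisition blur applied by the simulator."""
        return gaussian_psf(
            voxel_size=self.scene.voxel_size, shape=self.acquisition_psf_shape
        )


@dataclass
class DivisionMeasurement:
    seed: int
    fluorescence_ratio: float           # post/meta integrated density
    quantity_ratio: float               # post/meta segmented voxels
    threshold_meta: float
    threshold_post: float
    threshold_ratio: float
    quantity_meta: int
    quantity_post: int
    true_quantity_meta: int
    true_quantity_post: int
    hist_fixed_meta: histanalysis.GreyHistogram
    hist_fixed_post: histanalysis.GreyHistogram
    hist_rel_meta: histanalysis.GreyHistogram
    hist_rel_post: histanalysis.GreyHistogram
    class_fixed_meta: int
    class_fixed_post: int
    class_rel_meta: int
    class_rel_post: int


def _process_endpoint(
    red: np.ndarray,
    green: np.ndarray,
    rois: ROISet,
    cfg: ExperimentConfig,
    deconv_psf: np.ndarray,
) -> tuple[float, np.ndarray, ROISet]:
    """Align, subtract, crop and deconvolve one endpoint stack.

    Returns (integrated density on the aligned+subtracted green stack,
    processed green stack, ROIs cropped to the processed z-range).
    """
    _, tset = preprocess.align_stack(red)
    green_al = preprocess.apply_transforms(green, tset)
    green_sub = preprocess.subtract_bleedthrough(
        green_al, preprocess.apply_transforms(red, tset), cfg.subtract_fraction
    )
    intden = tseries.integrated_density(green_sub, rois)

    z0, z1 = rois.slice_range
    box = ((z0, z1 + 1), (0, green.shape[1]), (0, green.shape[2]))
    cropped = preprocess.crop_roi(green_sub, box)
    processed = preprocess.rl_deconvolve(cropped, deconv_psf, cfg.rl_iterations)
    cropped_rois = ROISet(
        polygons={z - z0: rois.polygons[z] for z in rois.polygons if z0 <= z <= z1}
    )
    return intden, processed, cropped_rois


def _segment_quantity(
    processed: np.ndarray, rois: ROISet, cfg: ExperimentConfig
) -> tuple[int, float]:
    thr = segmentation.global_threshold(processed, algorithm=cfg.threshold_algorithm)
    mask = processed > thr.value
    masked = segmentation.mask_outside_rois(mask, rois)
    return int(np.count_nonzero(masked)), thr.value


def run_division_replicate(
    seed: int,
    cfg: Optional[ExperimentConfig] = None,
    two_step: bool = False,
    psfs: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> DivisionMeasurement:
    """Simulate one division and measure the endpoint quantities.

    Multi-step mode acquires a z-stack at every interval, so the
    post-cytokinesis frame has accrued bleach from every earlier event.
    Two-step mode acquires only the two endpoint stacks: bleach accrues per
    acquisition event, so the late frame carries a single event's worth.
    """
    cfg = cfg or ExperimentConfig()
    scene_spec = replace(cfg.scene, rng_seed=seed)
    rng = np.random.default_rng(seed)
    mother = synthgen.generate_scene(scene_spec, rng)
    daughters = synthgen.divide_scene(mother, rng)

    acq_psf, deconv_psf = psfs if psfs is not None else (
        cfg.acquisition_psf(),
        cfg.deconvolution_psf(),
    )

    if two_step:
        schedule = replace(cfg.schedule, n_timepoints=2)
        scenes: Sequence[synthgen.Scene] = [mother, daughters]
        frames = [0, 1]
    else:
        schedule = cfg.schedule
        n_t = schedule.n_timepoints
        div = n_t // 2
        scenes = [mother] * div + [daughters] * (n_t - div)
        frames = [0, n_t - 1]

    sim = synthgen.simulate_timeseries(
        scenes,
        schedule,
        psf=acq_psf,
        bleedthrough_fraction=cfg.bleedthrough_fraction,
        jitter=cfg.jitter,
        noise=cfg.noise,
        rng_seed=seed,
        timepoints=frames,
    )
    stack = sim.stack.data.astype(np.float64)

    rois_meta = synthgen.cell_rois(mother, cfg.roi_margin_um)
    rois_post = synthgen.cell_rois(daughters, cfg.roi_margin_um)

    intden_m, proc_m, crois_m = _process_endpoint(
        stack[0, 0], stack[0, 1], rois_meta, cfg, deconv_psf
    )
    intden_p, proc_p, crois_p = _process_endpoint(
        stack[1, 0], stack[1, 1], rois_post, cfg, deconv_psf
    )

    q_m, thr_m = _segment_quantity(proc_m, crois_m, cfg)
    q_p, thr_p = _segment_quantity(proc_p, crois_p, cfg)

    hf_m = histanalysis.grey_histogram(proc_m, "fixed", cfg.fixed_x_max)
    hf_p = histanalysis.grey_histogram(proc_p, "fixed", cfg.fixed_x_max)
    hr_m = histanalysis.grey_histogram(proc_m, "relative")
    hr_p = histanalysis.grey_histogram(proc_p, "relative")

    return DivisionMeasurement(
        seed=seed,
        fluorescence_ratio=intden_p / intden_m,
        quantity_ratio=q_p / q_m if q_m else float("nan"),
        threshold_meta=thr_m,
        threshold_post=thr_p,
        threshold_ratio=thr_p / thr_m if thr_m else float("nan"),
        quantity_meta=q_m,
        quantity_post=q_p,
        true_quantity_meta=mother.true_foreground_voxels,
        true_quantity_post=daughters.true_foreground_voxels,
        hist_fixed_meta=hf_m,
        hist_fixed_post=hf_p,
        hist_rel_meta=hr_m,
        hist_rel_post=hr_p,
        class_fixed_meta=histanalysis.threshold_class_position(thr_m, hf_m),
        class_fixed_post=histanalysis.threshold_class_position(thr_p, hf_p),
        class_rel_meta=histanalysis.threshold_class_position(thr_m, hr_m),
        class_rel_post=histanalysis.threshold_class_position(thr_p, hr_p),
    )


def run_two_step_replicate(
    seed: int,
    cfg: Optional[ExperimentConfig] = None,
    acq_psf: Optional[np.ndarray] = None,
) -> float:
    """Fluorescence ratio for a two-stack acquisition of the same division.

    Only the two endpoint stacks are acquired, so the late frame carries a
    single prior event's worth of bleach.  The two-step protocol measures
    integrated density only (no segmentation), so the processing stops
    after alignment and bleedthrough subtraction.
    """
    cfg = cfg or ExperimentConfig()
    scene_spec = replace(cfg.scene, rng_seed=seed)
    rng = np.random.default_rng(seed)
    mother = synthgen.generate_scene(scene_spec, rng)
    daughters = synthgen.divide_scene(mother, rng)
    if acq_psf is None:
        acq_psf = cfg.acquisition_psf()
    schedule = replace(cfg.schedule, n_timepoints=2)
    sim = synthgen.simulate_timeseries(
        [mother, daughters],
        schedule,
        psf=acq_psf,
        bleedthrough_fraction=cfg.bleedthrough_fraction,
        jitter=cfg.jitter,
        noise=cfg.noise,
        rng_seed=seed + 10_000,
    )
    stack = sim.stack.data.astype(np.float64)
    ratios = []
    for t, scene in enumerate((mother, daughters)):
        rois = synthgen.cell_rois(scene, cfg.roi_margin_um)
        _, tset = preprocess.align_stack(stack[t, 0])
        green_al = preprocess.apply_transforms(stack[t, 1], tset)
        red_al = preprocess.apply_transforms(stack[t, 0], tset)
        green_sub = preprocess.subtract_bleedthrough(
            green_al, red_al, cfg.subtract_fraction
        )
        ratios.append(tseries.integrated_density(green_sub, rois))
    return ratios[1] / ratios[0]


def run_invariance_battery(
    n_replicates: int = 20,
    base_seed: int = 1,
    cfg: Optional[ExperimentConfig] = None,
    include_two_step: bool = True,
) -> dict:
    """Run seeded division replicates and collect the endpoint measurements.

    Returns a dict with the per-replicate DataFrame, the list of
    DivisionMeasurement objects, and (if requested) the two-step
    fluorescence ratios.
    """
    cfg = cfg or ExperimentConfig()
    psfs = (cfg.acquisition_psf(), cfg.deconvolution_psf())
    measurements = []
    two_step_ratios = []
    for i in range(n_replicates):
        seed = base_seed + i
        m = run_division_replicate(seed, cfg, psfs=psfs)
        measurements.append(m)
        if include_two_step:
            two_step_ratios.append(run_two_step_replicate(seed, cfg, psfs[0]))
    table = pd.DataFrame(
        {
            "seed": [m.seed for m in measurements],
            "fluorescence_ratio": [m.fluorescence_ratio for m in measurements],
            "quantity_ratio": [m.quantity_ratio for m in measurements],
            "threshold_ratio": [m.threshold_ratio for m in measurements],
            "class_fixed_meta": [m.class_fixed_meta for m in measurements],
            "class_fixed_post": [m.class_fixed_post for m in measurements],
            "class_rel_meta": [m.class_rel_meta for m in measurements],
            "class_rel_post": [m.class_rel_post for m in measurements],
            "true_ratio": [
                m.true_quantity_post / m.true_quantity_meta for m in measurements
            ],
        }
    )
    return {
        "table": table,
        "measurements": measurements,
        "two_step_ratios": np.asarray(two_step_ratios),
        "config": cfg,
    }


def summarise_battery(battery: dict) -> dict:
    """Invariance statistics and histogram contrasts for a battery run."""
    table: pd.DataFrame = battery["table"]
    ms: list[DivisionMeasurement] = battery["measurements"]

    fluor = tseries.invariance_tests(table["fluorescence_ratio"])
    quant = tseries.invariance_tests(table["quantity_ratio"])
    out = {"fluorescence": fluor, "quantity": quant}
    if len(battery["two_step_ratios"]) >= 3:
        out["two_step"] = tseries.invariance_tests(battery["two_step_ratios"])

    mean_fixed_meta = np.mean([m.hist_fixed_meta.frequencies for m in ms], axis=0)
    mean_fixed_post = np.mean([m.hist_fixed_post.frequencies for m in ms], axis=0)
    mean_rel_meta = np.mean([m.hist_rel_meta.frequencies for m in ms], axis=0)
    mean_rel_post = np.mean([m.hist_rel_post.frequencies for m in ms], axis=0)
    out["fixed_regression"] = histanalysis.log_frequency_regression(
        mean_fixed_meta, mean_fixed_post
    )
    out["relative_regression"] = histanalysis.log_frequency_regression(
        mean_rel_meta, mean_rel_post
    )

    out["class_shift_fixed"] = tseries.invariance_tests(
        (table["class_fixed_post"] - table["class_fixed_meta"]).to_numpy(dtype=float),
        popmean=0.0,
    )
    rel_shift = (table["class_rel_post"] - table["class_rel_meta"]).to_numpy(dtype=float)
    out["class_shift_relative_mean"] = float(rel_shift.mean())
    try:
        out["class_shift_relative"] = tseries.invariance_tests(rel_shift, popmean=0.0)
    except ValueError:
        out["class_shift_relative"] = {"mean": float(rel_shift.mean())}

    out["threshold_bleach"] = histanalysis.threshold_bleach_correlation(
        table["threshold_ratio"], table["fluorescence_ratio"]
    )
    return out


def process_division_with_intermediates(
    seed: int,
    cfg: Optional[ExperimentConfig] = None,
    outdir: Optional["str | Path"] = None,
) -> dict:
    """One simulated division with every processing stage written to disk.

    Saves the raw two-channel endpoint stacks and, per endpoint, the
    aligned, bleedthrough-subtracted, cropped and deconvolved green stacks
    (OME-TIFF) plus the transform text files, per-object CSV tables and a
    JSON report — the save-points of the processing chain.
    """
    from pathlib import Path

    from . import segmentation as segm
    from .stackio import ImageStack, write_stack

    cfg = cfg or ExperimentConfig()
    outdir = Path(outdir) if outdir is not None else Path("mitoquant_division")
    outdir.mkdir(parents=True, exist_ok=True)

    scene_spec = replace(cfg.scene, rng_seed=seed)
    rng = np.random.default_rng(seed)
    mother = synthgen.generate_scene(scene_spec, rng)
    daughters = synthgen.divide_scene(mother, rng)
    acq_psf, deconv_psf = cfg.acquisition_psf(), cfg.deconvolution_psf()
    n_t = cfg.schedule.n_timepoints
    div = n_t // 2
    sim = synthgen.simulate_timeseries(
        [mother] * div + [daughters] * (n_t - div),
        cfg.schedule,
        psf=acq_psf,
        bleedthrough_fraction=cfg.bleedthrough_fraction,
        jitter=cfg.jitter,
        noise=cfg.noise,
        rng_seed=seed,
        timepoints=[0, n_t - 1],
    )
    vs = cfg.scene.voxel_size
    write_stack(sim.stack, outdir / "raw.ome.tif")
    synthgen.save_ground_truth(sim.ground_truth, outdir / "raw")

    report: dict = {"seed": seed}
    for name, t, scene in (("metaphase", 0, mother), ("postcytokinesis", 1, daughters)):
        red = sim.stack.data[t, 0].astype(np.float64)
        green = sim.stack.data[t, 1].astype(np.float64)
        rois = synthgen.cell_rois(scene, cfg.roi_margin_um)

        _, tset = preprocess.align_stack(red)
        tset.to_text(outdir / f"{name}.transforms.txt")
        green_al = preprocess.apply_transforms(green, tset)
        red_al = preprocess.apply_transforms(red, tset)
        write_stack(
            ImageStack(green_al[None, None], voxel_size=vs),
            outdir / f"{name}.aligned.ome.tif",
        )
        green_sub = preprocess.subtract_bleedthrough(
            green_al, red_al, cfg.subtract_fraction
        )
        write_stack(
            ImageStack(green_sub[None, None], voxel_size=vs),
            outdir / f"{name}.subtracted.ome.tif",
        )
        z0, z1 = rois.slice_range
        cropped = preprocess.crop_roi(
            green_sub, ((z0, z1 + 1), (0, green.shape[1]), (0, green.shape[2]))
        )
        write_stack(
            ImageStack(cropped[None, None], voxel_size=vs),
            outdir / f"{name}.cropped.ome.tif",
        )
        processed = preprocess.rl_deconvolve(cropped, deconv_psf, cfg.rl_iterations)
        write_stack(
            ImageStack(processed[None, None].astype(np.float32), voxel_size=vs),
            outdir / f"{name}.deconvolved.ome.tif",
        )

        thr = segm.global_threshold(processed, algorithm=cfg.threshold_algorithm)
        seg = segm.measure_objects(processed > thr.value, vs, mode="3d")
        seg.objects.to_csv(outdir / f"{name}.objects.csv", index=False)
        rois.to_json(outdir / f"{name}.rois.json")
        report[name] = {
            "integrated_density": tseries.integrated_density(green_sub, rois),
            "threshold": thr.value,
            "total_quantity": seg.total_quantity,
            "n_objects": int(len(seg.objects)),
        }

    report["fluorescence_ratio"] = (
        report["postcytokinesis"]["integrated_density"]
        / report["metaphase"]["integrated_density"]
    )
    report["quantity_ratio"] = (
        report["postcytokinesis"]["total_quantity"]
        / report["metaphase"]["total_quantity"]
    )
    import json

    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def bleach_trace_replicate(
    seed: int,
    cfg: Optional[ExperimentConfig] = None,
    acq_psf: Optional[np.ndarray] = None,
) -> tseries.BleachSeries:
    """Full multi-step trace: integrated density at every acquisition event.

    The specimen is simulated without motion jitter (alignment does not
    change integrated densities inside generous ROIs) and measured on
    bleedthrough-subtracted green stacks, one value per timepoint.
    """
    cfg = cfg or ExperimentConfig()
    scene_spec = replace(cfg.scene, rng_seed=seed)
    rng = np.random.default_rng(seed)
    mother = synthgen.generate_scene(scene_spec, rng)
    daughters = synthgen.divide_scene(mother, rng)
    if acq_psf is None:
        acq_psf = cfg.acquisition_psf()
    n_t = cfg.schedule.n_timepoints
    div = n_t // 2
    scenes = [mother] * div + [daughters] * (n_t - div)
    sim = synthgen.simulate_timeseries(
        scenes,
        cfg.schedule,
        psf=acq_psf,
        bleedthrough_fraction=cfg.bleedthrough_fraction,
        jitter=None,
        noise=cfg.noise,
        rng_seed=seed,
    )
    rois_m = synthgen.cell_rois(mother, cfg.roi_margin_um)
    rois_d = synthgen.cell_rois(daughters, cfg.roi_margin_um)
    volumes = []
    rois_list = []
    for t in range(n_t):
        red = sim.stack.data[t, 0].astype(np.float64)
        green = sim.stack.data[t, 1].astype(np.float64)
        volumes.append(
            preprocess.subtract_bleedthrough(green, red, cfg.subtract_fraction)
        )
        rois_list.append(rois_m if t < div else rois_d)
    return tseries.integrated_density_trace(
        volumes, rois_list, interval_s=cfg.schedule.interval_s
    )
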