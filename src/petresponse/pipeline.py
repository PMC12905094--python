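"""End-to-end pipeline: simulate -> segment -> quantify -> pvc -> respond -> report.

Every stage reads and writes plain files (NIfTI volumes and masks, CSV
tables, JSON summaries) inside one output directory, so each number in the
final report can be recomputed from persisted intermediates.  A run is
deterministic given its seed, and the resolved configuration is echoed
into the output directory alongside a stage-granular log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import demo_cohort_spec, seed_inits_from_truth
from .delineation import SeedInit, delineate
from .image import (
    GridSpec,
    SuvImage,
    load_mask_nifti,
    load_suv_nifti,
    save_mask_nifti,
    save_suv_nifti,
)
from .phantom import (
    GroundTruthManifest,
    LesionSpec,
    PairedStudySpec,
    PhantomSpec,
    generate_paired_study,
)
from .pvc import RlConfig, make_gaussian_psf, richardson_lucy_damped
from .quantify import (
    EVALUABLE_VOLUME_ML,
    FDG_AVID_SUV_MAX,
    LesionMetrics,
    compute_lesion_metrics,
)
from .response import (
    ResponseThresholds,
    build_response_table,
    per_target_table,
    summarize_all,
)

logger = logging.getLogger("petresponse")

__all__ = ["AnalysisConfig", "run_pipeline", "load_config"]


@dataclass
class AnalysisConfig:
    """Resolved parameters of one analysis run.

    The defaults reproduce the reference parameter set: 4-mm isotropic
    voxels on a 96x96x64 grid, evaluability at 1.728 mL, FDG avidity at
    7.5 g/mL, response/progression thresholds at +15%/+30%, and
    Richardson-Lucy correction with 5 iterations, damping 0.1, a 4-mm-FWHM
    Gaussian PSF on an 11-voxel kernel and no subsampling.
    """

    seed: int = 0
    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: float = 4.0
    background_suv: float = 1.0
    blur_fwhm_mm: float = 4.0
    noise_sigma_suv: float = 0.1
    demo_cohort: bool = True
    lesions: list[dict] = field(default_factory=list)
    true_rd_percent: dict[int, float] = field(default_factory=dict)
    propagate_baseline_masks: bool = True
    evaluable_volume_ml: float = EVALUABLE_VOLUME_ML
    fdg_avid_suv_max: float = FDG_AVID_SUV_MAX
    response_max_percent: float = 15.0
    progression_min_percent: float = 30.0
    rl_iterations: int = 5
    rl_damping: float = 0.1
    rl_fwhm_mm: float = 4.0
    rl_kernel_size: int = 11
    rl_subsample: int = 1
    maximize_sphere_mean: bool = False

    @property
    def thresholds(self) -> ResponseThresholds:
        return ResponseThresholds(
            response_max_percent=self.response_max_percent,
            progression_min_percent=self.progression_min_percent,
        )

    @property
    def rl_config(self) -> RlConfig:
        return RlConfig(
            iterations=self.rl_iterations,
            damping=self.rl_damping,
            subsample=self.rl_subsample,
        )

    def paired_study_spec(self) -> PairedStudySpec:
        if self.demo_cohort:
            return demo_cohort_spec(seed=self.seed)
        lesions = []
        for d in self.lesions:
            semi = d.get("semi_axes_mm")
            if semi is None:
                r = float(d["radius_mm"])
                semi = (r, r, r)
            lesions.append(
                LesionSpec(
                    lesion_id=int(d["lesion_id"]),
                    center_mm=tuple(d["center_mm"]),
                    semi_axes_mm=tuple(semi),
                    true_suv=float(d["true_suv"]),
                )
            )
        baseline = PhantomSpec(
            grid=GridSpec(shape=self.grid_shape, spacing_mm=self.spacing_mm),
            background_suv=self.background_suv,
            lesions=tuple(lesions),
            blur_fwhm_mm=self.blur_fwhm_mm,
            noise_sigma_suv=self.noise_sigma_suv,
            rng_seed=self.seed,
        )
        rd = {int(k): float(v) for k, v in self.true_rd_percent.items()}
        return PairedStudySpec(baseline=baseline, true_rd_percent=rd)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        return d


def load_config(path=None, **overrides) -> AnalysisConfig:
    """Load a YAML config file; keyword overrides win over file values."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "grid_shape" in data:
        data["grid_shape"] = tuple(data["grid_shape"])
    return AnalysisConfig(**data)


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def metrics_to_frame(
    metrics: dict[str, dict[int, LesionMetrics]]
) -> pd.DataFrame:
    """Flatten {(condition, timepoint): {lesion_id: LesionMetrics}} to a table."""
    rows = []
    for (condition, timepoint), per_lesion in metrics.items():
        for lid, m in sorted(per_lesion.items()):
            rows.append(
                {
                    "lesion_id": lid,
                    "condition": condition,
                    "timepoint": timepoint,
                    "suv_max": m.suv_max,
                    "suv_mean": m.suv_mean,
                    "suv_peak": m.suv_peak if m.suv_peak is not None else np.nan,
                    "volume_ml": m.volume_ml,
                    "evaluable": m.evaluable,
                    "fdg_avid": m.fdg_avid,
                }
            )
    return pd.DataFrame(rows)


def simulate_stage(config: AnalysisConfig, outdir: Path) -> tuple[SuvImage, SuvImage, GroundTruthManifest]:
    """Generate the paired study and persist volumes, manifest and roster."""
    spec = config.paired_study_spec()
    pre, post, truth = generate_paired_study(spec)
    save_suv_nifti(pre, outdir / "pre.nii.gz", description="baseline SUV")
    save_suv_nifti(post, outdir / "post.nii.gz", description="follow-up SUV")
    truth.to_json(outdir / "ground_truth.json")
    truth.to_frame().to_csv(outdir / "lesion_roster.csv", index=False)
    inits = seed_inits_from_truth(truth, pre.grid)
    seed_rows = [
        {
            "lesion_id": lid,
            "seed_i": s.seed_voxel[0],
            "seed_j": s.seed_voxel[1],
            "seed_k": s.seed_voxel[2],
            "drag_i": s.drag_voxel[0],
            "drag_j": s.drag_voxel[1],
            "drag_k": s.drag_voxel[2],
        }
        for lid, s in sorted(inits.items())
    ]
    pd.DataFrame(seed_rows).to_csv(outdir / "seeds.csv", index=False)
    logger.info("simulate: %d lesions on grid %s", len(truth.lesions), pre.grid.shape)
    return pre, post, truth


def read_seeds_csv(path) -> dict[int, SeedInit]:
    df = pd.read_csv(path)
    return {
        int(r.lesion_id): SeedInit(
            seed_voxel=(int(r.seed_i), int(r.seed_j), int(r.seed_k)),
            drag_voxel=(int(r.drag_i), int(r.drag_j), int(r.drag_k)),
        )
        for r in df.itertuples()
    }


def segment_stage(
    image: SuvImage,
    seeds: dict[int, SeedInit],
    outdir: Path | None = None,
    tag: str = "baseline",
) -> dict[int, np.ndarray]:
    """Delineate every seeded lesion; optionally persist masks as NIfTI."""
    masks = {}
    for lid, init in sorted(seeds.items()):
        lesion_mask = delineate(image, init, lesion_id=lid)
        masks[lid] = lesion_mask.mask
        logger.info("segment[%s]: lesion %d -> %d voxels", tag, lid, lesion_mask.n_voxels)
        if outdir is not None:
            save_mask_nifti(lesion_mask.mask, image.grid, outdir / f"mask_{lid:02d}.nii.gz")
    return masks


def quantify_stage(
    image: SuvImage, masks: dict[int, np.ndarray], config: AnalysisConfig
) -> dict[int, LesionMetrics]:
    out = {}
    for lid, mask in sorted(masks.items()):
        m = compute_lesion_metrics(
            image, mask, lesion_id=lid, maximize_sphere_mean=config.maximize_sphere_mean
        )
        if m.suv_peak is None:
            logger.warning("quantify: lesion %d has no SUV_peak (degenerate sphere)", lid)
        out[lid] = m
    return out


def pvc_stage(
    pre: SuvImage, post: SuvImage, config: AnalysisConfig, outdir: Path | None = None
) -> tuple[SuvImage, SuvImage]:
    """Richardson-Lucy correction of both timepoints with one PSF/config."""
    psf = make_gaussian_psf(
        config.rl_fwhm_mm, pre.grid.spacing_mm, size=config.rl_kernel_size
    )
    cfg = config.rl_config
    pre_pvc = richardson_lucy_damped(pre, psf, cfg)
    post_pvc = richardson_lucy_damped(post, psf, cfg)
    params = {
        "iterations": cfg.iterations,
        "damping": cfg.damping,
        "subsample": cfg.subsample,
        "fwhm_mm": config.rl_fwhm_mm,
        "kernel_size": config.rl_kernel_size,
    }
    if outdir is not None:
        desc = f"RL PVC it={cfg.iterations} damp={cfg.damping} fwhm={config.rl_fwhm_mm}"
        save_suv_nifti(pre_pvc, outdir / "pre_pvc.nii.gz", description=desc)
        save_suv_nifti(post_pvc, outdir / "post_pvc.nii.gz", description=desc)
        _write_json(params, outdir / "pvc_params.json")
    logger.info("pvc: %s", params)
    return pre_pvc, post_pvc


def respond_stage(
    metrics: dict[tuple[str, str], dict[int, LesionMetrics]],
    config: AnalysisConfig,
    outdir: Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build per-target response tables and the four cohort summary blocks."""
    baseline_raw_suv_max = {
        lid: m.suv_max for lid, m in metrics[("raw", "pre")].items()
    }
    tables = []
    for condition in ("raw", "pvc"):
        if (condition, "pre") not in metrics:
            continue
        tables.append(
            build_response_table(
                metrics[(condition, "pre")],
                metrics[(condition, "post")],
                condition=condition,
                baseline_raw_suv_max=baseline_raw_suv_max,
                thresholds=config.thresholds,
            )
        )
    table = pd.concat(tables, ignore_index=True)
    summary = summarize_all(table)
    target_table = per_target_table(table)
    if outdir is not None:
        target_table.to_csv(outdir / "per_target_responses.csv", index=False)
        summary.to_csv(outdir / "cohort_summaries.csv", index=False)
        blocks = {}
        for r in summary.itertuples():
            key = f"{r.metric}.{r.subset}.{r.condition}"
            blocks[key] = {
                "n_targets": int(r.n_targets),
                "n_response": int(r.n_response),
                "n_indeterminate": int(r.n_indeterminate),
                "n_progression": int(r.n_progression),
                "rate_response": None if pd.isna(r.rate_response) else r.rate_response,
                "rate_indeterminate": None
                if pd.isna(r.rate_indeterminate)
                else r.rate_indeterminate,
                "rate_progression": None
                if pd.isna(r.rate_progression)
                else r.rate_progression,
            }
        _write_json(blocks, outdir / "cohort_summaries.json")
    return table, summary


def truth_comparison(
    truth: GroundTruthManifest, table: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Measured vs true relative differences and categories per target."""
    from .response import classify

    true_rows = {
        t.lesion_id: t for t in truth.lesions
    }
    rows = []
    sub = table[(table["metric"] == "suv_mean") & (table["condition"] == "raw")]
    for r in sub.itertuples():
        t = true_rows[r.lesion_id]
        rows.append(
            {
                "lesion_id": r.lesion_id,
                "true_rd_percent": t.true_rd_percent,
                "measured_rd_percent": r.rd_percent,
                "true_category": classify(t.true_rd_percent, config.thresholds),
                "measured_category": r.category,
                "true_volume_ml": t.true_volume_ml,
                "measured_volume_ml": r.volume_ml,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: AnalysisConfig, outdir) -> dict:
    """Run every stage and write the full report bundle.

    Returns a dictionary with the in-memory stage products (images, masks,
    metrics, tables) for programmatic use.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

        pre, post, truth = simulate_stage(config, outdir)
        seeds = read_seeds_csv(outdir / "seeds.csv")
        masks_dir = outdir / "masks"
        masks_dir.mkdir(exist_ok=True)
        masks = segment_stage(pre, seeds, masks_dir, tag="baseline")
        if not config.propagate_baseline_masks:
            masks_post = segment_stage(post, seeds, masks_dir, tag="followup")
        else:
            masks_post = masks

        metrics = {
            ("raw", "pre"): quantify_stage(pre, masks, config),
            ("raw", "post"): quantify_stage(post, masks_post, config),
        }
        pre_pvc, post_pvc = pvc_stage(pre, post, config, outdir)
        metrics[("pvc", "pre")] = quantify_stage(pre_pvc, masks, config)
        metrics[("pvc", "post")] = quantify_stage(post_pvc, masks_post, config)
        metrics_to_frame(metrics).to_csv(outdir / "lesion_metrics.csv", index=False)

        table, summary = respond_stage(metrics, config, outdir)
        truth_cmp = truth_comparison(truth, table, config)
        truth_cmp.to_csv(outdir / "truth_comparison.csv", index=False)

        manifest = {
            "package_version": __version__,
            "python_version": platform.python_version(),
            "numpy_version": np.__version__,
            "seed": config.seed,
            "stages": [
                "simulate",
                "segment",
                "quantify",
                "pvc",
                "respond",
                "report",
            ],
        }
        _write_json(manifest, outdir / "run_manifest.json")
        logger.info("report: bundle written to %s", outdir)
    except Exception:
        logger.exception("pipeline aborted")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return {
        "pre": pre,
        "post": post,
        "truth": truth,
        "masks": masks,
        "metrics": metrics,
        "table": table,
        "summary": summary,
        "truth_comparison": truth_cmp,
    }
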