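"""Config-driven orchestration of whole-map, ROI and context analyses.

Each run resolves every parameter explicitly, derives per-stage random
substreams from a single global seed, and writes a machine-readable manifest
(inputs, resolved parameters, seed, package version) alongside its outputs so
any result can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .context_bow import (
    apply_context_exclusions,
    build_bow,
    jsd_similarity,
    stopword_hash,
)
from .events_io import BoldRun, SceneTable, load_bold, load_scene_table
from .group_stats import ClusterResult, cluster_mass_correct, signflip_test
from .model import ContextModulationModel, ReactivationModel
from .reactivation import reactivation_timecourse, timecourse_summary
from .representations import searchlight_spheres
from .simulate import (
    SimulationConfig,
    SpectralHighpass,
    gen_one_over_f,
    plant_reactivation,
    scene_timings_fitting,
)

__all__ = [
    "AnalysisConfig",
    "load_config",
    "build_cohort",
    "run_reactivation_map",
    "run_roi_timecourse",
    "run_context_map",
]


@dataclasses.dataclass
class AnalysisConfig:
    """Validated analysis parameters; every field is recorded in the manifest."""

    dataset_style: str = "sherlock_like"
    analysis_variant: str = "within"
    index_mode: str = "main_effect"
    d_total: int = 10
    control_offset_trs: int = 10
    hrf_shift_trs: int = 4
    gap_trs: int = 5
    searchlight_radius: float = 3.0
    n_permutations: int = 1000
    voxel_p: float = 0.05
    cluster_p: float = 0.005
    connectivity: int = 26
    tails: str = "two"
    seed: int = 0
    output_dir: str = "eventreact_out"
    # real data: list of {"bold": path, "mask": path}; scene_table path
    subjects: list | None = None
    scene_table: str | None = None
    # synthetic cohort: generated when subjects is None
    synthetic: dict = dataclasses.field(
        default_factory=lambda: {
            "n_subjects": 10,
            "grid": [5, 5, 5],
            "plant_weight": 0.0,
            "plant_rule": "fixed_lag",
            "plant_lag": 3,
        }
    )
    context: dict = dataclasses.field(
        default_factory=lambda: {"exclude_scenes": [], "partial_minwords": True}
    )

    def __post_init__(self):
        if self.analysis_variant not in ("within", "between_boundary", "between_scene"):
            raise ValueError(f"unknown analysis_variant {self.analysis_variant!r}")
        if self.index_mode not in ("main_effect", "congruent_only", "interaction"):
            raise ValueError(f"unknown index_mode {self.index_mode!r}")
        if self.d_total < 0 or self.d_total % 2:
            raise ValueError("d_total must be an even integer >= 0")
        if not 0 < self.voxel_p < 1 or not 0 < self.cluster_p < 1:
            raise ValueError("thresholds must lie in (0, 1)")


def load_config(path: str | Path) -> AnalysisConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return AnalysisConfig(**raw)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(config: AnalysisConfig, out: Path, stage: str, extra: dict):
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stopword_hash": stopword_hash(),
        **extra,
    }
    out.mkdir(parents=True, exist_ok=True)
    (out / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _grid_coords(grid: Sequence[int]) -> np.ndarray:
    nx, ny, nz = grid
    return np.array(
        [(i, j, k) for i in range(nx) for j in range(ny) for k in range(nz)], dtype=int
    )


def build_cohort(
    config: AnalysisConfig, rng: np.random.Generator
) -> tuple[list[BoldRun], SceneTable]:
    """Load the configured cohort, or synthesise one on a small voxel grid."""
    if config.subjects:
        if not config.scene_table:
            raise ValueError("scene_table is required with real subjects")
        table = load_scene_table(config.scene_table)
        runs = [load_bold(s["bold"], s["mask"]) for s in config.subjects]
        return runs, table
    spec = config.synthetic
    sim_cfg = (
        SimulationConfig.sherlock_like()
        if config.dataset_style == "sherlock_like"
        else SimulationConfig.year21_like()
    )
    sim_cfg = dataclasses.replace(
        sim_cfg,
        n_subjects=int(spec.get("n_subjects", 10)),
        hrf_shift_trs=config.hrf_shift_trs,
        gap_trs=config.gap_trs,
    )
    grid = spec.get("grid", [5, 5, 5])
    coords = _grid_coords(grid)
    n_vox = coords.shape[0]
    table = scene_timings_fitting(sim_cfg, rng)
    filt = SpectralHighpass(
        sim_cfg.n_trs, sim_cfg.tr_seconds, sim_cfg.highpass_cutoff_s
    )
    weight = float(spec.get("plant_weight", 0.0))
    runs = []
    for _ in range(sim_cfg.n_subjects):
        data = filt.apply(gen_one_over_f(sim_cfg.n_trs, n_vox, seed=rng))
        if weight > 0:
            data = plant_reactivation(
                data,
                table,
                target_rule=spec.get("plant_rule", "fixed_lag"),
                weight=weight,
                hrf_shift_trs=config.hrf_shift_trs,
                lag=int(spec.get("plant_lag", 3)),
                gap_trs=config.gap_trs,
                seed=rng,
            )
        runs.append(
            BoldRun(data=data, tr_seconds=sim_cfg.tr_seconds, voxel_coords=coords)
        )
    return runs, table


def _maps_to_grid(values: np.ndarray, coords: np.ndarray) -> np.ndarray:
    shape = tuple(coords.max(axis=0) + 1)
    grid = np.zeros(shape)
    grid[tuple(coords.T)] = values
    return grid


def run_reactivation_map(config: AnalysisConfig, runs=None, table=None):
    """Searchlight reactivation maps with cluster-mass correction.

    Computes the reactivation index per sphere centre per subject, then a
    sign-flip cluster-mass-corrected group map; writes NIfTI maps, a subject
    TSV and a manifest.  Returns (subject_maps, ClusterResult).
    """
    out = Path(config.output_dir)
    rng_cohort, rng_cluster = _substreams(config.seed, 2)
    if runs is None or table is None:
        runs, table = build_cohort(config, rng_cohort)
    coords = runs[0].voxel_coords
    spheres = searchlight_spheres(coords, config.searchlight_radius)
    n_sub = len(runs)
    grid_shape = tuple(coords.max(axis=0) + 1)
    maps = np.zeros((n_sub,) + grid_shape)
    for c, sphere in enumerate(spheres):
        sub_runs = [
            BoldRun(
                data=r.data[:, sphere],
                tr_seconds=r.tr_seconds,
                voxel_coords=r.voxel_coords[sphere],
            )
            for r in runs
        ]
        model = ReactivationModel(
            sub_runs,
            table,
            d_total=config.d_total,
            mode=config.index_mode,
            variant=config.analysis_variant,
            hrf_shift_trs=config.hrf_shift_trs,
            gap_trs=config.gap_trs,
        )
        cc = tuple(coords[c])
        for s in range(n_sub):
            maps[(s,) + cc] = model.subject_index(s)
    cluster = cluster_mass_correct(
        maps,
        voxel_p=config.voxel_p,
        cluster_p=config.cluster_p,
        n_permutations=config.n_permutations,
        connectivity=config.connectivity,
        tails=config.tails,
        rng=rng_cluster,
        mask=_maps_to_grid(np.ones(len(coords)), coords) > 0,
    )
    _save_map_outputs(config, out, maps, cluster, runs[0])
    _write_manifest(
        config,
        out,
        "reactivation_map",
        {
            "n_subjects": n_sub,
            "n_spheres": len(spheres),
            "surviving_clusters": int(cluster.cluster_labels.max()),
        },
    )
    return maps, cluster


def _save_map_outputs(config, out: Path, maps, cluster: ClusterResult, ref_run):
    import nibabel as nib

    out.mkdir(parents=True, exist_ok=True)
    affine = ref_run.affine if ref_run.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(cluster.t_map.astype(np.float32), affine), out / "group_t.nii.gz")
    nib.save(
        nib.Nifti1Image(cluster.cluster_labels.astype(np.int16), affine),
        out / "clusters.nii.gz",
    )
    cluster.clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)


def run_roi_timecourse(
    config: AnalysisConfig,
    roi_mask: np.ndarray | None = None,
    runs=None,
    table=None,
    window=tuple(range(-3, 13)),
    min_scene_len_trs: int = 20,
):
    """TR-resolved ROI reactivation timecourses and their group summary test.

    ``roi_mask`` is boolean over the cohort's voxels (default: all voxels).
    Returns (per-subject timecourse array, per-subject summaries, StatResult).
    """
    out = Path(config.output_dir)
    rng_cohort, rng_test = _substreams(config.seed, 2)
    if runs is None or table is None:
        runs, table = build_cohort(config, rng_cohort)
    if roi_mask is None:
        roi_mask = np.ones(runs[0].n_voxels, bool)
    roi_mask = np.asarray(roi_mask, bool)
    if roi_mask.sum() == 0:
        raise ValueError("empty ROI")
    tcs = []
    for r in runs:
        roi_run = BoldRun(
            data=r.data[:, roi_mask],
            tr_seconds=r.tr_seconds,
            voxel_coords=r.voxel_coords[roi_mask],
        )
        tcs.append(
            reactivation_timecourse(
                roi_run,
                table,
                window=window,
                min_scene_len_trs=min_scene_len_trs,
                d_total=config.d_total,
                mode=config.index_mode,
                hrf_shift_trs=config.hrf_shift_trs,
                gap_trs=config.gap_trs,
            )
        )
    tcs = np.array(tcs)
    summaries = np.array([timecourse_summary(tc, window) for tc in tcs])
    stat = signflip_test(
        summaries,
        n_permutations=config.n_permutations,
        tails=config.tails,
        rng=rng_test,
    )
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(tcs, columns=[f"tr{o:+d}" for o in window])
    df.insert(0, "subject", np.arange(len(runs)))
    df["summary"] = summaries
    df.to_csv(out / "roi_timecourses.tsv", sep="\t", index=False)
    _write_manifest(
        config,
        out,
        "roi_timecourse",
        {"n_subjects": len(runs), "statistic": stat.statistic, "p": stat.p_value},
    )
    return tcs, summaries, stat


def run_context_map(
    config: AnalysisConfig,
    transcripts: Sequence[str] | None = None,
    runs=None,
    table=None,
    roi_mask: np.ndarray | None = None,
):
    """Context-modulation statistics per sphere (or per ROI).

    Builds the bag-of-words model once, computes the per-subject modulation
    statistic (time main effect, or Time x Congruency interaction when
    ``index_mode='interaction'``), and runs one-tailed group inference.  With
    ``roi_mask`` set, returns the ROI StatResult; otherwise a cluster-
    corrected one-tailed map.
    """
    out = Path(config.output_dir)
    rng_cohort, rng_stat = _substreams(config.seed, 2)
    if runs is None or table is None:
        runs, table = build_cohort(config, rng_cohort)
    if transcripts is None:
        transcripts = [s.text for s in table.scenes]
        if not any(transcripts):
            raise ValueError("no transcripts available for the context model")
    ctx = build_bow(transcripts, scene_index=[s.index for s in table.scenes])
    jsd_similarity(ctx)
    exclude = config.context.get("exclude_scenes", [])
    if exclude:
        ctx = apply_context_exclusions(ctx, exclude)
    mode = "interaction" if config.index_mode == "interaction" else "main_effect"
    partial = bool(config.context.get("partial_minwords", True))

    def make_model(sub_runs):
        return ContextModulationModel(
            sub_runs,
            table,
            ctx,
            d_total=config.d_total,
            mode=mode,
            variant=config.analysis_variant,
            partial_minwords=partial,
            hrf_shift_trs=config.hrf_shift_trs,
            gap_trs=config.gap_trs,
        )

    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, bool)
        roi_runs = [
            BoldRun(
                data=r.data[:, roi_mask],
                tr_seconds=r.tr_seconds,
                voxel_coords=r.voxel_coords[roi_mask],
            )
            for r in runs
        ]
        res = make_model(roi_runs).fit(
            n_permutations=config.n_permutations, tails="one", rng=rng_stat
        )
        _write_manifest(
            config,
            out,
            "context_roi",
            {"statistic": res.stat.statistic, "p": res.stat.p_value},
        )
        return res
    coords = runs[0].voxel_coords
    spheres = searchlight_spheres(coords, config.searchlight_radius)
    grid_shape = tuple(coords.max(axis=0) + 1)
    maps = np.zeros((len(runs),) + grid_shape)
    for c, sphere in enumerate(spheres):
        sub_runs = [
            BoldRun(
                data=r.data[:, sphere],
                tr_seconds=r.tr_seconds,
                voxel_coords=r.voxel_coords[sphere],
            )
            for r in runs
        ]
        model = make_model(sub_runs)
        cc = tuple(coords[c])
        for s in range(len(runs)):
            maps[(s,) + cc] = model.subject_index(s)
    cluster = cluster_mass_correct(
        maps,
        voxel_p=config.voxel_p,
        cluster_p=config.cluster_p,
        n_permutations=config.n_permutations,
        connectivity=config.connectivity,
        tails="one",
        rng=rng_stat,
        mask=_maps_to_grid(np.ones(len(coords)), coords) > 0,
    )
    _save_map_outputs(config, out, maps, cluster, runs[0])
    _write_manifest(
        config,
        out,
        "context_map",
        {"surviving_clusters": int(cluster.cluster_labels.max())},
    )
    return maps, cluster
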