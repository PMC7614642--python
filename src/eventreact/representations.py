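"""Boundary and scene representations from masked BOLD runs.

A boundary representation is the voxel pattern at the single TR that ends a
scene, shifted by the hemodynamic (HRF) delay.  A scene representation is the
mean pattern over within-scene TRs that are at least ``gap_trs`` away from
both adjacent event boundaries, so that boundary and scene samples never
alias.  With gap g, a contiguous scene of L TRs retains exactly
max(0, L - 2g + 1) TRs; at the default g = 5 a 10-TR scene is the shortest
with a non-empty interior.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .events_io import BoldRun, SceneTable

__all__ = [
    "RepresentationSet",
    "extract_boundary_reps",
    "extract_scene_reps",
    "extract_representations",
    "searchlight_spheres",
    "average_reps_across_subjects",
]

DEFAULT_HRF_SHIFT_TRS = 4
DEFAULT_GAP_TRS = 5


@dataclasses.dataclass
class RepresentationSet:
    """Boundary (n_boundaries x voxels) and scene (n_scenes x voxels) patterns."""

    boundary_reps: np.ndarray
    scene_reps: np.ndarray
    boundary_scene_index: np.ndarray  # serial index of the scene each boundary ends
    scene_index: np.ndarray
    hrf_shift_trs: int
    gap_trs: int


def _included(table: SceneTable):
    scenes = table.included
    if not scenes:
        raise ValueError("no included scenes in table")
    return scenes


def extract_boundary_reps(
    run: BoldRun,
    table: SceneTable,
    hrf_shift_trs: int = DEFAULT_HRF_SHIFT_TRS,
    extra_offset_trs: int = 0,
) -> np.ndarray:
    """Voxel pattern at each included scene's boundary TR + shifts.

    ``extra_offset_trs`` supports control timepoints (e.g. -10/+10 TRs) and
    TR-resolved timecourse sampling.
    """
    rows = []
    for s in _included(table):
        tr = s.boundary_tr + hrf_shift_trs + extra_offset_trs
        if not 1 <= tr <= run.n_trs:
            raise ValueError(
                f"boundary of scene {s.index} falls at TR {tr}, outside run "
                f"of {run.n_trs} TRs"
            )
        rows.append(run.data[tr - 1])
    return np.array(rows)


def scene_interior_trs(
    table: SceneTable,
    scene: "int | None" = None,
    gap_trs: int = DEFAULT_GAP_TRS,
    hrf_shift_trs: int = DEFAULT_HRF_SHIFT_TRS,
) -> dict[int, np.ndarray]:
    """1-based TRs contributing to each included scene's representation.

    A TR t (in unshifted stimulus time) is admissible for scene s when
    ``t - previous_boundary_tr >= gap_trs`` and ``boundary_tr - t >= gap_trs``;
    the whole window is then HRF-shifted.  The previous boundary of the first
    scene is taken as the TR before its onset.
    """
    out: dict[int, np.ndarray] = {}
    scenes = table.scenes
    for k, s in enumerate(scenes):
        if s.excluded:
            continue
        if scene is not None and s.index != scene:
            continue
        prev_boundary = scenes[k - 1].offset_tr if k > 0 else s.onset_tr - 1
        lo = max(s.onset_tr, prev_boundary + gap_trs)
        hi = s.offset_tr - gap_trs
        trs = np.arange(lo, hi + 1) + hrf_shift_trs
        out[s.index] = trs
    return out


def extract_scene_reps(
    run: BoldRun,
    table: SceneTable,
    gap_trs: int = DEFAULT_GAP_TRS,
    hrf_shift_trs: int = DEFAULT_HRF_SHIFT_TRS,
) -> np.ndarray:
    """Mean pattern over each included scene's admissible interior TRs."""
    interiors = scene_interior_trs(table, gap_trs=gap_trs, hrf_shift_trs=hrf_shift_trs)
    rows = []
    for s in _included(table):
        trs = interiors[s.index]
        if trs.size == 0:
            raise ValueError(
                f"scene {s.index} has no admissible interior TRs at gap "
                f"{gap_trs}; it should have been excluded upstream"
            )
        if trs[0] < 1 or trs[-1] > run.n_trs:
            raise ValueError(f"scene {s.index} interior extends outside the run")
        rows.append(run.data[trs - 1].mean(axis=0))
    return np.array(rows)


def extract_representations(
    run: BoldRun,
    table: SceneTable,
    hrf_shift_trs: int = DEFAULT_HRF_SHIFT_TRS,
    gap_trs: int = DEFAULT_GAP_TRS,
    extra_offset_trs: int = 0,
) -> RepresentationSet:
    idx = np.array([s.index for s in _included(table)])
    return RepresentationSet(
        boundary_reps=extract_boundary_reps(
            run, table, hrf_shift_trs=hrf_shift_trs, extra_offset_trs=extra_offset_trs
        ),
        scene_reps=extract_scene_reps(
            run, table, gap_trs=gap_trs, hrf_shift_trs=hrf_shift_trs
        ),
        boundary_scene_index=idx,
        scene_index=idx.copy(),
        hrf_shift_trs=hrf_shift_trs,
        gap_trs=gap_trs,
    )


def searchlight_spheres(
    voxel_coords: np.ndarray, radius_voxels: float = 3.0
) -> list[np.ndarray]:
    """In-mask voxel index sets within Euclidean ``radius_voxels`` of each voxel.

    Distances are in voxel units; ties at the radius are included.  Spheres
    are clipped at mask edges and always contain their centre.
    """
    coords = np.asarray(voxel_coords, dtype=int)
    lookup = {tuple(c): i for i, c in enumerate(coords)}
    r = float(radius_voxels)
    ri = int(np.floor(r))
    offsets = [
        (dx, dy, dz)
        for dx in range(-ri, ri + 1)
        for dy in range(-ri, ri + 1)
        for dz in range(-ri, ri + 1)
        if dx * dx + dy * dy + dz * dz <= r * r + 1e-9
    ]
    spheres = []
    for c in coords:
        members = []
        cx, cy, cz = (int(v) for v in c)
        for dx, dy, dz in offsets:
            j = lookup.get((cx + dx, cy + dy, cz + dz))
            if j is not None:
                members.append(j)
        spheres.append(np.array(sorted(members)))
    return spheres


def average_reps_across_subjects(
    rep_list: Sequence[np.ndarray], leave_out: int
) -> np.ndarray:
    """Element-wise mean of all subjects' matrices except ``leave_out``."""
    if len(rep_list) < 2:
        raise ValueError("need at least 2 subjects to average the others")
    shapes = {np.shape(m) for m in rep_list}
    if len(shapes) != 1:
        raise ValueError(f"representation shape mismatch: {shapes}")
    if not 0 <= leave_out < len(rep_list):
        raise IndexError(f"leave_out {leave_out} out of range")
    others = [np.asarray(m, float) for i, m in enumerate(rep_list) if i != leave_out]
    return np.mean(others, axis=0)
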