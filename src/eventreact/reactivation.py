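"""Boundary-by-scene similarity matrices and reactivation indices.

The similarity matrix holds Fisher-z-transformed Pearson correlations
between each event-boundary pattern (rows) and each scene pattern (columns).
Cell (i, j) has ``offset = row_scene_index[i] - col_scene_index[j]``;
offsets > 0 are *past* (the boundary follows the scene), offsets < 0 are
*future*.  The main diagonal (offset 0, the just-ended scene) is always in
the removal mask.  The reactivation index is the difference between the mean
of unmasked past cells and the mean of unmasked future cells: symmetric
scene-by-scene structure appears equally in both parts and cancels, so a
positive index indicates reinstatement of past information.

High-pass-filtered fMRI noise induces artefactual correlations around the
main diagonal.  ``removal_mask_for`` builds the symmetric diagonal-removal
set (d/2 past diagonals including the main diagonal, d/2 future diagonals)
used to neutralise that bias in within-participant analyses.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .events_io import BoldRun, SceneTable
from .representations import (
    DEFAULT_GAP_TRS,
    DEFAULT_HRF_SHIFT_TRS,
    extract_boundary_reps,
    extract_scene_reps,
)

__all__ = [
    "SimilarityMatrix",
    "boundary_scene_similarity",
    "removal_mask_for",
    "reactivation_index",
    "balanced_control_contrast",
    "flush_control_variant",
    "reactivation_timecourse",
    "timecourse_summary",
]

_R_CLIP = 1.0 - 1e-15  # keeps Fisher z finite for degenerate perfect correlations

INDEX_MODES = ("main_effect", "congruent_only", "interaction")


def congruency_from_labels(
    row_labels: np.ndarray, col_labels: np.ndarray, joint_label: str = "JOINT"
) -> np.ndarray:
    """Same-narrative mask; JOINT scenes are congruent with everything."""
    row_labels = np.asarray(row_labels)
    col_labels = np.asarray(col_labels)
    same = row_labels[:, None] == col_labels[None, :]
    joint = (row_labels[:, None] == joint_label) | (col_labels[None, :] == joint_label)
    return same | joint


@dataclasses.dataclass
class SimilarityMatrix:
    """Fisher-z boundary-by-scene similarity with offset bookkeeping."""

    z: np.ndarray
    row_scene_index: np.ndarray
    col_scene_index: np.ndarray
    removal_mask: np.ndarray  # True = cell excluded from analysis
    congruency: np.ndarray | None = None  # True = same narrative

    def __post_init__(self):
        self.z = np.asarray(self.z, float)
        self.row_scene_index = np.asarray(self.row_scene_index, int)
        self.col_scene_index = np.asarray(self.col_scene_index, int)
        self.removal_mask = np.asarray(self.removal_mask, bool)
        if self.z.shape != (self.row_scene_index.size, self.col_scene_index.size):
            raise ValueError("z shape inconsistent with scene indices")
        if self.removal_mask.shape != self.z.shape:
            raise ValueError("removal_mask shape mismatch")
        if not np.isfinite(self.z[~self.removal_mask]).all():
            raise ValueError("non-finite similarity outside the removal mask")

    @property
    def offsets(self) -> np.ndarray:
        return self.row_scene_index[:, None] - self.col_scene_index[None, :]

    def past_cells(self) -> np.ndarray:
        return (self.offsets > 0) & ~self.removal_mask

    def future_cells(self) -> np.ndarray:
        return (self.offsets < 0) & ~self.removal_mask

    def with_offsets_removed(self, offsets: Sequence[int]) -> "SimilarityMatrix":
        mask = self.removal_mask.copy()
        off = self.offsets
        for o in offsets:
            mask |= off == o
        return dataclasses.replace(self, removal_mask=mask)

    def with_diagonals_removed(self, d_total: int) -> "SimilarityMatrix":
        """Apply the symmetric d-diagonal removal; d_total=0 is a no-op
        (only the always-masked main diagonal remains removed)."""
        if d_total == 0:
            return self
        return self.with_offsets_removed(sorted(removal_mask_for_offsets(d_total)))


def removal_mask_for_offsets(d_total: int) -> frozenset[int]:
    if d_total % 2 != 0 or d_total < 2:
        raise ValueError("d_total must be an even integer >= 2")
    past = range(0, d_total // 2)  # main diagonal belongs to the past part
    future = range(-d_total // 2, 0)
    return frozenset(past) | frozenset(future)


def removal_mask_for(n_scenes: int, d_total: int) -> frozenset[int]:
    """Offsets removed by a symmetric d-diagonal removal.

    Positive offsets are past: {0, ..., d/2-1} (the just-ended scene and the
    d/2-1 before it) and {-1, ..., -d/2} (the d/2 scenes after the boundary).
    """
    offs = removal_mask_for_offsets(d_total)
    if d_total >= n_scenes:
        raise ValueError(
            f"removing {d_total} diagonals from a {n_scenes}-scene matrix "
            "leaves no analysable cells"
        )
    return offs


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def _rowwise_standardise(m: np.ndarray):
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    zero = sd[:, 0] == 0
    sd[zero] = 1.0
    return (m - mu) / sd, zero


def boundary_scene_similarity(
    boundary_reps: np.ndarray,
    scene_reps: np.ndarray,
    congruency_labels: np.ndarray | None = None,
    boundary_scene_index: np.ndarray | None = None,
    scene_index: np.ndarray | None = None,
) -> SimilarityMatrix:
    """Fisher-z Pearson correlations between boundary and scene patterns.

    The main diagonal (each boundary against its own just-ended scene) is
    masked at construction.  Zero-variance patterns yield masked cells with
    a warning rather than NaNs.
    """
    B = np.asarray(boundary_reps, float)
    S = np.asarray(scene_reps, float)
    if B.ndim != 2 or S.ndim != 2 or B.shape[1] != S.shape[1]:
        raise ValueError("boundary and scene matrices must share the voxel axis")
    if B.shape[1] < 3:
        raise ValueError("need at least 3 voxels for a defined correlation")
    rows = (
        np.arange(1, B.shape[0] + 1)
        if boundary_scene_index is None
        else np.asarray(boundary_scene_index, int)
    )
    cols = (
        np.arange(1, S.shape[0] + 1)
        if scene_index is None
        else np.asarray(scene_index, int)
    )
    Bz, bad_b = _rowwise_standardise(B)
    Sz, bad_s = _rowwise_standardise(S)
    r = Bz @ Sz.T / B.shape[1]
    z = _fisher_z(r)
    mask = rows[:, None] == cols[None, :]  # main diagonal
    if bad_b.any() or bad_s.any():
        warnings.warn(
            f"{int(bad_b.sum())} boundary and {int(bad_s.sum())} scene patterns "
            "have zero variance; their cells are masked",
            RuntimeWarning,
            stacklevel=2,
        )
        mask = mask | bad_b[:, None] | bad_s[None, :]
        z[mask] = 0.0
    congruency = None
    if congruency_labels is not None:
        labels = np.asarray(congruency_labels)
        lab_by_idx = dict(zip(cols.tolist(), labels.tolist()))
        row_labels = np.array([lab_by_idx.get(i, "NONE") for i in rows.tolist()])
        congruency = congruency_from_labels(row_labels, labels)
    return SimilarityMatrix(
        z=z,
        row_scene_index=rows,
        col_scene_index=cols,
        removal_mask=mask,
        congruency=congruency,
    )


def _part_mean(sim: SimilarityMatrix, cells: np.ndarray, name: str) -> float:
    if not cells.any():
        raise ValueError(f"no unmasked cells in the {name} part")
    return float(sim.z[cells].mean())


def reactivation_index(sim: SimilarityMatrix, mode: str = "main_effect") -> float:
    """Past-minus-future reactivation index over unmasked cells.

    ``main_effect``: mean(past) - mean(future).  ``congruent_only``: the same
    restricted to congruent cells.  ``interaction``: the Time x Congruency
    interaction [past(cong) - past(incong)] - [future(cong) - future(incong)],
    with unweighted means per cell class.
    """
    if mode not in INDEX_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {INDEX_MODES}")
    past = sim.past_cells()
    future = sim.future_cells()
    if mode == "main_effect":
        return _part_mean(sim, past, "past") - _part_mean(sim, future, "future")
    if sim.congruency is None:
        raise ValueError(f"mode {mode!r} requires congruency labels")
    cong = sim.congruency
    if mode == "congruent_only":
        return _part_mean(sim, past & cong, "past congruent") - _part_mean(
            sim, future & cong, "future congruent"
        )
    return (
        _part_mean(sim, past & cong, "past congruent")
        - _part_mean(sim, past & ~cong, "past incongruent")
    ) - (
        _part_mean(sim, future & cong, "future congruent")
        - _part_mean(sim, future & ~cong, "future incongruent")
    )


def flush_control_variant(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Also exclude the post-boundary scene (offset -1); idempotent."""
    if sim.col_scene_index.size < 3:
        raise ValueError("flush control needs at least 3 scenes")
    return sim.with_offsets_removed([-1])


def _similarity_for(
    run: BoldRun,
    table: SceneTable,
    d_total: int,
    hrf_shift_trs: int,
    gap_trs: int,
    extra_offset_trs: int = 0,
    boundary_shift_trs: int | None = None,
    use_congruency: bool = False,
    min_scene_len_trs: int | None = None,
) -> SimilarityMatrix:
    b_shift = hrf_shift_trs if boundary_shift_trs is None else boundary_shift_trs
    scenes = table.included
    idx = np.array([s.index for s in scenes])
    S = extract_scene_reps(run, table, gap_trs=gap_trs, hrf_shift_trs=hrf_shift_trs)
    if min_scene_len_trs is not None:
        rows_keep = np.array([s.length_trs >= min_scene_len_trs for s in scenes])
        if not rows_keep.any():
            raise ValueError(
                f"no boundaries from scenes of >= {min_scene_len_trs} TRs"
            )
    else:
        rows_keep = np.ones(len(scenes), bool)
    B_full = extract_boundary_reps(
        run, table, hrf_shift_trs=b_shift, extra_offset_trs=extra_offset_trs
    )
    labels = np.array([s.narrative for s in scenes]) if use_congruency else None
    return boundary_scene_similarity(
        B_full[rows_keep],
        S,
        congruency_labels=labels,
        boundary_scene_index=idx[rows_keep],
        scene_index=idx,
    ).with_diagonals_removed(d_total)


def balanced_control_contrast(
    run: BoldRun,
    table: SceneTable,
    control_offset_trs: int,
    d_total: int = 2,
    mode: str = "main_effect",
    hrf_shift_trs: int = DEFAULT_HRF_SHIFT_TRS,
    gap_trs: int = DEFAULT_GAP_TRS,
) -> float:
    """Boundary index minus the mean of the two balanced-control indices.

    The controls sample boundary representations ``control_offset_trs``
    before and after each boundary; their filtering-induced biases are
    symmetric in time and cancel in the average.
    """
    use_con = mode in ("congruent_only", "interaction")
    vals = {}
    for tag, extra in (("boundary", 0), ("past", -control_offset_trs), ("future", control_offset_trs)):
        sim = _similarity_for(
            run,
            table,
            d_total,
            hrf_shift_trs,
            gap_trs,
            extra_offset_trs=extra,
            use_congruency=use_con,
        )
        vals[tag] = reactivation_index(sim, mode=mode)
    return vals["boundary"] - 0.5 * (vals["past"] + vals["future"])


DEFAULT_TIMECOURSE_OFFSETS = tuple(range(-3, 13))


def reactivation_timecourse(
    run: BoldRun,
    table: SceneTable,
    window: Sequence[int] = DEFAULT_TIMECOURSE_OFFSETS,
    min_scene_len_trs: int = 20,
    d_total: int = 2,
    mode: str = "main_effect",
    hrf_shift_trs: int = DEFAULT_HRF_SHIFT_TRS,
    gap_trs: int = DEFAULT_GAP_TRS,
) -> np.ndarray:
    """Reactivation index at single TRs around the (HRF-uncorrected) boundary.

    Boundary representations are sampled at the literal scene-end TR plus the
    window offset (no HRF shift), to show the true temporal correspondence;
    only boundaries of scenes of at least ``min_scene_len_trs`` contribute,
    because short-lag autocorrelations are substantial.
    """
    use_con = mode in ("congruent_only", "interaction")
    out = []
    for o in window:
        sim = _similarity_for(
            run,
            table,
            d_total,
            hrf_shift_trs,
            gap_trs,
            extra_offset_trs=int(o),
            boundary_shift_trs=0,
            use_congruency=use_con,
            min_scene_len_trs=min_scene_len_trs,
        )
        out.append(reactivation_index(sim, mode=mode))
    return np.array(out)


def timecourse_summary(
    tc: np.ndarray, window: Sequence[int] = DEFAULT_TIMECOURSE_OFFSETS
) -> float:
    """Signal (offsets +1..+6) minus baseline (offsets -1 and 0) mean."""
    tc = np.asarray(tc, float)
    window = np.asarray(list(window), int)
    if tc.shape != window.shape:
        raise ValueError("timecourse and window lengths differ")
    signal = tc[np.isin(window, np.arange(1, 7))]
    baseline = tc[np.isin(window, [-1, 0])]
    if signal.size == 0 or baseline.size == 0:
        raise ValueError("window must cover offsets -1..0 and +1..+6")
    return float(signal.mean() - baseline.mean())
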