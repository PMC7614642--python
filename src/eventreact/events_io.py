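"""Scene timing tables and masked BOLD input/output.

Scene timings are kept in integer TR units, 1-based and inclusive: a scene
with ``onset_tr=1, offset_tr=10`` occupies the first ten volumes of the run
and its event boundary is TR 10 (the TR that ends the scene).  Excluded
scenes keep their serial index so that diagonal offsets in downstream
similarity matrices stay meaningful.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Scene",
    "SceneTable",
    "BoldRun",
    "load_scene_table",
    "save_scene_table",
    "apply_scene_exclusions",
    "load_bold",
]


class SceneTableError(ValueError):
    """Raised for malformed or inconsistent scene tables."""


@dataclasses.dataclass(frozen=True)
class Scene:
    """One narrative scene.

    ``index`` is the 1-based serial position in the stimulus; it is never
    renumbered, even after exclusions.
    """

    index: int
    onset_tr: int
    offset_tr: int
    narrative: str = "NONE"
    text: str = ""
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def length_trs(self) -> int:
        return self.offset_tr - self.onset_tr + 1

    @property
    def boundary_tr(self) -> int:
        """The TR that ends the scene."""
        return self.offset_tr


class SceneTable:
    """Ordered, validated collection of :class:`Scene` records."""

    def __init__(self, scenes: Sequence[Scene]):
        scenes = list(scenes)
        if not scenes:
            raise SceneTableError("scene table is empty")
        bad = [s.index for s in scenes if s.offset_tr < s.onset_tr]
        if bad:
            raise SceneTableError(f"onset_tr > offset_tr for scenes {bad}")
        for a, b in zip(scenes, scenes[1:]):
            if b.onset_tr <= a.onset_tr:
                raise SceneTableError(
                    f"scenes {a.index} and {b.index} are not strictly ordered by onset"
                )
            if b.onset_tr <= a.offset_tr:
                raise SceneTableError(f"scenes {a.index} and {b.index} overlap")
        self.scenes: tuple[Scene, ...] = tuple(scenes)

    def __len__(self) -> int:
        return len(self.scenes)

    def __iter__(self):
        return iter(self.scenes)

    def __getitem__(self, i) -> Scene:
        return self.scenes[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, SceneTable) and self.scenes == other.scenes

    @property
    def included(self) -> tuple[Scene, ...]:
        return tuple(s for s in self.scenes if not s.excluded)

    @property
    def max_offset_tr(self) -> int:
        return max(s.offset_tr for s in self.scenes)

    def narratives(self) -> np.ndarray:
        return np.array([s.narrative for s in self.scenes])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scene_index": [s.index for s in self.scenes],
                "onset_tr": [s.onset_tr for s in self.scenes],
                "offset_tr": [s.offset_tr for s in self.scenes],
                "narrative": [s.narrative for s in self.scenes],
                "text": [s.text for s in self.scenes],
                "excluded": [s.excluded for s in self.scenes],
                "exclusion_reason": [s.exclusion_reason or "" for s in self.scenes],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SceneTable":
        def clean_str(value, default=""):
            if value is None or (isinstance(value, float) and math.isnan(value)):
                return default
            return str(value)

        def clean_bool(value):
            if isinstance(value, str):
                return value.strip().lower() in {"true", "1", "yes"}
            return bool(value)

        scenes = []
        for _, row in df.iterrows():
            reason = clean_str(row.get("exclusion_reason"), "")
            scenes.append(
                Scene(
                    index=int(row["scene_index"]),
                    onset_tr=int(row["onset_tr"]),
                    offset_tr=int(row["offset_tr"]),
                    narrative=clean_str(row.get("narrative"), "NONE") or "NONE",
                    text=clean_str(row.get("text")),
                    excluded=clean_bool(row.get("excluded", False)),
                    exclusion_reason=reason or None,
                )
            )
        return cls(scenes)

    def replace(self, scenes: Sequence[Scene]) -> "SceneTable":
        return SceneTable(scenes)


def load_scene_table(
    path: str | Path,
    narrative_column: str | None = "narrative",
    text_column: str | None = "text",
    seconds: bool = False,
    tr_seconds: float | None = None,
) -> SceneTable:
    """Read a scene table from TSV/CSV.

    Required columns: ``onset_tr`` and ``offset_tr`` (or ``onset_s`` /
    ``offset_s`` with ``seconds=True``).  Optional: ``scene_index``,
    ``narrative``, ``text``.  With ``seconds=True`` the onset is floored and
    the offset is ceiled into TR units so no stimulus time is dropped.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if seconds:
        if tr_seconds is None:
            raise SceneTableError("tr_seconds is required when seconds=True")
        for col in ("onset_s", "offset_s"):
            if col not in df.columns:
                raise SceneTableError(f"missing required column {col!r}")
        df["onset_tr"] = [int(math.floor(v / tr_seconds)) + 1 for v in df["onset_s"]]
        df["offset_tr"] = [int(math.ceil(v / tr_seconds)) for v in df["offset_s"]]
    for col in ("onset_tr", "offset_tr"):
        if col not in df.columns:
            raise SceneTableError(f"missing required column {col!r}")
    if "scene_index" not in df.columns:
        df["scene_index"] = np.arange(1, len(df) + 1)
    if narrative_column and narrative_column in df.columns:
        df["narrative"] = df[narrative_column].fillna("NONE")
    else:
        df["narrative"] = "NONE"
    if text_column and text_column in df.columns:
        df["text"] = df[text_column].fillna("")
    else:
        df["text"] = ""
    return SceneTable.from_dataframe(df)


def save_scene_table(table: SceneTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    table.to_dataframe().to_csv(path, sep=sep, index=False)


def apply_scene_exclusions(
    table: SceneTable,
    min_len_trs: int = 1,
    drop_labels: Iterable[str] = (),
    drop_last_per_run: bool = False,
    run_ends: Sequence[int] | None = None,
) -> SceneTable:
    """Flag scenes excluded from analysis.

    Scenes shorter than ``min_len_trs``, scenes whose narrative label is in
    ``drop_labels`` (e.g. unrelated filler cartoons), and optionally the
    final scene before each run end are flagged.  Serial indices are kept.
    Idempotent: applying the same rules twice changes nothing.
    """
    if min_len_trs < 1:
        raise ValueError("min_len_trs must be >= 1")
    drop_labels = set(drop_labels)
    if drop_last_per_run:
        ends = list(run_ends) if run_ends else [table.max_offset_tr]
        last_per_run: set[int] = set()
        for end in ends:
            in_run = [s for s in table.scenes if s.offset_tr <= end]
            if in_run:
                last_per_run.add(max(in_run, key=lambda s: s.offset_tr).index)
    else:
        last_per_run = set()

    out = []
    for s in table.scenes:
        reason = s.exclusion_reason
        excluded = s.excluded
        if s.length_trs < min_len_trs:
            excluded, reason = True, f"shorter than {min_len_trs} TRs"
        elif s.narrative in drop_labels:
            excluded, reason = True, f"label {s.narrative}"
        elif s.index in last_per_run:
            excluded, reason = True, "last scene of run"
        out.append(dataclasses.replace(s, excluded=excluded, exclusion_reason=reason))
    result = SceneTable(out)
    if not result.included:
        raise SceneTableError("exclusion rules removed every scene")
    return result


@dataclasses.dataclass
class BoldRun:
    """A masked 4D BOLD run as a (time x voxel) matrix.

    ``data[t]`` is the voxel pattern at TR ``t + 1`` (tables are 1-based).
    ``voxel_coords`` are integer (i, j, k) grid coordinates per voxel, used
    for searchlight and cluster geometry.
    """

    data: np.ndarray
    tr_seconds: float
    voxel_coords: np.ndarray
    affine: np.ndarray | None = None
    space: str = "unknown"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (time x voxel)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        if self.voxel_coords.shape != (self.data.shape[1], 3):
            raise ValueError("voxel_coords must be (n_voxels, 3)")
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise ValueError(f"{n_bad} non-finite values in BOLD data")

    @property
    def n_trs(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def pattern_at(self, tr: int) -> np.ndarray:
        """Voxel pattern at 1-based TR ``tr``."""
        if not 1 <= tr <= self.n_trs:
            raise IndexError(f"TR {tr} outside run of {self.n_trs} TRs")
        return self.data[tr - 1]


def load_bold(path: str | Path, mask: str | Path) -> BoldRun:
    """Load a 4D NIfTI restricted to a 3D mask on the same grid."""
    import nibabel as nib

    img = nib.load(str(path))
    msk = nib.load(str(mask))
    if img.ndim != 4:
        raise ValueError(f"expected a 4D image, got {img.ndim}D")
    if img.shape[:3] != msk.shape:
        raise ValueError(
            f"grid mismatch: image {img.shape[:3]} vs mask {msk.shape}"
        )
    mask_data = np.asanyarray(msk.dataobj) > 0
    n_in = int(mask_data.sum())
    if n_in == 0:
        raise ValueError("mask contains no in-mask voxels")
    data4d = np.asanyarray(img.dataobj)
    data = data4d[mask_data].T.astype(float)  # (time, voxel)
    coords = np.column_stack(np.nonzero(mask_data))
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    return BoldRun(
        data=data,
        tr_seconds=tr if tr > 0 else 1.0,
        voxel_coords=coords,
        affine=img.affine,
        space="file",
    )
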