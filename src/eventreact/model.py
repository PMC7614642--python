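"""Model/Results objects for boundary-reactivation analyses.

These wrap the functional pipeline in the fit-and-summarise idiom: a model
is constructed from data (a cohort of masked BOLD runs plus a scene table),
``fit`` runs the per-subject analysis and group sign-flip permutation test,
and the returned results object carries the estimates, their permutation
p-value, the effect size and a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .context_bow import (
    ContextModel,
    context_modulation_interaction,
    context_modulation_main_effect,
)
from .events_io import BoldRun, SceneTable
from .group_stats import StatResult, signflip_test
from .reactivation import (
    SimilarityMatrix,
    boundary_scene_similarity,
    flush_control_variant,
    reactivation_index,
)
from .representations import (
    DEFAULT_GAP_TRS,
    DEFAULT_HRF_SHIFT_TRS,
    average_reps_across_subjects,
    extract_boundary_reps,
    extract_scene_reps,
)

__all__ = ["ReactivationModel", "ReactivationResults", "ContextModulationModel"]

VARIANTS = ("within", "between_boundary", "between_scene")


def _subject_similarity(
    runs: Sequence[BoldRun],
    table: SceneTable,
    subject: int,
    variant: str,
    hrf_shift_trs: int,
    gap_trs: int,
    use_congruency: bool,
) -> SimilarityMatrix:
    """One subject's boundary-by-scene similarity under the chosen variant.

    within: both representation sets from the subject's own run.
    between_boundary: the subject's scene representations against boundary
    representations averaged across all other subjects (no autocorrelation
    issues, so no diagonal removal is needed beyond the main diagonal).
    between_scene: the subject's boundary representations against the other
    subjects' averaged scene representations.
    """
    idx = np.array([s.index for s in table.included])
    labels = np.array([s.narrative for s in table.included]) if use_congruency else None

    def b_of(i):
        return extract_boundary_reps(runs[i], table, hrf_shift_trs=hrf_shift_trs)

    def s_of(i):
        return extract_scene_reps(
            runs[i], table, gap_trs=gap_trs, hrf_shift_trs=hrf_shift_trs
        )

    if variant == "within":
        B, S = b_of(subject), s_of(subject)
    elif variant == "between_boundary":
        B = average_reps_across_subjects([b_of(i) for i in range(len(runs))], subject)
        S = s_of(subject)
    elif variant == "between_scene":
        B = b_of(subject)
        S = average_reps_across_subjects([s_of(i) for i in range(len(runs))], subject)
    else:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    return boundary_scene_similarity(
        B, S, congruency_labels=labels, boundary_scene_index=idx, scene_index=idx
    )


@dataclasses.dataclass
class ReactivationResults:
    """Group reactivation estimates from :class:`ReactivationModel.fit`."""

    model: "ReactivationModel"
    subject_indices: np.ndarray
    stat: StatResult

    @property
    def group_mean(self) -> float:
        return float(self.subject_indices.mean())

    @property
    def pvalue(self) -> float:
        return self.stat.p_value

    @property
    def tvalue(self) -> float:
        return self.stat.statistic

    @property
    def effect_size(self) -> float:
        return self.stat.effect_size

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": np.arange(len(self.subject_indices)),
                "index": self.subject_indices,
            }
        )

    def summary(self) -> str:
        m = self.model
        lines = [
            "Reactivation analysis",
            "=" * 54,
            f"variant:            {m.variant}",
            f"index mode:         {m.mode}",
            f"diagonals removed:  {m.d_total} (symmetric, incl. main diagonal)"
            if m.d_total
            else "diagonals removed:  main diagonal only",
            f"subjects:           {len(self.subject_indices)}",
            f"group mean index:   {self.group_mean:+.5f}",
            f"group t:            {self.stat.statistic:.3f}",
            f"permutation p:      {self.stat.p_value:.4g} ({self.stat.tails}-tailed, "
            f"{self.stat.n_permutations} flips)",
            f"Cohen's D:          {self.stat.effect_size:.3f}",
        ]
        return "\n".join(lines)


class ReactivationModel:
    """Past-minus-future boundary reactivation for a cohort of runs.

    Parameters
    ----------
    runs : cohort of :class:`BoldRun`, one per subject, same voxel set
    table : :class:`SceneTable` with exclusions already applied
    d_total : symmetric diagonal removal (0 = main diagonal only; use the
        dataset-calibrated value for within-participant analyses)
    mode : 'main_effect', 'congruent_only' or 'interaction'
    variant : 'within', 'between_boundary' or 'between_scene'
    flush_control : also remove the post-boundary scene (offset -1)
    """

    def __init__(
        self,
        runs: Sequence[BoldRun],
        table: SceneTable,
        d_total: int = 0,
        mode: str = "main_effect",
        variant: str = "within",
        hrf_shift_trs: int = DEFAULT_HRF_SHIFT_TRS,
        gap_trs: int = DEFAULT_GAP_TRS,
        flush_control: bool = False,
    ):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        if len(runs) < 2 and variant != "within":
            raise ValueError("between-participant variants need >= 2 subjects")
        self.runs = list(runs)
        self.table = table
        self.d_total = d_total
        self.mode = mode
        self.variant = variant
        self.hrf_shift_trs = hrf_shift_trs
        self.gap_trs = gap_trs
        self.flush_control = flush_control

    def subject_similarity(self, subject: int) -> SimilarityMatrix:
        sim = _subject_similarity(
            self.runs,
            self.table,
            subject,
            self.variant,
            self.hrf_shift_trs,
            self.gap_trs,
            use_congruency=self.mode in ("congruent_only", "interaction"),
        ).with_diagonals_removed(self.d_total)
        if self.flush_control:
            sim = flush_control_variant(sim)
        return sim

    def subject_index(self, subject: int) -> float:
        return reactivation_index(self.subject_similarity(subject), mode=self.mode)

    def fit(
        self,
        n_permutations: int = 1000,
        tails: str = "two",
        seed: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> ReactivationResults:
        values = np.array([self.subject_index(i) for i in range(len(self.runs))])
        stat = signflip_test(
            values, n_permutations=n_permutations, tails=tails, seed=seed, rng=rng
        )
        return ReactivationResults(model=self, subject_indices=values, stat=stat)


class ContextModulationModel(ReactivationModel):
    """Modulation of reactivation by bag-of-words context similarity.

    ``mode='main_effect'`` contrasts the past and future correlations between
    the neural and context similarity matrices (optionally partialling out
    the pairwise minimum word count); ``mode='interaction'`` contrasts the
    congruent-incongruent correlation differences of the two parts.  Scenes
    excluded from the context model are masked from the neural matrix too.
    """

    def __init__(
        self,
        runs: Sequence[BoldRun],
        table: SceneTable,
        context: ContextModel,
        d_total: int = 0,
        mode: str = "main_effect",
        variant: str = "within",
        partial_minwords: bool = True,
        hrf_shift_trs: int = DEFAULT_HRF_SHIFT_TRS,
        gap_trs: int = DEFAULT_GAP_TRS,
    ):
        if mode not in ("main_effect", "interaction"):
            raise ValueError("context modulation mode is main_effect or interaction")
        super().__init__(
            runs,
            table,
            d_total=d_total,
            mode=mode,
            variant=variant,
            hrf_shift_trs=hrf_shift_trs,
            gap_trs=gap_trs,
        )
        self.context = context
        self.partial_minwords = partial_minwords

    def subject_similarity(self, subject: int) -> SimilarityMatrix:
        sim = _subject_similarity(
            self.runs,
            self.table,
            subject,
            self.variant,
            self.hrf_shift_trs,
            self.gap_trs,
            use_congruency=self.mode == "interaction",
        )
        return sim.with_diagonals_removed(self.d_total)

    def subject_index(self, subject: int) -> float:
        sim = self.subject_similarity(subject)
        if self.mode == "main_effect":
            return context_modulation_main_effect(
                sim, self.context, partial_minwords=self.partial_minwords
            )
        return context_modulation_interaction(sim, self.context)

    def fit(self, n_permutations: int = 1000, tails: str = "one", seed=None, rng=None):
        # one-tailed by default: the hypothesis is directional (similar
        # context induces more reactivation)
        return super().fit(
            n_permutations=n_permutations, tails=tails, seed=seed, rng=rng
        )
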