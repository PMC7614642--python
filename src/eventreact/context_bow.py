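"""Bag-of-words context model and context modulation of reactivation.

Each scene's transcript becomes a word-count vector over the stimulus-wide
vocabulary (stop words removed), normalised to a probability vector.  Scene
context similarity is 1 minus the Jensen-Shannon distance (base-2 logs, so
the distance lies in [0, 1]).  The modulation statistics correlate the
unmasked past/future cells of a neural boundary-by-scene similarity matrix
with the matching context similarities and contrast the Fisher-transformed
coefficients, so that any time-symmetric scene-similarity structure cancels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import re
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import jensenshannon

from .reactivation import SimilarityMatrix

__all__ = [
    "DEFAULT_STOPWORDS",
    "stopword_hash",
    "ContextModel",
    "build_bow",
    "jsd_similarity",
    "time_bias_diagnostics",
    "apply_context_exclusions",
    "context_modulation_main_effect",
    "context_modulation_interaction",
]

# Fixed English stop-word list shipped with the package (function words with
# no scene-specific semantic content).  Results should be robust to the exact
# list; pass `stopwords=` to substitute.  The hash is exposed for provenance.
DEFAULT_STOPWORDS = frozenset(
    """
    a about above after again against all am an and any are aren't as at be
    because been before being below between both but by can can't cannot could
    couldn't did didn't do does doesn't doing don't down during each few for
    from further had hadn't has hasn't have haven't having he he'd he'll he's
    her here here's hers herself him himself his how how's i i'd i'll i'm
    i've if in into is isn't it it's its itself let's me more most mustn't my
    myself no nor not of off on once only or other ought our ours ourselves
    out over own same shan't she she'd she'll she's should shouldn't so some
    such than that that's the their theirs them themselves then there there's
    these they they'd they'll they're they've this those through to too under
    until up very was wasn't we we'd we'll we're we've were weren't what
    what's when when's where where's which while who who's whom why why's with
    won't would wouldn't you you'd you'll you're you've your yours yourself
    yourselves
    """.split()
)

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z0-9]+)*")


def stopword_hash(stopwords: Iterable[str] = DEFAULT_STOPWORDS) -> str:
    """sha256 of the sorted stop-word list, for provenance manifests."""
    blob = "\n".join(sorted(stopwords)).encode()
    return hashlib.sha256(blob).hexdigest()


def tokenize(text: str) -> list[str]:
    """Case-folded, punctuation-stripped tokens."""
    return _TOKEN_RE.findall(text.lower())


@dataclasses.dataclass
class ContextModel:
    """Per-scene word counts, probabilities and context similarity."""

    vocabulary: tuple[str, ...]
    counts: np.ndarray  # (n_scenes, vocab) int
    probs: np.ndarray  # row-stochastic, zero rows for empty scenes
    word_totals: np.ndarray
    scene_index: np.ndarray  # serial indices (1-based)
    empty_scenes: frozenset[int]  # serial indices with zero retained words
    context_sim: np.ndarray | None = None
    minwords: np.ndarray | None = None
    excluded_scenes: frozenset[int] = frozenset()

    @property
    def n_scenes(self) -> int:
        return self.counts.shape[0]

    def usable(self) -> np.ndarray:
        """Boolean per scene: has words and is not excluded."""
        bad = self.empty_scenes | self.excluded_scenes
        return np.array([i not in bad for i in self.scene_index.tolist()])

    def position_of(self, serial_index: int) -> int:
        pos = np.nonzero(self.scene_index == serial_index)[0]
        if pos.size == 0:
            raise KeyError(f"scene {serial_index} not in context model")
        return int(pos[0])


def build_bow(
    scene_texts: Sequence[str],
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
    scene_index: Sequence[int] | None = None,
) -> ContextModel:
    """Count word occurrences per scene over the stimulus-wide vocabulary."""
    stop = set(stopwords)
    toks = [[w for w in tokenize(t) if w not in stop] for t in scene_texts]
    vocab = sorted({w for ts in toks for w in ts})
    if len(scene_texts) < 2:
        raise ValueError("need at least 2 scenes")
    index = (
        np.arange(1, len(scene_texts) + 1)
        if scene_index is None
        else np.asarray(scene_index, int)
    )
    pos = {w: k for k, w in enumerate(vocab)}
    counts = np.zeros((len(scene_texts), len(vocab)), dtype=int)
    for i, ts in enumerate(toks):
        for w in ts:
            counts[i, pos[w]] += 1
    totals = counts.sum(axis=1)
    empty = frozenset(int(index[i]) for i in np.nonzero(totals == 0)[0])
    if len(scene_texts) - len(empty) < 2:
        raise ValueError("fewer than 2 scenes with retained words")
    if empty:
        import warnings

        warnings.warn(
            f"scenes {sorted(empty)} have no retained words and are flagged "
            "empty; they are excluded from similarity computations",
            RuntimeWarning,
            stacklevel=2,
        )
    probs = np.zeros_like(counts, dtype=float)
    nz = totals > 0
    probs[nz] = counts[nz] / totals[nz, None]
    minwords = np.minimum(totals[:, None], totals[None, :])
    return ContextModel(
        vocabulary=tuple(vocab),
        counts=counts,
        probs=probs,
        word_totals=totals,
        scene_index=index,
        empty_scenes=empty,
        minwords=minwords,
    )


def jsd_similarity(model: ContextModel) -> np.ndarray:
    """1 - Jensen-Shannon distance (base 2) between scene word distributions.

    Symmetric, unit diagonal, bounded in [0, 1]; cells touching an empty
    scene are NaN.  The matrix is stored on the model and returned.
    """
    n = model.n_scenes
    sim = np.full((n, n), np.nan)
    ok = np.array([i not in model.empty_scenes for i in model.scene_index.tolist()])
    idx = np.nonzero(ok)[0]
    for a_pos, a in enumerate(idx):
        sim[a, a] = 1.0
        for b in idx[a_pos + 1 :]:
            d = jensenshannon(model.probs[a], model.probs[b], base=2)
            d = 0.0 if np.isnan(d) else float(d)
            sim[a, b] = sim[b, a] = 1.0 - d
    model.context_sim = sim
    return sim


def _require_sim(model: ContextModel) -> np.ndarray:
    if model.context_sim is None:
        jsd_similarity(model)
    return model.context_sim


def _upper_pairs(model: ContextModel):
    """Positions and serial indices of usable upper-triangle scene pairs."""
    use = model.usable()
    pos = np.nonzero(use)[0]
    ii, jj = np.triu_indices(pos.size, k=1)
    return pos[ii], pos[jj]


def time_bias_diagnostics(
    model: ContextModel,
    group_a: Iterable[int],
    time_covariate: str = "pair_mean",
) -> dict:
    """Time-related structure in the context-similarity matrix.

    ``r_time``: Pearson correlation between upper-triangle similarities and a
    time covariate (default: the mean serial position (i+j)/2 of the pair).
    ``t_groups``: two-sample t comparing pairs involving ``group_a`` scenes
    against pairs among the remaining scenes.  ``df`` = n_pairs - 2 for both.
    """
    sim = _require_sim(model)
    group_a = set(int(g) for g in group_a)
    usable_serial = set(model.scene_index[model.usable()].tolist())
    if not group_a or not (usable_serial - group_a):
        raise ValueError("group_a must be a non-empty proper subset of usable scenes")
    ai, bj = _upper_pairs(model)
    vals = sim[ai, bj]
    si = model.scene_index[ai].astype(float)
    sj = model.scene_index[bj].astype(float)
    if time_covariate == "pair_mean":
        tcov = (si + sj) / 2.0
    elif time_covariate == "lag":
        tcov = np.abs(si - sj)
    elif time_covariate == "earliest":
        tcov = np.minimum(si, sj)
    else:
        raise ValueError(f"unknown time covariate {time_covariate!r}")
    if np.ptp(vals) == 0 or np.ptp(tcov) == 0:
        r_time = 0.0
    else:
        r_time = float(stats.pearsonr(tcov, vals)[0])
    in_a = np.isin(model.scene_index[ai], list(group_a)) | np.isin(
        model.scene_index[bj], list(group_a)
    )
    x, y = vals[in_a], vals[~in_a]
    if x.size < 2 or y.size < 2 or (np.ptp(vals) == 0):
        t_groups = 0.0
    else:
        t_groups = float(stats.ttest_ind(x, y, equal_var=True)[0])
    return {"r_time": r_time, "t_groups": t_groups, "df": int(vals.size - 2)}


def apply_context_exclusions(
    model: ContextModel, exclude: Iterable[int]
) -> ContextModel:
    """Mask scenes (by serial index) out of all context statistics.

    The paired neural similarity matrix is masked identically downstream by
    the modulation functions, which honour ``excluded_scenes``.
    """
    exclude = frozenset(int(e) for e in exclude)
    new_excluded = model.excluded_scenes | exclude
    remaining = [
        i
        for i in model.scene_index.tolist()
        if i not in new_excluded and i not in model.empty_scenes
    ]
    if len(remaining) < 3:
        raise ValueError("context exclusions leave fewer than 3 usable scenes")
    return dataclasses.replace(model, excluded_scenes=new_excluded)


def _residualise(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _cells(
    neural: SimilarityMatrix, model: ContextModel, which: str, congruent: bool | None
):
    """Neural z, context similarity and minwords for one cell class."""
    sim = _require_sim(model)
    usable_serial = set(model.scene_index[model.usable()].tolist())
    rows_ok = np.isin(neural.row_scene_index, list(usable_serial))
    cols_ok = np.isin(neural.col_scene_index, list(usable_serial))
    cells = ~neural.removal_mask & rows_ok[:, None] & cols_ok[None, :]
    off = neural.offsets
    cells &= off > 0 if which == "past" else off < 0
    if congruent is not None:
        if neural.congruency is None:
            raise ValueError("neural matrix has no congruency labels")
        cells &= neural.congruency if congruent else ~neural.congruency
    ri, cj = np.nonzero(cells)
    rpos = np.array([model.position_of(i) for i in neural.row_scene_index[ri]])
    cpos = np.array([model.position_of(j) for j in neural.col_scene_index[cj]])
    z = neural.z[ri, cj]
    ctx = sim[rpos, cpos]
    mw = model.minwords[rpos, cpos].astype(float)
    return z, ctx, mw


def _corr(
    z: np.ndarray, ctx: np.ndarray, mw: np.ndarray, partial_minwords: bool, name: str
) -> float:
    if z.size < 4:
        raise ValueError(f"fewer than 4 usable cells in the {name} part")
    if partial_minwords:
        z = _residualise(z, mw)
        ctx = _residualise(ctx, mw)
    if np.ptp(z) == 0 or np.ptp(ctx) == 0:
        return 0.0
    return float(np.corrcoef(z, ctx)[0, 1])


def context_modulation_main_effect(
    neural: SimilarityMatrix,
    model: ContextModel,
    partial_minwords: bool = True,
) -> float:
    """atanh(r_past) - atanh(r_future) between neural z and context similarity.

    ``partial_minwords`` partials the pairwise minimum word count out of both
    variables (by residualisation), guarding against sparse short scenes.
    """
    rs = {}
    for part in ("past", "future"):
        z, ctx, mw = _cells(neural, model, part, None)
        rs[part] = _corr(z, ctx, mw, partial_minwords, part)
    return float(np.arctanh(rs["past"]) - np.arctanh(rs["future"]))


def context_modulation_interaction(
    neural: SimilarityMatrix, model: ContextModel
) -> float:
    """Time x Congruency contrast of context correlations.

    [atanh(r_past,cong) - atanh(r_past,incong)] minus the same for the
    future part; plain Pearson correlations per cell class.
    """
    r = {}
    for part in ("past", "future"):
        for cong in (True, False):
            z, ctx, mw = _cells(neural, model, part, cong)
            tag = f"{part} {'congruent' if cong else 'incongruent'}"
            r[(part, cong)] = _corr(z, ctx, mw, False, tag)
    return float(
        (np.arctanh(r[("past", True)]) - np.arctanh(r[("past", False)]))
        - (np.arctanh(r[("future", True)]) - np.arctanh(r[("future", False)]))
    )
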