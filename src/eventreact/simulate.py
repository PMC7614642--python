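"""Synthetic-data generators and the null-bias simulation program.

The generators emulate the statistical structure of naturalistic fMRI runs
well enough to exercise and calibrate every stage of the analysis with no
real data: voxel time series with a 1/f power spectrum, the high-pass
filters (sharp spectral cutoff by default, Gaussian running line behind a
flag) that induce the autocorrelation artefact the reactivation index must
be protected from, scene timings in the two stimulus styles (a continuous
movie-like design and a story-like design with silences and two alternating
narratives), planted scene patterns and reactivation signal, and
topic-structured scene texts for the bag-of-words model.

``null_bias_suite`` runs the full null calibration: repeated cohorts of pure
1/f subjects pushed through filtering, representation extraction and the
reactivation index, yielding the null distribution of the group index for
each diagonal-removal choice (plus control-timepoint, interaction-mode and
context-modulation variants).  Internally it uses a vectorised engine; a
test asserts the engine agrees with the public per-step API.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.fft import dct, idct, irfft, next_fast_len, rfft

from .context_bow import ContextModel
from .events_io import Scene, SceneTable, apply_scene_exclusions
from .reactivation import congruency_from_labels, removal_mask_for_offsets
from .representations import scene_interior_trs

__all__ = [
    "SimulationConfig",
    "gen_one_over_f",
    "RunningLineFilter",
    "SpectralHighpass",
    "highpass_filter",
    "gen_scene_timings",
    "scene_timings_fitting",
    "inject_scene_patterns",
    "plant_reactivation",
    "gen_scene_texts",
    "year21_context_model",
    "null_bias_suite",
    "NullSuiteResult",
]


def _rng_of(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    if seed_or_rng is None:
        raise ValueError("a seed (or Generator) is required")
    return np.random.default_rng(seed_or_rng)


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset style.

    Defaults mirror the two naturalistic designs: a movie-like run of 1,976
    TRs with a 140 s high-pass and 10 removed diagonals, and a story-like run
    of 2,242 TRs with a 120 s high-pass and 6 removed diagonals; TR 1.5 s,
    10 subjects of 120 voxels.
    """

    style: str
    n_subjects: int = 10
    n_voxels: int = 120
    n_trs: int = 1976
    tr_seconds: float = 1.5
    highpass_cutoff_s: float = 140.0
    d_total: int = 10
    control_offset_trs: int = 10
    n_scenes: int = 48
    hrf_shift_trs: int = 4
    gap_trs: int = 5
    min_scene_len_trs: int = 10

    def __post_init__(self):
        for name in ("n_subjects", "n_voxels", "n_trs", "n_scenes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.highpass_cutoff_s <= 2 * self.tr_seconds:
            raise ValueError("cutoff must exceed 2 TRs")

    @classmethod
    def sherlock_like(cls, **overrides) -> "SimulationConfig":
        base = dict(
            style="sherlock_like",
            n_trs=1976,
            highpass_cutoff_s=140.0,
            d_total=10,
            control_offset_trs=10,
            n_scenes=48,
            min_scene_len_trs=10,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def year21_like(cls, **overrides) -> "SimulationConfig":
        base = dict(
            style="year21_like",
            n_trs=2242,
            highpass_cutoff_s=120.0,
            d_total=6,
            control_offset_trs=5,
            n_scenes=45,
            min_scene_len_trs=1,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# noise and filtering


def gen_one_over_f(
    n_trs: int,
    n_voxels: int,
    seed=None,
    dtype=np.float64,
) -> np.ndarray:
    """Unit-variance 1/f-power-spectrum noise, (n_trs x n_voxels).

    Independent Gaussian spectral coefficients are scaled so the power
    spectral density is proportional to 1/f for f > 0 (amplitude f^-1/2, DC
    removed) and inverse-transformed, so each series has zero mean and a
    log-log power slope of -1.
    """
    if n_trs < 16:
        raise ValueError("n_trs must be >= 16")
    rng = _rng_of(seed)
    freqs = np.fft.rfftfreq(n_trs)
    amp = np.zeros(freqs.size, dtype=dtype)
    amp[1:] = freqs[1:] ** -0.5
    re = rng.standard_normal((n_voxels, freqs.size)).astype(dtype, copy=False)
    im = rng.standard_normal((n_voxels, freqs.size)).astype(dtype, copy=False)
    coef = (re + 1j * im) * amp
    x = irfft(coef, n_trs, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return np.ascontiguousarray(x.T)


class RunningLineFilter:
    """Gaussian-weighted running-line high-pass filter with a reusable plan.

    At each timepoint a straight line is fit to the series under a Gaussian
    weight of sigma = cutoff / (2 TR) (in TRs) and subtracted, removing from
    each TR the commonalities with its weighted temporal neighbourhood.  The
    smoothing convolutions use precomputed FFT plans, so reusing one filter
    across many same-length datasets is cheap.
    """

    def __init__(self, n_trs: int, tr_seconds: float, cutoff_s: float):
        if cutoff_s <= 2 * tr_seconds:
            raise ValueError("cutoff must exceed 2 TRs")
        sigma = cutoff_s / (2.0 * tr_seconds)
        K = int(4.0 * sigma + 0.5)
        k = np.arange(-K, K + 1, dtype=float)
        w = np.exp(-0.5 * (k / sigma) ** 2)
        w /= w.sum()
        self.n_trs = n_trs
        self.sigma = sigma
        self._L = next_fast_len(n_trs + 2 * K)
        kern = np.concatenate([w[K:], np.zeros(self._L - 2 * K - 1), w[:K]])
        self._wf = rfft(kern, self._L)
        t = np.arange(n_trs, dtype=float)
        self._t = t
        W = self._smooth(np.ones((1, n_trs)))[0]
        Wx = self._smooth(t[None, :])[0]
        Wxx = self._smooth((t * t)[None, :])[0]
        denom = Wxx * W - Wx * Wx
        # local fit value: fit(t) = [Wy*(Wxx - Wx t) + Wxy*(W t - Wx)] / denom
        self._cy = (Wxx - Wx * t) / denom
        self._cxy = (W * t - Wx) / denom

    def _smooth(self, rows: np.ndarray) -> np.ndarray:
        wf = self._wf.astype(np.complex64) if rows.dtype == np.float32 else self._wf
        F = rfft(rows, self._L, axis=-1)
        F *= wf
        return irfft(F, self._L, axis=-1)[..., : self.n_trs]

    def apply_rows(self, rows: np.ndarray) -> np.ndarray:
        """Filter (n_series, n_trs) rows."""
        if rows.shape[-1] != self.n_trs:
            raise ValueError("series length differs from the filter plan")
        V = rows.shape[0]
        t = self._t.astype(rows.dtype, copy=False)
        sm = self._smooth(np.concatenate([rows, rows * t], axis=0))
        fit = sm[:V] * self._cy.astype(rows.dtype) + sm[V:] * self._cxy.astype(
            rows.dtype
        )
        return rows - fit

    def apply(self, data: np.ndarray) -> np.ndarray:
        """Filter (n_trs, n_voxels) data."""
        return np.ascontiguousarray(self.apply_rows(np.ascontiguousarray(data.T)).T)


class SpectralHighpass:
    """Sharp discrete-cosine high-pass: components slower than the cutoff are
    zeroed.

    The hard cutoff leaves the alternating (ringing) autocorrelation
    structure that linear high-pass filtering imprints on slow noise; this is
    the filter the null-bias suite calibrates against.
    """

    def __init__(self, n_trs: int, tr_seconds: float, cutoff_s: float):
        if cutoff_s <= 2 * tr_seconds:
            raise ValueError("cutoff must exceed 2 TRs")
        self.n_trs = n_trs
        f = np.arange(n_trs) / (2.0 * n_trs * tr_seconds)
        self._kill = f < 1.0 / cutoff_s

    def apply_rows(self, rows: np.ndarray) -> np.ndarray:
        if rows.shape[-1] != self.n_trs:
            raise ValueError("series length differs from the filter plan")
        coef = dct(rows, axis=-1, norm="ortho")
        coef[..., self._kill] = 0.0
        return idct(coef, axis=-1, norm="ortho")

    def apply(self, data: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(self.apply_rows(np.ascontiguousarray(data.T)).T)


FILTER_KINDS = {"spectral": SpectralHighpass, "running_line": RunningLineFilter}


def highpass_filter(
    data: np.ndarray,
    tr_seconds: float,
    cutoff_s: float,
    kind: str = "spectral",
) -> np.ndarray:
    """High-pass filter a (time x voxel) matrix.

    ``spectral`` (default) zeroes discrete-cosine components slower than the
    cutoff; ``running_line`` subtracts a Gaussian-weighted local linear fit
    (sigma = cutoff / 2, in seconds).
    """
    data = np.asarray(data, float)
    one_d = data.ndim == 1
    if one_d:
        data = data[:, None]
    if kind not in FILTER_KINDS:
        raise ValueError(f"unknown filter kind {kind!r}")
    out = FILTER_KINDS[kind](data.shape[0], tr_seconds, cutoff_s).apply(data)
    return out[:, 0] if one_d else out


# ---------------------------------------------------------------------------
# scene timings and stimuli


def gen_scene_timings(
    style: str,
    n_scenes: int,
    seed=None,
    n_trs: int | None = None,
    tr_seconds: float = 1.5,
) -> SceneTable:
    """Synthetic scene timings in one of the two stimulus styles.

    ``sherlock_like``: contiguous scenes, lengths log-normal around a 51 s
    median, clipped to [12, 184.5] s.  ``year21_like``: scene lengths from a
    Beta(2, 4.4) scaled onto [60, 84] s (median about 67.5 s), separated by
    4.5-6 s silences, narratives A/B alternating over the first 30 scenes and
    JOINT afterwards.  Errors if the result overruns ``n_trs``.
    """
    if n_scenes < 5:
        raise ValueError("n_scenes must be >= 5")
    rng = _rng_of(seed)
    if style == "sherlock_like":
        lens_s = np.exp(np.log(51.0) + 0.5 * rng.standard_normal(n_scenes))
        lens_s = np.clip(lens_s, 12.0, 184.5)
        gaps = np.zeros(n_scenes, dtype=int)
        labels = ["NONE"] * n_scenes
    elif style == "year21_like":
        lens_s = 60.0 + 24.0 * rng.beta(2.0, 4.4, size=n_scenes)
        gaps_s = rng.uniform(4.5, 6.0, size=n_scenes)
        gaps = np.round(gaps_s / tr_seconds).astype(int)
        gaps[-1] = 0
        n_alt = min(30, n_scenes)
        labels = ["A" if k % 2 == 0 else "B" for k in range(n_alt)]
        labels += ["JOINT"] * (n_scenes - n_alt)
    else:
        raise ValueError(f"unknown style {style!r}")
    lens = np.maximum(1, np.round(lens_s / tr_seconds).astype(int))
    scenes = []
    cur = 1
    for k in range(n_scenes):
        onset = cur
        offset = onset + int(lens[k]) - 1
        scenes.append(
            Scene(index=k + 1, onset_tr=onset, offset_tr=offset, narrative=labels[k])
        )
        cur = offset + 1 + int(gaps[k])
    if n_trs is not None and scenes[-1].offset_tr > n_trs:
        raise ValueError(
            f"timings end at TR {scenes[-1].offset_tr}, beyond the {n_trs}-TR run"
        )
    return SceneTable(scenes)


def scene_timings_fitting(
    config: SimulationConfig, rng: np.random.Generator, max_tries: int = 1000
) -> SceneTable:
    """Draw timings until they fit the configured run, then apply the style's
    analysis exclusions (short scenes; the final scene, whose boundary lacks
    the post-boundary TRs)."""
    for _ in range(max_tries):
        try:
            table = gen_scene_timings(
                config.style,
                config.n_scenes,
                seed=rng,
                n_trs=config.n_trs - config.hrf_shift_trs - config.control_offset_trs,
                tr_seconds=config.tr_seconds,
            )
        except ValueError:
            continue
        return apply_scene_exclusions(
            table,
            min_len_trs=config.min_scene_len_trs,
            drop_last_per_run=True,
        )
    raise RuntimeError("could not draw timings that fit the run")


def _scene_windows(table: SceneTable) -> list[np.ndarray]:
    return [np.arange(s.onset_tr - 1, s.offset_tr) for s in table.scenes]


def inject_scene_patterns(
    data: np.ndarray,
    table: SceneTable,
    kind: str = "uniform",
    weight: float = 1.0,
    seed=None,
) -> np.ndarray:
    """Add a stable scene-specific pattern to every TR of each scene.

    Patterns: ``uniform`` (independent per scene), ``one_over_f`` (scene
    representations of an auxiliary 1/f dataset, autocorrelated in scene
    order), or ``congruency_templates`` (a narrative template plus Gaussian
    noise, so same-narrative scenes correlate).  ``weight`` scales the
    pattern relative to the root-mean-square of the data's own scene-mean
    representations.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    data = np.asarray(data, float)
    if weight == 0:
        return data.copy()
    rng = _rng_of(seed)
    n_trs, n_vox = data.shape
    windows = _scene_windows(table)
    base = np.array([data[w].mean(axis=0) for w in windows])
    ref_rms = float(np.sqrt(np.mean(base**2)))
    n = len(windows)
    if kind == "uniform":
        pats = rng.uniform(-1.0, 1.0, size=(n, n_vox))
    elif kind == "one_over_f":
        aux = gen_one_over_f(n_trs, n_vox, seed=rng)
        pats = np.array([aux[w].mean(axis=0) for w in windows])
    elif kind == "congruency_templates":
        labels = table.narratives()
        uniq = [u for u in dict.fromkeys(labels.tolist()) if u != "JOINT"]
        templates = {u: rng.standard_normal(n_vox) for u in uniq}
        joint = np.mean(list(templates.values()), axis=0) if templates else 0.0
        pats = np.array(
            [
                (templates.get(lab, joint) if lab != "JOINT" else joint)
                + 0.5 * rng.standard_normal(n_vox)
                for lab in labels
            ]
        )
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    pats = pats / np.sqrt(np.mean(pats**2, axis=1, keepdims=True)) * ref_rms * weight
    out = data.copy()
    for w, p in zip(windows, pats):
        out[w] += p
    return out


def plant_reactivation(
    data: np.ndarray,
    table: SceneTable,
    target_rule: str = "fixed_lag",
    weight: float = 1.0,
    hrf_shift_trs: int = 4,
    context: ContextModel | None = None,
    seed=None,
    lag: int = 3,
    gap_trs: int = 5,
) -> np.ndarray:
    """Add a remote past scene's representation at each boundary TR.

    At each included boundary (TR + HRF shift) the representation of one
    remote past scene is added, scaled by ``weight`` times the standard
    deviation of the data.  Target selection: ``fixed_lag`` (the scene
    ``lag`` positions back) or ``most_context_similar`` (the context-most-
    similar remote past scene, excluding the just-ended one).  Boundaries
    with no eligible past scene are skipped.
    """
    data = np.asarray(data, float)
    out = data.copy()
    if weight == 0:
        return out
    if target_rule == "most_context_similar" and context is None:
        raise ValueError("most_context_similar requires a context model")
    interiors = scene_interior_trs(table, gap_trs=gap_trs, hrf_shift_trs=hrf_shift_trs)
    included = [s for s in table.included]
    scale = float(data.std())
    if context is not None and context.context_sim is None:
        from .context_bow import jsd_similarity

        jsd_similarity(context)
    for s in included:
        past = [p for p in included if p.index < s.index - 1]
        if not past:
            continue
        if target_rule == "fixed_lag":
            wanted = s.index - lag
            cands = [p for p in past if p.index == wanted]
            if not cands:
                continue
            target = cands[0]
        elif target_rule == "most_context_similar":
            spos = context.position_of(s.index)
            sims = [
                (context.context_sim[spos, context.position_of(p.index)], p)
                for p in past
            ]
            sims = [(v, p) for v, p in sims if np.isfinite(v)]
            if not sims:
                continue
            target = max(sims, key=lambda vp: vp[0])[1]
        else:
            raise ValueError(f"unknown target rule {target_rule!r}")
        trs = interiors[target.index]
        rep = data[trs - 1].mean(axis=0)
        sd = rep.std()
        if sd == 0:
            continue
        row = s.boundary_tr - 1 + hrf_shift_trs
        out[row] += weight * scale * (rep - rep.mean()) / sd
    return out


def gen_scene_texts(
    n_scenes: int,
    vocab_size: int,
    topic_structure: Sequence[int],
    words_per_scene: int = 120,
    seed=None,
    mixture_topic: int = -1,
    drift: float = 0.0,
) -> list[str]:
    """Topic-structured synthetic scene transcripts.

    Each topic concentrates probability on its own block of the vocabulary;
    scenes sample ``words_per_scene`` words from their topic's multinomial,
    so same-topic scenes share words and have high bag-of-words similarity.
    Scenes labelled with ``mixture_topic`` draw from the average of all
    topics (a joint narrative).  ``drift`` in [0, 1) mixes in a positional
    vocabulary that slides along the narrative, so word overlap decays with
    scene lag the way the local context of a real story does.
    """
    topics = [int(t) for t in topic_structure]
    if len(topics) != n_scenes:
        raise ValueError("topic_structure must name a topic per scene")
    uniq = sorted({t for t in topics if t != mixture_topic})
    if vocab_size < 10 * max(2, len(uniq)):
        raise ValueError("vocab_size must be >= 10 per topic (min 2 topics)")
    rng = _rng_of(seed)

    def word_of(k: int) -> str:
        letters = []
        k += 26
        while k:
            k, r = divmod(k, 26)
            letters.append(chr(ord("a") + r))
        # leading 'q' keeps synthetic words disjoint from any stop-word list
        return "q" + "".join(reversed(letters))

    if not 0 <= drift < 1:
        raise ValueError("drift must lie in [0, 1)")
    n_pos_words = 4 * n_scenes if drift > 0 else 0
    words = [word_of(k) for k in range(vocab_size + n_pos_words)]
    block = vocab_size // max(1, len(uniq))
    dists = {}
    for pos, t in enumerate(uniq):
        p = np.full(vocab_size, 0.1 / vocab_size)
        lo = pos * block
        hi = vocab_size if pos == len(uniq) - 1 else lo + block
        p[lo:hi] += 0.9 / (hi - lo)
        dists[t] = p / p.sum()
    if uniq:
        dists[mixture_topic] = np.mean([dists[t] for t in uniq], axis=0)
    texts = []
    for k, t in enumerate(topics):
        p = dists[t]
        if drift > 0:
            # sliding window over the positional block: overlap between
            # scenes i and j decays to zero beyond |i - j| ~ 3
            p_pos = np.zeros(n_pos_words)
            lo = 4 * k
            hi = min(n_pos_words, lo + 12)
            p_pos[lo:hi] = 1.0 / (hi - lo)
            p = np.concatenate([(1.0 - drift) * p, drift * p_pos])
        counts = rng.multinomial(words_per_scene, p)
        toks = []
        for k in np.nonzero(counts)[0]:
            toks.extend([words[k]] * counts[k])
        rng.shuffle(toks)
        texts.append(" ".join(toks))
    return texts


def year21_context_model(
    text_seed: int = 7,
    drift: float = 0.3,
    vocab_size: int = 400,
    words_per_scene: int = 120,
    n_scenes: int = 45,
) -> ContextModel:
    """Canonical 21st-year-like context model for the bias suite.

    Two alternating topics over scenes 1-30 (narratives A/B), a mixture topic
    for the joint scenes 31-45, and moderate local-context drift; the last 15
    scenes are excluded, as in the context analyses of that design.
    """
    from .context_bow import apply_context_exclusions, build_bow, jsd_similarity

    n_alt = min(30, n_scenes)
    topics = [k % 2 for k in range(n_alt)] + [-1] * (n_scenes - n_alt)
    texts = gen_scene_texts(
        n_scenes,
        vocab_size,
        topics,
        words_per_scene=words_per_scene,
        seed=text_seed,
        drift=drift,
    )
    model = build_bow(texts)
    jsd_similarity(model)
    return apply_context_exclusions(model, range(n_alt + 1, n_scenes + 1))


# ---------------------------------------------------------------------------
# null-bias simulation suite


@dataclasses.dataclass
class NullSuiteResult:
    """Null distributions of the group reactivation index."""

    indices: dict  # key -> (n_reps,) array of group indices
    table: SceneTable
    config: SimulationConfig
    n_reps: int
    mean_similarity: np.ndarray  # group- and repetition-averaged z matrix
    scene_index: np.ndarray

    def summary(self) -> pd.DataFrame:
        rows = []
        for key, vals in self.indices.items():
            v = np.asarray(vals)
            rows.append(
                {
                    "measure": key if isinstance(key, str) else f"{key[0]}(d={key[1]})",
                    "mean": v.mean(),
                    "sd": v.std(ddof=1),
                    "mc_se": v.std(ddof=1) / np.sqrt(v.size),
                    "q05": np.quantile(v, 0.05),
                    "q50": np.quantile(v, 0.50),
                    "q95": np.quantile(v, 0.95),
                }
            )
        return pd.DataFrame(rows).set_index("measure")


class _SuiteEngine:
    """Precomputed geometry for fast repeated null-index evaluation."""

    def __init__(
        self,
        config: SimulationConfig,
        table: SceneTable,
        d_values: Sequence[int],
        control_offset_trs: int | None,
        interaction_d: int | None,
        context_model: ContextModel | None,
        context_d: int = 0,
    ):
        self.config = config
        self.table = table
        included = table.included
        self.idx = np.array([s.index for s in included])
        self.boundary_rows = np.array(
            [s.boundary_tr - 1 + config.hrf_shift_trs for s in included]
        )
        interiors = scene_interior_trs(
            table, gap_trs=config.gap_trs, hrf_shift_trs=config.hrf_shift_trs
        )
        self.scene_rows = [interiors[s.index] - 1 for s in included]
        for s, rows in zip(included, self.scene_rows):
            if rows.size == 0:
                raise ValueError(f"scene {s.index} has an empty interior")
        off = self.idx[:, None] - self.idx[None, :]
        self.masks = {}
        for d in d_values:
            removed = np.zeros(off.shape, bool)
            removed |= off == 0
            if d:
                for o in removal_mask_for_offsets(d):
                    removed |= off == o
            self.masks[d] = {
                "past": (off > 0) & ~removed,
                "future": (off < 0) & ~removed,
            }
        labels = np.array([s.narrative for s in included])
        self.congruency = congruency_from_labels(labels, labels)
        self.interaction_d = interaction_d
        self.control = control_offset_trs
        self.ctx = None
        if context_model is not None:
            self._prepare_context(context_model, off, context_d)

    def _prepare_context(self, model: ContextModel, off: np.ndarray, context_d: int):
        from .context_bow import jsd_similarity

        if model.context_sim is None:
            jsd_similarity(model)
        removed = np.zeros(off.shape, bool)
        removed |= off == 0
        if context_d:
            for o in removal_mask_for_offsets(context_d):
                removed |= off == o
        usable_serial = set(model.scene_index[model.usable()].tolist())
        ok = np.isin(self.idx, list(usable_serial))
        base = ~removed & ok[:, None] & ok[None, :]
        classes = {}
        for part, sel in (("past", off > 0), ("future", off < 0)):
            for cong in (True, False):
                cells = base & sel & (self.congruency if cong else ~self.congruency)
                ri, cj = np.nonzero(cells)
                rpos = np.array([model.position_of(i) for i in self.idx[ri]])
                cpos = np.array([model.position_of(j) for j in self.idx[cj]])
                ctx = model.context_sim[rpos, cpos]
                if ri.size < 4:
                    raise ValueError(
                        f"context class {part}/{cong} has fewer than 4 cells"
                    )
                classes[(part, cong)] = (ri, cj, ctx)
        self.ctx = classes

    # -- per-subject computations -------------------------------------------
    @staticmethod
    def _standardise(m: np.ndarray) -> np.ndarray:
        mu = m.mean(axis=1, keepdims=True)
        sd = m.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (m - mu) / sd

    def zmatrix(self, data: np.ndarray, extra: int = 0) -> np.ndarray:
        B = data[self.boundary_rows + extra]
        S = np.array([data[rows].mean(axis=0) for rows in self.scene_rows])
        Bz = self._standardise(B)
        Sz = self._standardise(S)
        r = Bz @ Sz.T / data.shape[1]
        np.clip(r, -1 + 1e-7, 1 - 1e-7, out=r)
        return np.arctanh(r)

    def main_index(self, z: np.ndarray, d: int) -> float:
        m = self.masks[d]
        return float(z[m["past"]].mean() - z[m["future"]].mean())

    def interaction_index(self, z: np.ndarray, d: int) -> float:
        m = self.masks[d]
        c = self.congruency
        return float(
            (z[m["past"] & c].mean() - z[m["past"] & ~c].mean())
            - (z[m["future"] & c].mean() - z[m["future"] & ~c].mean())
        )

    def context_interaction(self, z: np.ndarray) -> float:
        def r_of(key):
            ri, cj, ctx = self.ctx[key]
            zz = z[ri, cj]
            if np.ptp(zz) == 0 or np.ptp(ctx) == 0:
                return 0.0
            return float(np.corrcoef(zz, ctx)[0, 1])

        return float(
            (np.arctanh(r_of(("past", True))) - np.arctanh(r_of(("past", False))))
            - (
                np.arctanh(r_of(("future", True)))
                - np.arctanh(r_of(("future", False)))
            )
        )


def null_bias_suite(
    config: SimulationConfig,
    d_values: Sequence[int] = (2,),
    n_reps: int = 500,
    seed=None,
    control_offset_trs: int | None = None,
    interaction_d: int | None = None,
    context_model: ContextModel | None = None,
    context_d: int = 0,
    scene_pattern_kind: str | None = None,
    scene_pattern_weight: float = 0.0,
    table: SceneTable | None = None,
    filter_kind: str = "spectral",
    dtype=np.float32,
) -> NullSuiteResult:
    """Null distribution of the group reactivation index under pure 1/f noise.

    Per repetition: generate ``config.n_subjects`` independent 1/f datasets,
    high-pass filter, extract boundary and scene representations with one
    fixed draw of style-appropriate timings, build within-participant
    similarity matrices and average the per-subject index into a group index
    for every requested diagonal removal ``d`` (``d=0`` removes only the main
    diagonal).  Optional extras computed from the same matrices: indices at
    +/- ``control_offset_trs`` control timepoints with the balanced-control
    contrast; the Time x Congruency interaction index at ``interaction_d``;
    and the context-modulation interaction against ``context_model``.
    Optionally stable scene patterns are injected into every subject.
    Also accumulates the average group similarity matrix for inspection.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    rng = _rng_of(seed)
    if table is None:
        table = scene_timings_fitting(config, rng)
    engine = _SuiteEngine(
        config,
        table,
        d_values,
        control_offset_trs,
        interaction_d,
        context_model,
        context_d,
    )
    if filter_kind not in FILTER_KINDS:
        raise ValueError(f"unknown filter kind {filter_kind!r}")
    filt = FILTER_KINDS[filter_kind](
        config.n_trs, config.tr_seconds, config.highpass_cutoff_s
    )

    keys: list = [("main", d) for d in d_values]
    if interaction_d is not None:
        keys.append(("interaction", interaction_d))
    if control_offset_trs is not None:
        keys += ["control_past", "control_future", "balanced_contrast"]
    if context_model is not None:
        keys.append("context_interaction")
    out = {k: np.empty(n_reps) for k in keys}
    mean_sim = np.zeros((engine.idx.size, engine.idx.size))
    d_ref = max(d_values) if len(d_values) else 0

    for rep in range(n_reps):
        acc = {k: 0.0 for k in keys}
        sim_acc = np.zeros_like(mean_sim)
        for _ in range(config.n_subjects):
            raw = gen_one_over_f(config.n_trs, config.n_voxels, seed=rng, dtype=dtype)
            data = filt.apply(raw)
            if scene_pattern_kind is not None and scene_pattern_weight > 0:
                # patterns are stable representations in the analysed signal
                # space, so they are added after filtering (a pre-filter
                # injection would smear each pattern across scene edges)
                data = inject_scene_patterns(
                    data, table, scene_pattern_kind, scene_pattern_weight, seed=rng
                ).astype(dtype)
            z = engine.zmatrix(data)
            sim_acc += z
            for d in d_values:
                acc[("main", d)] += engine.main_index(z, d)
            if interaction_d is not None:
                acc[("interaction", interaction_d)] += engine.interaction_index(
                    z, interaction_d
                )
            if control_offset_trs is not None:
                zp = engine.zmatrix(data, extra=-control_offset_trs)
                zf = engine.zmatrix(data, extra=control_offset_trs)
                ip = engine.main_index(zp, d_ref)
                if_ = engine.main_index(zf, d_ref)
                ib = engine.main_index(z, d_ref)
                acc["control_past"] += ip
                acc["control_future"] += if_
                acc["balanced_contrast"] += ib - 0.5 * (ip + if_)
            if context_model is not None:
                acc["context_interaction"] += engine.context_interaction(z)
        for k in keys:
            out[k][rep] = acc[k] / config.n_subjects
        mean_sim += sim_acc / config.n_subjects
    mean_sim /= n_reps
    return NullSuiteResult(
        indices=out,
        table=table,
        config=config,
        n_reps=n_reps,
        mean_similarity=mean_sim,
        scene_index=engine.idx,
    )
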