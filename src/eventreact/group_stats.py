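"""Group-level permutation inference and meta-analysis.

Group tests are sign-flip permutation tests: under the null of a symmetric
zero-centred per-subject statistic, each subject's value can be negated.
P-values use the add-one rule p = (1 + #{null >= observed}) / (1 + B), which
is exactly valid at finite permutation counts.  Whole-brain maps are
corrected by the permutation distribution of the maximal cluster mass.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "StatResult",
    "signflip_test",
    "cluster_mass_correct",
    "ClusterResult",
    "fisher_meta",
    "bonferroni_alpha",
    "mega_analysis",
]


@dataclasses.dataclass
class StatResult:
    statistic: float  # group t
    p_value: float
    null_distribution: np.ndarray
    tails: str
    n_permutations: int
    effect_size: float  # Cohen's D: group mean / sample SD
    n_subjects: int

    def summary(self) -> str:
        return (
            f"t = {self.statistic:.3f}, p = {self.p_value:.4g} "
            f"({self.tails}-tailed, {self.n_permutations} sign-flip "
            f"permutations, n = {self.n_subjects}), Cohen's D = "
            f"{self.effect_size:.3f}"
        )


def _one_sample_t(values: np.ndarray) -> float:
    n = values.size
    sd = values.std(ddof=1)
    return float(values.mean() / (sd / np.sqrt(n)))


def _rng_from(seed, rng):
    if rng is not None:
        return rng
    if seed is None:
        raise ValueError("a seed (or rng) is required for permutation tests")
    return np.random.default_rng(seed)


def _perm_p(observed: float, null: np.ndarray, tails: str) -> float:
    if tails == "two":
        exceed = np.abs(null) >= abs(observed)
    elif tails == "one":
        exceed = null >= observed
    else:
        raise ValueError("tails must be 'one' or 'two'")
    return float((1 + exceed.sum()) / (1 + null.size))


def signflip_test(
    values: Sequence[float],
    n_permutations: int = 1000,
    tails: str = "two",
    strata: Sequence[int] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> StatResult:
    """One-sample group t-test with a random sign-flip null.

    ``strata`` label subjects by dataset; flips remain per-subject but the
    labels are validated here so stratified callers can share the code path.
    One-tailed tests count only same-direction exceedances.
    """
    values = np.asarray(values, float)
    if values.size < 3:
        raise ValueError("need at least 3 subjects")
    if values.std(ddof=1) == 0:
        raise ValueError("zero variance across subjects")
    if strata is not None and len(strata) != values.size:
        raise ValueError("strata must label every subject")
    if n_permutations < 100:
        warnings.warn(
            f"{n_permutations} permutations give a coarse p-value floor",
            RuntimeWarning,
            stacklevel=2,
        )
    g = _rng_from(seed, rng)
    t_obs = _one_sample_t(values)
    flips = g.choice([-1.0, 1.0], size=(n_permutations, values.size))
    flipped = flips * values
    means = flipped.mean(axis=1)
    sds = flipped.std(axis=1, ddof=1)
    null = means / (sds / np.sqrt(values.size))
    return StatResult(
        statistic=t_obs,
        p_value=_perm_p(t_obs, null, tails),
        null_distribution=null,
        tails=tails,
        n_permutations=n_permutations,
        effect_size=float(values.mean() / values.std(ddof=1)),
        n_subjects=values.size,
    )


_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclasses.dataclass
class ClusterResult:
    t_map: np.ndarray
    cluster_labels: np.ndarray  # 0 outside surviving clusters
    clusters: pd.DataFrame  # mass, size, p per suprathreshold cluster
    null_max_mass: np.ndarray
    voxel_t_threshold: float


def _cluster_masses(tmap: np.ndarray, thr: float, structure: np.ndarray, tails: str):
    supra = np.abs(tmap) > thr if tails == "two" else tmap > thr
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return labels, np.array([]), np.array([])
    masses = ndimage.sum_labels(np.abs(tmap), labels, index=np.arange(1, n + 1))
    sizes = ndimage.sum_labels(np.ones_like(tmap), labels, index=np.arange(1, n + 1))
    return labels, masses, sizes


def cluster_mass_correct(
    subject_maps: np.ndarray,
    voxel_p: float = 0.05,
    cluster_p: float = 0.005,
    n_permutations: int = 1000,
    connectivity: int = 26,
    tails: str = "two",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mask: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster-mass family-wise correction of a group map.

    ``subject_maps`` is (n_subjects, X, Y, Z).  Voxels whose group t exceeds
    the two-tailed ``voxel_p`` critical value (df = n-1) are clustered by the
    chosen connectivity; a cluster survives when its summed |t| beats the
    sign-flip permutation distribution of the maximal cluster mass at
    ``cluster_p``.  No suprathreshold voxels is an empty result, not an error.
    """
    maps = np.asarray(subject_maps, float)
    if maps.ndim != 4:
        raise ValueError("subject_maps must be (n_subjects, X, Y, Z)")
    n = maps.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    g = _rng_from(seed, rng)
    if mask is None:
        mask = np.isfinite(maps).all(axis=0)
    maps = np.where(mask, maps, 0.0)

    thr = float(stats.t.ppf(1 - voxel_p / 2, df=n - 1))

    def tmap_of(data):
        mu = data.mean(axis=0)
        sd = data.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mu / (sd / np.sqrt(n))
        t[~mask | (sd == 0)] = 0.0
        return t

    t_obs = tmap_of(maps)
    labels, masses, sizes = _cluster_masses(t_obs, thr, structure, tails)

    null_max = np.zeros(n_permutations)
    for b in range(n_permutations):
        flips = g.choice([-1.0, 1.0], size=n)
        t_b = tmap_of(maps * flips[:, None, None, None])
        _, m_b, _ = _cluster_masses(t_b, thr, structure, tails)
        null_max[b] = m_b.max() if m_b.size else 0.0

    rows = []
    surviving = np.zeros_like(labels)
    next_label = 0
    for k, (mass, size) in enumerate(zip(masses, sizes), start=1):
        p = float((1 + (null_max >= mass).sum()) / (1 + n_permutations))
        keep = p < cluster_p
        if keep:
            next_label += 1
            surviving[labels == k] = next_label
        rows.append({"mass": float(mass), "size": int(size), "p": p, "kept": keep})
    table = pd.DataFrame(rows, columns=["mass", "size", "p", "kept"])
    return ClusterResult(
        t_map=t_obs,
        cluster_labels=surviving,
        clusters=table,
        null_max_mass=null_max,
        voxel_t_threshold=thr,
    )


def fisher_meta(p_values: Sequence[float]) -> dict:
    """Fisher's combined probability: chi2 = -2 sum(ln p), df = 2k."""
    p = np.asarray(p_values, float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; cap reported 'p<x' at x")
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return {"chi2": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df))}


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted alpha level.

    Rounded to 3 decimals when the rounding preserves the level (e.g.
    0.05 / 3 -> 0.017); tiny levels that 3 decimals would distort are
    returned exactly (e.g. 0.01 / 4 -> 0.0025).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    q = alpha / m
    r = round(q, 3)
    return r if r > 0 and abs(r - q) <= 0.05 * q else q


def mega_analysis(
    values_by_dataset: Mapping[str, Sequence[float]],
    n_permutations: int = 1000,
    tails: str = "two",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> StatResult:
    """Pooled test of a common effect with dataset-specific intercepts.

    Fits y = X b with dataset indicator columns and tests the average of the
    dataset effects (t for the contrast mean(b)); the null flips single
    subjects' signs, i.e. sign flips stratified within dataset.
    """
    names = list(values_by_dataset)
    if len(names) < 2:
        raise ValueError("need at least 2 datasets")
    groups = [np.asarray(values_by_dataset[k], float) for k in names]
    for k, v in zip(names, groups):
        if v.size < 2:
            raise ValueError(f"dataset {k!r} has fewer than 2 subjects")
    y = np.concatenate(groups)
    labels = np.concatenate([np.full(v.size, i) for i, v in enumerate(groups)])
    K = len(groups)
    X = np.eye(K)[labels]
    c = np.full(K, 1.0 / K)
    XtX_inv = np.linalg.inv(X.T @ X)
    cvar = float(c @ XtX_inv @ c)
    dof = y.size - K

    def t_of(yy):
        beta = XtX_inv @ (X.T @ yy)
        resid = yy - X @ beta
        s2 = float(resid @ resid) / dof
        return float((c @ beta) / np.sqrt(s2 * cvar))

    g = _rng_from(seed, rng)
    t_obs = t_of(y)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = t_of(y * g.choice([-1.0, 1.0], size=y.size))
    mean = float(np.mean([v.mean() for v in groups]))
    sd = float(y.std(ddof=1))
    return StatResult(
        statistic=t_obs,
        p_value=_perm_p(t_obs, null, tails),
        null_distribution=null,
        tails=tails,
        n_permutations=n_permutations,
        effect_size=mean / sd if sd > 0 else np.nan,
        n_subjects=y.size,
    )
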