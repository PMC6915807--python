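"""Pixel-wise two-group inference on concern masks.

The statistic is the pooled two-proportion z score per pixel,

    z = (p1 - p2) / sqrt( pbar (1 - pbar) (1/n1 + 1/n2) ),

with pbar the pooled proportion.  Significance comes from a permutation
(relabeling) test: group labels are shuffled across subjects, the full z map
is recomputed for each relabeling, and the two-sided p value at a pixel is
the add-one rank of |z_obs| in the permutation set,

    p = (1 + #{b : |z_b| >= |z_obs|}) / (B + 1).

Family-wise control is by cluster extent: supra-threshold pixels
(p < alpha) are grouped into 8-connected clusters, and a cluster survives
iff its pixel extent reaches the (1 - alpha) quantile of the null
distribution of the *maximum* cluster extent, obtained by thresholding each
permutation's map identically.

Implementation notes
--------------------
Relabelings are drawn as uniform random subsets of size min(n1, n2), which
makes the sampled partitions (and hence p maps) independent of which label
is listed first.  Smoothing, when requested, is applied to each subject
mask once up front; by linearity of convolution the smoothed group
proportion map is then just a mean over subjects, so every permutation is a
single matrix product.  Rather than storing all B permutation maps, the
engine keeps a per-pixel top-K buffer (K = ceil(alpha (B+1))) from which
the exact supra-threshold rule "p < alpha" can be evaluated for any map in
the pooled set, then replays the seeded permutation stream to harvest null
maximum cluster extents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .maps import smooth_grid

__all__ = [
    "StatMapResult",
    "two_proportion_z",
    "z_map",
    "permutation_pmap",
    "cluster_correct",
]

#: 8-connectivity structuring element for cluster labeling.
_CONN8 = np.ones((3, 3), dtype=int)


class ProvenanceError(ValueError):
    """Permutation provenance (B, seed, smoothing) does not match."""


def two_proportion_z(x1: float, n1: int, x2: float, n2: int) -> float:
    """Pooled-variance two-proportion z statistic.

    Returns 0.0 on degenerate input where the pooled proportion is 0 or 1
    (no variability under the null).  Counts may be fractional (effective
    counts from smoothed proportions).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError(f"group sizes must be >= 1, got n1={n1}, n2={n2}")
    if not (0 <= x1 <= n1) or not (0 <= x2 <= n2):
        raise ValueError(
            f"counts out of range: x1={x1} (n1={n1}), x2={x2} (n2={n2})"
        )
    return float(_z_from_props(np.float64(x1) / n1, np.float64(x2) / n2, n1, n2))


def _z_from_props(p1, p2, n1: int, n2: int):
    """Vectorized z from group proportions; degenerate pixels -> 0."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    var = pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n2)
    denom = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, (p1 - p2) / np.where(denom > 0, denom, 1.0), 0.0)
    return z


def _group_props(masks, fwhm_px):
    stack = np.stack([np.asarray(m, dtype=float) for m in masks])
    grid = stack.mean(axis=0)
    if fwhm_px is not None:
        grid = smooth_grid(grid, fwhm_px)
    return grid


def z_map(group_a, group_b, fwhm_px: float | None = None) -> np.ndarray:
    """Per-pixel two-proportion z between two groups of binary masks.

    With smoothing the effective count at a pixel is n * (smoothed
    proportion); antisymmetric under swapping the group arguments.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if group_a[0].shape != group_b[0].shape:
        raise ValueError(
            f"dims mismatch: {group_a[0].shape} vs {group_b[0].shape}"
        )
    pa = _group_props(group_a, fwhm_px)
    pb = _group_props(group_b, fwhm_px)
    return _z_from_props(pa, pb, len(group_a), len(group_b))


@dataclass
class StatMapResult:
    """Pixel-wise z map with permutation p values and cluster correction.

    ``clusters``/``surviving``/``null_max_extent`` are filled by
    :func:`cluster_correct`; ``p_uncorrected`` lies in [1/(B+1), 1].
    """

    z: np.ndarray
    p_uncorrected: np.ndarray
    B: int
    seed: int
    alpha: float
    fwhm_px: float | None
    group_order: tuple[str, str]
    n1: int
    n2: int
    clusters: np.ndarray | None = None
    surviving: np.ndarray | None = None
    null_max_extent: np.ndarray | None = None
    cluster_extent_threshold: int | None = None
    # internal state for the cluster-correction replay pass
    _supra_threshold: np.ndarray | None = field(default=None, repr=False)
    _stack: np.ndarray | None = field(default=None, repr=False)
    _m: int | None = field(default=None, repr=False)


def _perm_chunks(rng, B: int, n: int, m: int, chunk: int):
    """Yield (C, n) float matrices whose rows are indicators of a uniform
    random m-subset (the permuted 'small' group)."""
    done = 0
    while done < B:
        C = min(chunk, B - done)
        keys = rng.random((C, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        M = np.zeros((C, n), dtype=np.float64)
        np.put_along_axis(M, idx, 1.0, axis=1)
        yield M
        done += C


def permutation_pmap(
    masks,
    labels,
    B: int = 5000,
    seed: int = 0,
    fwhm_px: float | None = None,
    alpha: float = 0.05,
    chunk: int = 256,
) -> StatMapResult:
    """Permutation test of the per-pixel two-proportion z over a cohort.

    Parameters
    ----------
    masks
        One binary (H, W) mask per subject.
    labels
        Group label per subject; exactly two distinct values.
    B
        Number of random relabelings (group sizes preserved).
    seed
        RNG seed; the whole analysis is reproducible from it.
    fwhm_px
        Optional Gaussian smoothing FWHM applied identically to the observed
        and every permuted map.
    alpha
        Significance level, also the cluster-forming threshold.
    """
    masks = list(masks)
    labels = list(labels)
    if len(masks) != len(labels):
        raise ValueError("masks and labels must have equal length")
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two distinct labels required, got {uniq}")
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")

    g1, g2 = uniq
    idx1 = [i for i, lab in enumerate(labels) if lab == g1]
    idx2 = [i for i, lab in enumerate(labels) if lab == g2]
    n1, n2 = len(idx1), len(idx2)
    n = n1 + n2
    shape = masks[0].shape

    # smooth each subject mask once; permutations become matrix products
    stack = np.stack([np.asarray(m, dtype=np.float64) for m in masks])
    if fwhm_px is not None:
        stack = np.stack([smooth_grid(m, fwhm_px) for m in stack])
    S = np.ascontiguousarray(stack.reshape(n, -1))
    P = S.shape[1]
    total = S.sum(axis=0)

    p_obs1 = S[idx1].mean(axis=0)
    p_obs2 = S[idx2].mean(axis=0)
    z_obs = _z_from_props(p_obs1, p_obs2, n1, n2)
    abs_obs = np.abs(z_obs)

    # the permuted "small" group has m subjects; partitions are independent
    # of label naming, making p exactly invariant to a label swap
    m = min(n1, n2)
    n_other = n - m

    K = int(math.ceil(alpha * (B + 1)))
    topk = abs_obs[None, :].copy()          # pooled set starts with observed
    count_ge = np.zeros(P, dtype=np.int64)

    rng = np.random.default_rng(seed)
    for M in _perm_chunks(rng, B, n, m, chunk):
        sum_small = M @ S
        p_small = sum_small / m
        p_other = (total[None, :] - sum_small) / n_other
        abs_z = np.abs(_z_from_props(p_small, p_other, m, n_other))
        count_ge += (abs_z >= abs_obs[None, :]).sum(axis=0)
        pooled = np.concatenate([topk, abs_z], axis=0)
        keep = min(K, pooled.shape[0])
        pooled.partition(pooled.shape[0] - keep, axis=0)
        topk = pooled[-keep:]

    p_unc = (1.0 + count_ge) / (B + 1.0)
    # map i in the pooled set satisfies p_i < alpha iff |z_i| strictly
    # exceeds the K-th largest pooled value
    supra_thr = topk[0] if topk.shape[0] >= K else np.full(P, np.inf)

    return StatMapResult(
        z=z_obs.reshape(shape),
        p_uncorrected=p_unc.reshape(shape),
        B=B,
        seed=seed,
        alpha=alpha,
        fwhm_px=fwhm_px,
        group_order=(str(g1), str(g2)),
        n1=n1,
        n2=n2,
        _supra_threshold=supra_thr.reshape(shape),
        _stack=S,
        _m=m,
    )


def _max_extent(supra: np.ndarray) -> int:
    lab, nlab = ndimage.label(supra, structure=_CONN8)
    if nlab == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def cluster_correct(
    result: StatMapResult,
    B: int | None = None,
    seed: int | None = None,
    alpha: float | None = None,
    chunk: int = 256,
) -> StatMapResult:
    """Fill cluster labels and the cluster-extent-corrected significance mask.

    Replays the identical seeded permutation stream used by
    :func:`permutation_pmap`, thresholds each permuted map with the same
    supra-threshold rule (p < alpha), and keeps observed clusters whose
    extent reaches the (1 - alpha) quantile of the null maximum-extent
    distribution.  ``B``/``seed``/``alpha``, if given, must match the
    provenance recorded in ``result``.
    """
    for name, given, have in (
        ("B", B, result.B),
        ("seed", seed, result.seed),
        ("alpha", alpha, result.alpha),
    ):
        if given is not None and given != have:
            raise ProvenanceError(
                f"{name} mismatch: cluster correction requested with {name}={given} "
                f"but the permutation map was built with {name}={have}"
            )
    if result._stack is None or result._supra_threshold is None:
        raise ProvenanceError(
            "result carries no permutation state; run permutation_pmap first"
        )

    shape = result.z.shape
    thr = result._supra_threshold.ravel()
    S = result._stack
    n = S.shape[0]
    m = result._m
    total = S.sum(axis=0)
    n_other = n - m

    null_max = np.empty(result.B, dtype=np.int64)
    pos = 0
    rng = np.random.default_rng(result.seed)
    for M in _perm_chunks(rng, result.B, n, m, chunk):
        sum_small = M @ S
        p_small = sum_small / m
        p_other = (total[None, :] - sum_small) / n_other
        abs_z = np.abs(_z_from_props(p_small, p_other, m, n_other))
        supra = abs_z > thr[None, :]
        for row in supra:
            null_max[pos] = _max_extent(row.reshape(shape))
            pos += 1

    supra_obs = result.p_uncorrected < result.alpha
    clusters, nclust = ndimage.label(supra_obs, structure=_CONN8)
    crit = int(np.quantile(null_max, 1.0 - result.alpha, method="higher"))
    # a null critical extent of 0 would declare any supra pixel significant;
    # a cluster is at least 1 pixel, so the effective floor is 1
    crit = max(crit, 1)

    surviving = np.zeros(shape, dtype=np.uint8)
    if nclust:
        extents = np.bincount(clusters.ravel())
        for lab in range(1, nclust + 1):
            if extents[lab] >= crit:
                surviving[clusters == lab] = 1

    result.clusters = clusters
    result.surviving = surviving
    result.null_max_extent = null_max
    result.cluster_extent_threshold = crit
    return result
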