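"""Nonparametric cluster-mass permutation inference on searchlight maps.

Voxel-wise statistics (one-sample dependent t, pooled-variance independent
two-sample t, or the t of an OLS slope) are thresholded two-sided at
``voxel_alpha``; suprathreshold voxels are grouped into connected components
separately for positive and negative signs, and each component's mass (the
sum of its t values) is referred to a Monte-Carlo null distribution of the
per-permutation maximum absolute cluster mass.  Permutations are subject
sign flips (one-sample), group relabelings preserving group sizes
(two-sample), or covariate shuffles (regression).  A cluster is reported
significant when its Monte-Carlo p-value, (1 + #{null >= mass}) / (1 +
n_perm), falls below ``cluster_alpha`` and it spans at least
``min_cluster_voxels`` voxels.  When ``n_perm`` meets or exceeds the number
of distinct permutations the test enumerates them exactly.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .config import PermutationScheme

__all__ = [
    "StatMap",
    "Cluster",
    "ClusterTestResult",
    "ClusterPermutationTest",
    "voxelwise_stats",
    "label_clusters",
    "permutation_cluster_test",
    "restrict_search_space",
    "cluster_mean_extract",
]

_STRUCTURES = {6: 1, 18: 2, 26: 3}


@dataclass
class StatMap:
    t: np.ndarray
    p: np.ndarray
    df: int
    contrast: str


@dataclass(eq=False)
class Cluster:
    voxels: np.ndarray  # (k, 3) integer coordinates
    mass: float
    sign: str
    peak_t: float
    peak_ijk: tuple
    p_mc: float = np.nan

    @property
    def size(self) -> int:
        return self.voxels.shape[0]

    def mask(self, grid_shape) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


def _stack(maps) -> np.ndarray:
    X = np.asarray(maps, dtype=float)
    if X.ndim != 4:
        raise ValueError("maps must be a (n_subjects, x, y, z) stack")
    return X


def _effective_mask(X, mask):
    """Restrict to voxels observed for every subject (searchlight edges may
    be undefined for some)."""
    return np.asarray(mask, dtype=bool) & np.isfinite(X).all(axis=0)


def _t_one_sample(S, X):
    """Sign-flip t maps: S (P, n) in {-1, +1}, X (n, V)."""
    n = X.shape[0]
    m = (S @ X) / n
    ss = (X * X).sum(axis=0)
    var = (ss - n * m * m) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return m / np.sqrt(var / n)


def _t_two_sample(A, X, n1):
    """Group-shuffle pooled t maps: A (P, n) membership of group 1."""
    n = X.shape[0]
    n2 = n - n1
    s = X.sum(axis=0)
    q = (X * X).sum(axis=0)
    s1 = A @ X
    q1 = A @ (X * X)
    m1 = s1 / n1
    m2 = (s - s1) / n2
    ssw = (q1 - n1 * m1 * m1) + ((q - q1) - n2 * m2 * m2)
    sp2 = ssw / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))


def _t_regression(C, X):
    """Covariate-shuffle slope t maps: C (P, n) centred covariate rows."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    xn = np.linalg.norm(Xc, axis=0)
    cn = np.linalg.norm(C, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (C @ Xc) / np.outer(cn, xn)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        return r * np.sqrt(df / (1.0 - r * r))


def voxelwise_stats(maps, mask, groups=None, covariate=None) -> StatMap:
    """Per-voxel t and two-sided p over a stack of subject maps.

    One-sample against zero by default; two-sample (pooled variance,
    first-listed group minus second) when ``groups`` is given; OLS-slope t
    when ``covariate`` is given.
    """
    X4 = _stack(maps)
    eff = _effective_mask(X4, mask)
    X = X4[:, eff]
    n = X.shape[0]
    if groups is not None and covariate is not None:
        raise ValueError("pass either groups or covariate, not both")
    if groups is not None:
        groups = np.asarray(groups)
        labels = pd.unique(groups)
        if len(labels) != 2:
            raise ValueError("exactly two groups required")
        a = groups == labels[0]
        if min(a.sum(), (~a).sum()) < 3:
            raise ValueError("need at least 3 subjects per group")
        t = _t_two_sample(a[None, :].astype(float), X, int(a.sum()))[0]
        df = n - 2
        contrast = "two_sample_independent"
    elif covariate is not None:
        c = np.asarray(covariate, dtype=float)
        if c.size != n:
            raise ValueError("covariate length does not match subjects")
        t = _t_regression((c - c.mean())[None, :], X)[0]
        df = n - 2
        contrast = "covariate_regression"
    else:
        if n < 3:
            raise ValueError("need at least 3 subjects")
        t = _t_one_sample(np.ones((1, n)), X)[0]
        df = n - 1
        contrast = "one_sample_dependent"
    p = 2.0 * stats.t.sf(np.abs(t), df)
    t_map = np.full(eff.shape, np.nan)
    p_map = np.full(eff.shape, np.nan)
    t_map[eff] = t
    p_map[eff] = p
    return StatMap(t=t_map, p=p_map, df=df, contrast=contrast)


def label_clusters(binary: np.ndarray, connectivity: int = 26):
    """Connected components of a binary volume; returns (labels, n)."""
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    return ndimage.label(binary, structure=structure)


def _clusters_from_tmap(t3d, eff, t_crit, connectivity):
    clusters = []
    for sign, supra in (("positive", t3d > t_crit), ("negative", t3d < -t_crit)):
        supra = supra & eff
        labels, n = label_clusters(supra, connectivity)
        for lab in range(1, n + 1):
            vox = np.argwhere(labels == lab)
            tv = t3d[tuple(vox.T)]
            peak = int(np.argmax(np.abs(tv)))
            clusters.append(
                Cluster(
                    voxels=vox,
                    mass=float(tv.sum()),
                    sign=sign,
                    peak_t=float(tv[peak]),
                    peak_ijk=tuple(int(v) for v in vox[peak]),
                )
            )
    return clusters


def _max_masses(T, eff, t_crit, connectivity, grid_shape, flat_idx):
    """Per-permutation maximum absolute cluster mass for a block of t maps."""
    out = np.zeros(T.shape[0])
    vol = np.zeros(grid_shape)
    for p in range(T.shape[0]):
        vol[:] = 0.0
        vol.ravel()[flat_idx] = T[p]
        best = 0.0
        for signed in (vol > t_crit, vol < -t_crit):
            if not signed.any():
                continue
            labels, n = label_clusters(signed, connectivity)
            masses = np.bincount(
                labels[signed], weights=vol[signed], minlength=n + 1
            )
            if masses.size > 1:
                best = max(best, np.abs(masses[1:]).max())
        out[p] = best
    return out


def _draw_permutations(scheme, n, n1, covariate, rng):
    """Permutation matrix plus a flag for exact enumeration."""
    kind = scheme.kind
    if kind == "sign_flip":
        total = 2**n if n < 63 else np.inf
        if total <= scheme.n_perm:
            S = np.array(list(itertools.product([-1.0, 1.0], repeat=n)))
            return S, True
        return rng.choice([-1.0, 1.0], size=(scheme.n_perm, n)), False
    if kind == "group_shuffle":
        total = math.comb(n, n1)
        if total <= scheme.n_perm:
            A = np.zeros((total, n))
            for i, combo in enumerate(itertools.combinations(range(n), n1)):
                A[i, list(combo)] = 1.0
            return A, True
        A = np.zeros((scheme.n_perm, n))
        for i in range(scheme.n_perm):
            A[i, rng.choice(n, size=n1, replace=False)] = 1.0
        return A, False
    # covariate_shuffle
    total = math.factorial(n) if n < 13 else np.inf
    c = covariate - covariate.mean()
    if total <= scheme.n_perm:
        C = np.array([c[list(p)] for p in itertools.permutations(range(n))])
        return C, True
    return np.array([c[rng.permutation(n)] for _ in range(scheme.n_perm)]), False


@dataclass
class ClusterTestResult:
    """Observed clusters, their Monte-Carlo p-values, and the null."""

    stat_map: StatMap
    clusters: list
    null_max_mass: np.ndarray
    t_crit: float
    scheme: PermutationScheme
    exact: bool = False
    grid_shape: tuple = ()

    @property
    def n_perm_used(self) -> int:
        return self.null_max_mass.size

    @property
    def significant_clusters(self) -> list:
        return [
            c
            for c in self.clusters
            if c.p_mc < self.scheme.cluster_alpha
            and c.size >= self.scheme.min_cluster_voxels
        ]

    def significance_mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        for c in self.significant_clusters:
            m |= c.mask(self.grid_shape)
        return m

    def cluster_table(self) -> pd.DataFrame:
        rows = [
            {
                "peak_x": c.peak_ijk[0],
                "peak_y": c.peak_ijk[1],
                "peak_z": c.peak_ijk[2],
                "peak_t": c.peak_t,
                "k": c.size,
                "mass": c.mass,
                "sign": c.sign,
                "p_mc": c.p_mc,
                "significant": c in self.significant_clusters,
            }
            for c in sorted(self.clusters, key=lambda c: -abs(c.mass))
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "peak_x", "peak_y", "peak_z", "peak_t",
                "k", "mass", "sign", "p_mc", "significant",
            ],
        )


class ClusterPermutationTest:
    """Cluster-mass Monte-Carlo test over a stack of subject maps.

    Parameters
    ----------
    maps : (n_subjects, x, y, z) array of searchlight maps (contrast maps
        for the one-sample test).
    mask : search mask; inference is restricted to its finite voxels.
    scheme : PermutationScheme (kind, n_perm, thresholds, connectivity, seed).
    groups : subject labels for the two-sample test.
    covariate : behavioural score for the regression test; the covariate is
        shuffled across subjects, preserving the maps' spatial covariance.
    """

    def __init__(self, maps, mask, scheme: PermutationScheme,
                 groups=None, covariate=None):
        self.maps = _stack(maps)
        self.mask = np.asarray(mask, dtype=bool)
        self.scheme = scheme
        self.groups = None if groups is None else np.asarray(groups)
        self.covariate = None if covariate is None else np.asarray(covariate, float)
        kinds = {"sign_flip": groups is None and covariate is None,
                 "group_shuffle": groups is not None,
                 "covariate_shuffle": covariate is not None}
        if not kinds[scheme.kind]:
            raise ValueError(
                f"scheme kind {scheme.kind!r} does not match the design inputs"
            )

    def fit(self, chunk_size: int = 128) -> ClusterTestResult:
        scheme = self.scheme
        eff = _effective_mask(self.maps, self.mask)
        X = self.maps[:, eff]
        n = X.shape[0]
        flat_idx = np.flatnonzero(eff)
        stat = voxelwise_stats(self.maps, self.mask, self.groups, self.covariate)
        t_crit = float(stats.t.ppf(1.0 - scheme.voxel_alpha / 2.0, stat.df))
        observed = _clusters_from_tmap(
            np.nan_to_num(stat.t), eff, t_crit, scheme.connectivity
        )

        rng = np.random.default_rng(scheme.seed)
        n1 = None
        if self.groups is not None:
            n1 = int((self.groups == pd.unique(self.groups)[0]).sum())
        P, exact = _draw_permutations(scheme, n, n1, self.covariate, rng)
        null = np.empty(P.shape[0])
        for sl in _chunk_slices(P.shape[0], chunk_size):
            block = P[sl]
            if scheme.kind == "sign_flip":
                T = _t_one_sample(block, X)
            elif scheme.kind == "group_shuffle":
                T = _t_two_sample(block, X, n1)
            else:
                T = _t_regression(block, X)
            null[sl] = _max_masses(
                np.nan_to_num(T), eff, t_crit, scheme.connectivity,
                eff.shape, flat_idx,
            )
        m = null.size
        for c in observed:
            c.p_mc = (1.0 + np.sum(null >= abs(c.mass))) / (1.0 + m)
        return ClusterTestResult(
            stat_map=stat,
            clusters=observed,
            null_max_mass=null,
            t_crit=t_crit,
            scheme=scheme,
            exact=exact,
            grid_shape=eff.shape,
        )


def _chunk_slices(n, size):
    for lo in range(0, n, size):
        yield slice(lo, min(lo + size, n))


def permutation_cluster_test(
    maps, scheme: PermutationScheme, mask, groups=None, covariate=None
) -> ClusterTestResult:
    """Functional wrapper around :class:`ClusterPermutationTest`."""
    return ClusterPermutationTest(maps, mask, scheme, groups, covariate).fit()


def restrict_search_space(clusters, grid_shape) -> np.ndarray:
    """Union of significant whole-group cluster voxels as a search mask.

    Emits a warning (and an empty mask) when no clusters survive; downstream
    restricted tests should then be skipped.
    """
    mask = np.zeros(grid_shape, dtype=bool)
    for c in clusters:
        mask |= c.mask(grid_shape)
    if not mask.any():
        warnings.warn("no significant clusters: restricted search space is empty")
    return mask


def cluster_mean_extract(maps, cluster) -> np.ndarray:
    """Per-subject mean of map values inside a cluster (missing-aware)."""
    X = _stack(maps)
    mask = cluster if isinstance(cluster, np.ndarray) else cluster.mask(X.shape[1:])
    if mask.dtype != bool:
        mask = mask.astype(bool)
    vals = X[:, mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(vals, axis=1)
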