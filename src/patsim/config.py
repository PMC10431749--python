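"""Configuration objects shared across the pipeline.

All stochastic stages derive their random state from a single integer seed via
:func:`rng_for`, which splits one root ``SeedSequence`` by stable string keys
(subject labels, stage names).  This makes every artifact a pure function of
``(config, seed)`` regardless of evaluation order or parallelism.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field

import numpy as np

CATEGORIES = ("face", "house")
PHASES = ("encoding", "recognition")

#: correlation magnitude cap applied before the Fisher transform; atanh
#: diverges at |r| = 1, which noise-free fixtures reach exactly.
DEFAULT_CLAMP_R = 1.0 - 1e-7


def rng_for(seed: int, *keys: object) -> np.random.Generator:
    """Independent generator for (seed, keys), stable across runs and workers.

    Keys are hashed with CRC32 so that string labels (subject ids, stage
    names) map to reproducible spawn keys.
    """
    hashed = tuple(zlib.crc32(str(k).encode("utf8")) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=hashed))


def _block_mask(grid_shape, x0, x1, y0, y1, z0, z1) -> np.ndarray:
    m = np.zeros(grid_shape, dtype=bool)
    m[x0:x1, y0:y1, z0:z1] = True
    return m


def default_signal_regions(grid_shape) -> dict:
    """Two disjoint cubic blocks, one per stimulus category.

    The face block sits in the low-x half and the house block in the high-x
    half of the grid, both centred in y and z.  Side length scales with the
    grid (5 voxels on the default 20-voxel grid, minimum 3).
    """
    nx, ny, nz = grid_shape
    side = max(3, min(5, nx // 4))
    ymid = ny // 2
    zmid = nz // 2
    y0, y1 = ymid - side // 2, ymid - side // 2 + side
    z0, z1 = zmid - side // 2, zmid - side // 2 + side
    fx0 = max(0, nx // 4 - side // 2)
    hx0 = min(nx - side, 3 * nx // 4 - side // 2)
    return {
        "face": _block_mask(grid_shape, fx0, fx0 + side, y0, y1, z0, z1),
        "house": _block_mask(grid_shape, hx0, hx0 + side, y0, y1, z0, z1),
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe the desk-scale study: two age groups of 12 subjects,
    12 items per category (half old, half new), a 20x20x20 voxel grid at
    2 mm isotropic resolution, category and item pattern templates planted in
    two disjoint blocks, and memory outcomes generated from trial-wise latent
    distinctiveness through a logistic link whose intercepts reproduce the
    groups' old/new response biases (false-alarm rates 0.26 and 0.42).
    """

    n_subjects_per_group: int = 12
    n_items_per_category: int = 12  # old + new; half are shown at encoding
    grid_shape: tuple = (20, 20, 20)
    voxel_size_mm: float = 2.0
    signal_region_cat: dict | None = None  # {category: 3D bool mask}
    signal_region_item: dict | None = None  # defaults to signal_region_cat
    cat_signal_sd: float = 1.0
    item_signal_sd: float = 0.5
    noise_sd: float = 1.0
    dediff_factor_old: float = 0.5  # multiplies signal amplitudes in the old group
    memory_slope: float = 1.0  # log-odds per unit latent specificity
    bias_young: float = float(np.log(0.26 / 0.74))  # logit of the young FA rate
    bias_old: float = float(np.log(0.42 / 0.58))  # logit of the old FA rate
    subject_bias_sd: float = 0.5  # random-intercept sd of the logistic link
    subject_slope_sd: float = 0.3  # random-slope sd of the logistic link
    latent_spec_mean: float = 1.0
    latent_spec_sd: float = 0.3
    tr_s: float = 2.0
    stim_duration_s: float = 1.2
    iti_range_s: tuple = (0.5, 8.0)
    seed: int = 0

    def __post_init__(self):
        if self.signal_region_cat is None:
            self.signal_region_cat = default_signal_regions(self.grid_shape)
        if self.signal_region_item is None:
            self.signal_region_item = {
                c: m.copy() for c, m in self.signal_region_cat.items()
            }
        self.validate()

    def validate(self) -> None:
        if self.n_items_per_category < 4:
            raise ConfigError("n_items_per_category must be >= 4")
        if self.n_items_per_category % 2:
            raise ConfigError("n_items_per_category must be even (half old, half new)")
        if not (0.0 <= self.dediff_factor_old <= 1.0):
            raise ConfigError("dediff_factor_old must lie in [0, 1]")
        if min(self.cat_signal_sd, self.item_signal_sd, self.noise_sd) < 0:
            raise ConfigError("signal and noise amplitudes must be >= 0")
        if self.tr_s <= 0 or self.voxel_size_mm <= 0:
            raise ConfigError("tr_s and voxel_size_mm must be positive")
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise ConfigError("grid_shape must be three positive integers")
        for name, regions in (("cat", self.signal_region_cat),
                              ("item", self.signal_region_item)):
            for cat in CATEGORIES:
                if cat not in regions:
                    raise ConfigError(f"signal_region_{name} missing {cat!r}")
                if tuple(regions[cat].shape) != tuple(self.grid_shape):
                    raise ConfigError(
                        f"signal_region_{name}[{cat!r}] does not match grid_shape"
                    )

    @property
    def n_old_per_category(self) -> int:
        return self.n_items_per_category // 2

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff


class ConfigError(ValueError):
    """Invalid configuration."""


@dataclass
class SearchlightSpec:
    """Spherical searchlight geometry.

    radius_mm: sphere radius (8 mm default; 4 and 12 mm supported).
    min_voxels: centres whose in-mask sphere holds fewer voxels are left
    undefined -- correlations over tiny voxel sets are unstable.
    """

    radius_mm: float = 8.0
    min_voxels: int = 10
    voxel_size_mm: float = 2.0

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ConfigError("radius_mm must be positive")
        if self.min_voxels < 2:
            raise ConfigError("min_voxels must be >= 2")


@dataclass
class PermutationScheme:
    """Cluster-mass Monte-Carlo inference settings.

    kind: 'sign_flip' (one-sample, dependent), 'group_shuffle' (independent
    two-sample), or 'covariate_shuffle' (voxel-wise regression slope).
    """

    kind: str = "sign_flip"
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    voxel_alpha: float = 0.005
    min_cluster_voxels: int = 10
    connectivity: int = 26
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("sign_flip", "group_shuffle", "covariate_shuffle"):
            raise ConfigError(f"unknown permutation kind {self.kind!r}")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")
        for a in (self.cluster_alpha, self.voxel_alpha):
            if not (0.0 < a < 1.0):
                raise ConfigError("alphas must lie in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")


def config_hash(obj) -> str:
    """Stable hash of a (possibly nested) configuration dataclass."""

    def encode(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {f.name: encode(getattr(o, f.name)) for f in dataclasses.fields(o)}
        if isinstance(o, np.ndarray):
            return hashlib.sha256(np.ascontiguousarray(o).tobytes()).hexdigest()
        if isinstance(o, dict):
            return {str(k): encode(v) for k, v in sorted(o.items())}
        if isinstance(o, (list, tuple)):
            return [encode(v) for v in o]
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return o

    payload = json.dumps(encode(obj), sort_keys=True).encode("utf8")
    return hashlib.sha256(payload).hexdigest()[:16]
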