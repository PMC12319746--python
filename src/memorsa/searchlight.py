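"""Moving-sphere similarity mapping with permutation FWE control.

The ROI similarity analysis is repeated inside a sphere (default radius
3 voxels) centered on every in-mask voxel; the contrast over the eight
condition-cell means becomes the center voxel's value in a per-subject
effect map. Subject maps are combined with a second-level one-sample t
test. Family-wise error control uses the sign-flipping max-statistic
permutation scheme: under the null of symmetrically distributed subject
effects, each voxel's corrected p is the proportion of permutations
whose volume-wide max |t| reaches the observed |t| (the observed
labeling counts as one permutation, so the smallest attainable
corrected p is 1/(n_perm+1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import TrialTable
from .rsa import PairSet, cell_means, pair_similarities


def sphere_offsets(radius: int) -> np.ndarray:
    """Integer lattice offsets with squared norm <= radius**2.

    Radius 3 gives the 123 voxels of the study's searchlight.
    """
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx ** 2 + dy ** 2 + dz ** 2 <= r * r
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


@dataclass
class SphereSpec:
    radius: int = 3
    min_voxels: int | None = None    # default: half the full sphere

    @property
    def offsets(self) -> np.ndarray:
        return sphere_offsets(self.radius)

    @property
    def min_voxels_effective(self) -> int:
        full = len(self.offsets)
        return self.min_voxels if self.min_voxels is not None else full // 2


def searchlight_effects(enc_vol: np.ndarray | None, ret_vol: np.ndarray,
                        pairs: PairSet, weights: np.ndarray,
                        mask: np.ndarray, sphere: SphereSpec | int = 3
                        ) -> np.ndarray:
    """Per-voxel contrast map for one subject.

    ``enc_vol``/``ret_vol`` are 4D (x, y, z, trials) single-trial t-map
    stacks; ``enc_vol`` may be None for an RRS pair set. ``pairs`` is a
    pre-enumerated pair set (the inclusion rules do not depend on the
    voxels, so the same pairs are reused at every center). Centers whose
    sphere covers fewer than ``min_voxels`` in-mask voxels are NaN.
    """
    if isinstance(sphere, int):
        sphere = SphereSpec(sphere)
    weights = np.asarray(weights, float)
    mask = np.asarray(mask, bool)
    shape = mask.shape
    if ret_vol.shape[:3] != shape:
        raise ValueError("volume and mask grids differ")
    if pairs.analysis == "ERS":
        if enc_vol is None:
            raise ValueError("ERS needs the encoding volume stack")
        if enc_vol.shape[:3] != shape:
            raise ValueError("volume and mask grids differ")

    offsets = sphere.offsets
    min_vox = sphere.min_voxels_effective
    out = np.full(shape, np.nan)
    centers = np.argwhere(mask)
    for cx, cy, cz in centers:
        coords = offsets + (cx, cy, cz)
        ok = ((coords >= 0).all(axis=1)
              & (coords < shape).all(axis=1))
        coords = coords[ok]
        inmask = mask[coords[:, 0], coords[:, 1], coords[:, 2]]
        coords = coords[inmask]
        if coords.shape[0] < min_vox:
            continue
        ret_pat = ret_vol[coords[:, 0], coords[:, 1], coords[:, 2], :].T
        if pairs.analysis == "ERS":
            enc_pat = enc_vol[coords[:, 0], coords[:, 1], coords[:, 2], :].T
            local = PairSet(pairs.analysis, pairs.a_idx, pairs.b_idx,
                            pairs.cell)
            pair_similarities(local, enc_pat, ret_pat)
        else:
            local = PairSet(pairs.analysis, pairs.a_idx, pairs.b_idx,
                            pairs.cell)
            pair_similarities(local, ret_pat)
        means, _ = cell_means(local)
        touched = np.abs(weights) > 0
        if np.isnan(means[touched]).any():
            continue
        out[cx, cy, cz] = float(np.nansum(means * weights)
                                / (np.abs(weights).sum() / 2.0))
    return out


def group_tmap(effect_maps: np.ndarray) -> np.ndarray:
    """Voxelwise one-sample t over subjects (axis 0 of a 4D stack).

    Voxels missing in any subject, or with zero between-subject
    variance, are NaN.
    """
    maps = np.asarray(effect_maps, float)
    n = maps.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subject maps")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = np.nan
    return t


def fwe_maxstat(effect_maps: np.ndarray, n_perm: int = 1000,
                seed: int | None = None,
                small_volume_mask: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Sign-flip max-statistic FWE-corrected p map.

    Returns (corrected p volume, observed t volume), NaN outside the
    (optional) small-volume mask or where t is undefined. Corrected
    p = (1 + #{perm max |t| >= observed |t|}) / (n_perm + 1), monotone
    nonincreasing in |t|; a smaller mask can only shrink the max and
    hence the p values.
    """
    maps = np.asarray(effect_maps, float)
    n = maps.shape[0]
    t_obs = group_tmap(maps)
    valid = np.isfinite(t_obs)
    if small_volume_mask is not None:
        valid &= np.asarray(small_volume_mask, bool)
    flat = maps.reshape(n, -1)[:, valid.ravel()]
    if flat.shape[1] == 0:
        raise ValueError("no valid voxels in the mask")
    rng = np.random.default_rng(seed)

    tv = t_obs[valid]
    maxstats = np.empty(n_perm)
    sq = np.sqrt(n)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], n)
        fm = signs[:, None] * flat
        mean = fm.mean(axis=0)
        sd = fm.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tperm = np.abs(mean / (sd / sq))
        maxstats[i] = np.nanmax(tperm)
    exceed = (maxstats[:, None] >= np.abs(tv)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p_vol = np.full(t_obs.shape, np.nan)
    p_vol[valid] = p
    return p_vol, t_obs
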