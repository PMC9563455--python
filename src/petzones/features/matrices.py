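"""Construction of the five gray-level texture matrices from a discretized ROI.

Conventions (all at voxel distance 1):

* GLCM and GLRLM use the 13 unique 3D direction offsets, counted
  symmetrically (GLCM) and aggregated per direction;
* GLSZM zones and GLDM dependencies use 26-connectivity;
* GLDM dependence tolerance is zero: a neighbor is dependent only when its
  gray level equals the centre's.  The dependence size of a voxel is
  1 + number of dependent in-mask neighbors, so an isolated voxel has
  dependence 1;
* NGTDM neighborhood averages use the 26 in-mask neighbors; voxels with no
  in-mask neighbor are excluded from the table.

Matrices are indexed by the distinct gray levels actually present in the
masked region; formulas downstream weight rows by the level *values*.
Voxels outside the mask never contribute to pairs, runs, zones,
dependencies, or neighborhood averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import ndimage

from ..errors import EmptyMaskError
from ..imaging import ROIMask
from .gray import GrayLevelImage

# 13 unique direction offsets covering the 26-neighborhood up to sign
DIRECTIONS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

__all__ = ["TextureMatrices", "build_matrices", "DIRECTIONS"]


@dataclass
class TextureMatrices:
    """Texture matrices for one ROI, plus the gray-level bookkeeping."""

    levels: np.ndarray           # distinct 1-based levels present, sorted
    n_voxels: int
    glcm: List[np.ndarray]       # per-direction symmetric count matrices (Ng x Ng)
    glcm_norm: np.ndarray        # normalized aggregate over directions
    glrlm: List[np.ndarray]      # per-direction run-length counts (Ng x Rmax)
    glszm: np.ndarray            # zone-size counts (Ng x Smax)
    gldm: np.ndarray             # dependence counts (Ng x Dmax)
    ngtdm_n: np.ndarray          # per-level voxel counts (valid neighborhoods)
    ngtdm_s: np.ndarray          # per-level summed |level - neighborhood mean|


def _shift_pairs(shape, d):
    """Index slices selecting (voxel, voxel+d) pairs within the grid."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(None)); dst.append(slice(None))
        elif step > 0:
            src.append(slice(0, n - step)); dst.append(slice(step, n))
        else:
            src.append(slice(-step, n)); dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


def _glcm_direction(lev, inside, rank, ng, d):
    src, dst = _shift_pairs(lev.shape, d)
    ok = inside[src] & inside[dst]
    i = rank[src][ok]
    j = rank[dst][ok]
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    return counts + counts.T  # symmetric counting


def _glrlm_direction(lev, inside, rank, ng, d):
    shape = lev.shape
    # same[v] is True when voxel v continues the run of v - d
    src, dst = _shift_pairs(shape, d)
    same = np.zeros(shape, dtype=bool)
    same[dst] = inside[src] & inside[dst] & (lev[src] == lev[dst])
    starts = inside & ~same
    pos = np.array(np.nonzero(starts))  # 3 x n_runs
    run_rank = rank[starts]
    lengths = np.ones(pos.shape[1], dtype=np.int64)
    active = np.arange(pos.shape[1])
    cur = pos.copy()
    dvec = np.array(d).reshape(3, 1)
    while active.size:
        nxt = cur[:, active] + dvec
        ok = np.all((nxt >= 0) & (nxt < np.array(shape).reshape(3, 1)), axis=0)
        idx = active[ok]
        nxt = nxt[:, ok]
        cont = same[tuple(nxt)]
        idx = idx[cont]
        lengths[idx] += 1
        cur[:, idx] = nxt[:, cont]
        active = idx
    rmax = int(lengths.max()) if lengths.size else 1
    mat = np.zeros((ng, rmax), dtype=np.float64)
    np.add.at(mat, (run_rank, lengths - 1), 1.0)
    return mat


def _glszm(lev, inside, levels):
    struct = np.ones((3, 3, 3), dtype=int)
    sizes_per_level = []
    smax = 1
    for lv in levels:
        lab, n = ndimage.label(lev == lv, structure=struct)
        if n == 0:
            sizes_per_level.append(np.array([], dtype=np.int64))
            continue
        sz = np.bincount(lab.ravel())[1:]
        sizes_per_level.append(sz)
        smax = max(smax, int(sz.max()))
    mat = np.zeros((len(levels), smax), dtype=np.float64)
    for r, sz in enumerate(sizes_per_level):
        if sz.size:
            np.add.at(mat, (r, sz - 1), 1.0)
    return mat


def _neighbor_offsets():
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx or dy or dz:
                    offs.append((dx, dy, dz))
    return offs


def _gldm_ngtdm(lev, inside, rank, ng):
    shape = lev.shape
    dep = np.zeros(shape, dtype=np.int64)        # dependent neighbors (alpha = 0)
    nb_count = np.zeros(shape, dtype=np.int64)   # in-mask neighbors
    nb_sum = np.zeros(shape, dtype=np.float64)   # sum of in-mask neighbor levels
    for d in _neighbor_offsets():
        src, dst = _shift_pairs(shape, d)
        both = inside[src] & inside[dst]
        eq = both & (lev[src] == lev[dst])
        # neighbor at dst contributes to the centre at src... accumulate on dst
        dep[dst] += eq
        nb_count[dst] += both
        nb_sum[dst] += np.where(both, lev[src], 0)
    dsize = dep[inside] + 1
    dmax = int(dsize.max())
    gldm = np.zeros((ng, dmax), dtype=np.float64)
    np.add.at(gldm, (rank[inside], dsize - 1), 1.0)

    valid = inside & (nb_count > 0)
    diffs = np.abs(lev[valid] - nb_sum[valid] / nb_count[valid])
    ngtdm_n = np.bincount(rank[valid], minlength=ng).astype(np.float64)
    ngtdm_s = np.zeros(ng, dtype=np.float64)
    np.add.at(ngtdm_s, rank[valid], diffs)
    return gldm, ngtdm_n, ngtdm_s


def build_matrices(gray: GrayLevelImage, mask: ROIMask) -> TextureMatrices:
    """Build all five texture matrices for the masked region."""
    inside = mask.values
    if not inside.any():
        raise EmptyMaskError("cannot build texture matrices on an empty mask")
    lev = gray.levels
    levels = np.unique(lev[inside])
    ng = len(levels)
    # dense rank map: gray level -> row index
    rank_of = np.zeros(int(levels.max()) + 1, dtype=np.int64)
    rank_of[levels] = np.arange(ng)
    rank = rank_of[np.where(inside, lev, levels[0])]

    glcm = [_glcm_direction(lev, inside, rank, ng, d) for d in DIRECTIONS]
    total = sum(m.sum() for m in glcm)
    if total > 0:
        agg = sum(glcm)
        glcm_norm = agg / agg.sum()
    else:
        # single-voxel ROI: treat as a constant image with one self-pair
        glcm_norm = np.ones((ng, ng)) / (ng * ng) if ng == 1 else np.eye(ng) / ng
    glrlm = [_glrlm_direction(lev, inside, rank, ng, d) for d in DIRECTIONS]
    glszm = _glszm(lev, inside, levels)
    gldm, ngtdm_n, ngtdm_s = _gldm_ngtdm(lev, inside, rank, ng)
    return TextureMatrices(
        levels=levels.astype(np.float64),
        n_voxels=int(inside.sum()),
        glcm=glcm,
        glcm_norm=glcm_norm,
        glrlm=glrlm,
        glszm=glszm,
        gldm=gldm,
        ngtdm_n=ngtdm_n,
        ngtdm_s=ngtdm_s,
    )
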