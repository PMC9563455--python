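"""Texture features computed from the gray-level matrices.

GLCM and GLRLM features are evaluated per direction and averaged without
weighting; GLSZM, GLDM and NGTDM features come from their single matrices.

Degenerate single-gray-level regions follow a fixed convention rather than
producing NaN: correlation-type features (glcm_Correlation, glcm_MCC,
glcm_imc1, glcm_imc2) are 0, entropies are 0, and the inverse-difference
family evaluates to 1.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .matrices import TextureMatrices

_EPS = np.spacing(1.0)

__all__ = [
    "texture_features",
    "glcm_features_single",
    "glrlm_features_single",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
]


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def glcm_features_single(P: np.ndarray, levels: np.ndarray | None = None) -> Dict[str, float]:
    """The 24 GLCM features from one normalized symmetric co-occurrence matrix.

    ``levels`` holds the gray-level value of each row (defaults to 1..Ng).
    """
    P = np.asarray(P, dtype=np.float64)
    ng = P.shape[0]
    i_vals = np.asarray(levels, dtype=np.float64) if levels is not None else np.arange(1, ng + 1, dtype=np.float64)
    I, J = np.meshgrid(i_vals, i_vals, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float((px * i_vals).sum())
    uy = float((py * i_vals).sum())
    sigx = float(np.sqrt((px * (i_vals - ux) ** 2).sum()))
    sigy = float(np.sqrt((py * (i_vals - uy) ** 2).sum()))

    diff = np.abs(I - J)
    dsum = I + J
    # distributions of |i-j| and i+j
    diff_vals = np.unique(diff)
    p_diff = np.array([P[diff == k].sum() for k in diff_vals])
    sum_vals = np.unique(dsum)
    p_sum = np.array([P[dsum == k].sum() for k in sum_vals])

    hxy = _entropy(P.ravel())
    hx = _entropy(px)
    hy = _entropy(py)
    with np.errstate(divide="ignore"):
        log_pxy = np.log2(np.outer(px, py) + _EPS)
    hxy1 = float(-(P * log_pxy).sum())
    hxy2 = _entropy(np.outer(px, py).ravel())

    da = float((p_diff * diff_vals).sum())
    contrast = float((P * (I - J) ** 2).sum())

    out: Dict[str, float] = {}
    out["glcm_Autocorrelation"] = float((P * I * J).sum())
    ct = float((P * (I + J - ux - uy) ** 2).sum())
    out["glcm_ClusterProminence"] = float((P * (I + J - ux - uy) ** 4).sum())
    out["glcm_ClusterShade"] = float((P * (I + J - ux - uy) ** 3).sum())
    out["glcm_ClusterTendency"] = ct
    out["glcm_Contrast"] = contrast
    if sigx > 0 and sigy > 0:
        out["glcm_Correlation"] = float(((P * I * J).sum() - ux * uy) / (sigx * sigy))
    else:
        out["glcm_Correlation"] = 0.0
    out["glcm_DifferenceAverage"] = da
    out["glcm_DifferenceEntropy"] = _entropy(p_diff)
    out["glcm_DifferenceVariance"] = float((p_diff * (diff_vals - da) ** 2).sum())
    out["glcm_JointAverage"] = ux
    out["glcm_JointEnergy"] = float((P ** 2).sum())
    out["glcm_JointEntropy"] = hxy
    out["glcm_MCC"] = _mcc(P, px, py, ng)
    out["glcm_MaximumProbability"] = float(P.max())
    out["glcm_SumAverage"] = float((p_sum * sum_vals).sum())
    out["glcm_SumEntropy"] = _entropy(p_sum)
    out["glcm_SumSquares"] = float((P * (I - ux) ** 2).sum())
    nz = diff > 0
    out["glcm_InverseVariance"] = float((P[nz] / (diff[nz] ** 2)).sum()) if nz.any() else 0.0
    out["glcm_id"] = float((P / (1.0 + diff)).sum())
    out["glcm_idm"] = float((P / (1.0 + diff ** 2)).sum())
    out["glcm_idmn"] = float((P / (1.0 + diff ** 2 / ng ** 2)).sum())
    out["glcm_idn"] = float((P / (1.0 + diff / ng)).sum())
    if ng > 1:
        denom = max(hx, hy)
        out["glcm_imc1"] = float((hxy - hxy1) / denom) if denom > 0 else 0.0
        out["glcm_imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0
    else:
        out["glcm_imc1"] = 0.0
        out["glcm_imc2"] = 0.0
    return out


def _mcc(P: np.ndarray, px: np.ndarray, py: np.ndarray, ng: int) -> float:
    if ng == 1:
        return 0.0
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    Q = (P / np.where(px[:, None] > 0, px[:, None], 1.0)) @ (P / np.where(py[None, :] > 0, py[None, :], 1.0)).T
    eig = np.linalg.eigvals(Q)
    eig = np.sort(np.real(eig))
    if eig.size < 2:
        return 0.0
    return float(np.sqrt(max(0.0, eig[-2])))


def _run_family(P: np.ndarray, levels: np.ndarray, prefix: str,
                names: Dict[str, str], n_voxels: int) -> Dict[str, float]:
    """Shared run-length / size-zone / dependence feature formulas.

    ``P`` is a counts matrix with rows = gray-level values ``levels`` and
    columns = run length / zone size / dependence size 1..Jmax.
    ``names`` maps generic keys to the category's canonical feature names;
    keys absent from ``names`` are skipped.
    """
    nr = P.sum()
    if nr == 0:
        return {v: 0.0 for v in names.values()}
    i = levels.astype(np.float64)
    j = np.arange(1, P.shape[1] + 1, dtype=np.float64)
    I, J = np.meshgrid(i, j, indexing="ij")
    pg = P.sum(axis=1)  # per gray level
    pr = P.sum(axis=0)  # per run length
    p = P / nr
    mu_i = float((p * I).sum())
    mu_j = float((p * J).sum())
    vals = {
        "sre": float((P / J ** 2).sum() / nr),
        "lre": float((P * J ** 2).sum() / nr),
        "gln": float((pg ** 2).sum() / nr),
        "glnn": float((pg ** 2).sum() / nr ** 2),
        "rln": float((pr ** 2).sum() / nr),
        "rlnn": float((pr ** 2).sum() / nr ** 2),
        "rp": float(nr / n_voxels),
        "glv": float((p * (I - mu_i) ** 2).sum()),
        "rv": float((p * (J - mu_j) ** 2).sum()),
        "re": _entropy(p.ravel()),
        "lgle": float((P / I ** 2).sum() / nr),
        "hgle": float((P * I ** 2).sum() / nr),
        "slgle": float((P / (I ** 2 * J ** 2)).sum() / nr),
        "shgle": float((P * I ** 2 / J ** 2).sum() / nr),
        "llgle": float((P * J ** 2 / I ** 2).sum() / nr),
        "lhgle": float((P * I ** 2 * J ** 2).sum() / nr),
    }
    return {canon: vals[k] for k, canon in names.items()}


_GLRLM_NAMES = {
    "sre": "glrlm_ShortRunEmphasis",
    "lre": "glrlm_LongRunEmphasis",
    "gln": "glrlm_GrayLevelNonUniformity",
    "glnn": "glrlm_GrayLevelNonUniformityNormalized",
    "rln": "glrlm_rln",
    "rlnn": "glrlm_RunLengthNonUniformityNormalized",
    "rp": "glrlm_RunPercentage",
    "glv": "glrlm_GrayLevelVariance",
    "rv": "glrlm_RunVariance",
    "re": "glrlm_RunEntropy",
    "lgle": "glrlm_LowGrayLevelRunEmphasis",
    "hgle": "glrlm_HighGrayLevelRunEmphasis",
    "slgle": "glrlm_ShortRunLowGrayLevelEmphasis",
    "shgle": "glrlm_ShortRunHighGrayLevelEmphasis",
    "llgle": "glrlm_LongRunLowGrayLevelEmphasis",
    "lhgle": "glrlm_LongRunHighGrayLevelEmphasis",
}

_GLSZM_NAMES = {
    "sre": "glszm_SmallAreaEmphasis",
    "lre": "glszm_LargeAreaEmphasis",
    "gln": "glszm_GrayLevelNonUniformity",
    "glnn": "glszm_GrayLevelNonUniformityNormalized",
    "rln": "glszm_SizeZoneNonUniformity",
    "rlnn": "glszm_SizeZoneNonUniformityNormalized",
    "rp": "glszm_ZonePercentage",
    "glv": "glszm_GrayLevelVariance",
    "rv": "glszm_ZoneVariance",
    "re": "glszm_ZoneEntropy",
    "lgle": "glszm_LowGrayLevelZoneEmphasis",
    "hgle": "glszm_HighGrayLevelZoneEmphasis",
    "slgle": "glszm_SmallAreaLowGrayLevelEmphasis",
    "shgle": "glszm_SmallAreaHighGrayLevelEmphasis",
    "llgle": "glszm_LargeAreaLowGrayLevelEmphasis",
    "lhgle": "glszm_LargeAreaHighGrayLevelEmphasis",
}

_GLDM_NAMES = {
    "sre": "gldm_SmallDependenceEmphasis",
    "lre": "gldm_LargeDependenceEmphasis",
    "gln": "gldm_GrayLevelNonUniformity",
    "rln": "gldm_dn",
    "rlnn": "gldm_DependenceNonUniformityNormalized",
    "glv": "gldm_GrayLevelVariance",
    "rv": "gldm_DependenceVariance",
    "re": "gldm_DependenceEntropy",
    "lgle": "gldm_LowGrayLevelEmphasis",
    "hgle": "gldm_HighGrayLevelEmphasis",
    "slgle": "gldm_sdlgle",
    "shgle": "gldm_SmallDependenceHighGrayLevelEmphasis",
    "llgle": "gldm_LargeDependenceLowGrayLevelEmphasis",
    "lhgle": "gldm_LargeDependenceHighGrayLevelEmphasis",
}


def glrlm_features_single(P: np.ndarray, levels: np.ndarray, n_voxels: int) -> Dict[str, float]:
    """The 16 run-length features for a single direction's matrix."""
    return _run_family(np.asarray(P, float), np.asarray(levels, float), "glrlm",
                       _GLRLM_NAMES, n_voxels)


def glszm_features(P: np.ndarray, levels: np.ndarray, n_voxels: int) -> Dict[str, float]:
    return _run_family(np.asarray(P, float), np.asarray(levels, float), "glszm",
                       _GLSZM_NAMES, n_voxels)


def gldm_features(P: np.ndarray, levels: np.ndarray, n_voxels: int) -> Dict[str, float]:
    return _run_family(np.asarray(P, float), np.asarray(levels, float), "gldm",
                       _GLDM_NAMES, n_voxels)


def ngtdm_features(levels: np.ndarray, n: np.ndarray, s: np.ndarray) -> Dict[str, float]:
    """The five neighborhood gray-tone difference features."""
    n = np.asarray(n, float)
    s = np.asarray(s, float)
    lv = np.asarray(levels, float)
    nvp = n.sum()
    out = {k: 0.0 for k in ("ngtdm_Coarseness", "ngtdm_Contrast", "ngtdm_Busyness",
                            "ngtdm_Complexity", "ngtdm_Strength")}
    if nvp == 0:
        out["ngtdm_Coarseness"] = 1e6
        return out
    present = n > 0
    p = n / nvp
    i = lv[present]
    pi = p[present]
    si = s[present]
    ngp = int(present.sum())
    dens = float((pi * si).sum())
    out["ngtdm_Coarseness"] = float(1.0 / dens) if dens > 0 else 1e6
    if ngp > 1:
        dij2 = (i[:, None] - i[None, :]) ** 2
        out["ngtdm_Contrast"] = float(
            (pi[:, None] * pi[None, :] * dij2).sum() / (ngp * (ngp - 1)) * (si.sum() / nvp)
        )
        denom = np.abs(i[:, None] * pi[:, None] - i[None, :] * pi[None, :]).sum()
        out["ngtdm_Busyness"] = float(dens / denom) if denom > 0 else 0.0
        absd = np.abs(i[:, None] - i[None, :])
        psum = pi[:, None] + pi[None, :]
        num = pi[:, None] * si[:, None] + pi[None, :] * si[None, :]
        out["ngtdm_Complexity"] = float((absd * num / psum).sum() / nvp)
        ssum = si.sum()
        out["ngtdm_Strength"] = float((psum * dij2).sum() / ssum) if ssum > 0 else 0.0
    return out


def texture_features(tm: TextureMatrices) -> Dict[str, float]:
    """All 75 texture features (24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM)."""
    out: Dict[str, float] = {}
    # GLCM: per direction (skipping directions with no pairs), averaged
    per_dir = []
    for P in tm.glcm:
        tot = P.sum()
        if tot > 0:
            per_dir.append(glcm_features_single(P / tot, tm.levels))
    if not per_dir:
        per_dir = [glcm_features_single(tm.glcm_norm, tm.levels)]
    for k in per_dir[0]:
        out[k] = float(np.mean([d[k] for d in per_dir]))

    rl_dir = [glrlm_features_single(P, tm.levels, tm.n_voxels) for P in tm.glrlm]
    for k in rl_dir[0]:
        out[k] = float(np.mean([d[k] for d in rl_dir]))

    out.update(glszm_features(tm.glszm, tm.levels, tm.n_voxels))
    out.update(gldm_features(tm.gldm, tm.levels, tm.n_voxels))
    out.update(ngtdm_features(tm.levels, tm.ngtdm_n, tm.ngtdm_s))
    return out
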