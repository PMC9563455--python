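"""Independent brute-force reference for texture features and exact tests.

Everything here enumerates voxel pairs, runs, zones, dependencies and
neighborhoods with explicit Python loops, and evaluates the feature
formulas in plain scalar arithmetic.  It is deliberately slow and shares
no code with the package implementation; it exists to pin the vectorized
extractor on small inputs.
"""

import itertools
import math

import numpy as np

DIRECTIONS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

NEIGHBORS26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inb(shape, v):
    return all(0 <= v[a] < shape[a] for a in range(3))


def _voxels(mask):
    return [tuple(v) for v in np.argwhere(mask)]


def oracle_glcm(lev, mask, d):
    levels = sorted({int(lev[v]) for v in _voxels(mask)})
    idx = {g: r for r, g in enumerate(levels)}
    M = np.zeros((len(levels), len(levels)))
    for v in _voxels(mask):
        w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
        if _inb(mask.shape, w) and mask[w]:
            M[idx[int(lev[v])], idx[int(lev[w])]] += 1
            M[idx[int(lev[w])], idx[int(lev[v])]] += 1
    return M, levels


def oracle_glrlm(lev, mask, d):
    levels = sorted({int(lev[v]) for v in _voxels(mask)})
    idx = {g: r for r, g in enumerate(levels)}
    runs = []
    for v in _voxels(mask):
        prev = (v[0] - d[0], v[1] - d[1], v[2] - d[2])
        if _inb(mask.shape, prev) and mask[prev] and lev[prev] == lev[v]:
            continue  # not a run start
        length = 1
        cur = v
        while True:
            nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
            if _inb(mask.shape, nxt) and mask[nxt] and lev[nxt] == lev[cur]:
                length += 1
                cur = nxt
            else:
                break
        runs.append((int(lev[v]), length))
    rmax = max(l for _, l in runs)
    M = np.zeros((len(levels), rmax))
    for g, l in runs:
        M[idx[g], l - 1] += 1
    return M, levels


def oracle_glszm(lev, mask):
    levels = sorted({int(lev[v]) for v in _voxels(mask)})
    idx = {g: r for r, g in enumerate(levels)}
    seen = set()
    zones = []
    for v in _voxels(mask):
        if v in seen:
            continue
        g = int(lev[v])
        stack, comp = [v], {v}
        seen.add(v)
        while stack:
            cur = stack.pop()
            for d in NEIGHBORS26:
                w = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if (
                    _inb(mask.shape, w) and mask[w] and w not in seen
                    and int(lev[w]) == g
                ):
                    seen.add(w)
                    comp.add(w)
                    stack.append(w)
        zones.append((g, len(comp)))
    smax = max(s for _, s in zones)
    M = np.zeros((len(levels), smax))
    for g, s in zones:
        M[idx[g], s - 1] += 1
    return M, levels


def oracle_gldm(lev, mask):
    levels = sorted({int(lev[v]) for v in _voxels(mask)})
    idx = {g: r for r, g in enumerate(levels)}
    entries = []
    for v in _voxels(mask):
        dep = 0
        for d in NEIGHBORS26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _inb(mask.shape, w) and mask[w] and lev[w] == lev[v]:
                dep += 1
        entries.append((int(lev[v]), dep + 1))
    dmax = max(dd for _, dd in entries)
    M = np.zeros((len(levels), dmax))
    for g, dd in entries:
        M[idx[g], dd - 1] += 1
    return M, levels


def oracle_ngtdm(lev, mask):
    levels = sorted({int(lev[v]) for v in _voxels(mask)})
    n = {g: 0 for g in levels}
    s = {g: 0.0 for g in levels}
    for v in _voxels(mask):
        nb = []
        for d in NEIGHBORS26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _inb(mask.shape, w) and mask[w]:
                nb.append(int(lev[w]))
        if nb:
            g = int(lev[v])
            n[g] += 1
            s[g] += abs(g - sum(nb) / len(nb))
    return levels, [n[g] for g in levels], [s[g] for g in levels]


def _ent(ps):
    return -sum(p * math.log2(p) for p in ps if p > 0)


def oracle_glcm_features(P, levels):
    """Scalar-loop GLCM formulas on one normalized symmetric matrix."""
    ng = len(levels)
    px = [sum(P[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i][j] for i in range(ng)) for j in range(ng)]
    ux = sum(px[i] * levels[i] for i in range(ng))
    uy = sum(py[j] * levels[j] for j in range(ng))
    sigx = math.sqrt(sum(px[i] * (levels[i] - ux) ** 2 for i in range(ng)))
    sigy = math.sqrt(sum(py[j] * (levels[j] - uy) ** 2 for j in range(ng)))
    pdiff, psum = {}, {}
    for i in range(ng):
        for j in range(ng):
            kd = abs(levels[i] - levels[j])
            ks = levels[i] + levels[j]
            pdiff[kd] = pdiff.get(kd, 0.0) + P[i][j]
            psum[ks] = psum.get(ks, 0.0) + P[i][j]
    da = sum(k * p for k, p in pdiff.items())
    hxy = _ent(P[i][j] for i in range(ng) for j in range(ng))
    hx, hy = _ent(px), _ent(py)
    eps = np.spacing(1.0)
    hxy1 = -sum(
        P[i][j] * math.log2(px[i] * py[j] + eps)
        for i in range(ng)
        for j in range(ng)
    )
    hxy2 = _ent(px[i] * py[j] for i in range(ng) for j in range(ng))
    out = {}
    out["glcm_Autocorrelation"] = sum(
        P[i][j] * levels[i] * levels[j] for i in range(ng) for j in range(ng)
    )
    for name, power in (("glcm_ClusterProminence", 4), ("glcm_ClusterShade", 3),
                        ("glcm_ClusterTendency", 2)):
        out[name] = sum(
            P[i][j] * (levels[i] + levels[j] - ux - uy) ** power
            for i in range(ng) for j in range(ng)
        )
    out["glcm_Contrast"] = sum(
        P[i][j] * (levels[i] - levels[j]) ** 2 for i in range(ng) for j in range(ng)
    )
    out["glcm_Correlation"] = (
        (out["glcm_Autocorrelation"] - ux * uy) / (sigx * sigy)
        if sigx > 0 and sigy > 0 else 0.0
    )
    out["glcm_DifferenceAverage"] = da
    out["glcm_DifferenceEntropy"] = _ent(pdiff.values())
    out["glcm_DifferenceVariance"] = sum(p * (k - da) ** 2 for k, p in pdiff.items())
    out["glcm_JointAverage"] = ux
    out["glcm_JointEnergy"] = sum(P[i][j] ** 2 for i in range(ng) for j in range(ng))
    out["glcm_JointEntropy"] = hxy
    # MCC via the Q matrix, second-largest eigenvalue
    if ng == 1:
        out["glcm_MCC"] = 0.0
    else:
        Q = np.zeros((ng, ng))
        for i in range(ng):
            for j in range(ng):
                tot = 0.0
                for k in range(ng):
                    if px[i] > 0 and py[k] > 0:
                        tot += P[i][k] * P[j][k] / (px[i] * py[k])
                Q[i, j] = tot
        eig = sorted(np.real(np.linalg.eigvals(Q)))
        out["glcm_MCC"] = math.sqrt(max(0.0, eig[-2]))
    out["glcm_MaximumProbability"] = max(P[i][j] for i in range(ng) for j in range(ng))
    out["glcm_SumAverage"] = sum(k * p for k, p in psum.items())
    out["glcm_SumEntropy"] = _ent(psum.values())
    out["glcm_SumSquares"] = sum(
        P[i][j] * (levels[i] - ux) ** 2 for i in range(ng) for j in range(ng)
    )
    out["glcm_InverseVariance"] = sum(
        P[i][j] / (levels[i] - levels[j]) ** 2
        for i in range(ng) for j in range(ng) if i != j and levels[i] != levels[j]
    )
    out["glcm_id"] = sum(
        P[i][j] / (1 + abs(levels[i] - levels[j])) for i in range(ng) for j in range(ng)
    )
    out["glcm_idm"] = sum(
        P[i][j] / (1 + (levels[i] - levels[j]) ** 2) for i in range(ng) for j in range(ng)
    )
    out["glcm_idmn"] = sum(
        P[i][j] / (1 + (levels[i] - levels[j]) ** 2 / ng ** 2)
        for i in range(ng) for j in range(ng)
    )
    out["glcm_idn"] = sum(
        P[i][j] / (1 + abs(levels[i] - levels[j]) / ng)
        for i in range(ng) for j in range(ng)
    )
    if ng > 1 and max(hx, hy) > 0:
        out["glcm_imc1"] = (hxy - hxy1) / max(hx, hy)
        out["glcm_imc2"] = (
            math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy)))) if hxy2 >= hxy else 0.0
        )
    else:
        out["glcm_imc1"] = 0.0
        out["glcm_imc2"] = 0.0
    return out


def oracle_run_family(M, levels, n_voxels):
    """Scalar-loop run-length-style formulas (shared shape for glrlm/glszm/gldm)."""
    ng, jmax = M.shape
    nr = M.sum()
    i_of = levels
    vals = {}
    vals["sre"] = sum(M[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(jmax)) / nr
    vals["lre"] = sum(M[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(jmax)) / nr
    vals["gln"] = sum(sum(M[i]) ** 2 for i in range(ng)) / nr
    vals["glnn"] = vals["gln"] / nr
    vals["rln"] = sum(M[:, j].sum() ** 2 for j in range(jmax)) / nr
    vals["rlnn"] = vals["rln"] / nr
    vals["rp"] = nr / n_voxels
    mu_i = sum(M[i][j] / nr * i_of[i] for i in range(ng) for j in range(jmax))
    mu_j = sum(M[i][j] / nr * (j + 1) for i in range(ng) for j in range(jmax))
    vals["glv"] = sum(
        M[i][j] / nr * (i_of[i] - mu_i) ** 2 for i in range(ng) for j in range(jmax)
    )
    vals["rv"] = sum(
        M[i][j] / nr * (j + 1 - mu_j) ** 2 for i in range(ng) for j in range(jmax)
    )
    vals["re"] = _ent(M[i][j] / nr for i in range(ng) for j in range(jmax))
    vals["lgle"] = sum(M[i][j] / i_of[i] ** 2 for i in range(ng) for j in range(jmax)) / nr
    vals["hgle"] = sum(M[i][j] * i_of[i] ** 2 for i in range(ng) for j in range(jmax)) / nr
    vals["slgle"] = sum(
        M[i][j] / (i_of[i] ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(jmax)
    ) / nr
    vals["shgle"] = sum(
        M[i][j] * i_of[i] ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(jmax)
    ) / nr
    vals["llgle"] = sum(
        M[i][j] * (j + 1) ** 2 / i_of[i] ** 2 for i in range(ng) for j in range(jmax)
    ) / nr
    vals["lhgle"] = sum(
        M[i][j] * i_of[i] ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(jmax)
    ) / nr
    return vals


def oracle_ngtdm_features(levels, n, s):
    nvp = sum(n)
    out = {
        "ngtdm_Coarseness": 0.0, "ngtdm_Contrast": 0.0, "ngtdm_Busyness": 0.0,
        "ngtdm_Complexity": 0.0, "ngtdm_Strength": 0.0,
    }
    if nvp == 0:
        out["ngtdm_Coarseness"] = 1e6
        return out
    present = [(g, ni / nvp, si) for g, ni, si in zip(levels, n, s) if ni > 0]
    ngp = len(present)
    dens = sum(p * si for _, p, si in present)
    out["ngtdm_Coarseness"] = 1.0 / dens if dens > 0 else 1e6
    if ngp > 1:
        ssum = sum(si for _, _, si in present)
        out["ngtdm_Contrast"] = (
            sum(
                pi * pj * (gi - gj) ** 2
                for gi, pi, _ in present for gj, pj, _ in present
            ) / (ngp * (ngp - 1)) * (ssum / nvp)
        )
        denom = sum(
            abs(gi * pi - gj * pj) for gi, pi, _ in present for gj, pj, _ in present
        )
        out["ngtdm_Busyness"] = dens / denom if denom > 0 else 0.0
        out["ngtdm_Complexity"] = sum(
            abs(gi - gj) * (pi * si + pj * sj) / (pi + pj)
            for gi, pi, si in present for gj, pj, sj in present
        ) / nvp
        out["ngtdm_Strength"] = (
            sum(
                (pi + pj) * (gi - gj) ** 2
                for gi, pi, _ in present for gj, pj, _ in present
            ) / ssum if ssum > 0 else 0.0
        )
    return out


_GLRLM_KEYS = {
    "sre": "glrlm_ShortRunEmphasis", "lre": "glrlm_LongRunEmphasis",
    "gln": "glrlm_GrayLevelNonUniformity", "glnn": "glrlm_GrayLevelNonUniformityNormalized",
    "rln": "glrlm_rln", "rlnn": "glrlm_RunLengthNonUniformityNormalized",
    "rp": "glrlm_RunPercentage", "glv": "glrlm_GrayLevelVariance",
    "rv": "glrlm_RunVariance", "re": "glrlm_RunEntropy",
    "lgle": "glrlm_LowGrayLevelRunEmphasis", "hgle": "glrlm_HighGrayLevelRunEmphasis",
    "slgle": "glrlm_ShortRunLowGrayLevelEmphasis", "shgle": "glrlm_ShortRunHighGrayLevelEmphasis",
    "llgle": "glrlm_LongRunLowGrayLevelEmphasis", "lhgle": "glrlm_LongRunHighGrayLevelEmphasis",
}
_GLSZM_KEYS = {
    "sre": "glszm_SmallAreaEmphasis", "lre": "glszm_LargeAreaEmphasis",
    "gln": "glszm_GrayLevelNonUniformity", "glnn": "glszm_GrayLevelNonUniformityNormalized",
    "rln": "glszm_SizeZoneNonUniformity", "rlnn": "glszm_SizeZoneNonUniformityNormalized",
    "rp": "glszm_ZonePercentage", "glv": "glszm_GrayLevelVariance",
    "rv": "glszm_ZoneVariance", "re": "glszm_ZoneEntropy",
    "lgle": "glszm_LowGrayLevelZoneEmphasis", "hgle": "glszm_HighGrayLevelZoneEmphasis",
    "slgle": "glszm_SmallAreaLowGrayLevelEmphasis", "shgle": "glszm_SmallAreaHighGrayLevelEmphasis",
    "llgle": "glszm_LargeAreaLowGrayLevelEmphasis", "lhgle": "glszm_LargeAreaHighGrayLevelEmphasis",
}
_GLDM_KEYS = {
    "sre": "gldm_SmallDependenceEmphasis", "lre": "gldm_LargeDependenceEmphasis",
    "gln": "gldm_GrayLevelNonUniformity", "rln": "gldm_dn",
    "rlnn": "gldm_DependenceNonUniformityNormalized", "glv": "gldm_GrayLevelVariance",
    "rv": "gldm_DependenceVariance", "re": "gldm_DependenceEntropy",
    "lgle": "gldm_LowGrayLevelEmphasis", "hgle": "gldm_HighGrayLevelEmphasis",
    "slgle": "gldm_sdlgle", "shgle": "gldm_SmallDependenceHighGrayLevelEmphasis",
    "llgle": "gldm_LargeDependenceLowGrayLevelEmphasis",
    "lhgle": "gldm_LargeDependenceHighGrayLevelEmphasis",
}


def oracle_texture_features(lev, mask):
    """All 75 texture features by explicit enumeration."""
    n_vox = int(mask.sum())
    out = {}
    per_dir = []
    fallback_levels = None
    for d in DIRECTIONS:
        M, levels = oracle_glcm(lev, mask, d)
        fallback_levels = levels
        tot = M.sum()
        if tot > 0:
            per_dir.append(oracle_glcm_features(M / tot, levels))
    if not per_dir:
        ng = len(fallback_levels)
        P = np.ones((1, 1)) if ng == 1 else np.eye(ng) / ng
        per_dir = [oracle_glcm_features(P, fallback_levels)]
    for k in per_dir[0]:
        out[k] = float(np.mean([d[k] for d in per_dir]))

    rl = []
    for d in DIRECTIONS:
        M, levels = oracle_glrlm(lev, mask, d)
        vals = oracle_run_family(M, levels, n_vox)
        rl.append({canon: vals[k] for k, canon in _GLRLM_KEYS.items()})
    for k in rl[0]:
        out[k] = float(np.mean([d[k] for d in rl]))

    M, levels = oracle_glszm(lev, mask)
    vals = oracle_run_family(M, levels, n_vox)
    out.update({canon: vals[k] for k, canon in _GLSZM_KEYS.items()})

    M, levels = oracle_gldm(lev, mask)
    vals = oracle_run_family(M, levels, n_vox)
    out.update({canon: vals[k] for k, canon in _GLDM_KEYS.items()})

    out.update(oracle_ngtdm_features(*oracle_ngtdm(lev, mask)))
    return out


def mann_whitney_exact_permutation(a, b):
    """Two-sided Mann-Whitney p by full enumeration of group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)

    def u_stat(xs, ys):
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in xs for y in ys
        )

    obs = u_stat(a, b)
    mu = na * len(b) / 2.0
    count = total = 0
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, na):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in comb]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total
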