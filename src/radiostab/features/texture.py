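"""Gray-level texture matrices and their features (75 total).

Families: GLCM (24), GLRLM (16), GLSZM (16), GLDM (14), NGTDM (5).
All operate on a discretized volume ``disc`` with integer levels 1..Ng
inside the ROI and 0 outside.  GLCM/GLRLM use the 13 unique 3D directions
at distance 1 and average the per-direction feature values; the other
families use the full 26-neighbourhood and are direction-free.
Matrices are compacted to the gray levels actually present (empty levels
removed), and formulas use the actual level values.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.linalg import svds
from skimage import measure

_EPS = np.spacing(1.0)

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)
NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def unique_direction_offsets() -> list[tuple[int, int, int]]:
    """13 unique 3D direction offsets (one per +/- pair) at distance 1."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) > (0, 0, 0):
                    offsets.append((dx, dy, dz))
    return offsets


def _offset_slices(shape, off):
    src = tuple(slice(max(0, -o), n - max(0, o)) for o, n in zip(off, shape))
    dst = tuple(slice(max(0, o), n - max(0, -o)) for o, n in zip(off, shape))
    return src, dst


# --------------------------------------------------------------------------
# GLCM


def _glcm_matrix(disc: np.ndarray, ng: int, off) -> np.ndarray:
    src, dst = _offset_slices(disc.shape, off)
    a, b = disc[src].ravel(), disc[dst].ravel()
    ok = (a > 0) & (b > 0)
    a, b = a[ok] - 1, b[ok] - 1
    P = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    return P + P.T  # symmetric


def _second_singular_value(B: np.ndarray) -> float:
    g = B.shape[0]
    if g < 2:
        return 1.0
    if g <= 64:
        s = np.linalg.svd(B, compute_uv=False)
    else:
        v0 = np.full(g, 1.0 / np.sqrt(g))  # fixed start vector: deterministic
        s = svds(B, k=2, return_singular_vectors=False, v0=v0)
    s = np.sort(s)[::-1]
    return float(min(s[1], 1.0))


def glcm_features_from_matrix(P: np.ndarray, levels: np.ndarray) -> dict[str, float]:
    """24 Haralick-style features from one symmetric co-occurrence matrix.

    ``levels``: actual gray-level values of the (compacted) rows/columns.
    """
    total = P.sum()
    if total == 0:
        return {k: 0.0 for k in GLCM_NAMES}
    p = P / total
    lv = levels.astype(np.float64)
    g = len(lv)

    px = p.sum(axis=1)
    ux = float(lv @ px)
    sigx = float(np.sqrt(((lv - ux) ** 2) @ px))

    ii = lv[:, None]
    jj = lv[None, :]
    diff = np.abs(ii - jj)
    autoc = float(np.sum(ii * jj * p))

    # distributions over integer sum / difference values
    dsum = np.bincount((ii + jj).astype(np.int64).ravel(), weights=p.ravel())
    dsum = dsum[dsum > 0]
    ddiff_w = np.bincount(diff.astype(np.int64).ravel(), weights=p.ravel())
    kd = np.arange(len(ddiff_w), dtype=np.float64)
    keep = ddiff_w > 0
    kd, ddiff = kd[keep], ddiff_w[keep]

    da = float(kd @ ddiff)
    nz = p > 0
    hxy = float(-np.sum(p[nz] * np.log2(p[nz])))

    pxpy = px[:, None] * px[None, :]
    valid = (p > 0) & (pxpy > 0)
    hxy1 = float(-np.sum(p[valid] * np.log2(pxpy[valid])))
    vv = pxpy > 0
    hxy2 = float(-np.sum(pxpy[vv] * np.log2(pxpy[vv])))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))

    if hx > 0:
        imc1 = (hxy - hxy1) / hx
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    if sigx > 0:
        correlation = (autoc - ux * ux) / (sigx * sigx)
    else:
        correlation = 1.0

    offdiag = diff > 0
    inv_var = float(np.sum(p[offdiag] / (diff[offdiag] ** 2))) if offdiag.any() else 0.0

    B = p / np.sqrt(np.outer(np.maximum(px, _EPS), np.maximum(px, _EPS)))
    mcc = _second_singular_value(B)

    ipj_c = ii + jj - 2.0 * ux
    return {
        "Autocorrelation": autoc,
        "ClusterProminence": float(np.sum(ipj_c**4 * p)),
        "ClusterShade": float(np.sum(ipj_c**3 * p)),
        "ClusterTendency": float(np.sum(ipj_c**2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": float(correlation),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-np.sum(ddiff * np.log2(ddiff))),
        "DifferenceVariance": float(((kd - da) ** 2) @ ddiff),
        "Id": float(np.sum(p / (1.0 + diff))),
        "Idm": float(np.sum(p / (1.0 + diff**2))),
        "Idmn": float(np.sum(p / (1.0 + (diff / g) ** 2))),
        "Idn": float(np.sum(p / (1.0 + diff / g))),
        "Imc1": float(imc1),
        "Imc2": float(imc2),
        "InverseVariance": inv_var,
        "JointAverage": ux,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": 2.0 * ux,
        "SumEntropy": float(-np.sum(dsum * np.log2(dsum))),
        "SumSquares": float(((lv - ux) ** 2) @ px),
    }


def glcm_features(disc: np.ndarray, ng: int) -> dict[str, float]:
    """Per-direction GLCM features averaged over the 13 directions."""
    acc: dict[str, float] = {k: 0.0 for k in GLCM_NAMES}
    offsets = unique_direction_offsets()
    for off in offsets:
        P = _glcm_matrix(disc, ng, off)
        present = P.sum(axis=1) > 0
        fe = glcm_features_from_matrix(
            P[np.ix_(present, present)], np.flatnonzero(present) + 1
        )
        for k, v in fe.items():
            acc[k] += v
    return {k: v / len(offsets) for k, v in acc.items()}


# --------------------------------------------------------------------------
# GLRLM


def _run_lengths(disc: np.ndarray, off) -> tuple[np.ndarray, np.ndarray]:
    """Gray level and length of every maximal run along direction ``off``."""
    mask = disc > 0
    shape = disc.shape
    src, dst = _offset_slices(shape, off)
    same_pair = (disc[src] == disc[dst]) & mask[src] & mask[dst]

    cont = np.zeros(shape, dtype=bool)  # cont[v]: run continues from v to v+off
    cont[src] = same_pair
    continued = np.zeros(shape, dtype=bool)  # continued[v]: v-off chains into v
    continued[dst] = same_pair

    starts = mask & ~continued
    pos = np.argwhere(starts)
    grays = disc[starts]
    lengths = np.ones(len(pos), dtype=np.int64)
    offv = np.asarray(off)
    cur = pos
    alive = cont[tuple(cur.T)]
    while alive.any():
        idx = np.flatnonzero(alive)
        cur = cur.copy()
        cur[idx] += offv
        lengths[idx] += 1
        nxt = np.zeros(len(pos), dtype=bool)
        nxt[idx] = cont[tuple(cur[idx].T)]
        alive = nxt
    return grays, lengths


def _sre_family(P: np.ndarray, lv: np.ndarray, jv: np.ndarray, n_runs: float, prefix: dict):
    """Shared small/large + low/high gray emphasis terms for run/zone/dep
    matrices.  ``prefix`` maps canonical keys to family-specific names."""
    ps = P / n_runs
    gl2 = lv[:, None] ** 2
    jl2 = jv[None, :] ** 2
    out = {}
    out[prefix["small"]] = float(np.sum(P / jl2) / n_runs)
    out[prefix["large"]] = float(np.sum(P * jl2) / n_runs)
    out[prefix["low"]] = float(np.sum(P / gl2) / n_runs)
    out[prefix["high"]] = float(np.sum(P * gl2) / n_runs)
    out[prefix["small_low"]] = float(np.sum(P / (gl2 * jl2)) / n_runs)
    out[prefix["small_high"]] = float(np.sum(P * gl2 / jl2) / n_runs)
    out[prefix["large_low"]] = float(np.sum(P * jl2 / gl2) / n_runs)
    out[prefix["large_high"]] = float(np.sum(P * gl2 * jl2) / n_runs)
    pg = ps.sum(axis=1)
    pj = ps.sum(axis=0)
    mu_g = float(lv @ pg)
    mu_j = float(jv @ pj)
    out[prefix["glv"]] = float(((lv - mu_g) ** 2) @ pg)
    out[prefix["jv_var"]] = float(((jv - mu_j) ** 2) @ pj)
    nzp = ps[ps > 0]
    out[prefix["entropy"]] = float(-np.sum(nzp * np.log2(nzp)))
    out[prefix["gln"]] = float(np.sum(P.sum(axis=1) ** 2) / n_runs)
    out[prefix["glnn"]] = float(np.sum(P.sum(axis=1) ** 2) / n_runs**2)
    out[prefix["jln"]] = float(np.sum(P.sum(axis=0) ** 2) / n_runs)
    out[prefix["jlnn"]] = float(np.sum(P.sum(axis=0) ** 2) / n_runs**2)
    return out


def _compact_matrix(grays, sizes):
    """Dense (levels x sizes) matrix over present values only."""
    ug, gi = np.unique(grays, return_inverse=True)
    us, si = np.unique(sizes, return_inverse=True)
    P = np.zeros((len(ug), len(us)), dtype=np.float64)
    np.add.at(P, (gi, si), 1.0)
    return P, ug.astype(np.float64), us.astype(np.float64)


def glrlm_features(disc: np.ndarray, ng: int) -> dict[str, float]:
    n_vox = float((disc > 0).sum())
    offsets = unique_direction_offsets()
    acc = {k: 0.0 for k in GLRLM_NAMES}
    prefix = {
        "small": "ShortRunEmphasis", "large": "LongRunEmphasis",
        "low": "LowGrayLevelRunEmphasis", "high": "HighGrayLevelRunEmphasis",
        "small_low": "ShortRunLowGrayLevelEmphasis",
        "small_high": "ShortRunHighGrayLevelEmphasis",
        "large_low": "LongRunLowGrayLevelEmphasis",
        "large_high": "LongRunHighGrayLevelEmphasis",
        "glv": "GrayLevelVariance", "jv_var": "RunVariance",
        "entropy": "RunEntropy",
        "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
        "jln": "RunLengthNonUniformity", "jlnn": "RunLengthNonUniformityNormalized",
    }
    for off in offsets:
        grays, lengths = _run_lengths(disc, off)
        P, lv, jv = _compact_matrix(grays, lengths)
        n_runs = float(len(grays))
        fe = _sre_family(P, lv, jv, n_runs, prefix)
        fe["RunPercentage"] = n_runs / n_vox
        for k in GLRLM_NAMES:
            acc[k] += fe[k]
    return {k: v / len(offsets) for k, v in acc.items()}


# --------------------------------------------------------------------------
# GLSZM


def glszm_features(disc: np.ndarray, ng: int) -> dict[str, float]:
    n_vox = float((disc > 0).sum())
    labels = measure.label(disc, background=0, connectivity=3)
    n_zones_total = int(labels.max())
    sizes = np.bincount(labels.ravel())[1:]
    gray_of = np.zeros(n_zones_total + 1, dtype=np.int64)
    gray_of[labels.ravel()] = disc.ravel()
    grays = gray_of[1:]

    P, lv, jv = _compact_matrix(grays, sizes)
    n_zones = float(n_zones_total)
    prefix = {
        "small": "SmallAreaEmphasis", "large": "LargeAreaEmphasis",
        "low": "LowGrayLevelZoneEmphasis", "high": "HighGrayLevelZoneEmphasis",
        "small_low": "SmallAreaLowGrayLevelEmphasis",
        "small_high": "SmallAreaHighGrayLevelEmphasis",
        "large_low": "LargeAreaLowGrayLevelEmphasis",
        "large_high": "LargeAreaHighGrayLevelEmphasis",
        "glv": "GrayLevelVariance", "jv_var": "ZoneVariance",
        "entropy": "ZoneEntropy",
        "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
        "jln": "SizeZoneNonUniformity", "jlnn": "SizeZoneNonUniformityNormalized",
    }
    fe = _sre_family(P, lv, jv, n_zones, prefix)
    fe["ZonePercentage"] = n_zones / n_vox
    return {k: fe[k] for k in GLSZM_NAMES}


# --------------------------------------------------------------------------
# GLDM


def gldm_features(disc: np.ndarray, ng: int, alpha: int = 0) -> dict[str, float]:
    mask = disc > 0
    dep = np.zeros(disc.shape, dtype=np.int64)
    for off in unique_direction_offsets():
        src, dst = _offset_slices(disc.shape, off)
        ok = mask[src] & mask[dst] & (np.abs(disc[src] - disc[dst]) <= alpha)
        dep[src] += ok
        dep[dst] += ok
    d = dep[mask] + 1  # centre voxel counts as part of its own dependence
    g = disc[mask]
    P, lv, jv = _compact_matrix(g, d)
    n = float(mask.sum())
    prefix = {
        "small": "SmallDependenceEmphasis", "large": "LargeDependenceEmphasis",
        "low": "LowGrayLevelEmphasis", "high": "HighGrayLevelEmphasis",
        "small_low": "SmallDependenceLowGrayLevelEmphasis",
        "small_high": "SmallDependenceHighGrayLevelEmphasis",
        "large_low": "LargeDependenceLowGrayLevelEmphasis",
        "large_high": "LargeDependenceHighGrayLevelEmphasis",
        "glv": "GrayLevelVariance", "jv_var": "DependenceVariance",
        "entropy": "DependenceEntropy",
        "gln": "GrayLevelNonUniformity", "glnn": "_unused_glnn",
        "jln": "DependenceNonUniformity", "jlnn": "DependenceNonUniformityNormalized",
    }
    fe = _sre_family(P, lv, jv, n, prefix)
    return {k: fe[k] for k in GLDM_NAMES}


# --------------------------------------------------------------------------
# NGTDM


def ngtdm_features(disc: np.ndarray, ng: int) -> dict[str, float]:
    mask = disc > 0
    nb_sum = np.zeros(disc.shape, dtype=np.float64)
    nb_cnt = np.zeros(disc.shape, dtype=np.int64)
    for off in unique_direction_offsets():
        src, dst = _offset_slices(disc.shape, off)
        ok = mask[src] & mask[dst]
        nb_sum[src] += np.where(ok, disc[dst], 0)
        nb_cnt[src] += ok
        nb_sum[dst] += np.where(ok, disc[src], 0)
        nb_cnt[dst] += ok

    valid = mask & (nb_cnt > 0)
    g = disc[valid].astype(np.float64)
    avg = nb_sum[valid] / nb_cnt[valid]
    n = float(valid.sum())

    lv_all, inv = np.unique(g, return_inverse=True)
    s = np.zeros(len(lv_all))
    np.add.at(s, inv, np.abs(g - avg))
    cnt = np.bincount(inv).astype(np.float64)
    p = cnt / n
    lv = lv_all

    ngp = len(lv)
    sum_ps = float(p @ s)
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6

    if ngp > 1:
        pi = p[:, None]
        pj = p[None, :]
        dij = lv[:, None] - lv[None, :]
        contrast = float(np.sum(pi * pj * dij**2) / (ngp * (ngp - 1))) * float(s.sum() / n)
        denom_busy = float(np.sum(np.abs(lv[:, None] * pi - lv[None, :] * pj)))
        busyness = sum_ps / denom_busy if denom_busy > 0 else 0.0
        complexity = float(
            np.sum(np.abs(dij) * (pi * s[:, None] + pj * s[None, :]) / (pi + pj)) / n
        )
        strength = (
            float(np.sum((pi + pj) * dij**2)) / float(s.sum()) if s.sum() > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
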