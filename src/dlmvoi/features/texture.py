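"""Forced-2D texture families: GLCM, GLRLM, GLSZM, GLDM, NGTDM.

Each family builds one matrix per axial slice (and per in-plane direction
for GLCM/GLRLM) over VOI voxels only, computes every feature on every
matrix, and averages feature values uniformly over the matrices — no
weighting.  Distance to neighbor is fixed at 1, giving each interior voxel
exactly 8 in-plane texture neighbors.

Slices (or slice-direction combinations) that yield no valid matrix are
skipped from the average; if no valid matrix exists at all an
:class:`UndefinedFeatureError` is raised.

Degenerate conventions (documented, deliberately matching the common
reference behavior): GLCM correlation of a zero-variance matrix is 1; MCC
of a single-gray-level matrix is 1; NGTDM coarseness is capped at 1e6 when
its denominator vanishes; NGTDM contrast/busyness/strength fall back to 0
when their denominators vanish.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "UndefinedFeatureError",
    "glcm_features", "glrlm_features", "glszm_features",
    "gldm_features", "ngtdm_features", "gldm_dependence_counts",
    "GLCM_NAMES", "GLRLM_NAMES", "GLSZM_NAMES", "GLDM_NAMES", "NGTDM_NAMES",
]

COARSENESS_CAP = 1e6

# in-plane distance-1 directions (di, dj): 0, 45, 90, 135 degrees
DIRECTIONS_2D = ((0, 1), (1, 1), (1, 0), (1, -1))

_EIGHT = np.ones((3, 3), dtype=int)


class UndefinedFeatureError(ValueError):
    """No valid texture matrix could be built from the VOI."""


def _average(per_matrix: list[dict[str, float]], names) -> dict[str, float]:
    if not per_matrix:
        raise UndefinedFeatureError("no valid texture matrix in VOI")
    return {n: float(np.mean([m[n] for m in per_matrix])) for n in names}


# ---------------------------------------------------------------------------
# GLCM

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)


def _glcm_matrix(lv: np.ndarray, di: int, dj: int, n_bins: int) -> np.ndarray | None:
    """Symmetric normalized co-occurrence matrix for one slice and offset."""
    h, w = lv.shape
    if di >= 0:
        a_i, b_i = slice(0, h - di), slice(di, h)
    else:
        a_i, b_i = slice(-di, h), slice(0, h + di)
    if dj >= 0:
        a_j, b_j = slice(0, w - dj), slice(dj, w)
    else:
        a_j, b_j = slice(-dj, w), slice(0, w + dj)
    a = lv[a_i, a_j]
    b = lv[b_i, b_j]
    valid = (a > 0) & (b > 0)
    if not valid.any():
        return None
    av = a[valid] - 1
    bv = b[valid] - 1
    P = np.zeros((n_bins, n_bins), dtype=np.float64)
    np.add.at(P, (av, bv), 1.0)
    np.add.at(P, (bv, av), 1.0)
    return P / P.sum()


def _glcm_features_one(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    px = P.sum(axis=1)  # == py by symmetry
    mu = float((i * px).sum())
    sig2 = float(((i - mu) ** 2 * px).sum())

    ii = i[:, None]
    jj = i[None, :]
    nz = P > 0

    # sum / difference distributions
    ksum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    kdiff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    for a in range(ng):
        p_sum[a:a + ng] += P[a]
        np.add.at(p_diff, np.abs(np.arange(ng) - a), P[a])

    def ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum()) if p.size else 0.0

    hxy = ent(P[nz])
    pxl = px[px > 0]
    hx = float(-(pxl * np.log2(pxl)).sum())
    outer = px[:, None] * px[None, :]
    with np.errstate(divide="ignore"):
        hxy1 = float(-(P[nz] * np.log2(outer[nz])).sum())
    onz = outer > 0
    hxy2 = float(-(outer[onz] * np.log2(outer[onz])).sum())

    da = float((kdiff * p_diff).sum())

    corr = (float((P * ii * jj).sum()) - mu * mu) / sig2 if sig2 > 0 else 1.0

    # maximal correlation coefficient
    present = px > 0
    if present.sum() <= 1:
        mcc = 1.0
    else:
        Pp = P[np.ix_(present, present)]
        pxp = px[present]
        Q = (Pp / pxp[:, None]) @ (Pp / pxp[None, :]).T
        ev = np.sort(np.abs(np.linalg.eigvals(Q)))[::-1]
        mcc = float(np.sqrt(max(ev[1].real, 0.0))) if ev.size > 1 else 1.0

    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    kpos = kdiff >= 1
    return {
        "Autocorrelation": float((P * ii * jj).sum()),
        "ClusterProminence": float((P * (ii + jj - 2 * mu) ** 4).sum()),
        "ClusterShade": float((P * (ii + jj - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((P * (ii + jj - 2 * mu) ** 2).sum()),
        "Contrast": float((P * (ii - jj) ** 2).sum()),
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((kdiff - da) ** 2 * p_diff).sum()),
        "Id": float((p_diff / (1.0 + kdiff)).sum()),
        "Idm": float((p_diff / (1.0 + kdiff ** 2)).sum()),
        "Idmn": float((p_diff / (1.0 + kdiff ** 2 / ng ** 2)).sum()),
        "Idn": float((p_diff / (1.0 + kdiff / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((p_diff[kpos] / kdiff[kpos] ** 2).sum()),
        "JointAverage": mu,
        "JointEnergy": float((P ** 2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(P.max()),
        "SumAverage": float((ksum * p_sum).sum()),
        "SumEntropy": ent(p_sum),
        "SumSquares": sig2,
    }


def glcm_features(disc) -> dict[str, float]:
    """24 GLCM features averaged over all (slice, direction) matrices."""
    per = []
    for lv in disc.slice_arrays():
        for di, dj in DIRECTIONS_2D:
            P = _glcm_matrix(lv, di, dj, disc.n_bins)
            if P is not None:
                per.append(_glcm_features_one(P))
    return _average(per, GLCM_NAMES)


# ---------------------------------------------------------------------------
# GLRLM

GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)


def _line_runs(line: np.ndarray):
    """(level, length) pairs of maximal constant runs, VOI voxels only."""
    n = line.size
    if n == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    change = np.flatnonzero(np.diff(line) != 0)
    starts = np.r_[0, change + 1]
    ends = np.r_[change, n - 1]
    vals = line[starts]
    keep = vals > 0
    return vals[keep], (ends - starts + 1)[keep]


def _slice_lines(lv: np.ndarray, di: int, dj: int):
    if (di, dj) == (0, 1):
        return list(lv)
    if (di, dj) == (1, 0):
        return list(lv.T)
    if (di, dj) == (1, 1):
        return [np.diagonal(lv, o).copy() for o in range(-lv.shape[0] + 1, lv.shape[1])]
    if (di, dj) == (1, -1):
        f = lv[:, ::-1]
        return [np.diagonal(f, o).copy() for o in range(-f.shape[0] + 1, f.shape[1])]
    raise ValueError(f"unsupported direction {(di, dj)}")


def _glrlm_matrix(lv: np.ndarray, di: int, dj: int, n_bins: int) -> np.ndarray | None:
    levels, lengths = [], []
    for line in _slice_lines(lv, di, dj):
        v, l = _line_runs(np.asarray(line))
        levels.append(v)
        lengths.append(l)
    levels = np.concatenate(levels)
    lengths = np.concatenate(lengths)
    if levels.size == 0:
        return None
    R = np.zeros((n_bins, int(lengths.max())), dtype=np.float64)
    np.add.at(R, (levels - 1, lengths - 1), 1.0)
    return R


def _glrlm_features_one(R: np.ndarray, n_pixels: int) -> dict[str, float]:
    nr = R.sum()
    i = np.arange(1, R.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, R.shape[1] + 1, dtype=np.float64)[None, :]
    p = R / nr
    gsum = R.sum(axis=1)
    rsum = R.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    pe = p[p > 0]
    return {
        "GrayLevelNonUniformity": float((gsum ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((gsum ** 2).sum() / nr ** 2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "HighGrayLevelRunEmphasis": float((R * i ** 2).sum() / nr),
        "LongRunEmphasis": float((R * j ** 2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((R * i ** 2 * j ** 2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((R * j ** 2 / i ** 2).sum() / nr),
        "LowGrayLevelRunEmphasis": float((R / i ** 2).sum() / nr),
        "RunEntropy": float(-(pe * np.log2(pe)).sum()),
        "RunLengthNonUniformity": float((rsum ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((rsum ** 2).sum() / nr ** 2),
        "RunPercentage": float(nr / n_pixels),
        "RunVariance": float((p * (j - mu_j) ** 2).sum()),
        "ShortRunEmphasis": float((R / j ** 2).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((R * i ** 2 / j ** 2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((R / (i ** 2 * j ** 2)).sum() / nr),
    }


def glrlm_features(disc) -> dict[str, float]:
    """16 run-length features averaged over all (slice, direction) matrices."""
    per = []
    for lv in disc.slice_arrays():
        n_pixels = int((lv > 0).sum())
        for d in DIRECTIONS_2D:
            R = _glrlm_matrix(lv, *d, disc.n_bins)
            if R is not None:
                per.append(_glrlm_features_one(R, n_pixels))
    return _average(per, GLRLM_NAMES)


# ---------------------------------------------------------------------------
# GLSZM

GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)


def _glszm_matrix(lv: np.ndarray, n_bins: int) -> np.ndarray | None:
    """Size-zone matrix: 8-connected same-level zones within the slice."""
    zones: list[tuple[int, int]] = []
    for level in np.unique(lv[lv > 0]):
        lab, nlab = ndimage.label(lv == level, structure=_EIGHT)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((int(level), int(s)) for s in sizes)
    if not zones:
        return None
    max_size = max(s for _, s in zones)
    S = np.zeros((n_bins, max_size), dtype=np.float64)
    for level, size in zones:
        S[level - 1, size - 1] += 1.0
    return S


def _glszm_features_one(S: np.ndarray, n_pixels: int) -> dict[str, float]:
    nz = S.sum()
    i = np.arange(1, S.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, S.shape[1] + 1, dtype=np.float64)[None, :]
    p = S / nz
    gsum = S.sum(axis=1)
    ssum = S.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    pe = p[p > 0]
    return {
        "GrayLevelNonUniformity": float((gsum ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((gsum ** 2).sum() / nz ** 2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "HighGrayLevelZoneEmphasis": float((S * i ** 2).sum() / nz),
        "LargeAreaEmphasis": float((S * j ** 2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((S * i ** 2 * j ** 2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((S * j ** 2 / i ** 2).sum() / nz),
        "LowGrayLevelZoneEmphasis": float((S / i ** 2).sum() / nz),
        "SizeZoneNonUniformity": float((ssum ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ssum ** 2).sum() / nz ** 2),
        "SmallAreaEmphasis": float((S / j ** 2).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((S * i ** 2 / j ** 2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((S / (i ** 2 * j ** 2)).sum() / nz),
        "ZoneEntropy": float(-(pe * np.log2(pe)).sum()),
        "ZonePercentage": float(nz / n_pixels),
        "ZoneVariance": float((p * (j - mu_j) ** 2).sum()),
    }


def glszm_features(disc) -> dict[str, float]:
    """16 size-zone features averaged over per-slice matrices."""
    per = []
    for lv in disc.slice_arrays():
        S = _glszm_matrix(lv, disc.n_bins)
        if S is not None:
            per.append(_glszm_features_one(S, int((lv > 0).sum())))
    return _average(per, GLSZM_NAMES)


# ---------------------------------------------------------------------------
# GLDM

GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

_EIGHT_SHIFTS = tuple((di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                      if (di, dj) != (0, 0))


def _neighbor_stack(lv: np.ndarray):
    """For each pixel, shifted neighbor levels (0 where off-slice)."""
    h, w = lv.shape
    pad = np.zeros((h + 2, w + 2), dtype=lv.dtype)
    pad[1:-1, 1:-1] = lv
    return [pad[1 + di:1 + di + h, 1 + dj:1 + dj + w] for di, dj in _EIGHT_SHIFTS]


def gldm_dependence_counts(lv: np.ndarray) -> np.ndarray:
    """Per-pixel count of in-VOI 8-neighbors with the same gray level.

    Defined only at VOI pixels (lv > 0); -1 outside.
    """
    d = np.zeros(lv.shape, dtype=np.int64)
    for nb in _neighbor_stack(lv):
        d += ((nb > 0) & (nb == lv)).astype(np.int64)
    d[lv == 0] = -1
    return d


def _gldm_matrix(lv: np.ndarray, n_bins: int) -> np.ndarray | None:
    """Dependence matrix over (gray level, dependence size).

    Dependence size j = 1 + number of same-level in-VOI 8-neighbors (the
    center voxel always depends on itself), so j ranges 1..9.
    """
    voi = lv > 0
    if not voi.any():
        return None
    d = gldm_dependence_counts(lv)
    D = np.zeros((n_bins, 9), dtype=np.float64)
    np.add.at(D, (lv[voi] - 1, d[voi]), 1.0)
    return D


def _gldm_features_one(D: np.ndarray) -> dict[str, float]:
    nd = D.sum()
    i = np.arange(1, D.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, D.shape[1] + 1, dtype=np.float64)[None, :]
    p = D / nd
    gsum = D.sum(axis=1)
    dsum = D.sum(axis=0)
    mu_j = float((p * j).sum())
    mu_i = float((p * i).sum())
    pe = p[p > 0]
    return {
        "DependenceEntropy": float(-(pe * np.log2(pe)).sum()),
        "DependenceNonUniformity": float((dsum ** 2).sum() / nd),
        "DependenceNonUniformityNormalized": float((dsum ** 2).sum() / nd ** 2),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "GrayLevelNonUniformity": float((gsum ** 2).sum() / nd),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "HighGrayLevelEmphasis": float((D * i ** 2).sum() / nd),
        "LargeDependenceEmphasis": float((D * j ** 2).sum() / nd),
        "LargeDependenceHighGrayLevelEmphasis": float((D * i ** 2 * j ** 2).sum() / nd),
        "LargeDependenceLowGrayLevelEmphasis": float((D * j ** 2 / i ** 2).sum() / nd),
        "LowGrayLevelEmphasis": float((D / i ** 2).sum() / nd),
        "SmallDependenceEmphasis": float((D / j ** 2).sum() / nd),
        "SmallDependenceHighGrayLevelEmphasis": float((D * i ** 2 / j ** 2).sum() / nd),
        "SmallDependenceLowGrayLevelEmphasis": float((D / (i ** 2 * j ** 2)).sum() / nd),
    }


def gldm_features(disc) -> dict[str, float]:
    """14 gray-level dependence features averaged over per-slice matrices."""
    per = []
    for lv in disc.slice_arrays():
        D = _gldm_matrix(lv, disc.n_bins)
        if D is not None:
            per.append(_gldm_features_one(D))
    return _average(per, GLDM_NAMES)


# ---------------------------------------------------------------------------
# NGTDM

NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def _ngtdm_table(lv: np.ndarray, n_bins: int):
    """Per-level voxel counts n_i and summed gray-tone differences s_i.

    Only VOI pixels with at least one in-VOI 8-neighbor participate.
    """
    voi = lv > 0
    nbr_sum = np.zeros(lv.shape, dtype=np.float64)
    nbr_cnt = np.zeros(lv.shape, dtype=np.int64)
    for nb in _neighbor_stack(lv):
        inb = nb > 0
        nbr_sum += np.where(inb, nb, 0)
        nbr_cnt += inb
    valid = voi & (nbr_cnt > 0)
    if not valid.any():
        return None
    A = nbr_sum[valid] / nbr_cnt[valid]
    levels = lv[valid]
    n_i = np.bincount(levels - 1, minlength=n_bins).astype(np.float64)
    s_i = np.bincount(levels - 1, weights=np.abs(levels - A), minlength=n_bins)
    return n_i, s_i


def _ngtdm_features_one(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    N = n_i.sum()
    p = n_i / N
    i = np.arange(1, len(n_i) + 1, dtype=np.float64)
    present = p > 0
    ngp = int(present.sum())
    ps = float((p * s_i).sum())

    coarse = 1.0 / ps if ps > 0 else COARSENESS_CAP
    coarse = min(coarse, COARSENESS_CAP)

    if ngp > 1:
        pi = p[present][:, None]
        pj = p[present][None, :]
        iv = i[present][:, None]
        jv = i[present][None, :]
        contrast = float((pi * pj * (iv - jv) ** 2).sum()) / (ngp * (ngp - 1)) \
            * float(s_i.sum()) / N
        busy_den = float(np.abs(iv * pi - jv * pj).sum())
        busyness = ps / busy_den if busy_den > 0 else 0.0
        si = s_i[present][:, None]
        sj = s_i[present][None, :]
        complexity = float((np.abs(iv - jv) * (pi * si + pj * sj) / (pi + pj)).sum()) / N
        strength_num = float(((pi + pj) * (iv - jv) ** 2).sum())
        ssum = float(s_i.sum())
        strength = strength_num / ssum if ssum > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarse,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


def ngtdm_features(disc) -> dict[str, float]:
    """5 neighboring gray-tone difference features averaged over slices."""
    per = []
    for lv in disc.slice_arrays():
        tab = _ngtdm_table(lv, disc.n_bins)
        if tab is not None:
            per.append(_ngtdm_features_one(*tab))
    return _average(per, NGTDM_NAMES)
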