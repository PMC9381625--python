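"""Independent naive reference implementation of the 93 radiomics features.

Deliberately written as explicit pure-Python loops straight from the
textbook matrix definitions — no shared code with ``dlmvoi.features`` —
so it can serve as the second route in oracle-equivalence tests.  Same
documented degenerate conventions as the package (constant-input skewness
and kurtosis 0, zero-variance GLCM correlation 1, NGTDM coarseness capped
at 1e6).
"""

from __future__ import annotations

import math

import numpy as np

DIRS = ((0, 1), (1, 1), (1, 0), (1, -1))
EIGHT = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


def ref_first_order(values, levels, voxel_volume=1.0):
    x = sorted(float(v) for v in np.asarray(values).ravel())
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    p10, p25, p50, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 50, 75, 90))
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust) if robust else mean
    counts: dict[int, int] = {}
    for l in np.asarray(levels).ravel():
        counts[int(l)] = counts.get(int(l), 0) + 1
    probs = [c / n for c in counts.values()]
    energy = sum(v * v for v in x)
    return {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume,
        "Entropy": -sum(p * math.log2(p) for p in probs if p > 0),
        "Minimum": x[0],
        "Percentile10": p10,
        "Percentile90": p90,
        "Maximum": x[-1],
        "Mean": mean,
        "Median": p50,
        "InterquartileRange": p75 - p25,
        "Range": x[-1] - x[0],
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": (sum(abs(v - rmean) for v in robust) / len(robust)
                                        if robust else 0.0),
        "RootMeanSquared": math.sqrt(sum(v * v for v in x) / n),
        "Skewness": m3 / m2 ** 1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2 ** 2 if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": sum(p * p for p in probs),
    }


def _slices(levels3d):
    out = []
    for k in range(levels3d.shape[2]):
        sl = levels3d[:, :, k]
        if (sl > 0).any():
            out.append(sl)
    return out


def _glcm_matrix(sl, di, dj, ng):
    h, w = sl.shape
    P = [[0.0] * ng for _ in range(ng)]
    total = 0
    for i in range(h):
        for j in range(w):
            a = sl[i, j]
            if a <= 0:
                continue
            ii, jj = i + di, j + dj
            if 0 <= ii < h and 0 <= jj < w and sl[ii, jj] > 0:
                b = sl[ii, jj]
                P[a - 1][b - 1] += 1
                P[b - 1][a - 1] += 1
                total += 2
    if total == 0:
        return None
    return [[v / total for v in row] for row in P]


def _glcm_feats(P):
    ng = len(P)
    px = [sum(P[i]) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    sig2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    p_sum = {}
    p_diff = {}
    for i in range(ng):
        for j in range(ng):
            if P[i][j] > 0 or True:
                p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + P[i][j]
                p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + P[i][j]
    da = sum(k * v for k, v in p_diff.items())
    hxy = -sum(P[i][j] * math.log2(P[i][j]) for i in range(ng) for j in range(ng)
               if P[i][j] > 0)
    hx = -sum(p * math.log2(p) for p in px if p > 0)
    hxy1 = -sum(P[i][j] * math.log2(px[i] * px[j]) for i in range(ng)
                for j in range(ng) if P[i][j] > 0 and px[i] * px[j] > 0)
    hxy2 = -sum(px[i] * px[j] * math.log2(px[i] * px[j]) for i in range(ng)
                for j in range(ng) if px[i] * px[j] > 0)
    autoc = sum(P[i][j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng))
    corr = (autoc - mu * mu) / sig2 if sig2 > 0 else 1.0
    present = [i for i in range(ng) if px[i] > 0]
    if len(present) <= 1:
        mcc = 1.0
    else:
        Q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                Q[a, b] = sum(P[i][k] * P[j][k] / (px[i] * px[k])
                              for k in present)
        ev = sorted(abs(np.linalg.eigvals(Q)), reverse=True)
        mcc = math.sqrt(max(ev[1].real, 0.0))
    return {
        "Autocorrelation": autoc,
        "ClusterProminence": sum(P[i][j] * (i + j + 2 - 2 * mu) ** 4
                                 for i in range(ng) for j in range(ng)),
        "ClusterShade": sum(P[i][j] * (i + j + 2 - 2 * mu) ** 3
                            for i in range(ng) for j in range(ng)),
        "ClusterTendency": sum(P[i][j] * (i + j + 2 - 2 * mu) ** 2
                               for i in range(ng) for j in range(ng)),
        "Contrast": sum(P[i][j] * (i - j) ** 2 for i in range(ng) for j in range(ng)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * math.log2(v) for v in p_diff.values() if v > 0),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in p_diff.items()),
        "Id": sum(v / (1 + k) for k, v in p_diff.items()),
        "Idm": sum(v / (1 + k * k) for k, v in p_diff.items()),
        "Idmn": sum(v / (1 + k * k / ng ** 2) for k, v in p_diff.items()),
        "Idn": sum(v / (1 + k / ng) for k, v in p_diff.items()),
        "Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "InverseVariance": sum(v / (k * k) for k, v in p_diff.items() if k >= 1),
        "JointAverage": mu,
        "JointEnergy": sum(P[i][j] ** 2 for i in range(ng) for j in range(ng)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": max(max(row) for row in P),
        "SumAverage": sum(k * v for k, v in p_sum.items()),
        "SumEntropy": -sum(v * math.log2(v) for v in p_sum.values() if v > 0),
        "SumSquares": sig2,
    }


def ref_glcm(levels3d, ng):
    feats = []
    for sl in _slices(levels3d):
        for di, dj in DIRS:
            P = _glcm_matrix(sl, di, dj, ng)
            if P is not None:
                feats.append(_glcm_feats(P))
    return _avg(feats)


def _avg(feats):
    assert feats, "no valid matrix"
    keys = feats[0].keys()
    return {k: sum(f[k] for f in feats) / len(feats) for k in keys}


def _lines(sl, di, dj):
    h, w = sl.shape
    starts = []
    if (di, dj) == (0, 1):
        starts = [(i, 0) for i in range(h)]
    elif (di, dj) == (1, 0):
        starts = [(0, j) for j in range(w)]
    elif (di, dj) == (1, 1):
        starts = [(i, 0) for i in range(h)] + [(0, j) for j in range(1, w)]
    elif (di, dj) == (1, -1):
        starts = [(i, w - 1) for i in range(h)] + [(0, j) for j in range(w - 1)]
    for i0, j0 in starts:
        line = []
        i, j = i0, j0
        while 0 <= i < h and 0 <= j < w:
            line.append(int(sl[i, j]))
            i, j = i + di, j + dj
        yield line


def ref_glrlm(levels3d, ng):
    feats = []
    for sl in _slices(levels3d):
        n_pix = int((sl > 0).sum())
        for di, dj in DIRS:
            runs: dict[tuple[int, int], int] = {}
            for line in _lines(sl, di, dj):
                pos = 0
                while pos < len(line):
                    if line[pos] == 0:
                        pos += 1
                        continue
                    lvl = line[pos]
                    length = 1
                    while pos + length < len(line) and line[pos + length] == lvl:
                        length += 1
                    runs[(lvl, length)] = runs.get((lvl, length), 0) + 1
                    pos += length
            if runs:
                feats.append(_rlm_szm_feats(runs, n_pix, kind="run"))
    return _avg(feats)


def _rlm_szm_feats(entries: dict, n_pix: int, kind: str):
    nr = sum(entries.values())
    gsum: dict[int, float] = {}
    jsum: dict[int, float] = {}
    for (i, j), c in entries.items():
        gsum[i] = gsum.get(i, 0.0) + c
        jsum[j] = jsum.get(j, 0.0) + c
    mu_i = sum(i * c for (i, j), c in entries.items()) / nr
    mu_j = sum(j * c for (i, j), c in entries.items()) / nr
    ent = -sum((c / nr) * math.log2(c / nr) for c in entries.values())
    f = {
        "GrayLevelNonUniformity": sum(v * v for v in gsum.values()) / nr,
        "GrayLevelNonUniformityNormalized": sum(v * v for v in gsum.values()) / nr ** 2,
        "GrayLevelVariance": sum(c * (i - mu_i) ** 2 for (i, j), c in entries.items()) / nr,
    }
    sre = sum(c / j ** 2 for (i, j), c in entries.items()) / nr
    lre = sum(c * j ** 2 for (i, j), c in entries.items()) / nr
    lgl = sum(c / i ** 2 for (i, j), c in entries.items()) / nr
    hgl = sum(c * i ** 2 for (i, j), c in entries.items()) / nr
    srl = sum(c / (i ** 2 * j ** 2) for (i, j), c in entries.items()) / nr
    srh = sum(c * i ** 2 / j ** 2 for (i, j), c in entries.items()) / nr
    lrl = sum(c * j ** 2 / i ** 2 for (i, j), c in entries.items()) / nr
    lrh = sum(c * i ** 2 * j ** 2 for (i, j), c in entries.items()) / nr
    jvar = sum(c * (j - mu_j) ** 2 for (i, j), c in entries.items()) / nr
    jnu = sum(v * v for v in jsum.values()) / nr
    jnun = sum(v * v for v in jsum.values()) / nr ** 2
    if kind == "run":
        f.update({
            "HighGrayLevelRunEmphasis": hgl, "LongRunEmphasis": lre,
            "LongRunHighGrayLevelEmphasis": lrh, "LongRunLowGrayLevelEmphasis": lrl,
            "LowGrayLevelRunEmphasis": lgl, "RunEntropy": ent,
            "RunLengthNonUniformity": jnu, "RunLengthNonUniformityNormalized": jnun,
            "RunPercentage": nr / n_pix, "RunVariance": jvar,
            "ShortRunEmphasis": sre, "ShortRunHighGrayLevelEmphasis": srh,
            "ShortRunLowGrayLevelEmphasis": srl,
        })
    else:
        f.update({
            "HighGrayLevelZoneEmphasis": hgl, "LargeAreaEmphasis": lre,
            "LargeAreaHighGrayLevelEmphasis": lrh, "LargeAreaLowGrayLevelEmphasis": lrl,
            "LowGrayLevelZoneEmphasis": lgl, "ZoneEntropy": ent,
            "SizeZoneNonUniformity": jnu, "SizeZoneNonUniformityNormalized": jnun,
            "ZonePercentage": nr / n_pix, "ZoneVariance": jvar,
            "SmallAreaEmphasis": sre, "SmallAreaHighGrayLevelEmphasis": srh,
            "SmallAreaLowGrayLevelEmphasis": srl,
        })
    return f


def ref_glszm(levels3d, ng):
    feats = []
    for sl in _slices(levels3d):
        n_pix = int((sl > 0).sum())
        zones: dict[tuple[int, int], int] = {}
        seen = np.zeros(sl.shape, dtype=bool)
        h, w = sl.shape
        for i in range(h):
            for j in range(w):
                if sl[i, j] <= 0 or seen[i, j]:
                    continue
                lvl = sl[i, j]
                stack = [(i, j)]
                seen[i, j] = True
                size = 0
                while stack:
                    a, b = stack.pop()
                    size += 1
                    for di, dj in EIGHT:
                        x, y = a + di, b + dj
                        if 0 <= x < h and 0 <= y < w and not seen[x, y] \
                                and sl[x, y] == lvl:
                            seen[x, y] = True
                            stack.append((x, y))
                zones[(int(lvl), size)] = zones.get((int(lvl), size), 0) + 1
        if zones:
            feats.append(_rlm_szm_feats(zones, n_pix, kind="zone"))
    return _avg(feats)


def ref_gldm(levels3d, ng):
    feats = []
    for sl in _slices(levels3d):
        entries: dict[tuple[int, int], int] = {}
        h, w = sl.shape
        for i in range(h):
            for j in range(w):
                if sl[i, j] <= 0:
                    continue
                d = 0
                for di, dj in EIGHT:
                    x, y = i + di, j + dj
                    if 0 <= x < h and 0 <= y < w and sl[x, y] == sl[i, j]:
                        d += 1
                key = (int(sl[i, j]), d + 1)  # size includes the center voxel
                entries[key] = entries.get(key, 0) + 1
        if entries:
            feats.append(_gldm_feats(entries))
    return _avg(feats)


def _gldm_feats(entries):
    nd = sum(entries.values())
    gsum: dict[int, float] = {}
    dsum: dict[int, float] = {}
    for (i, j), c in entries.items():
        gsum[i] = gsum.get(i, 0.0) + c
        dsum[j] = dsum.get(j, 0.0) + c
    mu_i = sum(i * c for (i, j), c in entries.items()) / nd
    mu_j = sum(j * c for (i, j), c in entries.items()) / nd
    return {
        "DependenceEntropy": -sum((c / nd) * math.log2(c / nd)
                                  for c in entries.values()),
        "DependenceNonUniformity": sum(v * v for v in dsum.values()) / nd,
        "DependenceNonUniformityNormalized": sum(v * v for v in dsum.values()) / nd ** 2,
        "DependenceVariance": sum(c * (j - mu_j) ** 2
                                  for (i, j), c in entries.items()) / nd,
        "GrayLevelNonUniformity": sum(v * v for v in gsum.values()) / nd,
        "GrayLevelVariance": sum(c * (i - mu_i) ** 2
                                 for (i, j), c in entries.items()) / nd,
        "HighGrayLevelEmphasis": sum(c * i ** 2 for (i, j), c in entries.items()) / nd,
        "LargeDependenceEmphasis": sum(c * j ** 2 for (i, j), c in entries.items()) / nd,
        "LargeDependenceHighGrayLevelEmphasis": sum(c * i ** 2 * j ** 2
                                                    for (i, j), c in entries.items()) / nd,
        "LargeDependenceLowGrayLevelEmphasis": sum(c * j ** 2 / i ** 2
                                                   for (i, j), c in entries.items()) / nd,
        "LowGrayLevelEmphasis": sum(c / i ** 2 for (i, j), c in entries.items()) / nd,
        "SmallDependenceEmphasis": sum(c / j ** 2 for (i, j), c in entries.items()) / nd,
        "SmallDependenceHighGrayLevelEmphasis": sum(c * i ** 2 / j ** 2
                                                    for (i, j), c in entries.items()) / nd,
        "SmallDependenceLowGrayLevelEmphasis": sum(c / (i ** 2 * j ** 2)
                                                   for (i, j), c in entries.items()) / nd,
    }


def ref_ngtdm(levels3d, ng):
    feats = []
    for sl in _slices(levels3d):
        h, w = sl.shape
        n_i = [0.0] * (ng + 1)
        s_i = [0.0] * (ng + 1)
        for i in range(h):
            for j in range(w):
                if sl[i, j] <= 0:
                    continue
                nb = [int(sl[i + di, j + dj]) for di, dj in EIGHT
                      if 0 <= i + di < h and 0 <= j + dj < w and sl[i + di, j + dj] > 0]
                if not nb:
                    continue
                lvl = int(sl[i, j])
                n_i[lvl] += 1
                s_i[lvl] += abs(lvl - sum(nb) / len(nb))
        N = sum(n_i)
        if N == 0:
            continue
        p = [c / N for c in n_i]
        present = [i for i in range(1, ng + 1) if p[i] > 0]
        ngp = len(present)
        ps = sum(p[i] * s_i[i] for i in present)
        coarse = min(1.0 / ps if ps > 0 else 1e6, 1e6)
        if ngp > 1:
            contrast = (sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
                        / (ngp * (ngp - 1))) * (sum(s_i) / N)
            busy_den = sum(abs(i * p[i] - j * p[j]) for i in present for j in present)
            busyness = ps / busy_den if busy_den > 0 else 0.0
            complexity = sum(abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
                             for i in present for j in present) / N
            ssum = sum(s_i)
            strength = (sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present)
                        / ssum if ssum > 0 else 0.0)
        else:
            contrast = busyness = complexity = strength = 0.0
        feats.append({"Busyness": busyness, "Coarseness": coarse,
                      "Complexity": complexity, "Contrast": contrast,
                      "Strength": strength})
    return _avg(feats)


def ref_all_features(values3d, voi_mask, bin_width, voxel_volume=1.0):
    """All 93 features from a 3D value array and boolean VOI mask."""
    vals = values3d[voi_mask]
    lo = vals.min()
    levels3d = np.zeros(values3d.shape, dtype=int)
    levels3d[voi_mask] = np.floor((vals - lo) / bin_width).astype(int) + 1
    ng = int(math.floor((vals.max() - lo) / bin_width)) + 1
    out = {}
    for name, v in ref_first_order(vals, levels3d[voi_mask], voxel_volume).items():
        out[f"firstorder_{name}"] = v
    for group, fn in (("glcm", ref_glcm), ("glrlm", ref_glrlm),
                      ("glszm", ref_glszm), ("gldm", ref_gldm),
                      ("ngtdm", ref_ngtdm)):
        for name, v in fn(levels3d, ng).items():
            out[f"{group}_{name}"] = v
    return out
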