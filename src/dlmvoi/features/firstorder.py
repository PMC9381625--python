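"""First-order (intensity-statistics) features on the 3D VOI voxel set.

Entropy and uniformity act on the discretized gray-level histogram; all
other statistics act on the continuous (normalized) intensities.  Moments
are population moments.  Degenerate conventions: a constant VOI has
skewness 0 and kurtosis 0.
"""

from __future__ import annotations

import numpy as np

FIRST_ORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order_features(
    values: np.ndarray,
    levels: np.ndarray,
    voxel_volume_mm3: float = 1.0,
) -> dict[str, float]:
    """18 named first-order features.

    Parameters
    ----------
    values : intensities of the VOI voxels (any order)
    levels : discretized gray level per voxel (1..n_bins), same length
    voxel_volume_mm3 : physical voxel volume; scales TotalEnergy only
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    lv = np.asarray(levels, dtype=np.int64).ravel()
    if x.size == 0:
        raise ValueError("empty VOI")
    if x.size != lv.size:
        raise ValueError("values and levels length mismatch")

    n = x.size
    mean = float(x.mean())
    m2 = float(np.mean((x - mean) ** 2))
    m3 = float(np.mean((x - mean) ** 3))
    m4 = float(np.mean((x - mean) ** 4))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmean = float(robust.mean()) if robust.size else mean

    counts = np.bincount(lv)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())

    energy = float((x ** 2).sum())
    skew = m3 / m2 ** 1.5 if m2 > 0 else 0.0
    kurt = m4 / m2 ** 2 if m2 > 0 else 0.0

    return {
        "Energy": energy,
        "TotalEnergy": energy * float(voxel_volume_mm3),
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - rmean))) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x ** 2))),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": m2,
        "Uniformity": uniformity,
    }
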