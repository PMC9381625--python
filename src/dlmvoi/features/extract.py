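"""Per-lesion feature extraction across bpMRI sequences.

The extraction contract mirrors common radiomics practice for multi-center
data without resampling: whole-image z-normalization (scaled by 100 so a
fixed bin width of 30 yields a few tens of gray levels), fixed-bin-width
discretization within the VOI, first-order statistics on the full 3D VOI
voxel set, and the five texture families in forced-2D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..voi import ImageVolume, VOIMask
from .firstorder import first_order_features, FIRST_ORDER_NAMES
from .texture import (
    UndefinedFeatureError,
    glcm_features, glrlm_features, glszm_features, gldm_features,
    ngtdm_features,
    GLCM_NAMES, GLRLM_NAMES, GLSZM_NAMES, GLDM_NAMES, NGTDM_NAMES,
)

__all__ = [
    "ExtractionParams", "DiscretizedVOI", "DegenerateInputError",
    "UndefinedFeatureError", "znormalize", "discretize_voi", "extract_case",
    "extract_features", "feature_names", "FEATURES_PER_SEQUENCE",
]


class DegenerateInputError(ValueError):
    """Input without enough variation for the requested operation."""


_GROUPS = (
    ("firstorder", FIRST_ORDER_NAMES),
    ("glcm", GLCM_NAMES),
    ("glrlm", GLRLM_NAMES),
    ("glszm", GLSZM_NAMES),
    ("gldm", GLDM_NAMES),
    ("ngtdm", NGTDM_NAMES),
)

FEATURES_PER_SEQUENCE = sum(len(names) for _, names in _GROUPS)  # 93


@dataclass(frozen=True)
class ExtractionParams:
    """Extraction settings; defaults reproduce the reference protocol
    (bin width 30, distance-1 neighbors, forced 2D, no resampling/filters)."""

    bin_width: float = 30.0
    normalize: bool = True
    normalization_scale: float = 100.0
    distance: int = 1
    sequences: tuple[str, ...] = ("T2", "ADC", "DWI")

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.distance != 1:
            raise ValueError("distance to neighbor is fixed at 1")


@dataclass(frozen=True)
class DiscretizedVOI:
    """Gray levels of the VOI voxels, with their slice decomposition.

    ``levels3d`` holds level 0 outside the VOI and 1..n_bins inside;
    ``indices`` are the VOI voxel coordinates (n, 3).
    """

    levels3d: np.ndarray
    n_bins: int
    indices: np.ndarray

    @property
    def levels(self) -> np.ndarray:
        """Per-VOI-voxel levels, in ``indices`` order."""
        return self.levels3d[tuple(self.indices.T)]

    def slice_arrays(self) -> list[np.ndarray]:
        """Cropped 2D level arrays, one per axial slice with VOI voxels."""
        out = []
        ks = np.unique(self.indices[:, 2])
        i0, j0 = self.indices[:, 0].min(), self.indices[:, 1].min()
        i1, j1 = self.indices[:, 0].max() + 1, self.indices[:, 1].max() + 1
        for k in ks:
            lv = self.levels3d[i0:i1, j0:j1, k]
            if (lv > 0).any():
                out.append(np.ascontiguousarray(lv))
        return out


def znormalize(vol: ImageVolume, scale: float = 100.0) -> ImageVolume:
    """Whole-image z-score normalization, multiplied by ``scale``."""
    x = vol.values
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("constant image cannot be z-normalized")
    return ImageVolume(values=(x - x.mean()) / sd * scale, spacing=vol.spacing)


def discretize_voi(vol: ImageVolume, voi: VOIMask, bin_width: float = 30.0) -> DiscretizedVOI:
    """Fixed-bin-width discretization of the VOI voxels.

    ``level(x) = floor((x - min_VOI) / W) + 1``;
    ``n_bins = floor((max_VOI - min_VOI) / W) + 1``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    idx = voi.indices()
    if idx.size == 0:
        raise ValueError("empty VOI")
    vals = vol.values[voi.mask]
    lo = vals.min()
    levels3d = np.zeros(vol.shape, dtype=np.int64)
    levels3d[voi.mask] = np.floor((vals - lo) / bin_width).astype(np.int64) + 1
    n_bins = int(np.floor((vals.max() - lo) / bin_width)) + 1
    return DiscretizedVOI(levels3d=levels3d, n_bins=n_bins, indices=idx)


def feature_names(params: ExtractionParams | None = None) -> list[str]:
    """Stable column order: sequence-major, then group, then feature."""
    params = params or ExtractionParams()
    return [
        f"{seq}_{group}_{name}"
        for seq in params.sequences
        for group, names in _GROUPS
        for name in names
    ]


def extract_features(vol: ImageVolume, voi: VOIMask,
                     params: ExtractionParams | None = None) -> dict[str, float]:
    """93 features for one sequence volume, unprefixed names."""
    params = params or ExtractionParams()
    work = znormalize(vol, params.normalization_scale) if params.normalize else vol
    disc = discretize_voi(work, voi, params.bin_width)
    values = work.values[voi.mask]
    out: dict[str, float] = {}
    for group, names in _GROUPS:
        if group == "firstorder":
            feats = first_order_features(values, disc.levels3d[voi.mask],
                                         vol.voxel_volume_mm3)
        elif group == "glcm":
            feats = glcm_features(disc)
        elif group == "glrlm":
            feats = glrlm_features(disc)
        elif group == "glszm":
            feats = glszm_features(disc)
        elif group == "gldm":
            feats = gldm_features(disc)
        else:
            feats = ngtdm_features(disc)
        for name in names:
            out[f"{group}_{name}"] = feats[name]
    return out


def extract_case(volumes: dict[str, ImageVolume], voi: VOIMask,
                 params: ExtractionParams | None = None) -> dict[str, float]:
    """Concatenated feature vector across sequences for one lesion VOI."""
    params = params or ExtractionParams()
    out: dict[str, float] = {}
    for seq in params.sequences:
        if seq not in volumes:
            raise KeyError(f"sequence {seq!r} missing from case volumes")
        feats = extract_features(volumes[seq], voi, params)
        for name, v in feats.items():
            out[f"{seq}_{name}"] = v
    return out
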