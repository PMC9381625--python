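"""Single-click auto-fixed VOI construction on the ADC map.

The method turns one mouse click inside a prostate lesion into a
reproducible spherical volume of interest (VOI):

1. the click is repositioned to the lowest-ADC voxel in its local 3D
   neighborhood, using an outlier-robust score so a single noisy voxel
   cannot capture the seed;
2. a sphere of fixed physical diameter (mm) is rasterized around the seed,
   honoring anisotropic voxel spacing;
3. the sphere is intersected with the whole-prostate mask, with a quality
   check that the seed voxel itself survives the masking.

Voxel indices are 0-based ``(i, j, k)`` with ``k`` the axial slice; all
physical quantities are in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ImageVolume",
    "ClickPoint",
    "NeighborhoodSpec",
    "VOIMask",
    "QualityControlError",
    "InvalidClickError",
    "default_search_neighborhood",
    "find_seed_voxel",
    "rasterize_sphere",
    "apply_prostate_mask",
    "build_dlm_voi",
    "sweep_diameters",
]


class QualityControlError(RuntimeError):
    """The prostate mask removed the seed voxel — a defective segmentation."""


class InvalidClickError(ValueError):
    """The click has no admissible candidate voxel inside grid and mask."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid with anisotropic voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume contains non-finite values")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing components must be > 0, got {sp}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass(frozen=True)
class ClickPoint:
    """A 0-based voxel index on the ADC grid."""

    index: tuple[int, int, int]

    def __post_init__(self) -> None:
        idx = tuple(int(v) for v in self.index)
        if len(idx) != 3:
            raise ValueError("click index must be (i, j, k)")
        object.__setattr__(self, "index", idx)


@dataclass(frozen=True)
class NeighborhoodSpec:
    """A set of integer voxel offsets, excluding the origin."""

    offsets: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        offs = tuple(tuple(int(v) for v in o) for o in self.offsets)
        if any(o == (0, 0, 0) for o in offs):
            raise ValueError("neighborhood must exclude the origin")
        if len(set(offs)) != len(offs):
            raise ValueError("duplicate offsets")
        object.__setattr__(self, "offsets", offs)

    def __len__(self) -> int:
        return len(self.offsets)

    def __contains__(self, offset: Sequence[int]) -> bool:
        return tuple(int(v) for v in offset) in self.offsets


@dataclass(frozen=True)
class VOIMask:
    """Binary VOI on the reference grid plus its seed voxel and diameter."""

    mask: np.ndarray
    seed_voxel: tuple[int, int, int]
    diameter_mm: float
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        seed = tuple(int(v) for v in self.seed_voxel)
        if m.ndim != 3:
            raise ValueError("VOI mask must be 3D")
        if not m[seed]:
            raise ValueError("seed voxel not set in VOI mask")
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "seed_voxel", seed)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def indices(self) -> np.ndarray:
        """(n, 3) array of set voxel indices."""
        return np.argwhere(self.mask)


def default_search_neighborhood() -> NeighborhoodSpec:
    """The 56-offset search neighborhood around the click.

    All nonzero integer offsets ``v`` with squared Euclidean lattice norm
    ``||v||^2 <= 5`` — the unique small lattice ball with exactly 56
    elements (shells of squared norm 1, 2, 3, 4 and 5 contribute
    6 + 12 + 8 + 6 + 24 offsets).
    """
    offs = []
    for di in range(-2, 3):
        for dj in range(-2, 3):
            for dk in range(-2, 3):
                n2 = di * di + dj * dj + dk * dk
                if 0 < n2 <= 5:
                    offs.append((di, dj, dk))
    return NeighborhoodSpec(tuple(offs))


_FACE_OFFSETS = (
    (1, 0, 0), (-1, 0, 0),
    (0, 1, 0), (0, -1, 0),
    (0, 0, 1), (0, 0, -1),
)


def _cross_mean(adc: np.ndarray, mask: np.ndarray | None, idx: tuple[int, int, int]) -> float:
    """Mean ADC over a voxel and its available in-bounds, in-mask face neighbors.

    A 1-voxel outlier cannot dominate this up-to-7-voxel mean, which is what
    makes the seed repositioning robust.
    """
    shape = adc.shape
    total = adc[idx]
    count = 1
    for d in _FACE_OFFSETS:
        p = (idx[0] + d[0], idx[1] + d[1], idx[2] + d[2])
        if not all(0 <= p[a] < shape[a] for a in range(3)):
            continue
        if mask is not None and not mask[p]:
            continue
        total += adc[p]
        count += 1
    return float(total) / count


def find_seed_voxel(
    adc: ImageVolume,
    click: ClickPoint,
    prostate_mask: np.ndarray | None = None,
    spec: NeighborhoodSpec | None = None,
) -> tuple[int, int, int]:
    """Reposition the click to the locally lowest-ADC voxel.

    Candidates are the click plus its search neighborhood, restricted to the
    grid and (when given) to the prostate mask.  Each candidate is scored by
    the outlier-robust cross-mean of the ADC; the lowest score wins.  Ties
    break by smallest physical distance to the click, then lexicographically
    by ``(k, j, i)`` — so a uniform image returns the click itself.
    """
    if spec is None:
        spec = default_search_neighborhood()
    arr = adc.values
    shape = arr.shape
    ci, cj, ck = click.index
    if not (0 <= ci < shape[0] and 0 <= cj < shape[1] and 0 <= ck < shape[2]):
        raise InvalidClickError(f"click {click.index} outside grid {shape}")
    mask = None
    if prostate_mask is not None:
        mask = np.asarray(prostate_mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError("prostate mask grid does not match ADC grid")

    candidates: list[tuple[int, int, int]] = []
    for d in ((0, 0, 0),) + spec.offsets:
        p = (ci + d[0], cj + d[1], ck + d[2])
        if not all(0 <= p[a] < shape[a] for a in range(3)):
            continue
        if mask is not None and not mask[p]:
            continue
        candidates.append(p)
    if not candidates:
        raise InvalidClickError(
            f"click {click.index} has no candidate voxel inside the prostate mask"
        )

    sx, sy, sz = adc.spacing

    def sort_key(p: tuple[int, int, int]):
        score = _cross_mean(arr, mask, p)
        dist2 = ((p[0] - ci) * sx) ** 2 + ((p[1] - cj) * sy) ** 2 + ((p[2] - ck) * sz) ** 2
        return (score, dist2, p[2], p[1], p[0])

    return min(candidates, key=sort_key)


def rasterize_sphere(
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center: tuple[int, int, int],
    diameter_mm: float,
) -> VOIMask:
    """Rasterize a physical-space sphere of ``diameter_mm`` around ``center``.

    Voxel ``(i, j, k)`` belongs to the sphere iff the Euclidean distance
    between its center and the seed voxel's center is at most the radius,
    using the anisotropic spacing; the sphere is clipped at grid bounds.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter_mm must be > 0")
    ci, cj, ck = (int(v) for v in center)
    shape = tuple(int(v) for v in grid_shape)
    if not all(0 <= c < s for c, s in zip((ci, cj, ck), shape)):
        raise ValueError(f"center {center} outside grid {shape}")
    sx, sy, sz = (float(s) for s in spacing)
    r = diameter_mm / 2.0
    # bounding box in voxel units, then exact distance test on voxel centers
    ni = int(np.floor(r / sx))
    nj = int(np.floor(r / sy))
    nk = int(np.floor(r / sz))
    i = np.arange(max(0, ci - ni), min(shape[0], ci + ni + 1))
    j = np.arange(max(0, cj - nj), min(shape[1], cj + nj + 1))
    k = np.arange(max(0, ck - nk), min(shape[2], ck + nk + 1))
    di = (i - ci)[:, None, None] * sx
    dj = (j - cj)[None, :, None] * sy
    dk = (k - ck)[None, None, :] * sz
    inside = di * di + dj * dj + dk * dk <= r * r
    mask = np.zeros(shape, dtype=bool)
    mask[np.ix_(i, j, k)] = inside
    mask[ci, cj, ck] = True
    return VOIMask(mask=mask, seed_voxel=(ci, cj, ck), diameter_mm=float(diameter_mm),
                   spacing=(sx, sy, sz))


def apply_prostate_mask(voi: VOIMask, prostate_mask: np.ndarray) -> VOIMask:
    """Intersect the VOI with the whole-prostate mask.

    Raises :class:`QualityControlError` if the masking would remove the seed
    voxel: the seed sits inside the lesion and hence inside the prostate, so
    losing it signals a defective prostate segmentation.
    """
    pm = np.asarray(prostate_mask, dtype=bool)
    if pm.shape != voi.mask.shape:
        raise ValueError("prostate mask grid does not match VOI grid")
    if not pm[voi.seed_voxel]:
        raise QualityControlError(
            f"prostate mask excludes the seed voxel {voi.seed_voxel}"
        )
    return VOIMask(mask=voi.mask & pm, seed_voxel=voi.seed_voxel,
                   diameter_mm=voi.diameter_mm, spacing=voi.spacing)


def build_dlm_voi(
    adc: ImageVolume,
    click: ClickPoint,
    prostate_mask: np.ndarray,
    diameter_mm: float,
    spec: NeighborhoodSpec | None = None,
) -> VOIMask:
    """Full click-to-VOI pipeline: seed repositioning, sphere, prostate masking."""
    seed = find_seed_voxel(adc, click, prostate_mask, spec)
    sphere = rasterize_sphere(adc.shape, adc.spacing, seed, diameter_mm)
    return apply_prostate_mask(sphere, prostate_mask)


def sweep_diameters() -> list[float]:
    """The 13 candidate sphere diameters: 6 to 30 mm in 2-mm increments."""
    return [float(d) for d in range(6, 31, 2)]
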