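"""Seeded synthetic bpMRI phantom cohorts.

Generates multi-center biparametric MRI cases — T2-weighted, ADC and
high-b DWI volumes on a shared anisotropic grid — with a gland-shaped
whole-prostate mask, spherical lesions whose low-ADC cores and texture
heterogeneity differ between clinically significant (CS) and non-CS
classes, per-center intensity scale and noise, and a controllable fraction
of gland-edge lesions whose naive sphere would leak outside the prostate.

Everything downstream (VOI construction, feature extraction, selection,
modeling, evaluation) is exercised on these cohorts; no clinical data are
required.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np
from scipy import ndimage

from .voi import ImageVolume

__all__ = ["PhantomConfig", "LesionTruth", "SyntheticCase", "generate_cohort",
           "simulate_click", "cohort_manifest"]

SEQUENCES = ("T2", "ADC", "DWI")


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic cohort.

    ADC-like intensities are in arbitrary units on the scale of
    10^-6 mm^2/s maps; the class ordering CS core < non-CS core < gland is
    enforced because low ADC is the hallmark of clinically significant
    disease.
    """

    n_cases: int = 120
    lesions_min: int = 1
    lesions_max: int = 3
    cs_fraction: float = 0.4
    n_centers: int = 5
    grid_shape: tuple[int, int, int] = (112, 112, 20)
    spacing: tuple[float, float, float] = (0.5, 0.5, 3.0)
    gland_axes_mm: tuple[float, float, float] = (25.0, 20.0, 15.0)
    gland_axes_jitter: float = 0.1
    adc_background: float = 800.0
    adc_gland: float = 1300.0
    adc_noncs_core: float = 950.0
    adc_cs_core: float = 650.0
    lesion_radius_mm: tuple[float, float] = (4.0, 8.0)
    # multiplicative random-field heterogeneity inside lesions:
    # (amplitude, correlation length mm) per class
    texture_noncs: tuple[float, float] = (0.08, 3.0)
    texture_cs: tuple[float, float] = (0.20, 1.2)
    center_scale_range: tuple[float, float] = (0.8, 1.25)
    center_noise_sd_range: tuple[float, float] = (20.0, 60.0)
    edge_lesion_fraction: float = 0.35
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0.0 <= self.cs_fraction <= 1.0:
            raise ValueError("cs_fraction must be in [0, 1]")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")
        if not self.adc_cs_core < self.adc_noncs_core < self.adc_gland:
            raise ValueError("require CS core < non-CS core < gland mean ADC")
        if self.lesions_min < 1 or self.lesions_max < self.lesions_min:
            raise ValueError("invalid lesions per case range")
        half_extent = [0.5 * s * (n - 1) for n, s in zip(self.grid_shape, self.spacing)]
        max_axes = [a * (1 + self.gland_axes_jitter) for a in self.gland_axes_mm]
        if any(a >= h for a, h in zip(max_axes, half_extent)):
            raise ValueError(
                f"grid {self.grid_shape} at spacing {self.spacing} too small for "
                f"gland half-axes {self.gland_axes_mm} mm"
            )


@dataclass(frozen=True)
class LesionTruth:
    """Ground truth for one lesion; ``is_cs`` emulates ISUP grade >= 2."""

    lesion_id: str
    center_voxel: tuple[int, int, int]
    radius_mm: float
    is_cs: bool

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")


@dataclass
class SyntheticCase:
    case_id: str
    center_id: int
    volumes: dict[str, ImageVolume]
    prostate_mask: np.ndarray
    lesions: list[LesionTruth]
    gland_axes_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)


def _physical_coords(shape, spacing):
    """Voxel-center coordinates (mm) relative to the grid center, per axis."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(shape, spacing)
    ]


def _smooth_field(rng: np.random.Generator, shape, spacing, corr_len_mm: float) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    noise = rng.standard_normal(shape)
    sigma = [max(corr_len_mm / s, 1e-6) for s in spacing]
    f = ndimage.gaussian_filter(noise, sigma=sigma, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


# per-sequence tissue levels: background, gland, and lesion-core level per class.
# T2 and DWI carry the same lesion classes but with sequence-appropriate contrast
# (lesions dark on T2 and ADC, bright on high-b DWI).
_SEQ_LEVELS = {
    "T2": dict(background=300.0, gland=500.0, core_noncs=420.0, core_cs=360.0),
    "DWI": dict(background=80.0, gland=120.0, core_noncs=190.0, core_cs=260.0),
}


def generate_cohort(config: PhantomConfig) -> list[SyntheticCase]:
    """Generate a deterministic synthetic cohort from ``config``.

    Returns cases whose lesion cores are depressed on ADC relative to the
    gland according to class levels, with per-center global intensity scale
    and additive Gaussian noise, and with approximately
    ``edge_lesion_fraction`` of lesion centers placed within 5 mm of the
    gland boundary.
    """
    rng = np.random.default_rng(config.seed)
    shape, spacing = config.grid_shape, config.spacing
    coords = _physical_coords(shape, spacing)
    X = coords[0][:, None, None]
    Y = coords[1][None, :, None]
    Z = coords[2][None, None, :]

    centers = []
    for _ in range(config.n_centers):
        centers.append(dict(
            scale=rng.uniform(*config.center_scale_range),
            noise_sd=rng.uniform(*config.center_noise_sd_range),
        ))

    cases: list[SyntheticCase] = []
    for ci in range(config.n_cases):
        center_id = int(rng.integers(config.n_centers))
        eff = centers[center_id]
        jit = 1.0 + config.gland_axes_jitter * rng.uniform(-1, 1, size=3)
        axes = tuple(a * j for a, j in zip(config.gland_axes_mm, jit))
        # axis-aligned ellipsoid gland centered on the grid
        q = (X / axes[0]) ** 2 + (Y / axes[1]) ** 2 + (Z / axes[2]) ** 2
        gland = q <= 1.0

        n_lesions = int(rng.integers(config.lesions_min, config.lesions_max + 1))
        lesions: list[LesionTruth] = []
        adc = np.full(shape, config.adc_background, dtype=np.float64)
        adc[gland] = config.adc_gland
        seq_vols = {}
        for s, lv in _SEQ_LEVELS.items():
            v = np.full(shape, lv["background"], dtype=np.float64)
            v[gland] = lv["gland"]
            seq_vols[s] = v

        for li in range(n_lesions):
            is_cs = bool(rng.random() < config.cs_fraction)
            radius = float(rng.uniform(*config.lesion_radius_mm))
            edge = bool(rng.random() < config.edge_lesion_fraction)
            center_vox = _place_lesion(rng, q, gland, axes, coords, edge)
            lesions.append(LesionTruth(
                lesion_id=f"case{ci:03d}_les{li}",
                center_voxel=center_vox,
                radius_mm=radius,
                is_cs=is_cs,
            ))
            amp, corr = config.texture_cs if is_cs else config.texture_noncs
            cx = coords[0][center_vox[0]]
            cy = coords[1][center_vox[1]]
            cz = coords[2][center_vox[2]]
            d2 = ((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) / radius ** 2
            inside = d2 <= 1.0
            # radial blend toward the core level, strongest at the center
            w = np.clip(1.0 - d2, 0.0, 1.0)
            field_ = 1.0 + amp * _smooth_field(rng, shape, spacing, corr)
            core = config.adc_cs_core if is_cs else config.adc_noncs_core
            adc = np.where(inside, (adc + w * (core - adc)) * field_, adc)
            for s, lv in _SEQ_LEVELS.items():
                score = lv["core_cs"] if is_cs else lv["core_noncs"]
                v = seq_vols[s]
                seq_vols[s] = np.where(inside, (v + w * (score - v)) * field_, v)

        volumes = {}
        for name, base in (("T2", seq_vols["T2"]), ("ADC", adc), ("DWI", seq_vols["DWI"])):
            noisy = base * eff["scale"] + rng.normal(
                0.0, eff["noise_sd"] * (1.0 if name == "ADC" else 0.3), size=shape)
            volumes[name] = ImageVolume(values=noisy, spacing=spacing)

        cases.append(SyntheticCase(
            case_id=f"case{ci:03d}",
            center_id=center_id,
            volumes=volumes,
            prostate_mask=gland,
            lesions=lesions,
            gland_axes_mm=axes,
        ))
    return cases


def _place_lesion(rng, q, gland, axes, coords, edge: bool) -> tuple[int, int, int]:
    """Pick a lesion center voxel inside the gland.

    Edge lesions land in the shell within ~5 mm of the gland boundary (so an
    18-mm sphere leaks outside); interior lesions in the deeper core.
    """
    mean_axis = float(np.mean(axes))
    # normalized ellipsoidal radius sqrt(q); 5 mm shell in units of mean axis
    shell = 5.0 / mean_axis
    r = np.sqrt(q)
    if edge:
        region = (r <= 1.0) & (r >= max(0.0, 1.0 - shell))
    else:
        region = r <= max(0.1, 1.0 - shell)
    region &= gland
    idx = np.argwhere(region)
    if len(idx) == 0:
        idx = np.argwhere(gland)
    pick = idx[rng.integers(len(idx))]
    return tuple(int(v) for v in pick)


def _lesion_sphere_mask(case: SyntheticCase, lesion: LesionTruth) -> np.ndarray:
    shape = case.prostate_mask.shape
    spacing = case.volumes["ADC"].spacing
    coords = _physical_coords(shape, spacing)
    cx = coords[0][lesion.center_voxel[0]]
    cy = coords[1][lesion.center_voxel[1]]
    cz = coords[2][lesion.center_voxel[2]]
    d2 = ((coords[0][:, None, None] - cx) ** 2
          + (coords[1][None, :, None] - cy) ** 2
          + (coords[2][None, None, :] - cz) ** 2)
    return d2 <= lesion.radius_mm ** 2


def simulate_click(
    case: SyntheticCase,
    lesion: LesionTruth,
    jitter_voxels: int = 2,
    seed: int = 0,
) -> tuple[int, int, int]:
    """Emulate a radiologist's click near the lesion's visually lowest ADC.

    Finds the true in-lesion, in-prostate ADC-argmin voxel and jitters it
    uniformly within a Chebyshev radius of ``jitter_voxels``, staying inside
    both the lesion sphere and the prostate mask.
    """
    if lesion not in case.lesions:
        raise ValueError("lesion does not belong to case")
    adc = case.volumes["ADC"].values
    allowed = _lesion_sphere_mask(case, lesion) & case.prostate_mask
    if not allowed.any():
        allowed = case.prostate_mask
    masked = np.where(allowed, adc, np.inf)
    argmin = np.unravel_index(int(np.argmin(masked)), adc.shape)
    if jitter_voxels == 0:
        return tuple(int(v) for v in argmin)
    rng = np.random.default_rng(seed)
    cands = np.argwhere(allowed)
    cheb = np.max(np.abs(cands - np.asarray(argmin)), axis=1)
    cands = cands[cheb <= jitter_voxels]
    pick = cands[rng.integers(len(cands))]
    return tuple(int(v) for v in pick)


def cohort_manifest(cases: list[SyntheticCase], clicks: dict[str, tuple[int, int, int]] | None = None) -> dict:
    """JSON-serializable manifest of case ids, centers, lesions, clicks, labels."""
    out = {"cases": []}
    for c in cases:
        rec = {
            "case_id": c.case_id,
            "center_id": c.center_id,
            "lesions": [],
        }
        for l in c.lesions:
            lrec = {
                "lesion_id": l.lesion_id,
                "center_voxel": list(l.center_voxel),
                "radius_mm": l.radius_mm,
                "is_cs": l.is_cs,
            }
            if clicks and l.lesion_id in clicks:
                lrec["click"] = list(clicks[l.lesion_id])
            rec["lesions"].append(lrec)
        out["cases"].append(rec)
    return out
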