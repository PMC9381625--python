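"""Seed repositioning, sphere rasterization and prostate masking."""

import numpy as np
import pytest

from dlmvoi.voi import (
    ClickPoint, ImageVolume, InvalidClickError, QualityControlError,
    apply_prostate_mask, build_dlm_voi, default_search_neighborhood,
    find_seed_voxel, rasterize_sphere, sweep_diameters,
)


class TestSearchNeighborhood:
    def test_has_exactly_56_offsets(self):
        assert len(default_search_neighborhood()) == 56

    def test_matches_lattice_ball_norm_le_5(self):
        spec = default_search_neighborhood()
        brute = {
            (di, dj, dk)
            for di in range(-3, 4) for dj in range(-3, 4) for dk in range(-3, 4)
            if 0 < di * di + dj * dj + dk * dk <= 5
        }
        assert set(spec.offsets) == brute
        assert (1, 0, 0) in spec
        assert (2, 1, 0) in spec
        assert (2, 2, 0) not in spec  # squared norm 8

    def test_closed_under_negation(self):
        spec = default_search_neighborhood()
        for v in spec.offsets:
            assert tuple(-x for x in v) in spec


def _cross_mean_brute(adc, mask, p):
    """Independent cross-mean: voxel + in-bounds in-mask face neighbors."""
    vals = [adc[p]]
    for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
        if all(0 <= q[a] < adc.shape[a] for a in range(3)):
            if mask is None or mask[q]:
                vals.append(adc[q])
    return sum(vals) / len(vals)


class TestFindSeedVoxel:
    def test_uniform_volume_returns_click(self):
        vol = ImageVolume(np.full((9, 9, 5), 1000.0), (0.5, 0.5, 3.0))
        assert find_seed_voxel(vol, ClickPoint((4, 4, 2))) == (4, 4, 2)

    def test_single_voxel_outlier_is_rejected(self):
        """A lone 100-ADC voxel must lose to a coherent 600-ADC block."""
        arr = np.full((9, 9, 5), 1000.0)
        arr[6, 5, 2] = 100.0           # isolated outlier at offset (2, 1, 0)
        arr[2:4, 4:6, 2:4] = 600.0     # 2x2x2 block starting at offset (-2, 0, 0)
        vol = ImageVolume(arr, (0.5, 0.5, 3.0))
        seed = find_seed_voxel(vol, ClickPoint((4, 4, 2)))
        assert arr[seed] == 600.0

    def test_agrees_with_brute_force_scoring(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            arr = rng.uniform(500, 1500, size=(11, 11, 7))
            mask = rng.random((11, 11, 7)) < 0.8
            click = (5, 5, 3)
            mask[click] = True
            vol = ImageVolume(arr, (0.5, 0.5, 3.0))
            seed = find_seed_voxel(vol, ClickPoint(click), mask)
            # brute-force: score all 57 candidates, pick min with same tie-break
            spec = default_search_neighborhood()
            best = None
            for d in ((0, 0, 0),) + spec.offsets:
                p = tuple(np.add(click, d))
                if not all(0 <= p[a] < 11 if a < 2 else 0 <= p[a] < 7 for a in range(3)):
                    continue
                if not mask[p]:
                    continue
                s = _cross_mean_brute(arr, mask, p)
                d2 = ((p[0] - 5) * 0.5) ** 2 + ((p[1] - 5) * 0.5) ** 2 + ((p[2] - 3) * 3.0) ** 2
                key = (s, d2, p[2], p[1], p[0])
                if best is None or key < best[0]:
                    best = (key, p)
            assert seed == best[1]

    def test_result_stays_inside_mask(self):
        arr = np.full((9, 9, 5), 1000.0)
        arr[:4] = 100.0  # lower ADC outside the mask
        mask = np.zeros((9, 9, 5), dtype=bool)
        mask[4:] = True
        vol = ImageVolume(arr, (0.5, 0.5, 3.0))
        seed = find_seed_voxel(vol, ClickPoint((4, 4, 2)), mask)
        assert mask[seed]

    def test_click_outside_mask_without_neighbors_raises(self):
        vol = ImageVolume(np.ones((9, 9, 5)), (0.5, 0.5, 3.0))
        mask = np.zeros((9, 9, 5), dtype=bool)
        with pytest.raises(InvalidClickError):
            find_seed_voxel(vol, ClickPoint((4, 4, 2)), mask)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(11)
        arr = rng.uniform(500, 1500, size=(14, 14, 9))
        vol = ImageVolume(arr, (0.5, 0.5, 3.0))
        seed = find_seed_voxel(vol, ClickPoint((5, 5, 3)))
        shifted = np.roll(arr, (2, 1, 1), axis=(0, 1, 2))
        # restrict to interior so the roll wrap does not enter the window
        seed2 = find_seed_voxel(ImageVolume(shifted, (0.5, 0.5, 3.0)),
                                ClickPoint((7, 6, 4)))
        assert seed2 == (seed[0] + 2, seed[1] + 1, seed[2] + 1)


class TestRasterizeSphere:
    def test_tiny_diameter_is_single_voxel(self):
        voi = rasterize_sphere((9, 9, 5), (0.5, 0.5, 3.0), (4, 4, 2), 0.4)
        assert voi.voxel_count == 1
        assert voi.mask[4, 4, 2]

    def test_count_matches_exhaustive_enumeration(self):
        voi = rasterize_sphere((61, 61, 21), (0.5, 0.5, 3.0), (30, 30, 10), 18.0)
        count = 0
        for i in range(61):
            for j in range(61):
                for k in range(21):
                    d2 = (0.25 * (i - 30) ** 2 + 0.25 * (j - 30) ** 2
                          + 9.0 * (k - 10) ** 2)
                    count += d2 <= 81.0
        assert voi.voxel_count == count

    def test_flip_symmetry(self):
        voi = rasterize_sphere((41, 41, 15), (0.7, 0.5, 2.0), (20, 20, 7), 14.0)
        m = voi.mask
        assert np.array_equal(m, m[::-1])
        assert np.array_equal(m, m[:, ::-1])
        assert np.array_equal(m, m[:, :, ::-1])

    def test_volume_converges_to_analytic_sphere(self):
        """Voxel count x voxel volume -> (pi/6) d^3 on a fine isotropic grid."""
        d = 18.0
        voi = rasterize_sphere((81, 81, 81), (0.25, 0.25, 0.25), (40, 40, 40), d)
        vol = voi.voxel_count * 0.25 ** 3
        analytic = np.pi / 6 * d ** 3
        assert abs(vol - analytic) / analytic < 0.02

    def test_count_monotone_in_diameter(self):
        counts = [
            rasterize_sphere((61, 61, 21), (0.5, 0.5, 3.0), (30, 30, 10), d).voxel_count
            for d in sweep_diameters()
        ]
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestApplyProstateMask:
    def test_full_mask_is_identity(self):
        voi = rasterize_sphere((31, 31, 11), (0.5, 0.5, 3.0), (15, 15, 5), 12.0)
        out = apply_prostate_mask(voi, np.ones((31, 31, 11), dtype=bool))
        assert np.array_equal(out.mask, voi.mask)

    def test_half_space_mask_count_matches_brute_force(self):
        voi = rasterize_sphere((41, 41, 15), (0.5, 0.5, 3.0), (20, 20, 7), 18.0)
        half = np.zeros((41, 41, 15), dtype=bool)
        half[:21] = True  # seed at i=20 is included
        out = apply_prostate_mask(voi, half)
        expected = int((voi.mask & half).sum())
        assert out.voxel_count == expected
        assert out.mask[out.seed_voxel]

    def test_mask_removing_seed_raises_quality_error(self):
        voi = rasterize_sphere((31, 31, 11), (0.5, 0.5, 3.0), (15, 15, 5), 12.0)
        bad = np.ones((31, 31, 11), dtype=bool)
        bad[15, 15, 5] = False
        with pytest.raises(QualityControlError):
            apply_prostate_mask(voi, bad)


class TestBuildDlmVoi:
    def test_edge_lesion_voi_stays_inside_prostate(self, small_cohort):
        _, cases, clicks = small_cohort
        checked = 0
        for case in cases:
            for lesion in case.lesions:
                voi = build_dlm_voi(case.volumes["ADC"],
                                    ClickPoint(clicks[lesion.lesion_id]),
                                    case.prostate_mask, 18.0)
                assert not (voi.mask & ~case.prostate_mask).any()
                assert voi.mask[voi.seed_voxel]
                checked += 1
        assert checked > 0

    def test_interior_lesion_equals_unmasked_sphere(self):
        arr = np.full((41, 41, 15), 1000.0)
        arr[20, 20, 7] = 100.0
        vol = ImageVolume(arr, (0.5, 0.5, 3.0))
        mask = np.ones((41, 41, 15), dtype=bool)
        voi = build_dlm_voi(vol, ClickPoint((20, 20, 7)), mask, 10.0)
        sphere = rasterize_sphere((41, 41, 15), (0.5, 0.5, 3.0), (20, 20, 7), 10.0)
        assert np.array_equal(voi.mask, sphere.mask)


class TestSweepDiameters:
    def test_thirteen_diameters_six_to_thirty_step_two(self):
        d = sweep_diameters()
        assert len(d) == 13
        assert d[0] == 6.0 and d[-1] == 30.0
        assert all(b - a == 2.0 for a, b in zip(d, d[1:]))
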