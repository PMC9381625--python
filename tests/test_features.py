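"""Feature extraction: normalization, discretization, per-family hand
checks, and oracle equivalence against the naive reference implementation."""

import numpy as np
import pytest

from dlmvoi.features import (
    ExtractionParams, DegenerateInputError, UndefinedFeatureError,
    discretize_voi, extract_case, extract_features, feature_names,
    first_order_features, glcm_features, glrlm_features, glszm_features,
    gldm_features, ngtdm_features, gldm_dependence_counts, znormalize,
    FEATURES_PER_SEQUENCE,
)
from dlmvoi.features.extract import DiscretizedVOI
from dlmvoi.voi import ImageVolume, VOIMask

from reference_features import ref_all_features


def _voi_from_mask(mask):
    seed = tuple(np.argwhere(mask)[0])
    return VOIMask(mask=mask, seed_voxel=seed, diameter_mm=1.0)


def _disc_from_slices(slices):
    """Build a DiscretizedVOI directly from 2D level arrays (one per slice)."""
    arr = np.stack(slices, axis=-1).astype(np.int64)
    idx = np.argwhere(arr > 0)
    return DiscretizedVOI(levels3d=arr, n_bins=int(arr.max()), indices=idx)


class TestZnormalize:
    def test_mean_zero_sd_scale(self):
        rng = np.random.default_rng(0)
        vol = ImageVolume(rng.uniform(0, 500, (20, 20, 6)), (0.5, 0.5, 3.0))
        out = znormalize(vol, scale=100.0)
        assert abs(out.values.mean()) < 1e-6 * 100
        assert abs(out.values.std() - 100.0) < 1e-6 * 100

    def test_idempotent_at_scale_one(self):
        rng = np.random.default_rng(1)
        vol = ImageVolume(rng.standard_normal((10, 10, 4)), (1, 1, 1))
        once = znormalize(vol, scale=1.0)
        twice = znormalize(once, scale=1.0)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_two_value_image(self):
        arr = np.zeros((4, 4, 2))
        arr[:2] = 10.0  # half zeros, half tens
        out = znormalize(ImageVolume(arr, (1, 1, 1)), scale=100.0)
        assert np.allclose(np.unique(out.values), [-100.0, 100.0])

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            znormalize(ImageVolume(np.ones((4, 4, 2)), (1, 1, 1)))


class TestDiscretize:
    def test_formula_example(self):
        arr = np.zeros((4, 1, 1))
        arr[:, 0, 0] = [0.0, 29.9, 30.0, 95.0]
        mask = np.ones((4, 1, 1), dtype=bool)
        disc = discretize_voi(ImageVolume(arr, (1, 1, 1)), _voi_from_mask(mask), 30.0)
        assert list(disc.levels) == [1, 1, 2, 4]
        assert disc.n_bins == 4

    def test_constant_voi_single_bin(self):
        arr = np.full((3, 3, 1), 7.0)
        mask = np.ones((3, 3, 1), dtype=bool)
        disc = discretize_voi(ImageVolume(arr, (1, 1, 1)), _voi_from_mask(mask), 30.0)
        assert disc.n_bins == 1
        assert set(disc.levels) == {1}

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        arr = rng.uniform(0, 300, (5, 5, 3))
        mask = rng.random((5, 5, 3)) < 0.7
        mask[0, 0, 0] = True
        vol = ImageVolume(arr, (1, 1, 1))
        voi = _voi_from_mask(mask)
        a = discretize_voi(vol, voi, 30.0)
        b = discretize_voi(ImageVolume(arr + 30.0, (1, 1, 1)), voi, 30.0)
        assert np.array_equal(a.levels, b.levels)
        assert a.n_bins == b.n_bins


class TestFirstOrder:
    def test_uniform_histogram_entropy(self):
        f = first_order_features(np.array([0., 40., 70., 100.]),
                                 np.array([1, 2, 3, 4]))
        assert f["Entropy"] == pytest.approx(2.0)
        assert f["Uniformity"] == pytest.approx(0.25)

    def test_hand_computed_moments(self):
        f = first_order_features(np.array([1., 2., 3., 4.]),
                                 np.array([1, 1, 2, 2]))
        assert f["Mean"] == pytest.approx(2.5)
        assert f["Variance"] == pytest.approx(1.25)
        assert f["Range"] == pytest.approx(3.0)

    def test_constant_conventions(self):
        f = first_order_features(np.full(5, 3.0), np.ones(5, dtype=int))
        assert f["Entropy"] == 0.0
        assert f["Variance"] == 0.0
        assert f["Skewness"] == 0.0
        assert f["Kurtosis"] == 0.0


class TestTextureHandChecks:
    def test_glcm_2x2_matches_pair_enumeration(self):
        disc = _disc_from_slices([np.array([[1, 1], [2, 2]])])
        f = glcm_features(disc)
        # direction (0,1): pairs (1,1) and (2,2) -> perfectly diagonal GLCM
        # direction (1,0): pairs (1,2) twice -> contrast 1 for that matrix
        # diagonals: one (1,2) pair each -> contrast 1
        # uniform average over 4 matrices: contrast = (0 + 1 + 1 + 1) / 4
        assert f["Contrast"] == pytest.approx(0.75)
        assert f["JointAverage"] == pytest.approx(1.5)

    def test_checkerboard_glcm_contrast(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 + 1
        disc = _disc_from_slices([board])
        f = glcm_features(disc)
        # 0/90 degrees always cross levels; diagonals never do
        assert f["MaximumProbability"] <= 1.0
        assert f["Contrast"] > 0

    def test_single_level_slice_conventions(self):
        disc = _disc_from_slices([np.ones((3, 3), dtype=int)])
        f = glcm_features(disc)
        assert f["Contrast"] == 0.0
        assert f["Correlation"] == 1.0

    def test_glrlm_single_run(self):
        disc = _disc_from_slices([np.array([[1, 1, 1, 1]])])
        f = glrlm_features(disc)
        # direction (0,1): one run of length 4; other directions: 4 runs of 1
        # RunPercentage average: (1/4 + 1 + 1 + 1) / 4
        assert f["RunPercentage"] == pytest.approx((0.25 + 3.0) / 4)
        assert f["LongRunEmphasis"] == pytest.approx((16.0 + 3.0) / 4)

    def test_glszm_two_zones(self):
        sl = np.array([
            [1, 1, 0],
            [0, 1, 0],
            [0, 0, 2],
        ])
        disc = _disc_from_slices([sl])
        f = glszm_features(disc)
        # zones: level-1 of size 3, level-2 of size 1 -> 2 zones over 4 pixels
        assert f["ZonePercentage"] == pytest.approx(0.5)
        assert f["LargeAreaEmphasis"] == pytest.approx((9 + 1) / 2)

    def test_gldm_uniform_dependence_counts(self):
        sl = np.ones((3, 3), dtype=int)
        d = gldm_dependence_counts(sl)
        assert d[1, 1] == 8
        assert d[0, 0] == 3
        assert d[0, 1] == 5

    def test_ngtdm_uniform_slice(self):
        disc = _disc_from_slices([np.ones((3, 3), dtype=int)])
        f = ngtdm_features(disc)
        assert f["Coarseness"] == pytest.approx(1e6)  # degenerate cap
        assert f["Contrast"] == 0.0

    def test_rotation_invariance_of_direction_average(self):
        rng = np.random.default_rng(4)
        sl = rng.integers(1, 5, size=(6, 6))
        a = glcm_features(_disc_from_slices([sl]))
        b = glcm_features(_disc_from_slices([np.rot90(sl).copy()]))
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9), k

    def test_all_singleton_slices_raise(self):
        sl = np.zeros((3, 3), dtype=int)
        sl[1, 1] = 1
        with pytest.raises(UndefinedFeatureError):
            glcm_features(_disc_from_slices([sl]))


@pytest.mark.parametrize("trial", range(25))
def test_oracle_equivalence_on_random_small_vois(trial):
    """Every implemented feature matches the independent naive reference
    to 1e-6 relative on a random small VOI."""
    rng = np.random.default_rng(100 + trial)
    shape = (int(rng.integers(5, 9)), int(rng.integers(5, 9)), int(rng.integers(2, 4)))
    spacing = (0.5, 0.5, 3.0)
    values = rng.uniform(0, 300, size=shape)
    mask = rng.random(shape) < 0.75
    # every used slice needs at least one in-plane pair for a valid GLCM
    for k in range(shape[2]):
        mask[0, 0, k] = True
        mask[0, 1, k] = True
    vol = ImageVolume(values, spacing)
    voi = _voi_from_mask(mask)
    params = ExtractionParams(bin_width=40.0, normalize=False)
    got = extract_features(vol, voi, params)
    expected = ref_all_features(values, mask, bin_width=40.0,
                                voxel_volume=np.prod(spacing))
    assert set(got) == set(expected)
    for name, ref in expected.items():
        assert got[name] == pytest.approx(ref, rel=1e-6, abs=1e-9), name


class TestExtractCase:
    def test_vector_length_and_order(self, small_cohort):
        assert FEATURES_PER_SEQUENCE == 93
        names = feature_names()
        assert len(names) == 279
        assert names[0].startswith("T2_firstorder_")
        assert names[-1].startswith("DWI_ngtdm_")

    def test_deterministic_and_shift_invariant(self):
        rng = np.random.default_rng(9)
        shape = (12, 12, 4)
        vols = {s: ImageVolume(rng.uniform(0, 400, shape), (0.5, 0.5, 3.0))
                for s in ("T2", "ADC", "DWI")}
        mask = np.zeros(shape, dtype=bool)
        mask[3:9, 3:9, 1:3] = True
        voi = _voi_from_mask(mask)
        a = extract_case(vols, voi)
        b = extract_case(vols, voi)
        assert a == b
        # shifting one sequence's intensities changes nothing (z-norm + binning)
        vols2 = dict(vols)
        vols2["ADC"] = ImageVolume(vols["ADC"].values + 123.0, (0.5, 0.5, 3.0))
        c = extract_case(vols2, voi)
        for k in a:
            assert a[k] == pytest.approx(c[k], rel=1e-9, abs=1e-9)

    def test_missing_sequence_rejected(self):
        shape = (6, 6, 2)
        vols = {"T2": ImageVolume(np.random.default_rng(0).uniform(0, 1, shape),
                                  (1, 1, 1))}
        mask = np.ones(shape, dtype=bool)
        with pytest.raises(KeyError):
            extract_case(vols, _voi_from_mask(mask))


def test_interior_voxel_has_eight_texture_neighbors():
    """Distance-1 forced-2D means each interior voxel sees exactly 8 neighbors."""
    sl = np.ones((5, 5), dtype=int)
    d = gldm_dependence_counts(sl)
    assert d[2, 2] == 8
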