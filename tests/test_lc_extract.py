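import numpy as np
import pytest
from scipy.stats import t as t_dist

from lcmap import (BinaryMask, ExtractionConfig, VolumeGrid, dilate_mask_mm,
                   enhancement_contrast, extract_lc, line_profile, measure_lc)
from lcmap.enhancement import EnhancementMap
from lcmap.errors import ConfigurationError, MaskOverlapError
from lcmap.gmm import LabelMap
from lcmap.lc_extract import LcSegmentation

AFF = np.diag([0.4, 0.4, 0.5, 1.0])
VOXEL_VOL = 0.4 * 0.4 * 0.5


def _center_seed_mask(shape=(25, 25, 21)):
    data = np.zeros(shape, dtype=bool)
    data[shape[0] // 2, shape[1] // 2, shape[2] // 2] = True
    return BinaryMask(data, AFF, label="seed")


def _enumeration_count(radius):
    """Integer-lattice oracle: centres within radius of the seed centre."""
    i, j, k = np.mgrid[-12:13, -12:13, -10:11]
    dist = np.sqrt((0.4 * i) ** 2 + (0.4 * j) ** 2 + (0.5 * k) ** 2)
    return int(np.sum(dist <= radius + 1e-9))


@pytest.mark.parametrize("radius", [0.5, 1.0, 2.0, 4.0])
def test_mm_dilation_matches_integer_enumeration(radius):
    out = dilate_mask_mm(_center_seed_mask(), radius)
    assert out.n_voxels == _enumeration_count(radius)


def test_dilation_radius_zero_is_identity(rng):
    data = rng.random((8, 8, 8)) > 0.7
    mask = BinaryMask(data, AFF)
    assert np.array_equal(dilate_mask_mm(mask, 0.0).data, data)


def test_dilation_contains_input(rng):
    data = rng.random((10, 10, 10)) > 0.9
    mask = BinaryMask(data, AFF)
    for radius in (0.5, 2.0):
        out = dilate_mask_mm(mask, radius)
        assert np.all(out.data[data])


def _label_map(nm_voxels, shape=(30, 30, 30)):
    labels = np.ones(shape, dtype=np.int16)  # everything wm
    for v in nm_voxels:
        labels[v] = 2
    return LabelMap(labels=labels, affine=AFF,
                    class_roles={1: "wm", 2: "nm", 3: "fluid"})


def test_extraction_keeps_nm_near_ventricle_only():
    vent = np.zeros((30, 30, 30), dtype=bool)
    vent[15, 15, 10:20] = True
    near = [(17, 15, z) for z in range(10, 20)]   # 0.8 mm away
    far = [(15, 2, z) for z in range(10, 20)]     # 5.2 mm away
    lmap = _label_map(near + far)
    seg = extract_lc(lmap, BinaryMask(vent, AFF), ExtractionConfig())
    got = set(map(tuple, np.argwhere(seg.mask.data)))
    assert got == set(near)
    assert seg.n_components == 1


def test_small_components_dropped():
    vent = np.zeros((30, 30, 30), dtype=bool)
    vent[15, 15, 15] = True
    blob = [(17, 15, z) for z in range(13, 19)]  # 6 voxels, survives
    speck = [(13, 15, 15)]                        # 1 voxel, dropped
    lmap = _label_map(blob + speck)
    seg = extract_lc(lmap, BinaryMask(vent, AFF),
                     ExtractionConfig(min_component_voxels=5))
    got = set(map(tuple, np.argwhere(seg.mask.data)))
    assert got == set(blob)


def test_empty_intersection_warns_not_raises():
    vent = np.zeros((30, 30, 30), dtype=bool)
    vent[15, 15, 15] = True
    lmap = _label_map([(15, 2, 15)])  # only a far NM voxel
    with pytest.warns(UserWarning, match="empty"):
        seg = extract_lc(lmap, BinaryMask(vent, AFF), ExtractionConfig())
    assert seg.mask.is_empty()
    assert seg.n_components == 0


def test_missing_nm_role_is_configuration_error():
    lmap = LabelMap(labels=np.ones((5, 5, 5), dtype=np.int16), affine=AFF,
                    class_roles={1: "wm"})
    vent = BinaryMask(np.zeros((5, 5, 5), dtype=bool), AFF)
    with pytest.raises(ConfigurationError):
        extract_lc(lmap, vent, ExtractionConfig())


def _segmentation_from_mask(data):
    mask = BinaryMask(data, AFF, label="lc")
    empty = BinaryMask(np.zeros_like(data), AFF)
    return LcSegmentation(mask=mask, left_mask=mask, right_mask=empty,
                          n_components=1, constraint_mask=mask)


def _constant_enh(shape, value=1.0):
    vals = np.full(shape, value, dtype=float)
    valid = np.ones(shape, dtype=bool)
    return EnhancementMap(values=VolumeGrid(vals, AFF),
                          valid_mask=BinaryMask(valid, AFF))


def test_measurement_volume_and_normalization():
    shape = (50, 50, 50)
    lc = np.zeros(shape, dtype=bool)
    lc.ravel()[:100] = True  # 100 voxels -> 8 mm^3
    brainstem = np.zeros(shape, dtype=bool)
    brainstem.ravel()[:100000] = True  # 8000 mm^3
    meas = measure_lc(_segmentation_from_mask(lc), _constant_enh(shape),
                      BinaryMask(brainstem, AFF, label="brainstem"))
    assert meas.volume_mm3_total == pytest.approx(8.0)
    assert meas.lc_norm_brainstem == pytest.approx(0.001)
    assert meas.lc_norm_wholebrain is None


def test_truth_mask_length_equals_tube_length(phantom):
    meas = measure_lc(
        LcSegmentation(mask=phantom.truth_lc, left_mask=phantom.truth_lc_left,
                       right_mask=phantom.truth_lc_right, n_components=2,
                       constraint_mask=phantom.truth_ventricle),
        EnhancementMap(values=VolumeGrid(np.ones(phantom.mt.shape),
                                         phantom.mt.affine),
                       valid_mask=BinaryMask(np.ones(phantom.mt.shape, bool),
                                             phantom.mt.affine)),
        phantom.truth_brainstem)
    assert abs(meas.length_mm - phantom.spec.tube_length_mm) <= 0.5


def test_line_profile_basics():
    emap = _constant_enh((20, 20, 20), value=2.0)
    prof = line_profile(emap, (0, 10, 10), (19, 10, 10), n_samples=17)
    assert prof.shape == (17,)
    assert np.all(prof == 2.0)
    with pytest.raises(IndexError):
        line_profile(emap, (0, 0, 0), (25, 0, 0), 5)
    with pytest.raises(ValueError):
        line_profile(emap, (0, 0, 0), (1, 0, 0), 1)


def test_line_profile_through_phantom_tubes_shows_two_peaks(phantom,
                                                            pipeline_result):
    """A left-right line through both tubes rises above WM exactly twice."""
    emap = pipeline_result.enhancement
    spec = phantom.spec
    aff = phantom.mt.affine
    # voxel indices of the tube plane: world y ~ 0.2, z ~ 0.25 are inside
    j = int(round((0.2 - aff[1, 3]) / aff[1, 1]))
    k = int(round((0.25 - aff[2, 3]) / aff[2, 2]))
    n = phantom.mt.shape[0]
    prof = line_profile(emap, (0, j, k), (n - 1, j, k), n_samples=n)
    x = aff[0, 0] * np.arange(n) + aff[0, 3]
    mu_fluid, mu_nm, mu_wm = spec.class_ratio_means
    above = np.isfinite(prof) & (prof > (mu_nm + mu_wm) / 2)
    # runs of consecutive above-threshold samples
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    runs = edges.reshape(-1, 2)
    tube_cx = spec.ventricle_radius_mm + spec.tube_lateral_offset_mm
    half_w = spec.tube_cross_section_mm[0] / 2
    tube_runs = [r for r in runs
                 if min(abs(abs(x[r[0]:r[1]].mean()) - tube_cx), 99) < half_w]
    assert len(tube_runs) == 2
    centers = sorted(x[r[0]:r[1]].mean() for r in tube_runs)
    assert abs(centers[0] + tube_cx) < half_w
    assert abs(centers[1] - tube_cx) < half_w


def test_contrast_identical_constants_gives_zero_effect():
    shape = (10, 10, 10)
    emap = _constant_enh(shape)
    a = np.zeros(shape, dtype=bool)
    b = np.zeros(shape, dtype=bool)
    a[:2] = True
    b[5:7] = True
    res = enhancement_contrast(emap, BinaryMask(a, AFF), BinaryMask(b, AFF))
    assert res.statistic == 0.0
    assert res.effect == 0.0
    assert res.p == 1.0


def test_contrast_rejects_overlapping_masks():
    shape = (6, 6, 6)
    emap = _constant_enh(shape)
    a = np.zeros(shape, dtype=bool)
    a[:3] = True
    with pytest.raises(MaskOverlapError):
        enhancement_contrast(emap, BinaryMask(a, AFF), BinaryMask(a, AFF))


def test_contrast_matches_hand_welch_formula():
    a = np.array([1.2, 1.3, 1.25, 1.31, 1.22, 1.28, 1.33, 1.27, 1.24, 1.3])
    b = np.array([1.0, 1.05, 0.98, 1.02, 1.01, 0.99, 1.04, 1.03, 0.97, 1.0])
    shape = (20, 1, 1)
    vals = np.concatenate([a, b]).reshape(shape)
    emap = EnhancementMap(values=VolumeGrid(vals, AFF),
                          valid_mask=BinaryMask(np.ones(shape, bool), AFF))
    ma = np.zeros(shape, bool)
    ma[:10] = True
    res = enhancement_contrast(emap, BinaryMask(ma, AFF),
                               BinaryMask(~ma, AFF))
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / 10 + v2 / 10
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / 10) ** 2 / 9 + (v2 / 10) ** 2 / 9)
    p = 2 * t_dist.sf(abs(t), df)
    assert res.statistic == pytest.approx(t, abs=1e-10)
    assert res.df == pytest.approx(df, abs=1e-10)
    assert res.p == pytest.approx(p, abs=1e-10)


def test_phantom_contrast_is_overwhelming(phantom, pipeline_result):
    """LC vs non-LC enhancement separation at >=5 sigma: p below 1e-6."""
    seg = pipeline_result.segmentation
    non_lc = BinaryMask(phantom.truth_brainstem.data & ~seg.mask.data,
                        phantom.truth_brainstem.affine)
    res = enhancement_contrast(pipeline_result.enhancement, seg.mask, non_lc)
    assert res.p < 1e-6
    assert res.mean_a > res.mean_b  # LC hyper-intense vs surrounding tissue
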