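import math

import numpy as np
import pytest

from wormfit.imaging import (
    SegmentationParams,
    correct_illumination,
    count_image_pair,
    crop_well,
    detect_gfp_children,
    segment_worms,
)
from wormfit.render import RenderConfig, WellImagePair, render_well_image

CLEAN = RenderConfig(clump_prob=0.0, n_debris=0)


def _radial_field(n=256, amp=0.6):
    rr, cc = np.mgrid[0:n, 0:n]
    d = np.hypot(rr - (n - 1) / 2, cc - (n - 1) / 2) / ((n - 1) / 2 * math.sqrt(2))
    return 0.8 * (1.0 - amp * d**2)


def test_correct_illumination_flattens_radial_gradient():
    out = correct_illumination(_radial_field())
    assert np.ptp(out) / out.mean() < 0.04  # every pixel within 2% of flat


def test_correct_illumination_leaves_flat_image_alone():
    rng = np.random.default_rng(0)
    img = 0.7 + rng.normal(0, 1e-4, size=(128, 128))
    out = correct_illumination(img)
    assert np.allclose(out, img, atol=2e-3)
    with pytest.warns(UserWarning, match="constant image"):
        out = correct_illumination(np.full((64, 64), 0.5))
    assert np.all(out == 0.5)


def test_corrected_well_has_equal_edge_and_center_brightness():
    pair = render_well_image(0, 0.0, RenderConfig(n_debris=0),
                             np.random.default_rng(5))
    out = correct_illumination(pair.brightfield)
    n = out.shape[0]
    c = (n - 1) / 2
    rr, cc = np.mgrid[0:n, 0:n]
    d = np.hypot(rr - c, cc - c) / (c * math.sqrt(2))
    ratio = out[(d > 0.6) & (d < 0.9)].mean() / out[d < 0.25].mean()
    raw = pair.brightfield
    raw_ratio = raw[(d > 0.6) & (d < 0.9)].mean() / raw[d < 0.25].mean()
    assert raw_ratio < 0.8  # renderer really does darken the edges
    assert 0.95 < ratio < 1.05


def test_crop_well_geometry():
    img = np.ones((100, 100))
    assert crop_well(img, 0.0) is img
    assert crop_well(img, 0.1).shape == (80, 80)
    with pytest.raises(ValueError):
        crop_well(img, 0.5)


def test_segment_disjoint_worms_and_debris_filter(rng):
    pair = render_well_image(5, 0.0, CLEAN, rng)
    bf = correct_illumination(pair.brightfield)
    labels, objects, ref = segment_worms(bf)
    assert len(objects) == 5
    assert all(o.multiplicity == 1 for o in objects)
    assert ref > 0

    # debris specks below min_area segment to nothing
    speck_cfg = RenderConfig(clump_prob=0.0, n_debris=12,
                             debris_radius_lo=1.5, debris_radius_hi=3.0)
    pair = render_well_image(0, 0.0, speck_cfg, rng)
    labels, objects, _ = segment_worms(correct_illumination(pair.brightfield))
    assert objects == []


def test_segment_empty_well_returns_zero_not_error(rng):
    pair = render_well_image(0, 0.0, CLEAN, rng)
    res, est = count_image_pair(pair)
    assert res.n_total == 0 and res.n_gfp == 0 and est is None


def test_clump_resolved_by_area_quantization():
    """Three touching worms form one component whose area is quantized back
    to multiplicity 3; reference area comes from the single worms."""
    img = np.full((300, 300), 0.9)
    for r0 in (20, 40, 60):  # three disjoint single worms set the reference
        img[r0 : r0 + 6, 30:130] = 0.3
    for k in range(3):  # three touching worms: one connected component
        img[200 + 6 * k : 206 + 6 * k, 100:200] = 0.3
    labels, objects, ref = segment_worms(img, SegmentationParams(min_area=100))
    assert len(objects) == 4
    assert ref == pytest.approx(600.0)
    mults = sorted(o.multiplicity for o in objects)
    assert mults == [1, 1, 1, 3]


def test_mild_renderer_clumping_approximately_counted(rng):
    cfg = RenderConfig(clump_prob=0.35, n_debris=0)
    total_err = 0
    for seed in range(4):
        pair = render_well_image(15, 0.0, cfg, np.random.default_rng(seed))
        res, _ = count_image_pair(pair)
        tt, _ = pair.truth_counts()
        total_err += abs(res.n_total - tt)
    assert total_err <= 6  # occasional off-by-one where clumps overlap heavily


def test_gfp_children_assignment_and_unassigned_blob():
    img = np.full((200, 200), 0.9)
    img[90:110, 40:160] = 0.3  # one worm-like dark bar
    fl = np.full((200, 200), 0.02)
    fl[95:105, 60:70] = 1.0  # blob inside the worm
    fl[20:30, 20:30] = 1.0  # blob on background
    labels, objects, _ = segment_worms(img, SegmentationParams(min_area=100))
    assert len(objects) == 1
    objects, unassigned = detect_gfp_children(labels, objects, fl)
    assert objects[0].gfp_children == 1
    assert unassigned == 1
    with pytest.raises(ValueError, match="frame"):
        detect_gfp_children(labels, objects, fl[:100, :100])


def test_cropped_off_gfp_head_causes_false_negative():
    """A worm whose GFP locus sits in the cropped-away border is
    misclassified as focal: the false-negative mechanism."""
    n = 200
    img = np.full((n, n), 0.9)
    img[95:105, 15:120] = 0.3  # worm crossing the crop border
    fl = np.full((n, n), 0.02)
    fl[96:104, 18:26] = 1.0  # GFP locus in the head, near the image edge
    pair = WellImagePair(brightfield=img, fluorescence=fl)

    res0, est0 = count_image_pair(pair, SegmentationParams(min_area=80))
    assert (res0.n_total, res0.n_gfp) == (1, 1)  # full frame: competitor

    res, est = count_image_pair(
        pair, SegmentationParams(min_area=80, crop_fraction=0.15)
    )
    assert (res.n_total, res.n_gfp) == (1, 0)  # cropped: read as focal
    assert est.p == 1.0


def test_counts_invariant_to_global_intensity_rescaling(rng):
    pair = render_well_image(15, 0.4, CLEAN, rng)
    res1, _ = count_image_pair(pair)
    scaled = WellImagePair(
        brightfield=pair.brightfield * 3.7,
        fluorescence=pair.fluorescence * 0.21,
        truth=pair.truth,
    )
    res2, _ = count_image_pair(scaled)
    assert (res1.n_total, res1.n_gfp) == (res2.n_total, res2.n_gfp)


def test_count_matches_construction(rng):
    pair = render_well_image(20, 0.4, CLEAN, rng)
    assert pair.truth_counts() == (20, 8)
    res, est = count_image_pair(pair)
    assert (res.n_total, res.n_gfp) == (20, 8)
    assert est.p == pytest.approx(0.6)


def test_more_debris_never_decreases_estimated_p(rng):
    """Debris is never fluorescent, so false positives can only push the
    focal frequency up."""
    p_by_density = []
    for n_debris in (0, 25, 60):
        cfg = RenderConfig(clump_prob=0.0, n_debris=n_debris,
                           debris_radius_lo=5.0, debris_radius_hi=8.0)
        ps = []
        for seed in range(4):
            pair = render_well_image(16, 0.5, cfg, np.random.default_rng(seed))
            _, est = count_image_pair(pair)
            ps.append(est.p)
        p_by_density.append(np.mean(ps))
    assert p_by_density[0] <= p_by_density[1] + 1e-9
    assert p_by_density[1] <= p_by_density[2] + 1e-9


def test_render_overcrowding_raises():
    tiny = RenderConfig(image_size=128, clump_prob=0.0, n_debris=0,
                        max_placement_attempts=20)
    with pytest.raises(RuntimeError, match="crowded"):
        render_well_image(200, 0.5, tiny, np.random.default_rng(0))
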