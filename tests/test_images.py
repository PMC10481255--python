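"""Template, lesion placement and subject-map rendering."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from nawm.config import PenumbraConfig
from nawm.images import (
    LATENT_SCALE,
    make_template,
    place_lesions,
    render_subject_maps,
)
from nawm.masking import make_nawm_mask, mask_volume_ml
from nawm.niftiio import load_volume, save_volume

VOXEL_ML = 2.5**3 / 1000.0  # 0.015625


def test_template_deterministic_and_plausible(small_template):
    again = make_template(shape=(16, 16, 16), voxel_mm=2.5, seed=42)
    np.testing.assert_array_equal(small_template.wm_mask, again.wm_mask)
    np.testing.assert_array_equal(
        small_template.mean_fields["FA"], again.mean_fields["FA"]
    )
    frac = small_template.wm_mask.mean()
    assert 0.2 <= frac <= 0.6
    fa_wm = small_template.mean_fields["FA"][small_template.wm_mask]
    assert abs(fa_wm.mean() - 0.45) < 0.05
    # single connected component
    from scipy import ndimage

    _, nlab = ndimage.label(small_template.wm_mask)
    assert nlab == 1


def test_template_volume_arithmetic():
    t = make_template(shape=(8, 8, 8), voxel_mm=2.5, seed=0)
    assert t.wm_volume_ml == pytest.approx(t.wm_mask.sum() * VOXEL_ML)


def test_template_fields_are_smooth(small_template):
    f = small_template.mean_fields["FA"]
    diffs = [np.abs(np.diff(f, axis=ax)).mean() for ax in range(3)]
    assert max(diffs) < f.std()


def test_degenerate_shape_rejected():
    with pytest.raises(ValueError):
        make_template(shape=(4, 8, 8))


def test_lesions_hit_target_volume(small_template):
    wm = small_template.wm_mask
    assert not place_lesions(wm, 0.0, 2.5, seed=1).any()
    one = place_lesions(wm, VOXEL_ML, 2.5, seed=1)
    assert one.sum() == 1
    big = place_lesions(wm, 3.0, 2.5, seed=2)
    assert abs(big.sum() * VOXEL_ML - 3.0) <= VOXEL_ML
    assert not (big & ~wm).any()  # lesions confined to WM
    with pytest.raises(ValueError):
        place_lesions(wm, small_template.wm_volume_ml + 1, 2.5)
    with pytest.raises(ValueError):
        place_lesions(wm, -0.1, 2.5)


def test_lesions_are_contiguous_blobs(small_template):
    from scipy import ndimage

    lesion = place_lesions(small_template.wm_mask, 1.0, 2.5, seed=3)
    _, nlab = ndimage.label(lesion)
    # at most the seeded number of centres, never voxel dust
    assert 1 <= nlab <= 5


def test_render_without_noise_reproduces_template(small_template):
    maps = render_subject_maps(
        small_template, {m: 0.0 for m in LATENT_SCALE}, noise_ratio=0.0
    )
    for m in LATENT_SCALE:
        np.testing.assert_allclose(maps[m], np.clip(small_template.mean_fields[m], 0, None))


def test_render_latent_shift_is_exact(small_template):
    base = render_subject_maps(small_template, {"FA": 0.0}, noise_ratio=0.0)["FA"]
    low = render_subject_maps(small_template, {"FA": -0.2}, noise_ratio=0.0)["FA"]
    wm = small_template.wm_mask
    drop = base[wm].mean() - low[wm].mean()
    assert drop == pytest.approx(0.2 * LATENT_SCALE["FA"], rel=1e-6)


def test_render_unknown_metric_rejected(small_template):
    with pytest.raises(ValueError, match="QQ"):
        render_subject_maps(small_template, {"QQ": 0.0})


def test_penumbra_zero_distance_is_inert(small_template):
    lesion = place_lesions(small_template.wm_mask, 1.0, 2.5, seed=5)
    off = render_subject_maps(
        small_template, {"FA": 0.0}, lesion_mask=lesion,
        penumbra=PenumbraConfig(distance_vox=0.0, amplitude=1.0), noise_ratio=0.0,
    )["FA"]
    plain = render_subject_maps(small_template, {"FA": 0.0}, noise_ratio=0.0)["FA"]
    np.testing.assert_array_equal(off, plain)


def test_penumbra_degrades_lesion_neighbourhood(small_template):
    lesion = place_lesions(small_template.wm_mask, 1.0, 2.5, seed=5)
    pen = render_subject_maps(
        small_template, {"FA": 0.0, "MD": 0.0}, lesion_mask=lesion,
        penumbra=PenumbraConfig(distance_vox=2.0, amplitude=1.0), noise_ratio=0.0,
    )
    plain = render_subject_maps(small_template, {"FA": 0.0, "MD": 0.0}, noise_ratio=0.0)
    from scipy import ndimage

    shell = ndimage.binary_dilation(lesion) & ~lesion & small_template.wm_mask
    assert (pen["FA"][shell] < plain["FA"][shell]).all()
    assert (pen["MD"][shell] > plain["MD"][shell]).all()
    far = small_template.wm_mask & (ndimage.distance_transform_edt(~lesion) > 3)
    np.testing.assert_allclose(pen["FA"][far], plain["FA"][far])


def test_wmhv_rank_correlates_with_wm_mean_fa_under_penumbra(small_template):
    # heavier lesion load -> more degraded WM when the penumbra term is on
    rng = np.random.default_rng(7)
    wmhvs = np.exp(rng.normal(np.log(2.9), 1.0, size=200)).clip(0, 8)
    means = []
    for i, v in enumerate(wmhvs):
        lesion = place_lesions(small_template.wm_mask, v, 2.5, seed=100 + i)
        fa = render_subject_maps(
            small_template, {"FA": 0.0}, lesion_mask=lesion,
            penumbra=PenumbraConfig(distance_vox=2.0, amplitude=0.5),
            noise_ratio=0.05, seed=i,
        )["FA"]
        means.append(fa[small_template.wm_mask].mean())
    rho = spearmanr(wmhvs, means).statistic
    assert rho < -0.5


def test_volumes_roundtrip_bit_exact(tmp_path, small_template):
    maps = render_subject_maps(small_template, {"FA": 0.3}, seed=1)
    data = maps["FA"].astype(np.float32)
    p = save_volume(data, small_template.grid, tmp_path / "fa.nii.gz")
    back, grid = load_volume(p)
    np.testing.assert_array_equal(back, data)
    assert grid == small_template.grid
    lesion = place_lesions(small_template.wm_mask, 1.0, 2.5, seed=1)
    p2 = save_volume(lesion, small_template.grid, tmp_path / "wmh.nii.gz")
    back2, _ = load_volume(p2)
    np.testing.assert_array_equal(back2 > 0, lesion)
    nawm = make_nawm_mask(small_template.wm_mask, lesion)
    assert mask_volume_ml(nawm, 2.5) <= mask_volume_ml(small_template.wm_mask, 2.5)
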