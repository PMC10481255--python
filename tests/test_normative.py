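"""Healthy-reference fitting and voxel-wise z-scoring."""

import numpy as np
import pytest
from scipy.stats import lognorm

from nawm.config import GridSpec
from nawm.normative import NormativeReference, mean_z_over_mask, select_reference

GRID2 = GridSpec(shape=(8, 8, 8), voxel_mm=2.5)
NVOX = 512


def _flat_masks(n, nvox=NVOX, value=True):
    return np.full((n, nvox), value, dtype=bool)


def test_select_reference_is_strict_at_threshold():
    sel = select_reference([0.5, 1.0, 1.5], threshold_ml=1.0)
    np.testing.assert_array_equal(sel, [True, False, False])


def test_select_reference_empty_advises_larger_threshold():
    with pytest.raises(ValueError, match="threshold"):
        select_reference([1.2, 3.0], threshold_ml=1.0)


def test_reference_fraction_matches_lognormal_cdf():
    from nawm.cohort import draw_cohort
    from nawm.config import EffectConfig

    cfg = EffectConfig(n=500, seed=17)
    df = draw_cohort(cfg)
    frac = select_reference(df["wmhv_ml"].to_numpy()).mean()
    expected = lognorm.cdf(1.0, s=cfg.wmhv_log_sd, scale=np.exp(cfg.wmhv_log_mean))
    assert frac == pytest.approx(expected, abs=0.05)


def test_fit_reference_mean_and_sample_sd():
    maps = {"FA": np.array([[0.4] * NVOX, [0.6] * NVOX])}
    ref = NormativeReference.fit(
        maps, _flat_masks(2), ["a", "b"], GRID2, n_min=2
    )
    assert ref.mean["FA"][0] == pytest.approx(0.5)
    # n-1 denominator: sd = sqrt(((0.4-0.5)^2 + (0.6-0.5)^2) / 1) = 0.14142...
    assert ref.sd["FA"][0] == pytest.approx(0.1414213562, abs=1e-9)


def test_identical_reference_maps_flagged_unusable():
    maps = {"FA": np.full((3, NVOX), 0.5)}
    ref = NormativeReference.fit(maps, _flat_masks(3), list("abc"), GRID2, n_min=2)
    assert not ref.usable("FA").any()


def test_low_coverage_voxels_flagged_unusable():
    masks = _flat_masks(3)
    masks[1:, 0] = False  # voxel 0 covered by a single subject
    maps = {"FA": np.random.default_rng(0).uniform(0.3, 0.6, size=(3, NVOX))}
    ref = NormativeReference.fit(maps, masks, list("abc"), GRID2, n_min=2)
    assert not ref.usable("FA")[0]
    assert ref.n["FA"][0] == 1
    assert ref.usable("FA")[1:].all()


def test_fit_requires_two_subjects():
    with pytest.raises(ValueError, match=">= 2"):
        NormativeReference.fit({"FA": np.ones((1, NVOX))}, _flat_masks(1), ["a"], GRID2)


@pytest.fixture()
def simple_reference():
    rng = np.random.default_rng(1)
    maps = {"FA": 0.5 + 0.1 * rng.standard_normal((20, NVOX))}
    return NormativeReference.fit(maps, _flat_masks(20), [f"s{i}" for i in range(20)], GRID2, n_min=2)


def test_zscore_arithmetic(simple_reference):
    ref = simple_reference
    z = ref.zscore(ref.mean["FA"], "FA")
    np.testing.assert_allclose(z[ref.usable("FA")], 0.0, atol=1e-12)
    z1 = ref.zscore(ref.mean["FA"] + ref.sd["FA"], "FA")
    np.testing.assert_allclose(z1[ref.usable("FA")], 1.0, atol=1e-9)


def test_zscore_hand_value():
    maps = {"FA": np.vstack([np.full(NVOX, 0.4), np.full(NVOX, 0.6)])}
    ref = NormativeReference.fit(maps, _flat_masks(2), ["a", "b"], GRID2, n_min=2)
    ref.mean["FA"][:] = 0.5
    ref.sd["FA"][:] = 0.1
    z = ref.zscore(np.full(NVOX, 0.43), "FA")
    np.testing.assert_allclose(z, -0.7, atol=1e-12)


def test_zscore_grid_mismatch(simple_reference):
    with pytest.raises(ValueError, match="grid mismatch"):
        simple_reference.zscore(np.zeros(100), "FA")


def test_mean_z_over_mask_behaviour():
    z = np.array([1.0, -1.0, np.nan, 5.0])
    mask = np.array([True, True, True, False])
    mean, usable = mean_z_over_mask(z, mask)
    assert mean == 0.0 and usable == 2
    mean, usable = mean_z_over_mask(np.full(4, np.nan), mask)
    assert np.isnan(mean) and usable == 0
    with pytest.raises(ValueError, match="empty"):
        mean_z_over_mask(z, np.zeros(4, dtype=bool))


def test_affine_equivariance():
    # rescaling a metric by a>0 and shifting by b leaves all z-maps unchanged
    rng = np.random.default_rng(2)
    stack = 0.5 + 0.1 * rng.standard_normal((15, NVOX))
    masks = _flat_masks(15)
    ids = [f"s{i}" for i in range(15)]
    ref1 = NormativeReference.fit({"FA": stack}, masks, ids, GRID2, n_min=2)
    a, b = 3.7, -0.2
    ref2 = NormativeReference.fit({"FA": a * stack + b}, masks, ids, GRID2, n_min=2)
    probe = 0.5 + 0.1 * rng.standard_normal(NVOX)
    np.testing.assert_allclose(
        ref1.zscore(probe, "FA"), ref2.zscore(a * probe + b, "FA"), atol=1e-8
    )


def test_uniformly_lower_map_gives_strictly_lower_mean_z(simple_reference):
    ref = simple_reference
    probe = 0.5 + 0.05 * np.random.default_rng(3).standard_normal(NVOX)
    mask = np.ones(NVOX, dtype=bool)
    hi, _ = mean_z_over_mask(ref.zscore(probe, "FA"), mask)
    lo, _ = mean_z_over_mask(ref.zscore(probe - 0.02, "FA"), mask)
    assert lo < hi


def test_summarize_counts_and_self_normalization(small_study):
    table, objs = small_study
    ref = objs["reference"]
    assert (table["fa_usable"] <= table["nawm_voxel_count"]).all()
    is_ref = table["subject_id"].isin(ref.subject_ids)
    # reference subjects z-scored against a model containing themselves
    # average out to ~0 per metric
    for m in ("fa", "md", "ndi", "odi"):
        assert abs(table.loc[is_ref, f"{m}_z"].mean()) < 0.03


def test_reference_roundtrip(tmp_path, simple_reference):
    simple_reference.save(tmp_path / "ref")
    back = NormativeReference.load(tmp_path / "ref")
    assert back.subject_ids == simple_reference.subject_ids
    np.testing.assert_allclose(back.mean["FA"], simple_reference.mean["FA"], rtol=1e-6)
    np.testing.assert_array_equal(back.n["FA"], simple_reference.n["FA"])
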