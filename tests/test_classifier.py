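"""Decision-tree classifier: oracle equivalence, partition, monotonicity."""

import dataclasses

import numpy as np
import pytest

from aquaveg import (
    CLASS_CODES,
    ReflectanceScene,
    SceneSpec,
    Thresholds,
    calibrate_avi_threshold,
    classify_batch,
    classify_scene,
    extract_water_mask,
    generate_lake_timeseries,
    generate_scene,
)
from aquaveg.classify import CalibrationError, DEFAULT_THRESHOLDS
from aquaveg.indices import compute_avi, compute_fai, compute_ndvi, compute_ndwi
from aquaveg.raster import CLASS_NAMES, IndexRaster
from aquaveg.sensors import get_profile


def _reference_classifier(scene, thresholds):
    """Per-pixel nested-conditional reference implementation."""
    avi = compute_avi(scene).values
    ndvi = compute_ndvi(scene).values
    fai = compute_fai(scene).values
    out = np.zeros(scene.shape, dtype=np.uint8)
    for r in range(scene.shape[0]):
        for c in range(scene.shape[1]):
            if not scene.valid[r, c]:
                out[r, c] = CLASS_CODES["nodata"]
            elif avi[r, c] > thresholds.t_avi:
                if ndvi[r, c] > thresholds.t_ndvi:
                    out[r, c] = CLASS_CODES["FEAV"]
                else:
                    out[r, c] = CLASS_CODES["SAV"]
            else:
                if fai[r, c] > thresholds.t_fai:
                    out[r, c] = CLASS_CODES["AB"]
                else:
                    out[r, c] = CLASS_CODES["OW"]
    return out


@pytest.mark.parametrize("seed", range(50))
def test_vectorized_matches_nested_conditional_reference(seed):
    rng = np.random.default_rng(seed)
    shape = (int(rng.integers(2, 17)), int(rng.integers(2, 17)))
    bands = rng.uniform(0.0, 0.5, size=(6, *shape))
    valid = rng.random(shape) > 0.1
    scene = ReflectanceScene(bands=bands, sensor_id="TM", valid=valid)
    th = Thresholds(
        t_avi=float(rng.normal(0, 0.05)),
        t_ndvi=float(rng.uniform(-0.5, 0.5)),
        t_fai=float(rng.normal(0, 0.05)),
    )
    got = classify_scene(scene, thresholds=th).labels
    np.testing.assert_array_equal(got, _reference_classifier(scene, th))


def test_value_at_threshold_falls_to_lower_branch():
    # a pixel whose AVI equals t_avi exactly is non-AV; FAI at t_fai is OW
    profile = get_profile("TM")
    k = np.asarray(profile.wetness_coefficients)
    r = np.full(6, 0.1)
    avi_val = -float(k @ r)
    scene = ReflectanceScene(bands=r.reshape(6, 1, 1), sensor_id="TM")
    fai_val = compute_fai(scene).values[0, 0]
    th = Thresholds(t_avi=avi_val, t_fai=fai_val, t_ndvi=0.2)
    cm = classify_scene(scene, thresholds=th)
    assert cm.labels[0, 0] == CLASS_CODES["OW"]


def test_av_partition_property(rng):
    bands = rng.uniform(0.0, 0.5, size=(6, 24, 24))
    scene = ReflectanceScene(bands=bands, sensor_id="TM")
    th = Thresholds(t_avi=0.0)
    cm = classify_scene(scene, thresholds=th)
    avi = compute_avi(scene).values
    av = (cm.labels == CLASS_CODES["SAV"]) | (cm.labels == CLASS_CODES["FEAV"])
    np.testing.assert_array_equal(av, avi > 0.0)


def test_threshold_monotonicity(rng):
    bands = rng.uniform(0.0, 0.5, size=(6, 24, 24))
    scene = ReflectanceScene(bands=bands, sensor_id="TM")

    def counts(th):
        cm = classify_scene(scene, thresholds=th)
        return {c: int(cm.class_mask(c).sum()) for c in CLASS_NAMES}

    lo, hi = Thresholds(t_avi=-0.05), Thresholds(t_avi=0.05)
    assert (counts(hi)["SAV"] + counts(hi)["FEAV"]) <= (
        counts(lo)["SAV"] + counts(lo)["FEAV"]
    )
    lo, hi = Thresholds(t_ndvi=-0.2), Thresholds(t_ndvi=0.4)
    assert counts(hi)["FEAV"] <= counts(lo)["FEAV"]
    lo, hi = Thresholds(t_fai=-0.05), Thresholds(t_fai=0.05)
    assert counts(hi)["AB"] <= counts(lo)["AB"]


def test_classification_commutes_with_cropping(rng):
    bands = rng.uniform(0.0, 0.5, size=(6, 20, 28))
    scene = ReflectanceScene(bands=bands, sensor_id="TM")
    rows, cols = slice(3, 15), slice(5, 21)
    full_then_crop = classify_scene(scene).crop(rows, cols)
    crop_then_full = classify_scene(scene.crop(rows, cols))
    np.testing.assert_array_equal(full_then_crop.labels, crop_then_full.labels)
    assert full_then_crop.georef == crop_then_full.georef


def test_water_mask_trivial_cases():
    ones = IndexRaster(np.full((8, 8), 0.5), "NDWI")
    assert extract_water_mask(ones, 0.0).all()
    neg = IndexRaster(np.full((8, 8), -0.5), "NDWI")
    assert not extract_water_mask(neg, 0.0).any()
    half = np.full((8, 8), -0.5)
    half[:, 4:] = 0.5
    mask = extract_water_mask(IndexRaster(half, "NDWI"), 0.0)
    assert mask.sum() == 32 and mask[:, 4:].all()


def test_water_mask_requires_ndwi():
    with pytest.raises(ValueError, match="NDWI"):
        extract_water_mask(IndexRaster(np.zeros((4, 4)), "AVI"), 0.0)


def test_calibrate_constant_and_mean():
    const = IndexRaster(np.full((10, 10), -0.1), "AVI")
    mask = np.ones((10, 10), dtype=bool)
    assert calibrate_avi_threshold(const, mask, k_sigma=5.0) == pytest.approx(-0.1)
    vals = np.zeros((10, 10))
    vals.flat[:3] = [-2.0, 0.0, 2.0]
    tri = IndexRaster(vals, "AVI")
    m3 = np.zeros((10, 10), dtype=bool)
    m3.flat[:3] = True
    # mean of {-2, 0, 2} with k_sigma = 0 — but only 3 pixels: must refuse
    with pytest.raises(CalibrationError, match="3 water pixels"):
        calibrate_avi_threshold(tri, m3, k_sigma=0.0)
    # with enough zero pixels added the mean statistic is exact
    m53 = np.zeros((10, 10), dtype=bool)
    m53.flat[:53] = True
    assert calibrate_avi_threshold(tri, m53, k_sigma=0.0) == pytest.approx(0.0)


def test_calibrate_recovers_mu_plus_two_sigma(rng):
    mu, sigma = -0.05, 0.02
    vals = rng.normal(mu, sigma, size=(100, 100))
    t = calibrate_avi_threshold(
        IndexRaster(vals, "AVI"), np.ones((100, 100), bool), k_sigma=2.0
    )
    assert t == pytest.approx(mu + 2 * sigma, abs=4 * sigma / 100)


def test_classify_batch_empty_and_deterministic():
    assert classify_batch([]).maps == []
    scene, _ = generate_scene(SceneSpec(width=16, height=16, noise_sd=0.01, seed=3))
    res = classify_batch([("2001-04-20", scene), ("2002-04-20", scene)])
    assert not res.failures
    (d1, m1), (d2, m2) = res.maps
    np.testing.assert_array_equal(m1.labels, m2.labels)


def test_classify_batch_auto_avi_records_threshold_and_isolates_failures():
    series = generate_lake_timeseries(3, 0.5, 0.3, seed=7, size=32)
    good = [(d, s) for d, s, _ in series]
    # a scene with no open water at all cannot calibrate
    bad_scene, _ = generate_scene(
        SceneSpec(
            width=16, height=16, seed=0,
            layout=np.full((16, 16), CLASS_CODES["FEAV"], dtype=np.uint8),
        )
    )
    res = classify_batch(good + [("2099-01-01", bad_scene)], auto_avi=True)
    assert len(res.maps) == 3
    assert len(res.failures) == 1 and "Calibration" in res.failures[0][1]
    for _, cm in res.maps:
        assert cm.provenance["auto_avi"] is True
        assert np.isfinite(cm.provenance["thresholds"]["t_avi"])


def test_batch_recovers_declining_sav_trend():
    series = generate_lake_timeseries(5, 0.6, 0.1, seed=11, size=48)
    res = classify_batch([(d, s) for d, s, _ in series], auto_avi=True)
    assert not res.failures
    fracs = [
        cm.class_mask("SAV").sum() / cm.valid.sum() for _, cm in res.maps
    ]
    assert all(a > b for a, b in zip(fracs, fracs[1:]))


def test_nodata_propagates_through_classifier(quadrant_scene):
    scene, _ = quadrant_scene
    hole = np.ones(scene.shape, dtype=bool)
    hole[:5, :5] = False
    masked = scene.with_mask(hole)
    cm = classify_scene(masked)
    assert (cm.labels[:5, :5] == CLASS_CODES["nodata"]).all()
    assert (cm.labels[5:, 5:] != CLASS_CODES["nodata"]).all()
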