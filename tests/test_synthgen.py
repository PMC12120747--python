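"""Cohort generator: counts, reproducibility, dispersion and calibration."""

import numpy as np
import pytest
from scipy.stats import ks_2samp, norm

from organovote import (
    GeneratorConfig,
    calibrate_separation,
    extract_features,
    generate_cohort,
    render_pdo_image,
)
from organovote.synthgen import ConfigurationError, PatientProfile


def big_config(platform="Eba", **kw):
    kw.setdefault("n_high_patients", 5)
    kw.setdefault("n_low_patients", 5)
    kw.setdefault("pdos_per_patient_per_batch", 1000)
    return GeneratorConfig(platform=platform, seed=kw.pop("seed", 0), **kw)


def test_record_count_identity():
    cfg = GeneratorConfig(n_high_patients=3, n_low_patients=2,
                          pdos_per_patient_per_batch=49, batches=("training",))
    assert len(generate_cohort(cfg)) == 5 * 1 * 49


def test_batches_multiply_record_count():
    cfg = GeneratorConfig(n_high_patients=2, n_low_patients=1,
                          pdos_per_patient_per_batch=7,
                          batches=("training", "validation", "external"))
    cohort = generate_cohort(cfg)
    assert len(cohort) == 3 * 3 * 7
    assert set(cohort.to_frame().batch) == {"training", "validation", "external"}


def test_same_seed_reproduces_identical_tables():
    cfg = GeneratorConfig(seed=42, pdos_per_patient_per_batch=20)
    a = generate_cohort(cfg).to_frame()
    b = generate_cohort(cfg).to_frame()
    assert a.equals(b)


def test_different_seed_changes_features():
    a = generate_cohort(GeneratorConfig(seed=1)).to_frame()
    b = generate_cohort(GeneratorConfig(seed=2)).to_frame()
    assert not np.allclose(a.area_um2, b.area_um2)


@pytest.mark.parametrize(
    "platform, expected, tol",
    [("Eba", 0.18, 0.02), ("Std", 0.71, 0.07)],
)
def test_area_cv_matches_platform_dispersion(platform, expected, tol):
    """Pooled area CV of 10,000 draws sits at the platform's day-21 value."""
    areas = generate_cohort(big_config(platform)).to_frame().area_um2
    cv = areas.std(ddof=1) / areas.mean()
    assert cv == pytest.approx(expected, abs=tol)


def test_mean_diameter_recovered():
    areas = generate_cohort(big_config("Eba")).to_frame().area_um2
    diam = 2.0 * np.sqrt(areas.mean() / np.pi)
    assert diam == pytest.approx(200.0, rel=0.02)


def test_perimeter_identity_holds_exactly():
    frame = generate_cohort(GeneratorConfig(pdos_per_patient_per_batch=30)).to_frame()
    expected = np.sqrt(4 * np.pi * frame.area_um2 / frame.circularity)
    np.testing.assert_allclose(frame.perimeter_um, expected, rtol=1e-12)


@pytest.mark.parametrize(
    "target, expected",
    [(0.5, 0.0), (0.86, 2.1606386816), (0.64, 0.7169175865)],
)
def test_calibrate_separation_closed_form(target, expected):
    """Δ = 2·Φ⁻¹(target): the equal-variance Gaussian Bayes inverse."""
    assert calibrate_separation(target) == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize("bad", [1.0, 1.2, 0.4, -0.1])
def test_calibrate_separation_rejects_unattainable_targets(bad):
    with pytest.raises(ValueError):
        calibrate_separation(bad)


def test_bayes_oracle_attains_calibrated_accuracy():
    """With many patients, the z>0 rule on log-area hits the 0.86 target."""
    cfg = GeneratorConfig(n_high_patients=100, n_low_patients=100,
                          pdos_per_patient_per_batch=50,
                          target_single_pdo_accuracy=0.86, seed=7)
    frame = generate_cohort(cfg).to_frame()
    sigma = np.sqrt(np.log1p(cfg.effective_area_cv**2))
    mu = np.log(cfg.mean_area) - sigma**2 / 2
    z = (np.log(frame.area_um2) - mu) / sigma
    pred = np.where(z > 0, "High", "Low")
    assert (pred == frame.cea_class).mean() == pytest.approx(0.86, abs=0.02)


def test_zero_effect_classes_are_exchangeable():
    """With class_effect 0, High and Low area distributions coincide."""
    frame = generate_cohort(big_config("Eba", seed=3)).to_frame()
    high = frame.loc[frame.cea_class == "High", "area_um2"]
    low = frame.loc[frame.cea_class == "Low", "area_um2"]
    assert ks_2samp(high, low).pvalue > 0.01


def test_class_effect_shifts_feature_means():
    frame = generate_cohort(big_config("Eba", class_effect=1.0, seed=4)).to_frame()
    by_class = frame.groupby("cea_class").area_um2.mean()
    assert by_class["High"] > by_class["Low"]


def test_patient_random_effects_induce_within_class_spread():
    cfg = GeneratorConfig(n_high_patients=8, n_low_patients=8,
                          pdos_per_patient_per_batch=200,
                          target_single_pdo_accuracy=0.86, seed=9)
    frame = generate_cohort(cfg).to_frame()
    per_patient = np.log(frame.groupby("patient_id").area_um2.mean())
    within_class_sd = frame.assign(log_area=np.log(frame.area_um2)) \
        .groupby("cea_class").log_area.std().mean()
    # patient means spread by more than pure sampling noise would allow
    assert per_patient.groupby(frame.groupby("patient_id").cea_class.first()).std().mean() \
        > 3 * within_class_sd / np.sqrt(200)


def test_patient_profile_rejects_inconsistent_class():
    with pytest.raises(ValueError):
        PatientProfile(patient_id="x", serum_cea=1.0, cea_class="High", offset=0.0)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_high_patients": 0},
        {"pdos_per_patient_per_batch": 0},
        {"area_cv": -0.1},
        {"pixel_size": 0.0},
        {"target_single_pdo_accuracy": 0.4},
        {"target_single_pdo_accuracy": 1.0},
        {"batches": ("nope",)},
        {"platform": "Foo"},
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        GeneratorConfig(**kwargs)


# ---------------------------------------------------------------------------
# image rendering

def _one_record(**cfg_kw):
    cfg = GeneratorConfig(n_high_patients=1, n_low_patients=1,
                          pdos_per_patient_per_batch=1, **cfg_kw)
    return generate_cohort(cfg).records[0], cfg


def test_rendered_object_spans_expected_pixels():
    """A ~200 µm organoid at 2 µm/px spans roughly 100 px."""
    record, cfg = _one_record(area_cv=0.01, noise_sd=0.0, seed=1)
    img = render_pdo_image(record, cfg)
    dark_cols = np.nonzero((img.raster < 128).any(axis=0))[0]
    span = dark_cols.max() - dark_cols.min() + 1
    assert span == pytest.approx(100, rel=0.15)


def test_noiseless_render_matches_analytic_area():
    record, cfg = _one_record(noise_sd=0.0, roughness=0.0, seed=2)
    img = render_pdo_image(record, cfg)
    measured_px = int((img.raster < 128).sum())
    analytic_px = img.ground_truth["area_um2"] / cfg.pixel_size**2
    assert measured_px == pytest.approx(analytic_px, rel=0.02)


def test_render_is_deterministic():
    record, cfg = _one_record(noise_sd=5.0, roughness=0.05, seed=3)
    a = render_pdo_image(record, cfg)
    b = render_pdo_image(record, cfg)
    assert np.array_equal(a.raster, b.raster)


def test_render_ground_truth_consistent_with_record():
    record, cfg = _one_record(noise_sd=0.0, roughness=0.0, seed=4)
    img = render_pdo_image(record, cfg)
    assert img.ground_truth["area_um2"] == pytest.approx(record.features.area, rel=0.001)


def test_render_segment_measure_roundtrip():
    record, cfg = _one_record(noise_sd=0.0, roughness=0.0, seed=5)
    feats = extract_features(render_pdo_image(record, cfg))
    assert feats.area == pytest.approx(record.features.area, rel=0.03)
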