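import numpy as np
import pytest

from irecar import (
    CohortSpec,
    SpheroidTreatment,
    classify_response,
    estimate_threshold,
    gen_hydrogel_lesions,
    gen_invivo_cohort,
    gen_spheroid_timelapse,
    invert_lesion,
    track_from_frames,
    viability_at,
)
from irecar.invivo_metrics import ResponseClass
from irecar.synthetic_data import (
    DEFAULT_DOSE_RESPONSE,
    VIABILITY_ANCHORS,
    fit_dose_response,
    infiltration_fraction,
)

# printed post-IRE viability brackets: (min, max) viable fraction
BRACKETS = {0.0: (0.9353, 0.9710), 1000.0: (0.1337, 0.5459), 2000.0: (0.0047, 0.0540)}


def test_dose_response_hits_anchor_brackets():
    """Model viabilities at 0/1,000/2,000 V/cm fall inside the measured ranges."""
    for field, (lo, hi) in BRACKETS.items():
        assert lo <= viability_at(field) <= hi


def test_dose_response_baseline_and_exact_anchors():
    assert viability_at(0.0) == pytest.approx(VIABILITY_ANCHORS[0.0])
    assert viability_at(1000.0) == pytest.approx(VIABILITY_ANCHORS[1000.0], rel=1e-9)
    assert viability_at(2000.0) == pytest.approx(VIABILITY_ANCHORS[2000.0], rel=1e-9)


def test_dose_response_strictly_decreasing():
    fields = np.linspace(0, 3000, 40)
    v = [viability_at(f) for f in fields]
    assert all(a > b for a, b in zip(v, v[1:]))


def test_fit_requires_untreated_anchor():
    with pytest.raises(ValueError):
        fit_dose_response({500.0: 0.9, 1000.0: 0.4, 2000.0: 0.05})


def test_hydrogel_noiseless_round_trip():
    meas, fmap = gen_hydrogel_lesions(500.0, noise_cv=0.0, n=1, seed=0)
    assert invert_lesion(fmap, meas[0]) == pytest.approx(500.0, rel=1e-6)


def test_hydrogel_replicates_distinct_and_reproducible():
    m1, _ = gen_hydrogel_lesions(500.0, noise_cv=0.05, n=5, seed=7)
    m2, _ = gen_hydrogel_lesions(500.0, noise_cv=0.05, n=5, seed=7)
    extents = [m.extent_mm for m in m1]
    assert len(set(extents)) == 5
    assert extents == [m.extent_mm for m in m2]


def test_larger_truth_threshold_gives_smaller_extent():
    lo, fmap = gen_hydrogel_lesions(400.0, noise_cv=0.0, n=1, seed=0)
    hi, _ = gen_hydrogel_lesions(600.0, noise_cv=0.0, n=1, seed=0)
    assert hi[0].extent_mm < lo[0].extent_mm


def test_five_replicate_recovery_within_two_sd():
    meas, fmap = gen_hydrogel_lesions(500.0, noise_cv=0.05, n=5, seed=21)
    est = estimate_threshold(meas, fmap)
    assert abs(est.mean_v_per_cm - 500.0) <= 2 * est.sd_v_per_cm


def _norm_green_72(treatment, seed=5):
    frames = gen_spheroid_timelapse(treatment, seed=seed)
    track = track_from_frames(frames)
    return track.normalized_green


def test_control_series_stays_near_unity():
    ng = _norm_green_72(SpheroidTreatment(0.0, False))
    assert all(abs(v - 1.0) < 0.05 for v in ng)


def test_sublethal_field_rebounds_by_72h():
    """1 kV/cm: survivors regrow, so normalized green at 72 h exceeds 3 h."""
    for field in (1000.0, 1500.0):
        ng = _norm_green_72(SpheroidTreatment(field, False))
        assert ng[-1] > ng[1] + 0.1


def test_combination_suppresses_the_rebound():
    ire = _norm_green_72(SpheroidTreatment(1500.0, False))
    combo = _norm_green_72(SpheroidTreatment(1500.0, True))
    assert combo[-1] < ire[-1]


def test_spheroid_swelling_increases_with_field():
    areas = []
    for field in (1000.0, 2000.0, 2500.0):
        frames = gen_spheroid_timelapse(SpheroidTreatment(field, False), seed=4)
        track = track_from_frames(frames)
        areas.append(track.normalized_area[1])
    assert areas[0] < areas[1] < areas[2]
    assert areas[0] > 1.02  # every treated spheroid swells


def test_cart_erosion_shrinks_spheroid():
    frames = gen_spheroid_timelapse(SpheroidTreatment(0.0, True), seed=4)
    track = track_from_frames(frames)
    assert track.normalized_area[-1] < 0.8


def test_net_deepred_tracks_programmed_infiltration():
    """Measured net deep-red is proportional to the programmed infiltration
    fraction (within 5%)."""
    tr = SpheroidTreatment(0.0, True)
    frames = gen_spheroid_timelapse(tr, seed=8)
    track = track_from_frames(frames)
    reds = {f.timepoint_h: f.net_deepred for f in track.frames}
    ratio_measured = reds[72.0] / reds[3.0]
    ratio_programmed = infiltration_fraction(72.0, tr) / infiltration_fraction(3.0, tr)
    assert ratio_measured == pytest.approx(ratio_programmed, rel=0.05)


def test_spheroid_generator_deterministic():
    a = gen_spheroid_timelapse(SpheroidTreatment(1000.0, True), seed=3)
    b = gen_spheroid_timelapse(SpheroidTreatment(1000.0, True), seed=3)
    for fa, fb in zip(a, b):
        np.testing.assert_array_equal(fa.green, fb.green)
        np.testing.assert_array_equal(fa.deepred, fb.deepred)


def test_spheroid_timepoint_validation():
    from irecar.synthetic_data import SpheroidImagingSpec

    with pytest.raises(ValueError):
        gen_spheroid_timelapse(
            SpheroidTreatment(), seed=0, spec=SpheroidImagingSpec(timepoints_h=(0.0, 24.0))
        )


def test_cohort_deterministic_and_labels_recovered():
    spec = CohortSpec(master_seed=11)
    cal1, subs1, truth1 = gen_invivo_cohort(spec)
    cal2, subs2, truth2 = gen_invivo_cohort(spec)
    assert cal1.equals(cal2) and truth1 == truth2
    predicted = {s.animal_id: classify_response(s)[0] for s in subs1}
    assert predicted == truth1


def test_combination_group_never_recurs():
    for seed in range(20):
        _, subs, truth = gen_invivo_cohort(CohortSpec(master_seed=seed))
        combo = [truth[s.animal_id] for s in subs if s.group == "combination"]
        assert all(label == ResponseClass.ERADICATED_DURABLE for label in combo)


def test_sham_group_progresses_before_day_60():
    _, subs, _ = gen_invivo_cohort(CohortSpec(master_seed=5))
    for s in subs:
        if s.group == "sham":
            label, day = classify_response(s)
            assert label == ResponseClass.STABLE_OR_PROGRESSIVE
            assert day is not None and day < 60


def test_recurrence_count_matches_binomial_expectation():
    """Mean recurrent IRE animals over many seeds approaches n * p = 4."""
    counts = []
    for seed in range(200):
        _, subs, truth = gen_invivo_cohort(CohortSpec(master_seed=seed))
        counts.append(
            sum(
                1
                for s in subs
                if s.group == "IRE" and truth[s.animal_id] == ResponseClass.ERADICATED_RECURRENT
            )
        )
    # binomial(6, 2/3): se of the mean over 200 draws ~ 0.082
    assert np.mean(counts) == pytest.approx(4.0, abs=0.35)
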