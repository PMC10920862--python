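"""Daily profiles, transition-aligned responses, per-bin tests, latency."""

import numpy as np
import pytest

from actirhythm import (
    ActigraphyRecord,
    LightSchedule,
    SimParams,
    align_to_transition,
    daily_profile,
    onset_latency,
    per_bin_compare,
    rebin,
    simulate_cohort,
)
from actirhythm.response import ResponseMatrix, per_animal_daily_mean
from conftest import square_wave_record

LD = LightSchedule()


def const_record(value, days=2, temp=None, animal_id="c", group="g"):
    n = days * 288
    t = np.full(n, np.nan) if temp is None else np.full(n, float(temp))
    return ActigraphyRecord(animal_id, group, 300, np.full(n, value, dtype=np.int64), t, LD)


class TestRebin:
    def test_activity_summed(self):
        rec = ActigraphyRecord("a", "g", 300, np.array([1, 2, 3], dtype=np.int64),
                               np.array([36.0, 37.0, np.nan]), LD)
        out = rebin(rec, 15)
        assert list(out.activity) == [6]
        assert out.temperature[0] == pytest.approx(36.5)  # missing-aware mean

    def test_all_missing_stays_missing(self):
        rec = ActigraphyRecord("a", "g", 300, np.zeros(3, dtype=np.int64),
                               np.full(3, np.nan), LD)
        assert np.isnan(rebin(rec, 15).temperature[0])

    def test_identity_rebin(self):
        rec = const_record(4)
        assert rebin(rec, 5) is rec

    def test_non_multiple_rejected(self):
        with pytest.raises(ValueError):
            rebin(const_record(1), 7)


class TestDailyProfile:
    def test_two_constant_animals(self):
        recs = [const_record(3, animal_id="a"), const_record(5, animal_id="b")]
        prof = daily_profile(recs, "activity", 5)
        assert np.allclose(prof.mean, 4.0)
        assert np.allclose(prof.sem, 1.0)  # sample SD of {3,5} is sqrt(2); /sqrt(2) = 1

    def test_identical_animals_zero_sem(self, ld):
        recs = simulate_cohort([("g", 3, SimParams(deterministic=True))], ld, 3, 0)
        prof = daily_profile(recs, "activity", 5)
        assert np.allclose(prof.sem, 0.0)

    def test_deterministic_profile_equals_single_day(self, ld):
        recs = simulate_cohort([("g", 2, SimParams(deterministic=True))], ld, 5, 0)
        prof = daily_profile(recs, "activity", 5)
        one_day = recs[0].activity[:288]
        assert np.allclose(prof.mean, one_day)

    def test_matches_naive_recomputation(self, ld):
        recs = simulate_cohort([("g", 5, SimParams())], ld, 6, master_seed=4)
        prof = daily_profile(recs, "activity", 5)
        per_animal = np.array([r.activity.reshape(6, 288).mean(axis=0) for r in recs])
        assert np.allclose(prof.mean, per_animal.mean(axis=0), atol=1e-12)
        assert np.allclose(
            prof.sem, per_animal.std(axis=0, ddof=1) / np.sqrt(5), atol=1e-12
        )

    def test_needs_two_animals(self):
        with pytest.raises(ValueError):
            daily_profile([const_record(1)], "activity", 60)

    def test_anchor_offset_respected(self):
        # identical physical pattern recorded from a ZT6 anchor lands on
        # the same ZT bins after alignment
        sch6 = LightSchedule(anchor_zt_at_start=6.0)
        rec0 = square_wave_record(days=2)
        day = np.r_[np.zeros(72), np.full(144, 10), np.zeros(72)]  # starts at ZT6
        rec6 = ActigraphyRecord("s6", "test", 300, np.tile(day, 2).astype(np.int64),
                                np.full(576, np.nan), sch6)
        a = per_animal_daily_mean(rec0, "activity")
        b = per_animal_daily_mean(rec6, "activity")
        assert np.allclose(a, b)


class TestAlignToTransition:
    def test_square_wave_exact(self):
        rec = square_wave_record(days=3, high=8)
        m = align_to_transition([rec], "lights_off", (60, 120), 15)
        pre = m.rel_bin_start_min < 0
        assert np.allclose(m.values[0, pre], 0.0)
        assert np.allclose(m.values[0, ~pre], 24.0)  # 3 five-min bins of 8 counts

    def test_one_day_equals_many_identical_days(self):
        one = square_wave_record(days=1)
        ten = square_wave_record(days=10)
        m1 = align_to_transition([one], "lights_off", (60, 120), 15)
        m10 = align_to_transition([ten], "lights_off", (60, 120), 15)
        assert np.allclose(m1.values, m10.values)

    def test_shift_by_full_day_identical(self):
        rec = square_wave_record(days=4)
        shifted = ActigraphyRecord("s", "test", 300, np.roll(rec.activity, 288),
                                   rec.temperature, rec.schedule)
        ma = align_to_transition([rec], "lights_off", (60, 120), 15)
        mb = align_to_transition([shifted], "lights_off", (60, 120), 15)
        assert np.allclose(ma.values, mb.values)

    def test_dd_rejected(self):
        rec = square_wave_record(schedule=LightSchedule(cycle_kind="DD"))
        with pytest.raises(ValueError):
            align_to_transition([rec], "lights_off", (60, 120), 15)


def matrix_from(values):
    values = np.asarray(values, dtype=float)
    return ResponseMatrix(
        event="lights_off", variable="activity", bin_minutes=15,
        rel_bin_start_min=np.arange(values.shape[1], dtype=float) * 15.0,
        animal_ids=[f"a{i}" for i in range(values.shape[0])],
        values=values,
    )


class TestPerBinCompare:
    def test_identical_groups_p_one(self):
        m = matrix_from([[1.0, 5.0], [2.0, 6.0], [3.0, 7.0]])
        df = per_bin_compare(m, m)
        assert np.allclose(df["p_raw"], 1.0)
        assert not df["degenerate"].any()

    def test_known_t_per_bin(self):
        a = matrix_from(np.array([[1.0], [2.0], [3.0]]))
        b = matrix_from(np.array([[2.0], [3.0], [4.0]]))
        df = per_bin_compare(a, b)
        assert df.loc[0, "t"] == pytest.approx(-1.224745, abs=1e-5)
        assert df.loc[0, "df"] == 4
        assert df.loc[0, "p_raw"] == pytest.approx(0.287864, abs=1e-5)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = matrix_from(rng.normal(0, 1, (4, 6)))
        b = matrix_from(rng.normal(1, 1, (5, 6)))
        dab, dba = per_bin_compare(a, b), per_bin_compare(b, a)
        assert np.allclose(dab["t"], -dba["t"])
        assert np.allclose(dab["p_raw"], dba["p_raw"])
        assert np.allclose(dab["p_holm"], dba["p_holm"])

    def test_degenerate_bin_flagged_not_raised(self):
        a = matrix_from([[2.0, 1.0], [2.0, 2.0]])
        b = matrix_from([[2.0, 3.0], [2.0, 5.0]])
        df = per_bin_compare(a, b)
        assert bool(df.loc[0, "degenerate"])
        assert np.isnan(df.loc[0, "p_raw"])
        assert np.isfinite(df.loc[1, "p_raw"])

    def test_holm_alongside_raw(self):
        rng = np.random.default_rng(6)
        a = matrix_from(rng.normal(0, 1, (5, 8)))
        b = matrix_from(rng.normal(2, 1, (5, 8)))
        df = per_bin_compare(a, b)
        assert (df["p_holm"] >= df["p_raw"] - 1e-15).all()


class TestOnsetLatency:
    def test_step_at_lights_off(self):
        rec = square_wave_record(days=3)
        lat, n_used, flagged = onset_latency(rec)
        assert lat == 0.0 and n_used == 3 and flagged == 0

    def test_threshold_zero(self):
        rec = square_wave_record(days=2)
        lat, _, _ = onset_latency(rec, threshold_frac=0.0)
        assert lat == 0.0

    def test_deterministic_rise_latency(self, ld):
        from actirhythm import simulate_animal

        p = SimParams(onset_latency=30.0, rise_time=20.0, deterministic=True)
        rec = simulate_animal(p, ld, 5, seed=0)
        lat, n_used, _ = onset_latency(rec, bin_minutes=15)
        # drive reaches half its dark-phase mean within ~latency + rise;
        # quantized to 15-min bins
        assert n_used == 5
        assert 15.0 <= lat <= 60.0

    def test_all_zero_dark_phase_flagged(self):
        rec = const_record(0, days=2)
        lat, n_used, flagged = onset_latency(rec)
        assert np.isnan(lat) and n_used == 0 and flagged == 2

    def test_dd_rejected(self):
        rec = square_wave_record(schedule=LightSchedule(cycle_kind="DD"))
        with pytest.raises(ValueError):
            onset_latency(rec)


def test_group_ordering_of_latency_and_onset(ld):
    """del-like responds faster than wt-like: latency and detected onset
    both order correctly in seeded replicates."""
    from actirhythm import detect_markers, genotype_presets, summarize_markers

    presets = genotype_presets()
    ok_lat = ok_onset = 0
    reps = 10
    for rep in range(reps):
        recs = simulate_cohort(
            [("wt", 5, presets["wt_like"]), ("del", 5, presets["del_like"])],
            ld, 42, master_seed=900 + rep,
        )
        lats, onsets = {}, {}
        for r in recs:
            lats.setdefault(r.group, []).append(onset_latency(r)[0])
            s = summarize_markers({r.animal_id: detect_markers(r)})
            onsets.setdefault(r.group, []).append(float(s["onset_zt"].iloc[0]))
        ok_lat += np.mean(lats["del"]) < np.mean(lats["wt"])
        ok_onset += np.mean(onsets["del"]) < np.mean(onsets["wt"])
    assert ok_lat == reps
    assert ok_onset == reps
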