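"""Gridding, hold-time estimation, sample-and-hold, Tukey, imputation."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import labwatch as lw
from labwatch.preprocessing import (HELD, IMPUTED, MISSING, OBSERVED,
                                    HoldTimeTable, discretize,
                                    estimate_hold_times, filter_stays, impute,
                                    remove_outliers_tukey, sample_and_hold)
from labwatch.synthetic import (Demographics, Measurement, RawCohort,
                                RawStay)
from .conftest import make_gridded

DEMO = Demographics(60.0, "male", 80.0)


def _stay(measurements, duration_steps=11, stay_id="s0"):
    return RawStay(stay_id=stay_id, demographics=DEMO,
                   duration_steps=duration_steps,
                   measurements=[Measurement(*m) for m in measurements])


def _cohort_from_gaps(gaps):
    """One stay, one channel, measurements separated by the given gaps."""
    times = np.concatenate([[0.0], np.cumsum(gaps)])
    spec = lw.LabChannelSpec(name="x", normal_low=0, normal_high=1,
                             baseline_mean=0.5, baseline_sd=0.1)
    duration = int(np.ceil((times[-1] + 1) / 4.0))
    stay = RawStay("s0", DEMO, min(18, max(3, duration)),
                   [Measurement("x", float(t), 0.5) for t in times
                    if t < min(18, max(3, duration)) * 4])
    return RawCohort([stay], [spec], seed=0)


class TestDiscretize:
    def test_single_measurement_at_admission(self):
        g = discretize(_stay([("x", 0.0, 1.5)], duration_steps=3), 4.0, ["x"])
        assert g.mask[0, 0] == OBSERVED and g.values[0, 0] == 1.5
        assert (g.mask[1:, 0] == MISSING).all()

    def test_latest_measurement_wins_within_bin(self):
        g = discretize(_stay([("x", 1.0, 10.0), ("x", 3.0, 20.0)], 3), 4.0, ["x"])
        assert g.values[0, 0] == 20.0

    def test_44_hour_stay_gives_11_rows(self):
        g = discretize(_stay([("x", 0.0, 1.0)], duration_steps=11), 4.0, ["x"])
        assert g.n_steps == 11

    def test_measurement_beyond_duration_rejected(self):
        stay = _stay([("x", 0.0, 1.0)], 3)
        # bypass construction-time validation to exercise discretize's check
        stay.measurements.append(Measurement("x", 50.0, 1.0))
        with pytest.raises(ValueError, match="exceeds stay duration"):
            discretize(stay, 4.0, ["x"])


class TestHoldTimes:
    def test_uniform_gaps_give_one_step(self):
        table = estimate_hold_times(_cohort_from_gaps([4.0] * 6), 0.9)
        assert table.hold_hours["x"] == 4.0

    @pytest.mark.parametrize("threshold,expected",
                             [(0.9, 24.0), (0.7, 4.0)])
    def test_hand_enumerated_gap_multiset(self, threshold, expected):
        # gaps {4,4,4,4,4,8,24}: cumulative fractions 5/7, 6/7, 7/7
        table = estimate_hold_times(
            _cohort_from_gaps([4, 4, 4, 4, 4, 8, 24]), threshold)
        assert table.hold_hours["x"] == expected

    def test_monotone_in_threshold(self):
        cohort = _cohort_from_gaps([4, 4, 8, 8, 12, 24, 4, 4])
        prev = 0.0
        for th in (0.3, 0.5, 0.7, 0.9, 0.99):
            h = estimate_hold_times(cohort, th).hold_hours["x"]
            assert h >= prev
            prev = h

    def test_sparse_channel_falls_back_flagged(self):
        spec_y = lw.LabChannelSpec(name="y", normal_low=0, normal_high=1,
                                   baseline_mean=0.5, baseline_sd=0.1)
        cohort = _cohort_from_gaps([4.0] * 5)
        cohort = RawCohort(cohort.stays, cohort.channel_specs + [spec_y], 0)
        table = estimate_hold_times(cohort, 0.9)
        assert table.hold_hours["y"] == 4.0
        assert "y" in table.fallback_channels


class TestSampleAndHold:
    def test_hold_horizon_and_gap(self, demo):
        # observation at step 0 (hold 8 h) and step 5: steps 1-2 held,
        # steps 3-4 stay missing
        g = make_gridded(np.zeros((6, 1)), demo)
        g.values[:] = np.nan
        g.mask[:] = MISSING
        g.values[0, 0], g.mask[0, 0] = 10.0, OBSERVED
        g.values[5, 0], g.mask[5, 0] = 20.0, OBSERVED
        out = sample_and_hold(g, HoldTimeTable({"c0": 8.0}, 0.9))
        assert list(out.mask[:, 0]) == [OBSERVED, HELD, HELD, MISSING,
                                        MISSING, OBSERVED]
        assert out.values[1, 0] == 10.0 and out.values[2, 0] == 10.0

    def test_fully_observed_unchanged(self, demo):
        g = make_gridded(np.arange(12.0).reshape(6, 2), demo)
        out = sample_and_hold(g, HoldTimeTable({"c0": 8.0, "c1": 24.0}, 0.9))
        assert np.array_equal(out.values, g.values)
        assert np.array_equal(out.mask, g.mask)

    def test_never_overwrites_and_never_fills_backward(self, demo):
        rng = np.random.default_rng(0)
        g = make_gridded(rng.normal(size=(10, 3)), demo)
        observed = rng.random((10, 3)) < 0.4
        g.values[~observed] = np.nan
        g.mask[~observed] = MISSING
        out = sample_and_hold(g, HoldTimeTable(
            {"c0": 4.0, "c1": 8.0, "c2": 24.0}, 0.9))
        # observed cells untouched
        assert np.array_equal(out.values[observed], g.values[observed])
        assert (out.mask[observed] == OBSERVED).all()
        # no fill before the first observation of each channel
        for j in range(3):
            obs_idx = np.flatnonzero(observed[:, j])
            first = obs_idx[0] if obs_idx.size else 10
            assert (out.mask[:first, j] == MISSING).all()


class TestTukey:
    def test_constant_channel_loses_nothing(self, demo):
        stays = [make_gridded(np.full((8, 1), 3.14), demo)]
        out, counts, _ = remove_outliers_tukey(stays)
        assert counts == {"c0": 0}
        assert (out[0].mask == OBSERVED).all()

    def test_hand_computed_fences(self, demo):
        stays = [make_gridded(np.array([[1.0], [2.0], [3.0], [4.0], [100.0]]),
                              demo)]
        out, counts, fences = remove_outliers_tukey(stays, k=1.5)
        # linear-interpolated quartiles of {1,2,3,4,100}: Q1=2, Q3=4, IQR=2
        assert fences.lo["c0"] == -1.0 and fences.hi["c0"] == 7.0
        assert counts["c0"] == 1
        assert out[0].mask[4, 0] == MISSING and np.isnan(out[0].values[4, 0])

    def test_inlier_sample_untouched(self, demo):
        rng = np.random.default_rng(1)
        stays = [make_gridded(rng.uniform(0, 1, size=(12, 2)), demo)]
        out, counts, _ = remove_outliers_tukey(stays)
        assert sum(counts.values()) == 0
        assert np.array_equal(out[0].values, stays[0].values)

    def test_few_cells_skipped_flagged(self, demo):
        stays = [make_gridded(np.array([[1.0], [2.0], [3.0]]), demo)]
        _, counts, fences = remove_outliers_tukey(stays)
        assert counts["c0"] == 0 and "c0" in fences.skipped_channels

    def test_detection_recall_on_injected_outliers(self, panel):
        """>= 95% of multiplier-10 gross outliers are fenced out."""
        specs = [c.with_(outlier_prob=0.05) for c in panel]
        conf = lw.GeneratorConfig(channel_specs=specs, apply_missingness=False)
        cohort = lw.generate_cohort(conf, 60, seed=17)
        corrupted = {}
        stays = []
        rng = np.random.default_rng(99)
        for s in cohort.stays:
            s2, idx = lw.inject_outliers(s, specs, 10.0, rng)
            corrupted[s2.stay_id] = idx
            stays.append(s2)
        cohort = RawCohort(stays, specs, seed=0)
        hold = estimate_hold_times(cohort, 0.9)
        gridded = {s.stay_id: sample_and_hold(
            discretize(s, 4.0, cohort.channel_names), hold)
            for s in cohort.stays}
        cleaned, _, _ = remove_outliers_tukey(list(gridded.values()))
        cleaned = {s.stay_id: s for s in cleaned}
        col = {c: j for j, c in enumerate(cohort.channel_names)}
        hits = total = 0
        for s in cohort.stays:
            for i in corrupted[s.stay_id]:
                m = s.measurements[i]
                b = int(m.time_h // 4.0)
                j = col[m.channel]
                # only count injected values that survived binning
                if gridded[s.stay_id].values[b, j] == m.value:
                    total += 1
                    if cleaned[s.stay_id].mask[b, j] == MISSING:
                        hits += 1
        assert total > 200
        assert hits / total >= 0.95


class TestFilterImpute:
    def test_fifty_percent_boundary_is_retained(self, demo):
        g = make_gridded(np.ones((4, 2)), demo)
        g.values[:2, :] = np.nan
        g.mask[:2, :] = MISSING  # exactly 50% missing
        kept, discarded = filter_stays([g], 0.5)
        assert kept and not discarded

    def test_fully_missing_discarded(self, demo):
        g = make_gridded(np.ones((4, 2)), demo)
        g.values[:] = np.nan
        g.mask[:] = MISSING
        kept, discarded = filter_stays([g], 0.5)
        assert not kept and discarded == ["s0"]

    def test_complete_input_unchanged(self, demo):
        g = make_gridded(np.arange(20.0).reshape(10, 2), demo)
        out = impute([g])
        assert np.array_equal(out[0].values, g.values)

    def test_knn_with_single_complete_row(self, demo):
        vals = np.array([[1.0, 2.0], [np.nan, 5.0]])
        g = make_gridded(vals, demo)
        g.mask[1, 0] = MISSING
        out = impute([g], knn_k=1, use_svd=False)
        assert out[0].values[1, 0] == 1.0
        assert out[0].mask[1, 0] == IMPUTED

    def test_rank_one_matrix_recovered_by_svd_pass(self, demo):
        rng = np.random.default_rng(0)
        M = np.outer(rng.uniform(1, 2, 60), rng.uniform(1, 2, 6))
        holes = rng.random(M.shape) < 0.10
        vals = M.copy()
        vals[holes] = np.nan
        stays = []
        for i in range(6):
            g = make_gridded(vals[i * 10:(i + 1) * 10], demo, stay_id=f"s{i}")
            g.mask[np.isnan(g.values)] = MISSING
            stays.append(g)
        out = impute(stays, svd_rank=1)
        rec = np.concatenate([s.values for s in out])
        assert np.abs(rec[holes] - M[holes]).max() < 1e-6

    def test_all_missing_channel_is_an_error(self, demo):
        g = make_gridded(np.ones((5, 2)), demo)
        g.values[:, 1] = np.nan
        g.mask[:, 1] = MISSING
        with pytest.raises(ValueError, match="c1"):
            impute([g])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n_stays=st.integers(3, 12))
def test_pipeline_composition_leaves_no_missing_cells(seed, n_stays):
    """discretize -> hold -> tukey -> filter -> impute always yields
    complete finite matrices, for arbitrary generator draws."""
    cohort = lw.generate_cohort(lw.GeneratorConfig(), n_stays, seed=seed)
    stays = lw.PreprocessingPipeline().fit_transform(cohort)
    for s in stays:
        assert np.isfinite(s.values).all()
        assert (s.mask != MISSING).all()
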