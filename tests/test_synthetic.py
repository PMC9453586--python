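"""Generator: degenerate dynamics, Markov-episode statistics, determinism."""

import numpy as np
import pytest

import labwatch as lw
from labwatch.synthetic import (DemographicsModel, generate_cohort,
                                inject_missingness, inject_outliers,
                                read_cohort, simulate_stay, write_cohort)

DM = DemographicsModel()


def _one_channel(**kw):
    base = dict(name="x", normal_low=0.0, normal_high=1.0, baseline_mean=0.5,
                baseline_sd=0.25, ar_coefficient=0.85, episode_rate=0.03,
                episode_persistence=0.9, sampling_period_hours=4.0,
                missing_prob=0.0, outlier_prob=0.0, obs_noise_sd=0.05)
    base.update(kw)
    return lw.LabChannelSpec(**base)


def test_degenerate_dynamics_yield_constant_baseline():
    spec = _one_channel(ar_coefficient=0.0, episode_rate=0.0,
                        baseline_sd=0.0, obs_noise_sd=0.0)
    stay = simulate_stay([spec], DM, 10, seed=0)
    assert all(m.value == spec.baseline_mean for m in stay.measurements)
    assert np.all(stay.true_state == spec.baseline_mean)


def test_episode_is_absorbing_when_persistence_one():
    spec = _one_channel(episode_rate=1.0, episode_persistence=1.0)
    stay = simulate_stay([spec], DM, 18, seed=1)
    assert stay.episode_state.all()
    outside = ((stay.true_state[:, 0] < spec.normal_low)
               | (stay.true_state[:, 0] > spec.normal_high))
    assert outside.all()


def test_episode_fraction_matches_two_state_chain_stationary_law():
    # rate 0.1, persistence 0.9 -> stationary fraction 0.1/(0.1+0.1) = 0.5
    spec = _one_channel(episode_rate=0.1, episode_persistence=0.9)
    conf = lw.GeneratorConfig(channel_specs=[spec], apply_missingness=False)
    cohort = generate_cohort(conf, 1000, seed=5)
    flags = np.concatenate([s.episode_state[:, 0] for s in cohort.stays])
    assert flags.size >= 10_000
    # within-stay correlation inflates the variance; 0.05 is ~3 effective SDs
    assert abs(flags.mean() - 0.5) < 0.05


def test_abnormality_rate_monotone_in_episode_rate():
    fracs = []
    for rate in (0.0, 0.05, 0.2, 0.5):
        spec = _one_channel(episode_rate=rate)
        conf = lw.GeneratorConfig(channel_specs=[spec], apply_missingness=False)
        cohort = generate_cohort(conf, 300, seed=7)
        flags = np.concatenate([s.episode_state[:, 0] for s in cohort.stays])
        fracs.append(flags.mean())
    assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))


def test_missingness_zero_and_one_probabilities():
    spec0 = _one_channel(missing_prob=0.0)
    stay = simulate_stay([spec0], DM, 12, seed=2)
    assert inject_missingness(stay, [spec0], seed=0).measurements \
        == stay.measurements
    spec1 = spec0.with_(missing_prob=1.0)
    assert inject_missingness(stay, [spec1], seed=0).measurements == []


def test_missingness_binomial_rate():
    spec = _one_channel(sampling_period_hours=0.5, missing_prob=0.3)
    # ~144 obs per stay; pool stays to pass 1000 measurements
    stays = [simulate_stay([spec], DM, 18, seed=s) for s in range(10)]
    n_total = sum(len(s.measurements) for s in stays)
    kept = sum(len(inject_missingness(s, [spec], seed=100 + i).measurements)
               for i, s in enumerate(stays))
    expected = 0.7 * n_total
    sd = np.sqrt(n_total * 0.3 * 0.7)
    assert abs(kept - expected) <= 3 * sd


def test_outlier_injection_ground_truth_and_fences():
    spec = _one_channel(outlier_prob=1.0, baseline_sd=0.02)
    stay = simulate_stay([spec], DM, 10, seed=3)
    corrupted_stay, idx = inject_outliers(stay, [spec], 10.0, seed=0)
    assert idx == list(range(len(stay.measurements)))
    clean = np.array([m.value for m in stay.measurements])
    q1, q3 = np.percentile(clean, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    bad = np.array([m.value for m in corrupted_stay.measurements])
    assert np.all((bad < lo) | (bad > hi))

    spec_none = spec.with_(outlier_prob=0.0)
    same, idx0 = inject_outliers(stay, [spec_none], 10.0, seed=0)
    assert idx0 == [] and same.measurements == stay.measurements


def test_cohort_determinism_and_unique_ids(tmp_path):
    conf = lw.GeneratorConfig()
    a = generate_cohort(conf, 30, seed=42)
    b = generate_cohort(conf, 30, seed=42)
    assert a.measurements_frame().equals(b.measurements_frame())
    assert a.demographics_frame().equals(b.demographics_frame())
    assert len({s.stay_id for s in a.stays}) == 30
    write_cohort(a, tmp_path / "A")
    write_cohort(b, tmp_path / "B")
    for f in ("measurements.csv", "demographics.csv", "channel_specs.yaml"):
        assert (tmp_path / "A" / f).read_bytes() == (tmp_path / "B" / f).read_bytes()


def test_cohort_roundtrip_through_csv(tmp_path):
    conf = lw.GeneratorConfig()
    a = generate_cohort(conf, 5, seed=9)
    write_cohort(a, tmp_path / "c")
    back = read_cohort(tmp_path / "c")
    assert back.channel_names == a.channel_names
    assert [s.stay_id for s in back.stays] == [s.stay_id for s in a.stays]
    assert back.stays[0].measurements == a.stays[0].measurements


def test_duration_distribution_mean():
    conf = lw.GeneratorConfig()
    cohort = generate_cohort(conf, 3000, seed=13)
    durations = np.array([s.duration_steps for s in cohort.stays])
    assert durations.min() >= 3 and durations.max() <= 18
    # uniform over {3..18}: mean 10.5, sd 4.61
    assert abs(durations.mean() - 10.5) < 3 * 4.61 / np.sqrt(3000)


def test_invalid_inputs_rejected():
    spec = _one_channel()
    with pytest.raises(ValueError):
        simulate_stay([], DM, 10, seed=0)
    with pytest.raises(ValueError):
        simulate_stay([spec], DM, 0, seed=0)
    with pytest.raises(ValueError):
        generate_cohort(lw.GeneratorConfig(channel_specs=[spec]), 0, seed=0)
    with pytest.raises(ValueError):
        inject_outliers(simulate_stay([spec], DM, 5, seed=0), [spec], 1.0, 0)


def test_persistence_predictor_floor(ranges):
    """On a high-persistence low-noise cohort the naive persistence
    predictor reaches micro-F1 >= 0.8 on the latent state, so next-step
    abnormality is genuinely learnable."""
    from labwatch.evaluation import confusion_counts, micro_metrics

    cohort = lw.generate_cohort(lw.persistence_benchmark_config(), 200, seed=21)
    lo = np.array([c.normal_low for c in cohort.channel_specs])
    hi = np.array([c.normal_high for c in cohort.channel_specs])
    preds, trues = [], []
    for s in cohort.stays:
        ab = (s.true_state < lo) | (s.true_state > hi)
        preds.append(ab[:-1])
        trues.append(ab[1:])
    P = np.concatenate(preds).astype(np.uint8)
    T = np.concatenate(trues).astype(np.uint8)
    rep = micro_metrics(confusion_counts(P, T))
    assert rep.f1 >= 0.8
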