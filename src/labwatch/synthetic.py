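"""Synthetic ICU lab cohort generator.

Real extracts of ICU laboratory data (one row per timestamped measurement,
plus per-stay demographics) are restricted-access; this module generates
cohorts with the same structural signature so the entire pipeline —
gridding, sample-and-hold, outlier removal, imputation, windowing, model
training and cross-cohort evaluation — is testable end to end.

Generative model per stay and channel
-------------------------------------
The latent channel value on a 4-hour grid is a mean-reverting AR(1) process
around the channel baseline, plus an abnormal *episode* drift governed by a
two-state Markov chain: a normal step enters an episode with probability
``episode_rate`` and an episode persists with probability
``episode_persistence``.  While in an episode the latent value sits just
outside the reference range (direction drawn at entry), which makes
near-future abnormality predictable from recent history — the property the
forecasting task needs.  Recorded measurements are the latent values at
irregular observation times (channel cadence plus jitter) with additive
observation noise; missingness and gross outliers are injected on top.

Stays last 12–72 hours in 4-hour steps.  The latent grid (``true_state``)
is retained on each stay for oracle tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .channels import LabChannelSpec, default_panel

__all__ = [
    "Demographics",
    "DemographicsModel",
    "GeneratorConfig",
    "Measurement",
    "RawStay",
    "RawCohort",
    "simulate_stay",
    "inject_missingness",
    "inject_outliers",
    "generate_cohort",
    "shifted_cohort_config",
    "persistence_benchmark_config",
    "write_cohort",
    "read_cohort",
]

STEP_HOURS = 4.0
MIN_STEPS, MAX_STEPS = 3, 18  # 12 h .. 72 h at 4-hour steps


@dataclass(frozen=True)
class Demographics:
    """Static per-stay covariates: age (years), sex, weight (kg)."""

    age: float
    sex: str  # "female" | "male"
    weight: float

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex category {self.sex!r}")


@dataclass(frozen=True)
class DemographicsModel:
    """Marginal distributions for simulated demographics.

    Age and weight are truncated normals; sex is Bernoulli(female_rate).
    """

    age_mean: float = 65.0
    age_sd: float = 15.0
    age_bounds: tuple[float, float] = (18.0, 95.0)
    weight_mean: float = 85.0
    weight_sd: float = 20.0
    weight_bounds: tuple[float, float] = (35.0, 200.0)
    female_rate: float = 0.40


@dataclass(frozen=True)
class Measurement:
    """One recorded lab value: (channel, hours from admission, value)."""

    channel: str
    time_h: float
    value: float


@dataclass
class RawStay:
    """One ICU stay as irregular timestamped measurements plus demographics.

    ``true_state`` holds the latent per-grid-step channel values
    (duration_steps x n_channels) and ``episode_state`` the corresponding
    boolean episode indicators; both exist only on simulated stays and feed
    oracle tests, never the models.
    """

    stay_id: str
    demographics: Demographics
    duration_steps: int
    measurements: list[Measurement]
    true_state: np.ndarray | None = None
    episode_state: np.ndarray | None = None

    @property
    def duration_hours(self) -> float:
        return self.duration_steps * STEP_HOURS

    def __post_init__(self) -> None:
        if not MIN_STEPS <= self.duration_steps <= MAX_STEPS:
            raise ValueError(
                f"duration_steps={self.duration_steps} outside "
                f"[{MIN_STEPS}, {MAX_STEPS}]"
            )
        for m in self.measurements:
            if not 0.0 <= m.time_h < self.duration_hours:
                raise ValueError(
                    f"measurement time {m.time_h} h outside stay of "
                    f"{self.duration_hours} h"
                )


@dataclass
class RawCohort:
    """A set of stays sharing one channel panel and generator seed."""

    stays: list[RawStay]
    channel_specs: list[LabChannelSpec]
    seed: int
    name: str = "cohort"

    def __post_init__(self) -> None:
        if not self.channel_specs:
            raise ValueError("cohort needs at least one channel")
        ids = [s.stay_id for s in self.stays]
        if len(ids) != len(set(ids)):
            raise ValueError("stay_ids must be unique")

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channel_specs]

    def measurements_frame(self) -> pd.DataFrame:
        rows = [
            (s.stay_id, m.channel, m.time_h, m.value)
            for s in self.stays
            for m in s.measurements
        ]
        return pd.DataFrame(rows, columns=["stay_id", "channel", "time_h", "value"])

    def demographics_frame(self) -> pd.DataFrame:
        rows = [
            (s.stay_id, s.demographics.age, s.demographics.sex,
             s.demographics.weight, s.duration_steps)
            for s in self.stays
        ]
        return pd.DataFrame(
            rows, columns=["stay_id", "age", "sex", "weight", "duration_steps"]
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the cohort generator needs besides the seed."""

    channel_specs: list[LabChannelSpec] = field(default_factory=default_panel)
    demographics: DemographicsModel = field(default_factory=DemographicsModel)
    duration_low: int = MIN_STEPS
    duration_high: int = MAX_STEPS  # inclusive
    apply_missingness: bool = True
    # displacement of episode values beyond the violated range boundary,
    # in units of the range width
    episode_margin: float = 0.15
    name: str = "cohort"


def _simulate_demographics(model: DemographicsModel, rng: np.random.Generator
                           ) -> Demographics:
    def trunc_normal(mean, sd, lo, hi):
        for _ in range(100):
            v = rng.normal(mean, sd)
            if lo <= v <= hi:
                return float(v)
        return float(np.clip(v, lo, hi))

    age = trunc_normal(model.age_mean, model.age_sd, *model.age_bounds)
    weight = trunc_normal(model.weight_mean, model.weight_sd,
                          *model.weight_bounds)
    sex = "female" if rng.random() < model.female_rate else "male"
    return Demographics(age=age, sex=sex, weight=weight)


# fraction of the AR deviation carried into episode values; damped so that
# genuinely abnormal values stay inside cohort-wide Tukey fences while
# injected gross outliers (many range-widths out) do not
_EPISODE_DEV_SCALE = 0.3


def _episode_value(spec: LabChannelSpec, x_t: float, direction: int,
                   margin: float) -> float:
    """Latent value during an episode: just past the violated boundary.

    The value clears the boundary by ``margin`` range-widths plus a damped
    copy of the AR deviation, so every episode step is abnormal by
    construction yet remains clinically plausible (not a gross outlier).
    """
    dev = margin * spec.range_width + _EPISODE_DEV_SCALE * abs(
        x_t - spec.baseline_mean)
    if direction > 0:
        return spec.normal_high + dev
    return spec.normal_low - dev


def simulate_stay(
    channel_specs: list[LabChannelSpec],
    demographics_model: DemographicsModel,
    duration_steps: int,
    seed: int | np.random.Generator,
    stay_id: str = "stay-0",
    episode_margin: float = 0.15,
) -> RawStay:
    """Simulate one stay: latent grid dynamics plus irregular observations.

    Parameters
    ----------
    duration_steps : int
        Stay length in 4-hour grid steps, between 3 and 18 (12–72 h).
    seed : int or Generator
        Randomness source; an int is wrapped in a fresh Generator.
    """
    if not channel_specs:
        raise ValueError("channel_specs must be non-empty")
    if duration_steps <= 0:
        raise ValueError("duration_steps must be positive")
    if not MIN_STEPS <= duration_steps <= MAX_STEPS:
        raise ValueError(
            f"duration_steps must be in [{MIN_STEPS}, {MAX_STEPS}]"
        )
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    demo = _simulate_demographics(demographics_model, rng)
    L, C = duration_steps, len(channel_specs)
    true_state = np.empty((L, C))
    episode_state = np.zeros((L, C), dtype=bool)
    measurements: list[Measurement] = []

    for j, spec in enumerate(channel_specs):
        phi, mu, sd = spec.ar_coefficient, spec.baseline_mean, spec.baseline_sd
        innov_sd = sd * np.sqrt(1.0 - phi**2)
        x = np.empty(L)
        x[0] = mu + sd * rng.standard_normal()
        # start the episode chain at its stationary law so the per-step
        # abnormality marginal is flat across the stay; for an absorbing
        # chain (persistence 1) fall back to the entry rate
        r, q = spec.episode_rate, 1.0 - spec.episode_persistence
        p0 = r if q == 0.0 else (r / (r + q) if r + q > 0 else 0.0)
        in_episode = rng.random() < p0
        direction = 1 if rng.random() < 0.5 else -1
        episode_state[0, j] = in_episode
        true_state[0, j] = (_episode_value(spec, x[0], direction, episode_margin)
                            if in_episode else x[0])
        for t in range(1, L):
            x[t] = mu + phi * (x[t - 1] - mu) + innov_sd * rng.standard_normal()
            if in_episode:
                in_episode = rng.random() < spec.episode_persistence
            else:
                if rng.random() < spec.episode_rate:
                    in_episode = True
                    direction = 1 if rng.random() < 0.5 else -1
            episode_state[t, j] = in_episode
            true_state[t, j] = (_episode_value(spec, x[t], direction,
                                               episode_margin)
                                if in_episode else x[t])

        # observation times: channel cadence with jitter inside the grid bin
        period = spec.sampling_period_hours
        n_obs = int(np.floor((duration_steps * STEP_HOURS - 1e-9) / period)) + 1
        for k in range(n_obs):
            base = k * period
            jitter = rng.uniform(0.0, min(period, STEP_HOURS) * 0.999)
            t_obs = min(base + jitter, duration_steps * STEP_HOURS - 1e-6)
            grid_idx = min(int(t_obs // STEP_HOURS), L - 1)
            value = true_state[grid_idx, j] + spec.obs_noise_sd * rng.standard_normal()
            measurements.append(Measurement(spec.name, float(t_obs), float(value)))

    return RawStay(
        stay_id=stay_id,
        demographics=demo,
        duration_steps=duration_steps,
        measurements=measurements,
        true_state=true_state,
        episode_state=episode_state,
    )


def inject_missingness(
    stay: RawStay,
    channel_specs: list[LabChannelSpec],
    seed: int | np.random.Generator,
) -> RawStay:
    """Drop each measurement independently with its channel's missing_prob."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    probs = {c.name: c.missing_prob for c in channel_specs}
    kept = [m for m in stay.measurements
            if rng.random() >= probs.get(m.channel, 0.0)]
    return dataclasses.replace(stay, measurements=kept)


def inject_outliers(
    stay: RawStay,
    channel_specs: list[LabChannelSpec],
    magnitude_multiplier: float,
    seed: int | np.random.Generator,
) -> tuple[RawStay, list[int]]:
    """Replace measurements with gross outliers; return corrupted indices.

    With probability ``outlier_prob`` (per channel) a recorded value becomes
    ``baseline_mean ± magnitude_multiplier * range_width`` — far outside any
    plausible fence when the multiplier is large.  The returned index list
    (positions in ``stay.measurements``) is the ground truth for testing
    outlier-detection recall.
    """
    if magnitude_multiplier <= 1:
        raise ValueError("magnitude_multiplier must be > 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    by_name = {c.name: c for c in channel_specs}
    out: list[Measurement] = []
    corrupted: list[int] = []
    for i, m in enumerate(stay.measurements):
        spec = by_name[m.channel]
        if rng.random() < spec.outlier_prob:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            val = spec.baseline_mean + sign * magnitude_multiplier * spec.range_width
            out.append(dataclasses.replace(m, value=float(val)))
            corrupted.append(i)
        else:
            out.append(m)
    return dataclasses.replace(stay, measurements=out), corrupted


def generate_cohort(
    config: GeneratorConfig,
    n_stays: int,
    seed: int,
) -> RawCohort:
    """Generate a reproducible cohort of ``n_stays`` stays.

    The top seed is split through :class:`numpy.random.SeedSequence` so each
    stay gets an independent stream; identical ``(config, seed)`` pairs yield
    identical cohorts.
    """
    if n_stays < 1:
        raise ValueError("n_stays must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_stays)
    stays = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        dur = int(rng.integers(config.duration_low, config.duration_high + 1))
        stay = simulate_stay(
            config.channel_specs, config.demographics, dur, rng,
            stay_id=f"{config.name}-{i:05d}",
            episode_margin=config.episode_margin,
        )
        if config.apply_missingness:
            stay = inject_missingness(stay, config.channel_specs, rng)
        stays.append(stay)
    return RawCohort(stays=stays, channel_specs=list(config.channel_specs),
                     seed=seed, name=config.name)


def shifted_cohort_config(
    base: GeneratorConfig,
    baseline_shift_sds: float = 1.0,
    missing_prob_add: float = 0.10,
    name: str = "cohort-B",
) -> GeneratorConfig:
    """A second-hospital variant of ``base``: shifted baselines, more gaps.

    Emulates the covariate shift between two care systems (different assay
    calibrations and charting practices) so cross-cohort generalization can
    be measured without real multi-center data.
    """
    specs = [
        c.with_(
            baseline_mean=c.baseline_mean + baseline_shift_sds * c.baseline_sd,
            missing_prob=float(np.clip(c.missing_prob + missing_prob_add, 0, 1)),
        )
        for c in base.channel_specs
    ]
    return dataclasses.replace(base, channel_specs=specs, name=name)


def persistence_benchmark_config(
    episode_rate: float = 0.12,
    name: str = "persistence",
) -> GeneratorConfig:
    """Noiseless persistence cohort: abnormality is an absorbing state.

    Episode persistence 1, zero observation noise, no missingness: once a
    channel enters an episode it stays abnormal, so the next-step label is
    readable off the last observed row and any competent learner should
    approach the persistence predictor's score.  The latent AR(1) keeps a
    moderate dispersion (SD = range width / 6) so cohort-wide quartiles —
    hence Tukey fences — behave as they do on realistic data; without it the
    value distribution collapses to point masses, the IQR degenerates to
    zero and the fences would delete the genuinely abnormal values.
    """
    specs = [
        c.with_(
            baseline_sd=c.range_width / 6.0,
            obs_noise_sd=0.0,
            episode_rate=episode_rate,
            episode_persistence=1.0,
            missing_prob=0.0,
        )
        for c in default_panel()
    ]
    return GeneratorConfig(channel_specs=specs, apply_missingness=False,
                           name=name)


# ---------------------------------------------------------------------------
# cohort serialization: the drop-in CSV schema for real extracts
# ---------------------------------------------------------------------------

def write_cohort(cohort: RawCohort, out_dir: str | Path) -> None:
    """Write measurements.csv, demographics.csv and channel_specs.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.measurements_frame().to_csv(
        out / "measurements.csv", index=False, float_format="%.17g")
    cohort.demographics_frame().to_csv(
        out / "demographics.csv", index=False, float_format="%.17g")
    meta = {
        "name": cohort.name,
        "seed": cohort.seed,
        "channels": [dataclasses.asdict(c) for c in cohort.channel_specs],
    }
    (out / "channel_specs.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def read_cohort(in_dir: str | Path) -> RawCohort:
    """Read a cohort from the CSV/YAML schema written by :func:`write_cohort`."""
    src = Path(in_dir)
    meta = yaml.safe_load((src / "channel_specs.yaml").read_text())
    specs = [LabChannelSpec(**c) for c in meta["channels"]]
    meas = pd.read_csv(src / "measurements.csv", float_precision="round_trip")
    demo = pd.read_csv(src / "demographics.csv", float_precision="round_trip")
    stays = []
    meas_by_stay = dict(tuple(meas.groupby("stay_id", sort=False))) if len(meas) else {}
    for row in demo.itertuples(index=False):
        g = meas_by_stay.get(row.stay_id)
        ms = ([Measurement(r.channel, float(r.time_h), float(r.value))
               for r in g.itertuples(index=False)] if g is not None else [])
        stays.append(RawStay(
            stay_id=str(row.stay_id),
            demographics=Demographics(age=float(row.age), sex=str(row.sex),
                                      weight=float(row.weight)),
            duration_steps=int(row.duration_steps),
            measurements=ms,
        ))
    return RawCohort(stays=stays, channel_specs=specs,
                     seed=int(meta["seed"]), name=str(meta["name"]))
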