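"""Laboratory channel definitions: reference ranges and simulation parameters.

A :class:`LabChannelSpec` bundles everything the package needs to know about
one lab analyte: the reference range used to binarize values into
normal/abnormal labels, and the generative parameters used by the synthetic
cohort generator (baseline level, autocorrelation, abnormal-episode dynamics,
sampling cadence, missingness and gross-outlier rates).

The default panel below is a synthetic stand-in for the 25-analyte panel
relevant to mechanically ventilated ICU patients.  Reference intervals are
standard adult values from common clinical references; the dynamic parameters
are the generator's own and do not claim to match any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["LabChannelSpec", "default_panel", "reference_ranges"]


@dataclass(frozen=True)
class LabChannelSpec:
    """Static description of one lab channel.

    Parameters
    ----------
    name : str
        Channel identifier (e.g. ``"sodium"``).
    normal_low, normal_high : float
        Reference range in channel units; values outside are "abnormal".
    baseline_mean, baseline_sd : float
        Stationary mean and SD of the latent mean-reverting process.
    ar_coefficient : float
        Lag-1 autocorrelation of the latent AR(1) process, in ``[0, 1)``.
    episode_rate : float
        Per-step probability of entering an abnormal drift episode.
    episode_persistence : float
        Per-step probability of remaining in an episode once entered.
    sampling_period_hours : float
        Typical spacing between recorded measurements.
    missing_prob : float
        Probability that any single recorded measurement is dropped.
    outlier_prob : float
        Probability that a recorded value is replaced by a gross outlier
        (only when outlier injection is requested).
    obs_noise_sd : float
        SD of the additive measurement noise on recorded values.
    """

    name: str
    normal_low: float
    normal_high: float
    baseline_mean: float
    baseline_sd: float
    ar_coefficient: float = 0.85
    episode_rate: float = 0.03
    episode_persistence: float = 0.90
    sampling_period_hours: float = 4.0
    missing_prob: float = 0.15
    outlier_prob: float = 0.02
    obs_noise_sd: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not self.normal_low < self.normal_high:
            raise ValueError(
                f"channel {self.name!r}: normal_low must be < normal_high"
            )
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError(f"channel {self.name!r}: ar_coefficient not in [0,1)")
        for attr in ("episode_rate", "episode_persistence", "missing_prob",
                     "outlier_prob"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"channel {self.name!r}: {attr}={v} not in [0,1]")
        if self.sampling_period_hours <= 0:
            raise ValueError(f"channel {self.name!r}: sampling period must be > 0")

    @property
    def range_width(self) -> float:
        return self.normal_high - self.normal_low

    def with_(self, **kw) -> "LabChannelSpec":
        """Return a copy with selected fields replaced."""
        return replace(self, **kw)


def _spec(name, low, high, period=4.0, **kw) -> LabChannelSpec:
    width = high - low
    return LabChannelSpec(
        name=name,
        normal_low=low,
        normal_high=high,
        baseline_mean=(low + high) / 2.0,
        baseline_sd=kw.pop("baseline_sd", width / 4.0),
        sampling_period_hours=period,
        obs_noise_sd=kw.pop("obs_noise_sd", width / 20.0),
        **kw,
    )


# 25-channel panel.  Most channels are sampled every 4 h; a minority of
# slower-turnaround assays (liver panel, coagulation) every 8 or 24 h.
_DEFAULT_PANEL: tuple[LabChannelSpec, ...] = (
    _spec("wbc", 4.5, 11.0),                 # 10^9/L
    _spec("hemoglobin", 12.0, 17.0),         # g/dL
    _spec("hematocrit", 36.0, 50.0),         # %
    _spec("platelets", 150.0, 400.0),        # 10^9/L
    _spec("sodium", 136.0, 145.0),           # mmol/L
    _spec("potassium", 3.5, 5.1),            # mmol/L
    _spec("chloride", 98.0, 106.0),          # mmol/L
    _spec("bicarbonate", 22.0, 28.0),        # mmol/L
    _spec("bun", 8.0, 20.0),                 # mg/dL
    _spec("creatinine", 0.7, 1.3),           # mg/dL
    _spec("glucose", 70.0, 100.0),           # mg/dL
    _spec("calcium", 8.6, 10.2),             # mg/dL
    _spec("magnesium", 1.7, 2.4),            # mg/dL
    _spec("phosphate", 2.5, 4.5),            # mg/dL
    _spec("lactate", 0.5, 2.2),              # mmol/L
    _spec("ph", 7.35, 7.45),                 # arterial pH
    _spec("paco2", 35.0, 45.0),              # mmHg
    _spec("pao2", 75.0, 100.0),              # mmHg
    _spec("base_excess", -2.0, 2.0),         # mmol/L
    _spec("anion_gap", 8.0, 16.0),           # mmol/L
    _spec("albumin", 3.5, 5.5, period=24.0),         # g/dL
    _spec("bilirubin_total", 0.3, 1.2, period=24.0), # mg/dL
    _spec("alt", 10.0, 40.0, period=8.0),            # U/L
    _spec("ast", 10.0, 40.0, period=8.0),            # U/L
    _spec("inr", 0.8, 1.2, period=8.0),              # ratio
)


def default_panel() -> list[LabChannelSpec]:
    """The default 25-channel lab panel (fresh list; specs are immutable)."""
    return list(_DEFAULT_PANEL)


def reference_ranges(specs: list[LabChannelSpec]) -> dict[str, tuple[float, float]]:
    """Reference-range table ``{channel: (normal_low, normal_high)}``."""
    return {s.name: (s.normal_low, s.normal_high) for s in specs}
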