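"""From sparse irregular measurements to complete matrices on a 4-hour grid.

The chain is: discretize onto the grid (latest value per bin) -> time-windowed
sample-and-hold with per-channel hold times estimated from inter-measurement
gap frequencies -> Tukey-fence outlier deletion (cohort-wide quartiles) ->
discarding stays with more than half their cells missing -> kNN imputation
with optional low-rank SVD smoothing and channel-mean fallback.

Cell provenance is tracked in an integer mask: ``MISSING`` (0), ``OBSERVED``
(1), ``HELD`` (2, forward-filled), ``IMPUTED`` (3).  Outlier deletion runs
before imputation so a single imputation pass leaves no holes.

:class:`PreprocessingPipeline` wraps the chain with fit/transform semantics:
hold times and Tukey fences are estimated on the training cohort only and
reused verbatim on any other cohort, which keeps cross-cohort evaluation free
of information leakage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .synthetic import RawCohort, RawStay, Demographics, STEP_HOURS

__all__ = [
    "MISSING", "OBSERVED", "HELD", "IMPUTED",
    "GriddedStay", "HoldTimeTable", "TukeyFences",
    "discretize", "estimate_hold_times", "sample_and_hold",
    "remove_outliers_tukey", "filter_stays", "impute",
    "PreprocessingPipeline",
]

MISSING, OBSERVED, HELD, IMPUTED = 0, 1, 2, 3


@dataclass
class GriddedStay:
    """One stay on a fixed grid: L x C values with a provenance mask."""

    stay_id: str
    demographics: Demographics
    values: np.ndarray          # (L, C) float, NaN where mask == MISSING
    mask: np.ndarray            # (L, C) int8
    channel_names: list[str]
    step_hours: float = STEP_HOURS

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    def missing_fraction(self) -> float:
        return float((self.mask == MISSING).mean())

    def copy(self) -> "GriddedStay":
        return replace(self, values=self.values.copy(), mask=self.mask.copy())


@dataclass(frozen=True)
class HoldTimeTable:
    """Per-channel maximum forward-fill horizons in hours."""

    hold_hours: dict[str, float]
    coverage_threshold: float
    fallback_channels: tuple[str, ...] = ()  # <2 measurements cohort-wide

    def steps(self, channel: str, step_hours: float) -> int:
        return int(self.hold_hours[channel] // step_hours)


@dataclass(frozen=True)
class TukeyFences:
    """Per-channel closed intervals [lo, hi]; NaN bounds mean 'no fencing'."""

    lo: dict[str, float]
    hi: dict[str, float]
    k: float
    skipped_channels: tuple[str, ...] = ()  # <4 finite cells at fit time


def discretize(stay: RawStay, step_hours: float = STEP_HOURS,
               channel_names: list[str] | None = None) -> GriddedStay:
    """Assign measurements to grid bins ``floor(time_h / step_hours)``.

    Bin m covers ``[m*step, (m+1)*step)`` hours, 0-based from admission.
    When several measurements of one channel land in a bin the latest wins
    (the most recent value is the clinically operative one).  Empty bins are
    marked missing.
    """
    if step_hours <= 0:
        raise ValueError("step_hours must be positive")
    if channel_names is None:
        channel_names = sorted({m.channel for m in stay.measurements})
    col = {c: j for j, c in enumerate(channel_names)}
    L = math.ceil(stay.duration_hours / step_hours)
    C = len(channel_names)
    values = np.full((L, C), np.nan)
    mask = np.full((L, C), MISSING, dtype=np.int8)
    latest_time = np.full((L, C), -np.inf)
    for m in stay.measurements:
        if m.time_h >= stay.duration_hours:
            raise ValueError(
                f"measurement at {m.time_h} h exceeds stay duration "
                f"{stay.duration_hours} h"
            )
        j = col[m.channel]
        b = int(m.time_h // step_hours)
        if m.time_h >= latest_time[b, j]:
            latest_time[b, j] = m.time_h
            values[b, j] = m.value
            mask[b, j] = OBSERVED
    return GriddedStay(stay.stay_id, stay.demographics, values, mask,
                       list(channel_names), step_hours)


def estimate_hold_times(cohort: RawCohort, coverage_threshold: float = 0.9,
                        step_hours: float = STEP_HOURS) -> HoldTimeTable:
    """Frequency analysis of inter-measurement gaps -> per-channel hold time.

    For each channel, all consecutive inter-measurement time differences are
    pooled across stays; the hold time is the smallest distinct gap at which
    the cumulative count fraction strictly exceeds ``coverage_threshold``,
    rounded up to a positive multiple of the grid step.  Channels with fewer
    than two measurements cohort-wide fall back to one grid step and are
    flagged.
    """
    if not 0 < coverage_threshold <= 1:
        raise ValueError("coverage_threshold must be in (0, 1]")
    gaps: dict[str, list[float]] = {c.name: [] for c in cohort.channel_specs}
    for stay in cohort.stays:
        times: dict[str, list[float]] = {}
        for m in stay.measurements:
            times.setdefault(m.channel, []).append(m.time_h)
        for ch, ts in times.items():
            ts = sorted(ts)
            gaps.setdefault(ch, []).extend(np.diff(ts).tolist())
    if not any(gaps.values()):
        raise ValueError("no channel has >= 2 measurements cohort-wide")

    hold: dict[str, float] = {}
    fallback: list[str] = []
    for ch, g in gaps.items():
        if not g:
            hold[ch] = step_hours
            fallback.append(ch)
            continue
        arr = np.sort(np.asarray(g))
        distinct = np.unique(arr)
        n = arr.size
        chosen = distinct[-1]
        for d in distinct:
            if np.sum(arr <= d) / n > coverage_threshold:
                chosen = d
                break
        hold[ch] = max(step_hours, math.ceil(chosen / step_hours) * step_hours)
    return HoldTimeTable(hold_hours=hold, coverage_threshold=coverage_threshold,
                         fallback_channels=tuple(fallback))


def sample_and_hold(gridded: GriddedStay, hold_times: HoldTimeTable
                    ) -> GriddedStay:
    """Forward-fill each channel within its hold horizon.

    A value observed at step t remains valid for ``hold_time`` hours, i.e.
    it fills steps ``t+1 .. t + hold_time/step`` unless a newer observation
    appears first.  Cells beyond every hold horizon stay missing (the stale
    value is considered corrupted).  Observed cells are never overwritten
    and nothing is filled backward.
    """
    out = gridded.copy()
    L, C = out.values.shape
    for j, ch in enumerate(out.channel_names):
        h = hold_times.steps(ch, out.step_hours)
        obs = np.flatnonzero(out.mask[:, j] == OBSERVED)
        for t in obs:
            stop = min(L, t + h + 1)
            for s in range(t + 1, stop):
                if out.mask[s, j] == OBSERVED:
                    break
                out.values[s, j] = out.values[t, j]
                out.mask[s, j] = HELD
    return out


def remove_outliers_tukey(
    stays: list[GriddedStay],
    k: float = 1.5,
    fences: TukeyFences | None = None,
) -> tuple[list[GriddedStay], dict[str, int], TukeyFences]:
    """Delete cells outside the Tukey fences ``[Q1 - k*IQR, Q3 + k*IQR]``.

    Quartiles are computed per channel over all observed and held cells
    cohort-wide, by linear interpolation between order statistics.  The
    interval is closed, so a zero-IQR (constant) channel loses nothing.
    Channels with fewer than four finite cells are skipped and flagged.
    Deleted cells become missing and are re-filled by the imputation stage.

    Passing precomputed ``fences`` applies them instead of refitting —
    that is how a second cohort is screened with the training cohort's
    fences.  Returns (modified stays, per-channel removal counts, fences).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not stays:
        return [], {}, fences or TukeyFences({}, {}, k)
    channel_names = stays[0].channel_names
    if fences is None:
        lo, hi, skipped = {}, {}, []
        for j, ch in enumerate(channel_names):
            vals = np.concatenate([
                s.values[np.isin(s.mask[:, j], (OBSERVED, HELD)), j]
                for s in stays
            ])
            vals = vals[np.isfinite(vals)]
            if vals.size < 4:
                lo[ch], hi[ch] = np.nan, np.nan
                skipped.append(ch)
                continue
            q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation
            iqr = q3 - q1
            lo[ch], hi[ch] = q1 - k * iqr, q3 + k * iqr
        fences = TukeyFences(lo=lo, hi=hi, k=k, skipped_channels=tuple(skipped))

    counts = {ch: 0 for ch in channel_names}
    out = [s.copy() for s in stays]
    for s in out:
        for j, ch in enumerate(channel_names):
            flo, fhi = fences.lo.get(ch, np.nan), fences.hi.get(ch, np.nan)
            if not (np.isfinite(flo) and np.isfinite(fhi)):
                continue
            cells = np.isin(s.mask[:, j], (OBSERVED, HELD))
            bad = cells & ((s.values[:, j] < flo) | (s.values[:, j] > fhi))
            counts[ch] += int(bad.sum())
            s.values[bad, j] = np.nan
            s.mask[bad, j] = MISSING
    return out, counts, fences


def filter_stays(stays: list[GriddedStay], max_missing_fraction: float = 0.5
                 ) -> tuple[list[GriddedStay], list[str]]:
    """Drop stays whose missing-cell fraction strictly exceeds the cutoff.

    A stay with exactly the cutoff fraction (e.g. 50%) is retained.
    """
    kept, discarded = [], []
    for s in stays:
        if s.missing_fraction() > max_missing_fraction:
            discarded.append(s.stay_id)
        else:
            kept.append(s)
    return kept, discarded


def impute(stays: list[GriddedStay], knn_k: int = 5,
           svd_rank: int | None = None, use_svd: bool = True,
           chunk: int = 256) -> list[GriddedStay]:
    """Fill every remaining hole: kNN -> optional SVD smoothing -> mean.

    Each stay-time row with missing cells finds its ``knn_k`` nearest fully
    observed rows (Euclidean distance over the row's observed channels,
    z-scored cohort-wide) and takes their mean for the missing channels.
    Rows with no observed channel, or cohorts with no complete row, fall
    back to the cohort channel mean.  The optional SVD pass replaces just
    the imputed cells with their rank-``r`` reconstruction of the completed
    matrix, exploiting cross-channel correlation.  Output has no missing
    cells; filled cells are marked ``IMPUTED``.
    """
    if not stays:
        return []
    channel_names = stays[0].channel_names
    X = np.concatenate([s.values for s in stays], axis=0)
    n, C = X.shape
    obs = np.isfinite(X)
    if not obs.any(axis=0).all():
        j = int(np.flatnonzero(~obs.any(axis=0))[0])
        raise ValueError(
            f"channel {channel_names[j]!r} has no finite values cohort-wide"
        )
    col_mean = np.nanmean(X, axis=0)
    col_sd = np.nanstd(X, axis=0)
    col_sd[col_sd == 0] = 1.0
    Z = (X - col_mean) / col_sd

    complete = obs.all(axis=1)
    incomplete_idx = np.flatnonzero(~complete)
    Xfill = X.copy()
    if complete.any() and incomplete_idx.size:
        Zc = Z[complete]
        Xc = X[complete]
        for start in range(0, incomplete_idx.size, chunk):
            rows = incomplete_idx[start:start + chunk]
            Zi = Z[rows]                      # (m, C) with NaNs
            m_obs = np.isfinite(Zi)
            has_obs = m_obs.any(axis=1)
            diff = Zi[:, None, :] - Zc[None, :, :]   # (m, nc, C)
            diff = np.where(m_obs[:, None, :], diff, 0.0)
            d2 = np.einsum("mnc,mnc->mn", diff, diff)
            k_eff = min(knn_k, Zc.shape[0])
            nearest = np.argpartition(d2, k_eff - 1, axis=1)[:, :k_eff]
            fills = Xc[nearest].mean(axis=1)         # (m, C)
            for r, row in enumerate(rows):
                if not has_obs[r]:
                    continue  # no distance information; mean fallback below
                miss = ~obs[row]
                Xfill[row, miss] = fills[r, miss]
    # mean fallback for anything still missing
    still = ~np.isfinite(Xfill)
    Xfill[still] = np.broadcast_to(col_mean, Xfill.shape)[still]

    if use_svd and n >= 2 and C >= 2 and not obs.all():
        # iterative low-rank completion (hard-impute): repeatedly replace
        # the filled cells with their rank-r SVD reconstruction; recovers
        # exactly rank-r matrices and otherwise smooths the kNN/mean fill
        # using cross-channel correlation
        r = svd_rank if svd_rank is not None else min(5, C - 1)
        r = max(1, min(r, min(n, C)))
        fill_mask = ~obs
        for _ in range(100):
            U, s, Vt = np.linalg.svd(Xfill, full_matrices=False)
            recon = (U[:, :r] * s[:r]) @ Vt[:r]
            delta = float(np.abs(Xfill[fill_mask] - recon[fill_mask]).max(
                initial=0.0))
            Xfill[fill_mask] = recon[fill_mask]
            if delta <= 1e-9 * max(1.0, float(np.abs(Xfill).max())):
                break

    out = []
    offset = 0
    for s_ in stays:
        L = s_.n_steps
        vals = Xfill[offset:offset + L]
        msk = s_.mask.copy()
        msk[msk == MISSING] = IMPUTED
        out.append(replace(s_, values=vals, mask=msk))
        offset += L
    return out


@dataclass
class PreprocessingPipeline:
    """Fit the data-dependent preprocessing state on one cohort, reuse it.

    ``fit_transform`` estimates hold times and Tukey fences from the given
    cohort and returns its processed stays; ``transform`` applies the stored
    state to another cohort (imputation always uses the cohort being
    transformed — it has no tunable state worth transferring).
    """

    step_hours: float = STEP_HOURS
    coverage_threshold: float = 0.9
    tukey_k: float = 1.5
    knn_k: int = 5
    svd_rank: int | None = None
    use_svd: bool = True
    max_missing_fraction: float = 0.5
    hold_times: HoldTimeTable | None = field(default=None, repr=False)
    fences: TukeyFences | None = field(default=None, repr=False)
    discarded_ids: list[str] = field(default_factory=list, repr=False)

    def fit_transform(self, cohort: RawCohort) -> list[GriddedStay]:
        self.hold_times = estimate_hold_times(
            cohort, self.coverage_threshold, self.step_hours)
        return self._run(cohort, fit_fences=True)

    def transform(self, cohort: RawCohort) -> list[GriddedStay]:
        if self.hold_times is None:
            raise RuntimeError("pipeline not fitted; call fit_transform first")
        return self._run(cohort, fit_fences=False)

    def _run(self, cohort: RawCohort, fit_fences: bool) -> list[GriddedStay]:
        names = cohort.channel_names
        gridded = [discretize(s, self.step_hours, names) for s in cohort.stays]
        held = [sample_and_hold(g, self.hold_times) for g in gridded]
        cleaned, _counts, fences = remove_outliers_tukey(
            held, self.tukey_k, fences=None if fit_fences else self.fences)
        if fit_fences:
            self.fences = fences
        kept, discarded = filter_stays(cleaned, self.max_missing_fraction)
        self.discarded_ids = discarded
        return impute(kept, knn_k=self.knn_k, svd_rank=self.svd_rank,
                      use_svd=self.use_svd)
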