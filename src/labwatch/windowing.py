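"""Moving-window sample extraction and dataset assembly.

Each complete gridded stay of length L yields supervised pairs: a window of
W consecutive input steps and the binary abnormality vector of the step that
immediately follows.  For L >= W+1 that is exactly L - W samples (targets
m = W .. L-1).  Stays shorter than W+1 steps contribute one sample whose
inputs are left-padded with zero rows and whose target is the last step.
A value is labelled abnormal (1) when it falls strictly outside the closed
reference interval [normal_low, normal_high].

Windows from all stays are pooled, shuffled and split into train/validation/
test partitions — deliberately *not* grouped by stay, mirroring a design in
which subsequences of one stay may land in different partitions.  A grouped
(stay-level) split is available but off by default.  Per-channel z-scoring
statistics are computed from the training partition only (padding rows
excluded) and stored on the dataset; label binarization always uses raw
channel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import GriddedStay

__all__ = [
    "Sample", "SplitDataset", "binarize_labels", "extract_windows",
    "build_dataset", "largest_remainder_split",
]


@dataclass
class Sample:
    """One (input window, next-step label) pair.

    ``inputs`` is (W, C) in raw channel units with ``n_padded`` leading zero
    rows; ``demographics`` is the raw (age, sex01, weight) triple; ``target``
    the binary abnormality vector of the step after the window.
    """

    inputs: np.ndarray          # (W, C)
    demographics: np.ndarray    # (3,)
    target: np.ndarray          # (C,) uint8
    stay_id: str
    target_step: int
    n_padded: int = 0


@dataclass
class SplitDataset:
    """Shuffled train/validation/test samples plus training-set statistics."""

    train: list[Sample]
    validation: list[Sample]
    test: list[Sample]
    fractions: tuple[float, float, float]
    seed: int
    channel_names: list[str]
    window: int
    lab_mean: np.ndarray = field(repr=False, default=None)
    lab_sd: np.ndarray = field(repr=False, default=None)
    demo_mean: np.ndarray = field(repr=False, default=None)
    demo_sd: np.ndarray = field(repr=False, default=None)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def arrays(self, partition: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Normalized model-ready arrays (X, D, Y) for one partition.

        X is (n, W, C) z-scored with padding rows kept at exactly zero,
        D is (n, 3) z-scored demographics, Y is (n, C) uint8 labels.
        """
        samples: list[Sample] = getattr(self, partition)
        return self.normalize(samples)

    def normalize(self, samples: list[Sample]
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        W, C = self.window, self.n_channels
        n = len(samples)
        X = np.zeros((n, W, C))
        D = np.zeros((n, 3))
        Y = np.zeros((n, C), dtype=np.uint8)
        for i, s in enumerate(samples):
            z = (s.inputs - self.lab_mean) / self.lab_sd
            if s.n_padded:
                z[: s.n_padded] = 0.0
            X[i] = z
            D[i] = (s.demographics - self.demo_mean) / self.demo_sd
            Y[i] = s.target
        return X, D, Y


def binarize_labels(value_row: np.ndarray,
                    reference_ranges: dict[str, tuple[float, float]],
                    channel_names: list[str]) -> np.ndarray:
    """0 iff normal_low <= value <= normal_high (closed interval), else 1."""
    out = np.empty(len(channel_names), dtype=np.uint8)
    for j, ch in enumerate(channel_names):
        if ch not in reference_ranges:
            raise KeyError(f"no reference range for channel {ch!r}")
        lo, hi = reference_ranges[ch]
        v = value_row[j]
        if not np.isfinite(v):
            raise ValueError(f"non-finite value for channel {ch!r}")
        out[j] = 0 if lo <= v <= hi else 1
    return out


def _encode_demographics(stay: GriddedStay) -> np.ndarray:
    d = stay.demographics
    return np.array([d.age, 1.0 if d.sex == "male" else 0.0, d.weight])


def extract_windows(stay: GriddedStay, window: int,
                    reference_ranges: dict[str, tuple[float, float]]
                    ) -> list[Sample]:
    """All moving-window samples of one complete stay.

    For L >= window+1: targets m = window .. L-1 with inputs the preceding
    ``window`` rows (L - window samples).  For 2 <= L <= window: one sample,
    inputs X_0..X_{L-2} left-padded with zeros, target the last step.
    Stays with fewer than two steps yield nothing.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not np.isfinite(stay.values).all():
        raise ValueError(f"stay {stay.stay_id} still has missing values")
    L = stay.n_steps
    demo = _encode_demographics(stay)
    names = stay.channel_names
    samples: list[Sample] = []
    if L < 2:
        return samples
    if L >= window + 1:
        for m in range(window, L):
            samples.append(Sample(
                inputs=stay.values[m - window: m].copy(),
                demographics=demo.copy(),
                target=binarize_labels(stay.values[m], reference_ranges, names),
                stay_id=stay.stay_id,
                target_step=m,
            ))
    else:
        n_pad = window - (L - 1)
        inp = np.zeros((window, len(names)))
        inp[n_pad:] = stay.values[: L - 1]
        samples.append(Sample(
            inputs=inp,
            demographics=demo.copy(),
            target=binarize_labels(stay.values[L - 1], reference_ranges, names),
            stay_id=stay.stay_id,
            target_step=L - 1,
            n_padded=n_pad,
        ))
    return samples


def largest_remainder_split(n: int, fractions: tuple[float, float, float]
                            ) -> tuple[int, int, int]:
    """Partition sizes by largest-remainder rounding; sizes sum to n."""
    quotas = [n * f for f in fractions]
    sizes = [int(q) for q in quotas]
    rem = n - sum(sizes)
    order = np.argsort([-(q - int(q)) for q in quotas], kind="stable")
    for i in range(rem):
        sizes[order[i]] += 1
    return tuple(sizes)


def build_dataset(
    stays: list[GriddedStay],
    window: int,
    reference_ranges: dict[str, tuple[float, float]],
    split_fractions: tuple[float, float, float] = (0.68, 0.12, 0.20),
    seed: int = 0,
    group_by_stay: bool = False,
) -> SplitDataset:
    """Pool, shuffle and partition all windows; fit normalization on train.

    ``group_by_stay=True`` switches to a leakage-free stay-level split
    (all windows of one stay land in one partition); the default pools
    windows across partitions.
    """
    if not stays:
        raise ValueError("empty cohort")
    if any(f < 0 for f in split_fractions) or not np.isclose(
            sum(split_fractions), 1.0):
        raise ValueError("split fractions must be non-negative and sum to 1")
    channel_names = stays[0].channel_names
    samples: list[Sample] = []
    for s in stays:
        samples.extend(extract_windows(s, window, reference_ranges))
    if not samples:
        raise ValueError("no samples could be extracted (all stays too short)")
    rng = np.random.default_rng(seed)

    if group_by_stay:
        ids = sorted({s.stay_id for s in samples})
        perm_ids = [ids[i] for i in rng.permutation(len(ids))]
        n_tr, n_va, _ = largest_remainder_split(len(perm_ids), split_fractions)
        part_of = {}
        for r, sid in enumerate(perm_ids):
            part_of[sid] = 0 if r < n_tr else (1 if r < n_tr + n_va else 2)
        parts: tuple[list, list, list] = ([], [], [])
        for s in samples:
            parts[part_of[s.stay_id]].append(s)
        train, val, test = parts
    else:
        perm = rng.permutation(len(samples))
        shuffled = [samples[i] for i in perm]
        n_tr, n_va, _ = largest_remainder_split(len(shuffled), split_fractions)
        train = shuffled[:n_tr]
        val = shuffled[n_tr:n_tr + n_va]
        test = shuffled[n_tr + n_va:]

    ds = SplitDataset(train=train, validation=val, test=test,
                      fractions=tuple(split_fractions), seed=seed,
                      channel_names=list(channel_names), window=window)
    _fit_normalization(ds)
    return ds


def _fit_normalization(ds: SplitDataset) -> None:
    """Per-channel z-score statistics from training inputs, padding excluded."""
    ref = ds.train if ds.train else (ds.validation or ds.test)
    rows = np.concatenate(
        [s.inputs[s.n_padded:] for s in ref], axis=0) if ref else None
    if rows is None or rows.size == 0:
        raise ValueError("cannot fit normalization: no unpadded training rows")
    ds.lab_mean = rows.mean(axis=0)
    sd = rows.std(axis=0)
    sd[sd == 0] = 1.0
    ds.lab_sd = sd
    demo = np.stack([s.demographics for s in ref])
    ds.demo_mean = demo.mean(axis=0)
    dsd = demo.std(axis=0)
    dsd[dsd == 0] = 1.0
    ds.demo_sd = dsd


# ---------------------------------------------------------------------------
# dataset serialization (compressed arrays + JSON manifest)
# ---------------------------------------------------------------------------

def save_dataset(ds: SplitDataset, path) -> None:
    """Write a dataset to one ``.npz`` file (raw samples + manifest)."""
    import json

    arrays = {}
    manifest = {
        "window": ds.window, "seed": ds.seed,
        "fractions": list(ds.fractions),
        "channel_names": ds.channel_names,
        "sizes": {p: len(getattr(ds, p))
                  for p in ("train", "validation", "test")},
    }
    for part in ("train", "validation", "test"):
        samples = getattr(ds, part)
        if samples:
            arrays[f"{part}_inputs"] = np.stack([s.inputs for s in samples])
            arrays[f"{part}_demo"] = np.stack([s.demographics for s in samples])
            arrays[f"{part}_target"] = np.stack([s.target for s in samples])
            arrays[f"{part}_meta"] = np.array(
                [(s.stay_id, s.target_step, s.n_padded) for s in samples],
                dtype=object)
    for stat in ("lab_mean", "lab_sd", "demo_mean", "demo_sd"):
        arrays[stat] = getattr(ds, stat)
    arrays["manifest"] = np.array(json.dumps(manifest))
    np.savez_compressed(path, **arrays)


def load_dataset(path) -> SplitDataset:
    """Inverse of :func:`save_dataset`."""
    import json

    with np.load(path, allow_pickle=True) as z:
        manifest = json.loads(str(z["manifest"]))
        parts = {}
        for part in ("train", "validation", "test"):
            samples = []
            if manifest["sizes"][part]:
                inputs = z[f"{part}_inputs"]
                demo = z[f"{part}_demo"]
                target = z[f"{part}_target"]
                meta = z[f"{part}_meta"]
                for i in range(inputs.shape[0]):
                    sid, step, npad = meta[i]
                    samples.append(Sample(
                        inputs=inputs[i], demographics=demo[i],
                        target=target[i].astype(np.uint8), stay_id=str(sid),
                        target_step=int(step), n_padded=int(npad)))
            parts[part] = samples
        ds = SplitDataset(
            train=parts["train"], validation=parts["validation"],
            test=parts["test"], fractions=tuple(manifest["fractions"]),
            seed=int(manifest["seed"]),
            channel_names=list(manifest["channel_names"]),
            window=int(manifest["window"]),
            lab_mean=z["lab_mean"], lab_sd=z["lab_sd"],
            demo_mean=z["demo_mean"], demo_sd=z["demo_sd"])
    return ds
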