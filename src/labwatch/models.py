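"""Six predictor families behind one train/predict contract.

Five sequence architectures — LSTM, 1-D CNN, dual-stream M-CNN, a
transformer with a learned time encoding, and a temporal convolutional
network (TCN) — share the same topology convention: the lab-value window
(W steps x C channels) flows through the sequence encoder, is concatenated
with the static demographic vector, and ends in a dense stack whose sigmoid
head emits one abnormality probability per lab channel.  The sixth family
is a gradient-boosting baseline (LightGBM), one binary booster per label on
the flattened window.

The public surface is statsmodels-shaped: :class:`LabForecaster` is built
from a :class:`~labwatch.windowing.SplitDataset` plus a :class:`ModelSpec`;
``fit()`` runs mini-batch Adam on binary cross-entropy with min-delta early
stopping on the validation loss and returns :class:`ForecastResults`, which
carries the training history and exposes ``predict_proba`` / ``classify`` /
``evaluate`` / ``summary``.  Thin functional wrappers (``build_model``,
``train_model``, ``fit_boosting``, ``predict_probabilities``, ``classify``)
cover the same ground for script use.

All randomness flows from explicit seeds; runs are single-threaded and
bitwise reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .nn.autodiff import Tensor, bce_with_logits, concat
from .windowing import Sample, SplitDataset

__all__ = [
    "ARCHITECTURES", "ModelSpec", "TrainConfig", "LabForecaster",
    "ForecastResults", "build_model", "train_model", "fit_boosting",
    "predict_probabilities", "classify", "time_encode",
]

ARCHITECTURES = ("lstm", "cnn", "mcnn", "transformer", "tcn", "gbm")

_DEFAULT_HP: dict[str, dict] = {
    "lstm": {"units": 64, "hidden": 64, "cell": "lstm"},
    "cnn": {"filters": 64, "kernel_size": 3, "hidden": 64},
    "mcnn": {"filters": 32, "kernel_sizes": (2, 4), "hidden": 64},
    "transformer": {"d_model": 32, "n_heads": 2, "time_width": 8,
                    "ff_mult": 2, "hidden": 64},
    "tcn": {"filters": 32, "kernel_size": 3, "dilations": (1, 2, 4),
            "hidden": 64},
    "gbm": {"n_rounds": 200, "learning_rate": 0.1, "max_depth": 6,
            "num_leaves": 31, "min_child_samples": 5},
}


@dataclass(frozen=True)
class ModelSpec:
    """Architecture name, hyperparameters and input/output shape."""

    architecture: str
    window: int
    n_channels: int
    n_demo: int = 3
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"expected one of {ARCHITECTURES}"
            )
        hp = self.resolved()
        for key in ("kernel_size",):
            if key in hp and hp[key] > self.window:
                raise ValueError("kernel size must not exceed the window")
        if "kernel_sizes" in hp and max(hp["kernel_sizes"]) > self.window:
            raise ValueError("kernel size must not exceed the window")

    def resolved(self) -> dict:
        hp = dict(_DEFAULT_HP[self.architecture])
        hp.update(self.hyperparameters)
        return hp


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults mirror the evaluation protocol
    (binary cross-entropy, early stopping with min-delta 0.01 over 10
    epochs, decision threshold 0.5)."""

    max_epochs: int = 40
    batch_size: int = 64
    learning_rate: float = 5e-3
    early_stopping_delta: float = 0.01
    patience: int = 10
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.early_stopping_delta < 0:
            raise ValueError("early_stopping_delta must be >= 0")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# network topologies
# ---------------------------------------------------------------------------

class _LSTMNet(nn.Module):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        hp = spec.resolved()
        self.rnn = nn.LSTM(spec.n_channels, hp["units"], rng)
        self.bn = nn.BatchNorm(hp["units"])
        self.fc1 = nn.Dense(hp["units"] + spec.n_demo, hp["hidden"], rng,
                            activation="relu")
        self.head = nn.Dense(hp["hidden"], spec.n_channels, rng)
        self.training = True

    def __call__(self, x: Tensor, demo: Tensor) -> Tensor:
        h = self.bn(self.rnn(x))
        return self.head(self.fc1(concat([h, demo], axis=1)))


class _CNNNet(nn.Module):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        hp = spec.resolved()
        self.conv = nn.Conv1D(spec.n_channels, hp["filters"],
                              hp["kernel_size"], rng, activation="leaky_relu")
        flat = spec.window * hp["filters"]
        self.fc1 = nn.Dense(flat + spec.n_demo, hp["hidden"], rng,
                            activation="relu")
        self.head = nn.Dense(hp["hidden"], spec.n_channels, rng)
        self.training = True

    def __call__(self, x: Tensor, demo: Tensor) -> Tensor:
        N = x.shape[0]
        z = self.conv(x).reshape(N, -1)
        return self.head(self.fc1(concat([z, demo], axis=1)))


class _MCNNNet(nn.Module):
    """Two parallel convolutional streams with different kernel sizes,
    capturing short- and longer-range temporal patterns; their flattened
    outputs merge before the dense head."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        hp = spec.resolved()
        self.streams = [
            nn.Conv1D(spec.n_channels, hp["filters"], k, rng,
                      activation="leaky_relu")
            for k in hp["kernel_sizes"]
        ]
        flat = spec.window * hp["filters"] * len(self.streams)
        self.fc1 = nn.Dense(flat + spec.n_demo, hp["hidden"], rng,
                            activation="relu")
        self.head = nn.Dense(hp["hidden"], spec.n_channels, rng)
        self.training = True

    def __call__(self, x: Tensor, demo: Tensor) -> Tensor:
        N = x.shape[0]
        zs = [s(x).reshape(N, -1) for s in self.streams]
        return self.head(self.fc1(concat(zs + [demo], axis=1)))


class _TransformerNet(nn.Module):
    """Self-attention over the window with a learned time embedding
    (linear + periodic components of the step index) concatenated to the
    inputs before attention."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        hp = spec.resolved()
        self.time_enc = nn.TimeEncoding(hp["time_width"], rng)
        n_in = spec.n_channels + hp["time_width"]
        d = hp["d_model"]
        self.proj = nn.Dense(n_in, d, rng)
        self.attn = nn.MultiHeadSelfAttention(d, d, hp["n_heads"], rng)
        self.ln1 = nn.LayerNorm(d)
        self.ff1 = nn.Dense(d, d * hp["ff_mult"], rng, activation="relu")
        self.ff2 = nn.Dense(d * hp["ff_mult"], d, rng)
        self.ln2 = nn.LayerNorm(d)
        flat = spec.window * d
        self.fc1 = nn.Dense(flat + spec.n_demo, hp["hidden"], rng,
                            activation="relu")
        self.head = nn.Dense(hp["hidden"], spec.n_channels, rng)
        self.training = True

    def __call__(self, x: Tensor, demo: Tensor) -> Tensor:
        N = x.shape[0]
        z = self.proj(self.time_enc(x))
        z = self.ln1(z + self.attn(z))
        z = self.ln2(z + self.ff2(self.ff1(z)))
        z = z.reshape(N, -1)
        return self.head(self.fc1(concat([z, demo], axis=1)))


class _TCNNet(nn.Module):
    """Stacked dilated causal convolutions; the receptive field grows
    exponentially with depth while every layer preserves sequence length."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        hp = spec.resolved()
        blocks = []
        n_in = spec.n_channels
        for d in hp["dilations"]:
            blocks.append(nn.TCNBlock(n_in, hp["filters"], hp["kernel_size"],
                                      d, rng))
            n_in = hp["filters"]
        self.blocks = blocks
        self.fc1 = nn.Dense(hp["filters"] + spec.n_demo, hp["hidden"], rng,
                            activation="relu")
        self.head = nn.Dense(hp["hidden"], spec.n_channels, rng)
        self.training = True

    def __call__(self, x: Tensor, demo: Tensor) -> Tensor:
        z = x
        for b in self.blocks:
            z = b(z)
        last = z[:, -1, :]
        return self.head(self.fc1(concat([last, demo], axis=1)))


_NETS = {"lstm": _LSTMNet, "cnn": _CNNNet, "mcnn": _MCNNNet,
         "transformer": _TransformerNet, "tcn": _TCNNet}


def build_model(spec: ModelSpec, seed: int = 0) -> nn.Module:
    """Instantiate an untrained network for a neural ``spec``."""
    if spec.architecture == "gbm":
        raise ValueError("gbm has no network; use fit_boosting/LabForecaster")
    rng = np.random.default_rng(seed)
    return _NETS[spec.architecture](spec, rng)


def time_encode(step_indices: np.ndarray, width: int = 8,
                seed: int = 0) -> np.ndarray:
    """Standalone learned-initialization time embedding (T, width).

    Column 0 is affine in the step index; the rest are sinusoids of learned
    affine arguments.  Exposed mainly for inspection and tests; inside the
    transformer the parameters train jointly with the network.
    """
    enc = nn.TimeEncoding(width, np.random.default_rng(seed))
    return enc.encode(np.asarray(step_indices)).data


# ---------------------------------------------------------------------------
# boosting baseline
# ---------------------------------------------------------------------------

class _DegenerateBooster:
    """Stand-in for a label that is constant in training: emits the prior."""

    def __init__(self, prior: float):
        self.prior = float(prior)

    def predict_proba(self, X):
        p = np.full((X.shape[0], 2), [1 - self.prior, self.prior])
        return p


def _flatten_inputs(X: np.ndarray, D: np.ndarray) -> np.ndarray:
    return np.concatenate([X.reshape(X.shape[0], -1), D], axis=1)


class _BoosterWrapper:
    """Binary LightGBM booster with a two-column predict_proba."""

    def __init__(self, booster):
        self.booster_ = booster

    def predict_proba(self, X):
        p = self.booster_.predict(X)
        return np.column_stack([1 - p, p])


def _fit_gbm_boosters(spec: ModelSpec, Xtr, Dtr, Ytr, seed: int):
    import lightgbm as lgb

    hp = spec.resolved()
    F = _flatten_inputs(Xtr, Dtr)
    params = {
        "objective": "binary",
        "learning_rate": hp["learning_rate"],
        "max_depth": hp["max_depth"],
        "num_leaves": hp["num_leaves"],
        "min_data_in_leaf": hp["min_child_samples"],
        "seed": seed,
        "deterministic": True,
        "num_threads": 1,
        "force_row_wise": True,
        "verbose": -1,
    }
    boosters, flags = [], []
    for j in range(Ytr.shape[1]):
        y = Ytr[:, j]
        if y.min() == y.max():
            boosters.append(_DegenerateBooster(y.mean()))
            flags.append(True)
            continue
        booster = lgb.train(params, lgb.Dataset(F, label=y),
                            num_boost_round=hp["n_rounds"])
        boosters.append(_BoosterWrapper(booster))
        flags.append(False)
    return boosters, flags


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class LabForecaster:
    """Next-step lab-abnormality forecaster built from a split dataset.

    Parameters
    ----------
    dataset : SplitDataset
        Windowed, shuffled and normalized samples.
    spec : ModelSpec or str
        Architecture specification; a bare name uses default
        hyperparameters sized to the dataset.
    train_config : TrainConfig, optional
    """

    def __init__(self, dataset: SplitDataset,
                 spec: ModelSpec | str = "mcnn",
                 train_config: TrainConfig | None = None):
        if isinstance(spec, str):
            spec = ModelSpec(architecture=spec, window=dataset.window,
                             n_channels=dataset.n_channels)
        if spec.window != dataset.window or spec.n_channels != dataset.n_channels:
            raise ValueError("spec shape does not match dataset")
        self.dataset = dataset
        self.spec = spec
        self.config = train_config or TrainConfig()

    def fit(self) -> "ForecastResults":
        if self.spec.architecture == "gbm":
            return self._fit_gbm()
        return self._fit_neural()

    # -- neural training ---------------------------------------------------
    def _fit_neural(self) -> "ForecastResults":
        cfg = self.config
        ds = self.dataset
        Xtr, Dtr, Ytr = ds.arrays("train")
        Xva, Dva, Yva = ds.arrays("validation")
        if len(Xtr) == 0:
            raise ValueError("training partition is empty")
        has_val = len(Xva) > 0
        ss = np.random.SeedSequence(cfg.seed)
        init_seed, shuffle_seed = ss.spawn(2)
        net = _NETS[self.spec.architecture](
            self.spec, np.random.default_rng(init_seed))
        opt = nn.Adam(net.parameters(), lr=cfg.learning_rate)
        rng = np.random.default_rng(shuffle_seed)

        history: list[dict] = []
        best_val = None
        stale = 0
        n = Xtr.shape[0]
        for epoch in range(1, cfg.max_epochs + 1):
            net.set_training(True)
            perm = rng.permutation(n)
            total, count = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = perm[start:start + cfg.batch_size]
                xb, db = Tensor(Xtr[idx]), Tensor(Dtr[idx])
                loss = bce_with_logits(net(xb, db), Ytr[idx])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"NaN loss at epoch {epoch}, batch {start // cfg.batch_size}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.data) * len(idx)
                count += len(idx)
            train_loss = total / count

            net.set_training(False)
            if has_val:
                val_logits = self._forward_batched(net, Xva, Dva)
                val_loss = float(bce_with_logits(
                    Tensor(val_logits), Yva).data)
                val_prob = _sigmoid(val_logits)
                val_pred = (val_prob > cfg.threshold).astype(np.uint8)
                acc, f1 = _micro_acc_f1(val_pred, Yva)
            else:
                val_loss, acc, f1 = train_loss, np.nan, np.nan
            history.append({"epoch": epoch, "train_loss": train_loss,
                            "val_loss": val_loss, "val_accuracy": acc,
                            "val_f1": f1})
            # min-delta early stopping over the running best
            if best_val is not None and best_val - val_loss >= cfg.early_stopping_delta:
                stale = 0
            else:
                stale += 1
            if best_val is None or val_loss < best_val:
                best_val = val_loss
            if stale >= cfg.patience:
                break

        net.set_training(False)
        return ForecastResults(spec=self.spec, config=cfg, dataset=ds,
                               network=net,
                               history=pd.DataFrame(history))

    @staticmethod
    def _forward_batched(net, X, D, batch: int = 512) -> np.ndarray:
        outs = []
        for start in range(0, X.shape[0], batch):
            outs.append(net(Tensor(X[start:start + batch]),
                            Tensor(D[start:start + batch])).data)
        return np.concatenate(outs, axis=0) if outs else np.empty((0, 0))

    # -- boosting ----------------------------------------------------------
    def _fit_gbm(self) -> "ForecastResults":
        cfg = self.config
        ds = self.dataset
        Xtr, Dtr, Ytr = ds.arrays("train")
        boosters, flags = _fit_gbm_boosters(self.spec, Xtr, Dtr, Ytr, cfg.seed)
        res = ForecastResults(spec=self.spec, config=cfg, dataset=ds,
                              boosters=boosters, degenerate_labels=flags,
                              history=pd.DataFrame())
        # one-row history: training/validation loss of the fitted ensemble
        rows = {"epoch": 1}
        for part, (X, D, Y) in (("train", (Xtr, Dtr, Ytr)),
                                ("val", ds.arrays("validation"))):
            if len(X):
                p = res.predict_proba(X, D)
                eps = 1e-12
                rows[f"{part}_loss"] = float(-np.mean(
                    Y * np.log(p + eps) + (1 - Y) * np.log(1 - p + eps)))
        res.history = pd.DataFrame([rows])
        return res


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                    np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))


def _micro_acc_f1(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    total = tp + fp + fn + tn
    acc = (tp + tn) / total if total else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, f1


@dataclass
class ForecastResults:
    """Fitted forecaster: parameters, history, prediction interface."""

    spec: ModelSpec
    config: TrainConfig
    dataset: SplitDataset
    history: pd.DataFrame
    network: nn.Module | None = None
    boosters: list | None = None
    degenerate_labels: list[bool] | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.history)

    def predict_proba(self, X: np.ndarray, D: np.ndarray) -> np.ndarray:
        """Probability matrix (n, C) for normalized arrays."""
        if X.shape[0] == 0:
            return np.empty((0, self.spec.n_channels))
        if X.shape[1:] != (self.spec.window, self.spec.n_channels):
            raise ValueError(
                f"input shape {X.shape[1:]} does not match spec "
                f"({self.spec.window}, {self.spec.n_channels})")
        if self.network is not None:
            self.network.set_training(False)
            logits = LabForecaster._forward_batched(self.network, X, D)
            return _sigmoid(logits)
        F = _flatten_inputs(X, D)
        return np.column_stack([b.predict_proba(F)[:, 1] for b in self.boosters])

    def predict_samples(self, samples: list[Sample]) -> np.ndarray:
        """Probabilities for raw samples, normalized with training stats."""
        if not samples:
            return np.empty((0, self.spec.n_channels))
        X, D, _ = self.dataset.normalize(samples)
        return self.predict_proba(X, D)

    def classify(self, probabilities: np.ndarray,
                 threshold: float | None = None) -> np.ndarray:
        return classify(probabilities,
                        self.config.threshold if threshold is None else threshold)

    def evaluate(self, partition_or_samples="test"):
        """MetricsReport on a named partition or an explicit sample list."""
        from .evaluation import confusion_counts, micro_metrics

        if isinstance(partition_or_samples, str):
            X, D, Y = self.dataset.arrays(partition_or_samples)
        else:
            X, D, Y = self.dataset.normalize(partition_or_samples)
        pred = self.classify(self.predict_proba(X, D))
        return micro_metrics(confusion_counts(pred, Y))

    def summary(self) -> str:
        lines = [
            "Lab abnormality forecast results",
            "=" * 40,
            f"architecture:       {self.spec.architecture}",
            f"window (steps):     {self.spec.window}",
            f"lab channels:       {self.spec.n_channels}",
            f"threshold:          {self.config.threshold}",
        ]
        if self.network is not None:
            lines.append(f"parameters:         {self.network.n_parameters()}")
            lines.append(f"epochs trained:     {self.n_epochs}")
            if self.n_epochs:
                last = self.history.iloc[-1]
                lines.append(f"final train loss:   {last['train_loss']:.4f}")
                lines.append(f"final val loss:     {last['val_loss']:.4f}")
                lines.append(f"final val micro-F1: {last['val_f1']:.4f}")
        else:
            n_deg = sum(self.degenerate_labels)
            lines.append(f"boosters fitted:    {len(self.boosters)}"
                         + (f" ({n_deg} degenerate)" if n_deg else ""))
        if self.dataset.test:
            rep = self.evaluate("test")
            lines.append(
                f"test micro metrics: acc={rep.accuracy:.4f} "
                f"prec={rep.precision:.4f} rec={rep.recall:.4f} "
                f"f1={rep.f1:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def train_model(dataset: SplitDataset, spec: ModelSpec | str,
                train_config: TrainConfig | None = None) -> ForecastResults:
    """Fit any architecture (neural or gbm) on a dataset."""
    return LabForecaster(dataset, spec, train_config).fit()


def fit_boosting(dataset: SplitDataset,
                 gbm_config: dict | None = None,
                 train_config: TrainConfig | None = None) -> ForecastResults:
    """Fit the per-label gradient-boosting baseline."""
    spec = ModelSpec("gbm", dataset.window, dataset.n_channels,
                     hyperparameters=gbm_config or {})
    return LabForecaster(dataset, spec, train_config).fit()


def predict_probabilities(results: ForecastResults,
                          samples: list[Sample]) -> np.ndarray:
    return results.predict_samples(samples)


def classify(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary decisions: 1 iff probability strictly exceeds the threshold."""
    p = np.asarray(probabilities)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return (p > threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# checkpointing: parameter arrays + JSON spec sidecar
# ---------------------------------------------------------------------------

def save_results(results: ForecastResults, out_dir) -> None:
    """Persist a fitted model: spec/config JSON, parameters, history CSV."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "spec": dataclasses.asdict(results.spec),
        "config": dataclasses.asdict(results.config),
        "kind": "gbm" if results.boosters is not None else "neural",
    }
    (out / "spec.json").write_text(json.dumps(sidecar, indent=2, default=list))
    results.history.to_csv(out / "history.csv", index=False)
    if results.network is not None:
        params = {f"p{i}": p.data
                  for i, p in enumerate(results.network.parameters())}
        np.savez(out / "weights.npz", **params)
    else:
        texts, priors = [], []
        for b, deg in zip(results.boosters, results.degenerate_labels):
            if deg:
                texts.append("")
                priors.append(b.prior)
            else:
                texts.append(b.booster_.model_to_string())
                priors.append(-1.0)
        (out / "boosters.json").write_text(json.dumps(
            {"models": texts, "priors": priors}))


def load_results(in_dir, dataset: SplitDataset) -> ForecastResults:
    """Rebuild a fitted model saved by :func:`save_results`."""
    import json
    from pathlib import Path

    src = Path(in_dir)
    sidecar = json.loads((src / "spec.json").read_text())
    spec_d = sidecar["spec"]
    spec_d["hyperparameters"] = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in spec_d["hyperparameters"].items()}
    spec = ModelSpec(**spec_d)
    cfg = TrainConfig(**sidecar["config"])
    history = pd.read_csv(src / "history.csv")
    if sidecar["kind"] == "neural":
        net = _NETS[spec.architecture](spec, np.random.default_rng(0))
        with np.load(src / "weights.npz") as z:
            for i, p in enumerate(net.parameters()):
                p.data = z[f"p{i}"].copy()
        net.set_training(False)
        return ForecastResults(spec=spec, config=cfg, dataset=dataset,
                               history=history, network=net)
    import lightgbm as lgb

    blob = json.loads((src / "boosters.json").read_text())
    boosters, flags = [], []
    for text, prior in zip(blob["models"], blob["priors"]):
        if text == "":
            boosters.append(_DegenerateBooster(prior))
            flags.append(True)
        else:
            boosters.append(_BoosterWrapper(lgb.Booster(model_str=text)))
            flags.append(False)
    return ForecastResults(spec=spec, config=cfg, dataset=dataset,
                           history=history, boosters=boosters,
                           degenerate_labels=flags)
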