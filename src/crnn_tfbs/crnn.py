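"""The convolutional-recurrent binding classifier, statsmodels-style.

:class:`BindingClassifier` is the model object: construct it from a
:class:`~crnn_tfbs.crnn.ModelConfig`, call :meth:`fit` with labelled
train/validation datasets and get a :class:`BindingFitResults` carrying the
training history, the validation ROC-AUC and a ``summary()`` table.
Prediction maps fixed-length DNA sequences to binding scores in [0, 1];
scores above 0.5 denote a positive binding prediction.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from crnn_tfbs._network import Adam, CRNNetwork, apply_max_norm
from crnn_tfbs.errors import ConfigError, DivergenceError, InputError, ModelIOError
from crnn_tfbs.negatives import LabelledDataset, split_dataset
from crnn_tfbs.seqio import SequenceRecord, one_hot_encode

MODEL_FORMAT_VERSION = "crnn-tfbs-model-v1"


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameter bundle for the classifier.

    Defaults were selected by validation ROC-AUC on the package's default
    synthetic study conditions (see docs/methods.md): a 64-filter
    convolution (kernel 8 nt, stride-1 feature sequence, pool width 1)
    feeding a bidirectional LSTM whose final hidden states pass through a
    regularized dense layer to a single logistic output.
    """

    use_conv: bool = True
    conv_kernels: int = 64
    kernel_len: int = 8
    pool_size: int = 1
    conv_dropout: float = 0.1
    rnn_units: int = 48
    bidirectional: bool = True
    dense_units: int = 96
    dense_dropout: float = 0.25
    max_norm: float = 3.0
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 15
    input_length: int = 20
    rnn_cell: str = "lstm"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conv_dropout", "dense_dropout"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        if self.max_norm <= 0:
            raise ConfigError("max_norm must be > 0")
        if self.use_conv and self.kernel_len > self.input_length:
            raise ConfigError(
                f"kernel_len {self.kernel_len} > input_length {self.input_length}"
            )
        if self.rnn_cell != "lstm":
            raise ConfigError(f"unsupported recurrent cell {self.rnn_cell!r}")
        for name in (
            "conv_kernels", "kernel_len", "pool_size", "rnn_units", "dense_units",
            "batch_size", "max_epochs", "patience", "input_length",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)


def _encode_batch(seqs: Sequence[str], input_length: int, ids=None) -> np.ndarray:
    wrong = [
        (ids[i] if ids is not None else str(i))
        for i, s in enumerate(seqs)
        if len(s) != input_length
    ]
    if wrong:
        raise InputError(
            f"sequences must have length {input_length}; offending ids: "
            f"{wrong[:10]}{'...' if len(wrong) > 10 else ''}"
        )
    X = np.empty((len(seqs), input_length, 4))
    for i, s in enumerate(seqs):
        X[i] = one_hot_encode(s)
    return X


@dataclass
class BindingFitResults:
    """Fit results: history, selection metric, and a summary table."""

    model: "BindingClassifier"
    config: ModelConfig
    history: list[dict[str, float]]
    validation_auc: float
    best_epoch: int
    n_parameters: int

    def predict(self, seqs) -> np.ndarray:
        return self.model.predict(seqs)

    def summary(self) -> str:
        cfg = self.config
        arch = []
        if cfg.use_conv:
            arch.append(
                f"conv({cfg.conv_kernels}x{cfg.kernel_len}, relu) -> "
                f"maxpool({cfg.pool_size}) -> dropout({cfg.conv_dropout})"
            )
        arch.append(
            f"{'bi-' if cfg.bidirectional else ''}lstm({cfg.rnn_units})"
        )
        arch.append(f"dense({cfg.dense_units}, relu, dropout {cfg.dense_dropout})")
        arch.append("logistic(1)")
        lines = [
            "Binding classifier fit",
            "=" * 60,
            f"architecture       : {' -> '.join(arch)}",
            f"parameters         : {self.n_parameters}",
            f"epochs run         : {len(self.history)} (best epoch {self.best_epoch})",
            f"final train loss   : {self.history[-1]['train_loss']:.4f}",
            f"best val loss      : {min(h['val_loss'] for h in self.history):.4f}",
            f"validation ROC-AUC : {self.validation_auc:.4f}",
            f"seed               : {cfg.seed}",
            "=" * 60,
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        self.model.save(path)


class BindingClassifier:
    """CNN+BiLSTM sequence classifier mapping L-mers to scores in [0, 1]."""

    def __init__(self, config: ModelConfig | None = None) -> None:
        self.config = config or ModelConfig()
        self.network = CRNNetwork(self.config)
        self.fitted = False
        self.results_: BindingFitResults | None = None

    @property
    def n_parameters(self) -> int:
        return self.network.n_parameters

    # -- training ----------------------------------------------------------

    def fit(
        self,
        train_set: LabelledDataset,
        val_set: LabelledDataset,
    ) -> BindingFitResults:
        """Minimize binary cross-entropy with Adam and early stopping.

        Early stopping monitors validation loss with the configured
        patience and restores the best epoch's parameters; the per-epoch
        history and the final validation ROC-AUC are recorded.
        """
        from crnn_tfbs.evaluate import roc_auc

        if len(train_set) == 0:
            raise InputError("training set is empty")
        cfg = self.config
        for ds, name in ((train_set, "training"), (val_set, "validation")):
            for rec, _ in ds.records:
                if "N" in rec.seq:
                    raise InputError(f"{name} record {rec.id!r} contains N")
        X_train = _encode_batch(
            train_set.sequences(), cfg.input_length,
            [r.id for r, _ in train_set.records],
        )
        y_train = train_set.labels().astype(float)
        X_val = _encode_batch(
            val_set.sequences(), cfg.input_length, [r.id for r, _ in val_set.records]
        )
        y_val = val_set.labels().astype(float)

        rng = np.random.default_rng(cfg.seed + 1)
        net = self.network
        adam = Adam(net.params, lr=cfg.learning_rate)
        history: list[dict[str, float]] = []
        best_val = np.inf
        best_params = copy.deepcopy(net.params)
        best_epoch = 0
        bad_epochs = 0
        stale = 0  # epochs since last improvement, for LR decay

        for epoch in range(1, cfg.max_epochs + 1):
            perm = rng.permutation(len(y_train))
            batch_losses = []
            for lo in range(0, len(perm), cfg.batch_size):
                idx = perm[lo : lo + cfg.batch_size]
                prob, cache = net.forward(X_train[idx], train=True, rng=rng)
                loss = net.loss(prob, y_train[idx])
                if not np.isfinite(loss):
                    raise DivergenceError(f"non-finite loss at epoch {epoch}")
                grads = net.backward(cache, y_train[idx])
                adam.step(net.params, grads)
                apply_max_norm(net.params, cfg.max_norm)
                batch_losses.append(loss)
            val_prob = net.predict_proba(X_val, cfg.batch_size)
            val_loss = net.loss(val_prob, y_val)
            val_auc = roc_auc(val_prob[y_val == 1], val_prob[y_val == 0]).auc
            history.append(
                {
                    "epoch": epoch,
                    "train_loss": float(np.mean(batch_losses)),
                    "val_loss": val_loss,
                    "val_auc": val_auc,
                }
            )
            if val_loss < best_val:
                best_val = val_loss
                best_params = copy.deepcopy(net.params)
                best_epoch = epoch
                bad_epochs = 0
                stale = 0
            else:
                bad_epochs += 1
                stale += 1
                if bad_epochs >= cfg.patience:
                    break
                # halve the learning rate on a 3-epoch validation plateau;
                # sharpens late-stage convergence without touching the
                # early-stopping contract
                if stale >= 3:
                    adam.lr *= 0.5
                    stale = 0

        net.params = best_params
        val_prob = net.predict_proba(X_val, cfg.batch_size)
        validation_auc = roc_auc(val_prob[y_val == 1], val_prob[y_val == 0]).auc
        self.fitted = True
        self.results_ = BindingFitResults(
            model=self,
            config=cfg,
            history=history,
            validation_auc=validation_auc,
            best_epoch=best_epoch,
            n_parameters=net.n_parameters,
        )
        return self.results_

    # -- inference ---------------------------------------------------------

    def predict(self, seqs: Sequence[SequenceRecord] | Sequence[str]) -> np.ndarray:
        """Binding scores in [0, 1], one per sequence, order-preserving."""
        if len(seqs) == 0:
            return np.empty(0)
        if isinstance(seqs[0], SequenceRecord):
            ids = [r.id for r in seqs]  # type: ignore[union-attr]
            raw = [r.seq for r in seqs]  # type: ignore[union-attr]
        else:
            ids = None
            raw = [str(s).upper() for s in seqs]
        X = _encode_batch(raw, self.config.input_length, ids)
        return self.network.predict_proba(X, self.config.batch_size)

    def score_windows(self, windows: Sequence[str]) -> np.ndarray:
        """Scorer interface for :func:`crnn_tfbs.genome_scan.scan_sequence`."""
        return self.predict(windows)

    def filter_motif_summary(
        self, seqs: Sequence[str], consensus: str, top: int = 100
    ) -> dict:
        """Diagnostic: does the strongest convolution filter see the motif?

        Takes the ``top`` highest-activating length-``kernel_len`` windows
        of the filter with the largest peak activation over ``seqs``, forms
        their per-position majority string, and reports the best gapless
        identity of that string against ``consensus`` (either strand of the
        windows is not considered; training reads are single-stranded).
        Logged as a training diagnostic, not asserted anywhere.
        """
        cfg = self.config
        if not cfg.use_conv:
            raise InputError("model has no convolutional layer")
        from crnn_tfbs.seqio import BASES, one_hot_encode

        k = cfg.kernel_len
        windows: list[str] = []
        acts: list[float] = []
        Wc = self.network.params["Wc"]
        bc = self.network.params["bc"]
        for s in seqs:
            s = str(s).upper()
            X = one_hot_encode(s)
            cols = np.lib.stride_tricks.sliding_window_view(X, (k, 4), axis=(0, 1))
            cols = cols.reshape(-1, k * 4)
            z = cols @ Wc + bc  # (T, K)
            for t in range(z.shape[0]):
                windows.append(s[t : t + k])
                acts.append(float(z[t].max()))
        order = np.argsort(acts)[::-1][:top]
        chosen = [windows[i] for i in order]
        counts = np.zeros((4, k))
        for w in chosen:
            for i, c in enumerate(w):
                if c in BASES:
                    counts[BASES.index(c), i] += 1
        majority = "".join(BASES[int(i)] for i in counts.argmax(axis=0))
        # best gapless alignment of the majority string onto the consensus
        best = 0.0
        m, c = majority, consensus.upper()
        for off in range(-(len(m) - 1), len(c)):
            matches = sum(
                1
                for i, ch in enumerate(m)
                if 0 <= off + i < len(c) and c[off + i] == ch
            )
            best = max(best, matches / min(len(m), len(c)))
        return {
            "majority_window": majority,
            "identity_to_consensus": best,
            "n_windows_considered": len(chosen),
        }

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Persist to a directory: config manifest, parameter blob, history."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format": MODEL_FORMAT_VERSION,
            "fitted": self.fitted,
            "config": dataclasses.asdict(self.config),
        }
        (path / "config.json").write_text(json.dumps(manifest, indent=2))
        np.savez(path / "params.npz", **self.network.params)
        if self.results_ is not None:
            with open(path / "history.tsv", "w") as fh:
                fh.write("epoch\ttrain_loss\tval_loss\tval_auc\n")
                for h in self.results_.history:
                    fh.write(
                        f"{int(h['epoch'])}\t{h['train_loss']:.6f}\t"
                        f"{h['val_loss']:.6f}\t{h['val_auc']:.6f}\n"
                    )


def load_model(path) -> BindingClassifier:
    """Load a persisted classifier; predictions round-trip to 1e-6."""
    path = Path(path)
    try:
        manifest = json.loads((path / "config.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelIOError(f"cannot read model manifest at {path}: {exc}") from exc
    if manifest.get("format") != MODEL_FORMAT_VERSION:
        raise ModelIOError(
            f"incompatible model format {manifest.get('format')!r}; "
            f"expected {MODEL_FORMAT_VERSION}"
        )
    config = ModelConfig(**manifest["config"])
    model = BindingClassifier(config)
    try:
        with np.load(path / "params.npz") as blob:
            params = {k: blob[k] for k in blob.files}
    except Exception as exc:  # numpy raises BadZipFile/ValueError/OSError
        raise ModelIOError(f"cannot read parameter blob at {path}: {exc}") from exc
    expected = set(model.network.params)
    if set(params) != expected:
        raise ModelIOError(
            f"parameter blob keys {sorted(params)} do not match architecture "
            f"{sorted(expected)}"
        )
    for k, v in params.items():
        if v.shape != model.network.params[k].shape:
            raise ModelIOError(f"parameter {k} has shape {v.shape}, expected "
                               f"{model.network.params[k].shape}")
    model.network.params = params
    model.fitted = bool(manifest.get("fitted", False))
    return model


# ---------------------------------------------------------------------------
# Hyperparameter selection and consistency


@dataclass
class HyperparameterSearchResult:
    """Per-config validation AUCs and the selected configuration."""

    table: list[tuple[ModelConfig, float]]
    best_config: ModelConfig
    best_results: BindingFitResults


def grid_search(
    grid: Sequence[ModelConfig],
    train_set: LabelledDataset,
    val_set: LabelledDataset,
) -> HyperparameterSearchResult:
    """Train every config on a shared split; select by validation ROC-AUC.

    Ties break toward fewer parameters, then the lower seed. All configs are
    validated (constructed) before any training starts, so a bad grid fails
    fast.
    """
    if not grid:
        raise InputError("hyperparameter grid is empty")
    models = [BindingClassifier(cfg) for cfg in grid]  # validates every config
    table: list[tuple[ModelConfig, float]] = []
    fits: list[BindingFitResults] = []
    for model in models:
        res = model.fit(train_set, val_set)
        table.append((model.config, res.validation_auc))
        fits.append(res)
    order = sorted(
        range(len(grid)),
        key=lambda i: (-table[i][1], models[i].n_parameters, grid[i].seed),
    )
    best = order[0]
    return HyperparameterSearchResult(
        table=table, best_config=grid[best], best_results=fits[best]
    )


@dataclass
class ConsistencySummary:
    """Test-subset AUCs over repeated re-splits of one dataset."""

    aucs: list[float]
    mean: float
    sd: float
    min: float
    max: float


def consistency_check(
    config: ModelConfig,
    dataset: LabelledDataset,
    repeats: int = 100,
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    base_seed: int = 0,
) -> ConsistencySummary:
    """Re-split, retrain and re-test ``repeats`` times.

    Each repeat splits the dataset with seed ``base_seed + i`` and reports
    the ROC-AUC on its own test subset, probing the stability of a chosen
    hyperparameter set under resampling.
    """
    from crnn_tfbs.evaluate import roc_auc

    if repeats < 2:
        raise InputError("repeats must be >= 2")
    aucs = []
    for i in range(repeats):
        train, val, test = split_dataset(dataset, ratios, seed=base_seed + i)
        model = BindingClassifier(config)
        model.fit(train, val)
        scores = model.predict([rec for rec, _ in test.records])
        y = test.labels()
        aucs.append(roc_auc(scores[y == 1], scores[y == 0]).auc)
    arr = np.array(aucs)
    return ConsistencySummary(
        aucs=aucs,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        min=float(arr.min()),
        max=float(arr.max()),
    )
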