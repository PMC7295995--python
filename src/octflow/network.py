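"""SNR-stratified bank of 1D convolutional velocity classifiers.

Architecture (for a 128-sample input): one convolutional layer with 128
one-dimensional kernels of length 32 (valid convolution, output length 97),
ReLU, max pooling of length 4 and stride 4, then three fully connected layers
(1024, 256, n_classes) with ReLU between them and a softmax output.  The
softmax output is read as a velocity likelihood curve over the training grid.

The network is implemented directly on NumPy (im2col convolution + BLAS
matmuls) and trained with mini-batch SGD with momentum on the softmax
cross-entropy.  Because intensity time series are short and the feature
extractor is a single convolution, this stays fast enough for CPU training at
reduced library scale.

The classifier follows the scikit-learn estimator protocol (``fit`` /
``predict`` / ``predict_proba`` / ``get_params``), so it composes with
sklearn model-selection utilities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import ConfigurationError, IncompleteBankError, NormalizationError
from .simulator import SignalLibrary, VelocityGrid

__all__ = [
    "NetworkArchitecture",
    "TrainingConfig",
    "VelocityTimeSeriesClassifier",
    "NetworkBank",
    "InferenceResult",
    "build_network",
    "train_network",
    "train_bank",
    "infer_likelihood",
    "RELIABILITY_FLOOR_DB",
]

#: below this estimated SNR the framework cannot reliably estimate flow;
#: inference still runs (clamped to the lowest trained network) but results
#: are flagged unreliable.
RELIABILITY_FLOOR_DB = 4.0


@dataclass(frozen=True)
class NetworkArchitecture:
    input_len: int = 128
    conv_kernels: int = 128
    kernel_len: int = 32
    pool_len: int = 4
    pool_stride: int = 4
    hidden_sizes: tuple[int, int] = (1024, 256)
    n_output_classes: int = 64

    @property
    def conv_out_len(self) -> int:
        # valid (unpadded) convolution
        return self.input_len - self.kernel_len + 1

    @property
    def pooled_len(self) -> int:
        return (self.conv_out_len - self.pool_len) // self.pool_stride + 1

    @property
    def n_features(self) -> int:
        return self.pooled_len * self.conv_kernels

    @property
    def n_parameters(self) -> int:
        n = self.conv_kernels * (self.kernel_len + 1)
        sizes = (self.n_features, *self.hidden_sizes, self.n_output_classes)
        for a, b in zip(sizes[:-1], sizes[1:]):
            n += (a + 1) * b
        return n


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 0.01
    momentum: float = 0.9
    seed: int = 0
    early_stopping: bool = True
    patience: int = 4

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _check_normalized(X: np.ndarray) -> None:
    m = X.mean(axis=1)
    if not np.allclose(m, 1.0, atol=1e-3):
        raise NormalizationError(
            "input records must be self-normalized to unity mean"
        )


class VelocityTimeSeriesClassifier(BaseEstimator, ClassifierMixin):
    """1D-CNN classifier mapping a normalized intensity series to a velocity
    likelihood curve.

    Parameters mirror :class:`NetworkArchitecture` and
    :class:`TrainingConfig`; all state learned by ``fit`` is stored in
    trailing-underscore attributes.
    """

    def __init__(self, input_len=128, conv_kernels=128, kernel_len=32,
                 pool_len=4, pool_stride=4, hidden_sizes=(1024, 256),
                 epochs=30, batch_size=128, learning_rate=0.01, momentum=0.9,
                 seed=0, early_stopping=True, patience=4):
        self.input_len = input_len
        self.conv_kernels = conv_kernels
        self.kernel_len = kernel_len
        self.pool_len = pool_len
        self.pool_stride = pool_stride
        self.hidden_sizes = hidden_sizes
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.seed = seed
        self.early_stopping = early_stopping
        self.patience = patience

    # -- construction ------------------------------------------------------

    def architecture(self, n_classes: int) -> NetworkArchitecture:
        return NetworkArchitecture(
            input_len=self.input_len, conv_kernels=self.conv_kernels,
            kernel_len=self.kernel_len, pool_len=self.pool_len,
            pool_stride=self.pool_stride, hidden_sizes=tuple(self.hidden_sizes),
            n_output_classes=n_classes,
        )

    def initialize(self, n_classes: int) -> "VelocityTimeSeriesClassifier":
        """He-initialize all weights for ``n_classes`` outputs (seeded)."""
        arch = self.architecture(n_classes)
        rng = np.random.default_rng(self.seed)
        self.classes_ = np.arange(n_classes)
        self.arch_ = arch
        self.conv_w_ = (rng.standard_normal((arch.kernel_len, arch.conv_kernels))
                        * np.sqrt(2.0 / arch.kernel_len)).astype(np.float32)
        self.conv_b_ = np.zeros(arch.conv_kernels, dtype=np.float32)
        sizes = (arch.n_features, *arch.hidden_sizes, n_classes)
        self.fc_w_ = [
            (rng.standard_normal((a, b)) * np.sqrt(2.0 / a)).astype(np.float32)
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.fc_b_ = [np.zeros(b, dtype=np.float32) for b in sizes[1:]]
        self.history_ = {"loss": [], "val_accuracy": []}
        return self

    @property
    def n_parameters_(self) -> int:
        check_is_fitted(self, "arch_")
        return self.arch_.n_parameters

    # -- forward / backward ------------------------------------------------

    def _cols(self, X: np.ndarray) -> np.ndarray:
        # (n, conv_out_len, kernel_len) sliding windows
        return np.lib.stride_tricks.sliding_window_view(
            X, self.kernel_len, axis=1)

    def _forward(self, X: np.ndarray, want_cache: bool = False):
        arch = self.arch_
        n = X.shape[0]
        cols = np.ascontiguousarray(self._cols(X), dtype=np.float32)
        conv = cols.reshape(n * arch.conv_out_len, arch.kernel_len) @ self.conv_w_
        conv = conv.reshape(n, arch.conv_out_len, arch.conv_kernels) + self.conv_b_
        relu0 = np.maximum(conv, 0.0)
        usable = arch.pooled_len * arch.pool_stride
        pool_in = relu0[:, :usable, :].reshape(
            n, arch.pooled_len, arch.pool_stride, arch.conv_kernels)
        pool_idx = pool_in.argmax(axis=2)
        pooled = np.take_along_axis(pool_in, pool_idx[:, :, None, :], axis=2)[:, :, 0, :]
        h = pooled.reshape(n, arch.n_features)
        acts = [h]
        for i, (w, b) in enumerate(zip(self.fc_w_, self.fc_b_)):
            h = h @ w + b
            if i < len(self.fc_w_) - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        probs = _softmax(h.astype(np.float64))
        if not want_cache:
            return probs
        return probs, (cols, relu0, pool_idx, acts)

    def _backward_step(self, X, y, lr, vel):
        arch = self.arch_
        n = X.shape[0]
        probs, (cols, relu0, pool_idx, acts) = self._forward(X, want_cache=True)
        loss = -np.log(probs[np.arange(n), y] + 1e-12).mean()
        d = probs.astype(np.float32)
        d[np.arange(n), y] -= 1.0
        d /= n
        grads_w, grads_b = [None] * len(self.fc_w_), [None] * len(self.fc_b_)
        for i in range(len(self.fc_w_) - 1, -1, -1):
            a_in = acts[i]
            grads_w[i] = a_in.T @ d
            grads_b[i] = d.sum(axis=0)
            d = d @ self.fc_w_[i].T
            if i > 0:
                d *= (acts[i] > 0)
        # through pooling/relu to conv weights
        dpool = d.reshape(n, arch.pooled_len, arch.conv_kernels)
        dconv = np.zeros_like(relu0)
        usable = arch.pooled_len * arch.pool_stride
        dpin = dconv[:, :usable, :].reshape(
            n, arch.pooled_len, arch.pool_stride, arch.conv_kernels)
        np.put_along_axis(dpin, pool_idx[:, :, None, :], dpool[:, :, None, :], axis=2)
        dconv[:, :usable, :] = dpin.reshape(n, usable, arch.conv_kernels)
        dconv *= (relu0 > 0)
        dflat = dconv.reshape(n * arch.conv_out_len, arch.conv_kernels)
        gcw = cols.reshape(n * arch.conv_out_len, arch.kernel_len).T @ dflat
        gcb = dflat.sum(axis=0)
        params = [self.conv_w_, self.conv_b_] + self.fc_w_ + self.fc_b_
        grads = [gcw, gcb] + grads_w + grads_b
        for p, g, v in zip(params, grads, vel):
            v *= self.momentum
            v -= lr * g
            p += v
        return loss

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, validation_data=None):
        """Train on self-normalized records ``X`` with class labels ``y``.

        ``validation_data=(X_val, y_val)`` enables per-epoch held-out
        accuracy tracking and (if ``early_stopping``) keeps the best-epoch
        weights, stopping once validation accuracy has not improved for
        ``patience`` epochs.
        """
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != self.input_len:
            raise ConfigurationError(
                f"expected input of length {self.input_len}, got {X.shape}")
        _check_normalized(X)
        classes, y_idx = np.unique(y, return_inverse=True)
        self.initialize(len(classes))
        self.classes_ = classes
        rng = np.random.default_rng(self.seed + 1)
        vel = [np.zeros_like(p) for p in
               [self.conv_w_, self.conv_b_] + self.fc_w_ + self.fc_b_]
        has_val = validation_data is not None
        if has_val:
            Xv = np.asarray(validation_data[0], dtype=np.float32)
            _check_normalized(Xv)
            yv = np.searchsorted(classes, np.asarray(validation_data[1]))
        best_acc, best_state, stall = -1.0, None, 0
        for _epoch in range(self.epochs):
            order = rng.permutation(X.shape[0])
            losses = []
            for start in range(0, X.shape[0], self.batch_size):
                idx = order[start:start + self.batch_size]
                losses.append(self._backward_step(X[idx], y_idx[idx],
                                                  self.learning_rate, vel))
            self.history_["loss"].append(float(np.mean(losses)))
            if has_val:
                acc = float(np.mean(self._predict_idx(Xv) == yv))
                self.history_["val_accuracy"].append(acc)
                if acc > best_acc + 1e-4:
                    best_acc, stall = acc, 0
                    best_state = [p.copy() for p in
                                  [self.conv_w_, self.conv_b_] + self.fc_w_ + self.fc_b_]
                else:
                    stall += 1
                if self.early_stopping and stall >= self.patience:
                    break
        if has_val and best_state is not None:
            self.conv_w_, self.conv_b_ = best_state[0], best_state[1]
            nw = len(self.fc_w_)
            self.fc_w_ = best_state[2:2 + nw]
            self.fc_b_ = best_state[2 + nw:]
        return self

    def _predict_idx(self, X: np.ndarray, chunk: int = 2048) -> np.ndarray:
        out = np.empty(X.shape[0], dtype=np.int64)
        for s in range(0, X.shape[0], chunk):
            out[s:s + chunk] = self._forward(X[s:s + chunk]).argmax(axis=1)
        return out

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "conv_w_")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.input_len:
            raise ConfigurationError(
                f"expected input of length {self.input_len}, got {X.shape[1]}")
        chunks = [self._forward(X[s:s + 2048]) for s in range(0, X.shape[0], 2048)]
        return np.concatenate(chunks) if chunks else np.empty((0, len(self.classes_)))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        check_is_fitted(self, "conv_w_")
        arrays = {"conv_w": self.conv_w_, "conv_b": self.conv_b_,
                  "classes": self.classes_}
        for i, (w, b) in enumerate(zip(self.fc_w_, self.fc_b_)):
            arrays[f"fc_w{i}"] = w
            arrays[f"fc_b{i}"] = b
        np.savez(path, params=json.dumps(self.get_params()), **arrays)

    @classmethod
    def load(cls, path: str) -> "VelocityTimeSeriesClassifier":
        data = np.load(path, allow_pickle=False)
        est = cls(**json.loads(str(data["params"])))
        est.initialize(int(data["classes"].shape[0]))
        est.classes_ = data["classes"]
        est.conv_w_ = data["conv_w"]
        est.conv_b_ = data["conv_b"]
        n_fc = len([k for k in data.files if k.startswith("fc_w")])
        est.fc_w_ = [data[f"fc_w{i}"] for i in range(n_fc)]
        est.fc_b_ = [data[f"fc_b{i}"] for i in range(n_fc)]
        return est


@dataclass
class InferenceResult:
    """Likelihood curve plus the SNR bookkeeping of one inference."""

    probs: np.ndarray
    requested_snr_db: float
    used_snr_db: float
    reliable: bool


class NetworkBank:
    """Mapping of training SNR (dB) to a trained classifier.

    Inference selects the network at the nearest trained SNR; ties break
    toward the lower SNR (conservative), and requests outside the trained
    range are clamped with a warning.
    """

    def __init__(self, networks: dict[float, VelocityTimeSeriesClassifier],
                 grid: VelocityGrid):
        if not networks:
            raise IncompleteBankError("bank has no networks")
        self.networks = {float(k): v for k, v in networks.items()}
        self.grid = grid
        self.snr_levels = np.array(sorted(self.networks), dtype=float)

    def select_snr(self, snr_est_db: float) -> float:
        lv = self.snr_levels
        if snr_est_db < lv[0] or snr_est_db > lv[-1]:
            clamped = float(np.clip(snr_est_db, lv[0], lv[-1]))
            warnings.warn(
                f"estimated SNR {snr_est_db:.1f} dB outside trained range "
                f"[{lv[0]:g}, {lv[-1]:g}] dB; clamping to {clamped:g} dB",
                stacklevel=2)
            snr_est_db = clamped
        d = np.abs(lv - snr_est_db)
        # ties toward the lower SNR
        return float(lv[np.where(d == d.min())[0][0]])

    def __getitem__(self, snr_db: float) -> VelocityTimeSeriesClassifier:
        return self.networks[float(snr_db)]

    def save(self, directory: str) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "grid_mm_s": self.grid.values_mm_s.tolist(),
            "snr_levels_db": self.snr_levels.tolist(),
            "files": {},
        }
        for snr, net in self.networks.items():
            fname = f"net_snr{snr:g}.npz"
            net.save(str(d / fname))
            manifest["files"][f"{snr:g}"] = fname
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str) -> "NetworkBank":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        nets = {float(k): VelocityTimeSeriesClassifier.load(str(d / v))
                for k, v in manifest["files"].items()}
        return cls(nets, VelocityGrid(np.asarray(manifest["grid_mm_s"])))


# ---------------------------------------------------------------------------
# functional wrappers


def build_network(n_classes: int = 64, seed: int = 0,
                  **params) -> VelocityTimeSeriesClassifier:
    """Construct and He-initialize a classifier (deterministic in seed)."""
    return VelocityTimeSeriesClassifier(seed=seed, **params).initialize(n_classes)


def train_network(lib_slice: SignalLibrary, cfg: TrainingConfig
                  ) -> VelocityTimeSeriesClassifier:
    """Train one classifier on a single-SNR library slice."""
    Xt, yt, Xv, yv = lib_slice.train_val_arrays()
    est = VelocityTimeSeriesClassifier(
        input_len=lib_slice.spec.timing.n_samples,
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, momentum=cfg.momentum,
        seed=cfg.seed, early_stopping=cfg.early_stopping, patience=cfg.patience)
    est.fit(Xt, yt, validation_data=(Xv, yv) if len(Xv) else None)
    return est


def train_bank(lib: SignalLibrary, cfg: TrainingConfig) -> NetworkBank:
    """Train one classifier per configured SNR level."""
    nets = {}
    for snr in lib.spec.snr_levels_db:
        try:
            sl = lib.slice_snr(snr)
        except KeyError as exc:
            raise IncompleteBankError(f"library missing SNR slice {snr} dB") from exc
        nets[snr] = train_network(sl, cfg)
    return NetworkBank(nets, lib.spec.grid)


def infer_likelihood(series: np.ndarray, bank: NetworkBank,
                     snr_est_db: float) -> InferenceResult:
    """Evaluate one self-normalized series with the nearest-SNR network.

    Estimates below the reliability floor (4 dB) are still evaluated at the
    lowest trained SNR but flagged unreliable.
    """
    series = np.asarray(series, dtype=np.float32)
    _check_normalized(series[None, :] if series.ndim == 1 else series)
    used = bank.select_snr(max(snr_est_db, float(bank.snr_levels[0])))
    probs = bank[used].predict_proba(series)[0]
    return InferenceResult(probs=probs, requested_snr_db=snr_est_db,
                           used_snr_db=used,
                           reliable=snr_est_db >= RELIABILITY_FLOOR_DB)
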