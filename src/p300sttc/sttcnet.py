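"""P300-STTCNet: ERP-prior Transformer-CNN classifier.

Two ERP priors steer the network toward the physiology of the P300:

* channel prior — learnable per-channel input gains, initialized higher at
  Fz/C3/Cz/C4 where the group difference is strongest;
* attention prior — an additive bias (``PriorMask``) on the pre-softmax
  attention logits that boosts key positions whose epoch time falls inside
  the 250-450 ms P300 window, shared across heads and layers.

Attention per head is ``softmax(Q K' / sqrt(d_k) + PriorMask) V``.  Time
samples are tokens: a 10-channel sample vector is linearly embedded to
d_model and sinusoidal positional encoding is added (attention alone is
permutation-invariant and would discard the latency information the method
depends on).  The encoder output is read by a two-stage 3x3-conv / 2x2-pool
CNN head and an MLP producing the two class logits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import nn
from .containers import EpochSet

__all__ = [
    "PriorSpec",
    "apply_channel_prior",
    "build_prior_mask",
    "masked_attention",
    "multi_head",
    "encoder_forward",
    "STTCNet",
    "train_sttcnet",
]

PRIORITIZED_CHANNELS = ("Fz", "C3", "Cz", "C4")


@dataclass
class PriorSpec:
    """ERP prior package: channel gains and the attention-mask window.

    ``channel_weights`` maps label -> initial gain (unlisted channels get
    1.0); ``mask_magnitude`` is the additive logit bias lambda (0 disables
    the temporal prior).
    """

    channel_weights: dict = field(
        default_factory=lambda: {ch: 1.5 for ch in PRIORITIZED_CHANNELS})
    mask_window_ms: tuple = (250.0, 450.0)
    mask_magnitude: float = 1.0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.channel_weights.values()):
            raise ValueError("channel weights must be positive")
        if self.mask_magnitude < 0:
            raise ValueError("mask magnitude must be >= 0")

    def initial_weights(self, channels) -> np.ndarray:
        return np.array([self.channel_weights.get(ch, 1.0) for ch in channels])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"channel_weights": self.channel_weights,
                       "mask_window_ms": list(self.mask_window_ms),
                       "mask_magnitude": self.mask_magnitude}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PriorSpec":
        with open(path) as fh:
            d = json.load(fh)
        return cls(channel_weights=d["channel_weights"],
                   mask_window_ms=tuple(d["mask_window_ms"]),
                   mask_magnitude=d["mask_magnitude"])


def apply_channel_prior(data: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Multiply each channel by its gain; data is (trials, channels, time)."""
    data = np.asarray(data, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (data.shape[1],):
        raise ValueError("need exactly one weight per channel")
    return data * weights[None, :, None]


def build_prior_mask(t_axis, window_ms=(250.0, 450.0), magnitude: float = 1.0) -> np.ndarray:
    """Additive attention-logit mask, shape (n, n).

    Entry (i, j) equals ``magnitude`` when token j's time lies inside the
    closed window, else 0 — a bias on key positions applied to every query
    row.
    """
    t = np.asarray(t_axis, dtype=float)
    w0, w1 = window_ms
    key = (t >= w0) & (t <= w1)
    if not key.any():
        raise ValueError("mask window does not intersect the time axis")
    return np.broadcast_to(magnitude * key.astype(float), (t.size, t.size)).copy()


def masked_attention(Q, K, V, mask=None) -> np.ndarray:
    """Scaled dot-product attention with an additive logit mask (numpy).

    ``softmax(Q K' / sqrt(d_k) + mask) V``; rows of the weight matrix sum
    to 1 for any finite mask.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    d_k = Q.shape[-1]
    if d_k == 0:
        raise ValueError("d_k must be positive")
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    if mask is not None:
        scores = scores + mask
    scores = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    weights = e / e.sum(axis=-1, keepdims=True)
    return weights @ V


def multi_head(S, W_q, W_k, W_v, W_o, n_heads: int, mask=None) -> np.ndarray:
    """Multi-head attention (numpy reference): h projected heads, each
    masked-attended, concatenated and projected by ``W_o``.

    The combined (d, d) projection matrices hold head i in columns
    ``[i*d_k, (i+1)*d_k)``.
    """
    S = np.asarray(S, dtype=float)
    d = S.shape[-1]
    if d % n_heads:
        raise ValueError("d must be divisible by n_heads")
    d_k = d // n_heads
    heads = []
    for i in range(n_heads):
        sl = slice(i * d_k, (i + 1) * d_k)
        heads.append(masked_attention(S @ W_q[:, sl], S @ W_k[:, sl], S @ W_v[:, sl], mask))
    return np.concatenate(heads, axis=-1) @ W_o


def encoder_forward(module: nn.STTCNetModule, x: np.ndarray, mask=None) -> np.ndarray:
    """Deterministic (eval-mode) encoder representation, (B, n, d)."""
    return module.encode(np.asarray(x, dtype=float), mask, training=False).data


class STTCNet(BaseEstimator, ClassifierMixin):
    """Trial-level PTSD/HC classifier (scikit-learn estimator).

    Expects trials shaped (n_trials, n_channels, n_times).  ``channels`` and
    ``t_axis`` describe the epoch geometry so the ERP priors can be placed;
    without them the channel prior is uniform and the attention prior is off.

    Training minimizes softmax cross-entropy with Adam, with an internal
    stratified validation split and early stopping on validation loss; the
    best-validation weights are restored.  Fully deterministic given
    ``random_state``.
    """

    def __init__(self, channels=None, t_axis=None, prior: PriorSpec | None = None,
                 d_model: int = 64, n_heads: int = 4, n_layers: int = 4,
                 ffn_dim: int = 128, conv1_filters: int = 16, conv2_filters: int = 32,
                 mlp_hidden: int = 64, dropout: float = 0.1,
                 lr: float = 1e-3, weight_decay: float = 0.0,
                 batch_size: int = 32, max_epochs: int = 300,
                 patience: int = 30, min_epochs: int = 0,
                 val_fraction: float = 0.2, val_by_group: bool = False,
                 random_state: int = 0,
                 dtype: str = "float32", stop_at_train_acc: float | None = None,
                 augment: bool = True, augment_scale: tuple = (0.7, 1.3),
                 augment_noise: float = 0.2, augment_shift: int = 2,
                 scale_mode: str = "trial"):
        self.channels = channels
        self.t_axis = t_axis
        self.prior = prior
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.ffn_dim = ffn_dim
        self.conv1_filters = conv1_filters
        self.conv2_filters = conv2_filters
        self.mlp_hidden = mlp_hidden
        self.dropout = dropout
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_epochs = min_epochs
        self.val_fraction = val_fraction
        self.val_by_group = val_by_group
        self.random_state = random_state
        self.dtype = dtype
        self.stop_at_train_acc = stop_at_train_acc
        self.augment = augment
        self.augment_scale = augment_scale
        self.augment_noise = augment_noise
        self.augment_shift = augment_shift
        self.scale_mode = scale_mode

    def _build(self, n_channels: int, n_times: int, rng: np.random.Generator):
        prior = self.prior if self.prior is not None else PriorSpec()
        if self.channels is not None:
            if len(self.channels) != n_channels:
                raise ValueError("channels list does not match data")
            cw = prior.initial_weights(self.channels)
        else:
            cw = np.ones(n_channels)
        if self.t_axis is not None:
            t = np.asarray(self.t_axis, dtype=float)
            if t.size != n_times:
                raise ValueError("t_axis does not match data")
            mask = build_prior_mask(t, prior.mask_window_ms, prior.mask_magnitude)
        else:
            mask = None
        module = nn.STTCNetModule(
            n_channels=n_channels, n_times=n_times, d_model=self.d_model,
            n_heads=self.n_heads, n_layers=self.n_layers, ffn_dim=self.ffn_dim,
            conv1_filters=self.conv1_filters, conv2_filters=self.conv2_filters,
            mlp_hidden=self.mlp_hidden, dropout=self.dropout,
            channel_weights_init=cw, rng=rng)
        return module, mask

    def fit(self, X, y, groups=None):
        """Fit the network.

        ``groups`` (optional, one id per trial — e.g. subject ids) enables a
        group-aware validation split when ``val_by_group=True``: whole groups
        are held out for early stopping instead of individual trials.  At
        small cohort sizes a handful of held-out subjects is a noisy stopping
        signal, so trial-level splitting is the default.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be (trials, channels, time)")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training data must contain both classes")
        y_idx = np.searchsorted(self.classes_, y)

        rng = np.random.default_rng(self.random_state)
        self.scale_ = X.std(axis=(0, 2)) + 1e-12  # per-channel scale (global mode)
        Xs = self._scale(X)

        tr_i, va_i = self._val_split(y_idx, groups, rng)

        history = []
        with nn.default_dtype(self.dtype):
            self.module_, self.mask_ = self._build(X.shape[1], X.shape[2], rng)
            opt = nn.Adam(self.module_.params(), lr=self.lr,
                          weight_decay=self.weight_decay)
            best_key, best_weights, since_best = (-np.inf, -np.inf), None, 0
            for ep_i in range(self.max_epochs):
                order = rng.permutation(tr_i)
                tl, ta, nb = 0.0, 0.0, 0
                for s in range(0, order.size, self.batch_size):
                    idx = order[s:s + self.batch_size]
                    xb = Xs[idx]
                    if self.augment:
                        # per-trial amplitude scaling + additive noise + small
                        # temporal shifts: break subject-amplitude and
                        # noise-pattern memorization, preserve waveform shape
                        lo, hi = self.augment_scale
                        sc = rng.uniform(lo, hi, size=(len(idx), 1, 1))
                        xb = xb * sc + self.augment_noise * rng.standard_normal(xb.shape)
                        if self.augment_shift > 0:
                            shifts = rng.integers(-self.augment_shift,
                                                  self.augment_shift + 1, len(idx))
                            xb = np.stack([np.roll(x, s, axis=-1)
                                           for x, s in zip(xb, shifts)])
                    logits = self.module_.forward(xb, self.mask_, training=True, rng=rng)
                    loss = nn.cross_entropy(logits, y_idx[idx])
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                    tl += float(loss.data)
                    ta += float((logits.data.argmax(axis=1) == y_idx[idx]).mean())
                    nb += 1
                train_loss, train_acc = tl / max(nb, 1), ta / max(nb, 1)
                if va_i.size:
                    val_loss, val_acc = self._evaluate(Xs[va_i], y_idx[va_i])
                else:
                    val_loss, val_acc = train_loss, train_acc
                history.append({"epoch": ep_i, "train_loss": train_loss, "val_loss": val_loss,
                                "train_acc": train_acc, "val_acc": val_acc})
                if (self.stop_at_train_acc is not None
                        and train_acc >= self.stop_at_train_acc):
                    best_weights = None
                    break
                # checkpoint on validation accuracy, ties broken by loss
                key = (val_acc, -val_loss)
                if key > best_key:
                    best_key, best_weights, since_best = key, self.module_.get_weights(), 0
                else:
                    since_best += 1
                    if since_best >= self.patience and ep_i + 1 >= self.min_epochs:
                        break
            if best_weights is not None:
                self.module_.set_weights(best_weights)
        self.history_ = pd.DataFrame(history)
        return self

    def _scale(self, X: np.ndarray) -> np.ndarray:
        """Input normalization.

        "trial": each trial's channels are divided by their own within-trial
        standard deviation — cancels stable per-subject channel-gain nuisance
        without using labels or subject identity.  "global": divide by the
        training-set per-channel std.
        """
        if self.scale_mode == "trial":
            sd = X.std(axis=2, keepdims=True) + 1e-12
            return X / sd
        if self.scale_mode == "global":
            return X / self.scale_[None, :, None]
        raise ValueError("scale_mode must be 'trial' or 'global'")

    def _val_split(self, y_idx, groups, rng):
        n = len(y_idx)
        if self.val_fraction <= 0 or np.min(np.bincount(y_idx)) < 2:
            return np.arange(n), np.array([], dtype=int)
        if groups is None or not self.val_by_group:
            return train_test_split(np.arange(n), test_size=self.val_fraction,
                                    stratify=y_idx, random_state=self.random_state)
        groups = np.asarray(groups)
        # hold out whole groups, class-balanced
        val_groups = []
        for cls in range(len(self.classes_)):
            ug = list(dict.fromkeys(groups[y_idx == cls]))
            n_hold = max(1, int(round(self.val_fraction * len(ug))))
            pick = rng.permutation(len(ug))[:n_hold]
            val_groups.extend(ug[i] for i in pick)
        va = np.isin(groups, val_groups)
        if va.all() or not va.any():
            return train_test_split(np.arange(n), test_size=self.val_fraction,
                                    stratify=y_idx, random_state=self.random_state)
        return np.where(~va)[0], np.where(va)[0]

    def _evaluate(self, Xs, y_idx):
        losses, correct, n = 0.0, 0, 0
        for s in range(0, Xs.shape[0], self.batch_size):
            xb, yb = Xs[s:s + self.batch_size], y_idx[s:s + self.batch_size]
            logits = self.module_.forward(xb, self.mask_, training=False)
            losses += float(nn.cross_entropy(logits, yb).data) * len(yb)
            correct += int((logits.data.argmax(axis=1) == yb).sum())
            n += len(yb)
        return losses / n, correct / n

    def decision_logits(self, X) -> np.ndarray:
        check_is_fitted(self, "module_")
        X = self._scale(np.asarray(X, dtype=float))
        out = []
        with nn.default_dtype(self.dtype):
            for s in range(0, X.shape[0], self.batch_size):
                out.append(self.module_.forward(X[s:s + self.batch_size], self.mask_,
                                                training=False).data.astype(float))
        return np.concatenate(out, axis=0)

    def predict_proba(self, X) -> np.ndarray:
        z = self.decision_logits(X)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def train_sttcnet(ep: EpochSet, label_column: str = "group", **params) -> STTCNet:
    """Fit an STTCNet on an EpochSet, labeling trials by ``label_column``."""
    clf = STTCNet(channels=list(ep.channels), t_axis=ep.t_axis, **params)
    return clf.fit(ep.data, ep.meta[label_column].to_numpy())
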