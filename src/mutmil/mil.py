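"""Attention-based multiple-instance learning over bags of mutations.

A *bag* is one sample: a variable-length set of instance feature bundles
(any mix of genomic-concept encodings) with an optional fixed-length
sample vector and a bag-level label. The model is permutation invariant
by construction: instances are encoded independently, weighted by one or
more attention heads (linear map + adaptive sigmoid, so weights live
strictly in (0, 1)), and reduced segment-wise.

Aggregation modes:

``mean``
    per-head attention-weighted average (weights normalized to sum 1);
``sum``
    per-head attention-weighted sum followed by elementwise log1p — the
    log keeps activated feature sums bounded on the graph while the raw
    sum lets bag size carry signal;
``dynamic``
    two-round attention: a first weighted mean produces a sample vector
    that is broadcast back and concatenated onto every instance, a second
    attention is computed from that context, and a second aggregation
    (mean or log-sum) produces the output. This lets an instance's weight
    depend on its bag.

Batches of ragged bags are instance-major matrices plus per-bag row
counts (see :mod:`mutmil.autodiff`); no padding is ever performed.

The estimator follows the Model/Results convention: build a
:class:`MILClassifier` from bags + config, call :meth:`MILClassifier.fit`,
and read estimates, history and attention off the returned
:class:`MILResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import training as _training
from .activations import ARU_ALPHA0, ASU_ALPHA0, aru, asu
from .autodiff import Tensor, concat, repeat_rows, segment_sum
from .concepts import one_hot_sequences

logger = logging.getLogger(__name__)

__all__ = [
    "Bag",
    "ModelConfig",
    "CategoricalConcept",
    "IdentityConcept",
    "SequenceConceptSpec",
    "MILClassifier",
    "MILResults",
    "msi_reference_config",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass
class Bag:
    """One sample: a set of instances plus optional sample-level covariates."""

    sample_id: str
    instances: dict[str, np.ndarray]
    label: Optional[int] = None
    sample_features: Optional[np.ndarray] = None
    key_flags: Optional[np.ndarray] = None  # per-instance ground truth, if known

    @property
    def n_instances(self) -> int:
        return len(next(iter(self.instances.values())))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``n_heads=None`` resolves to one head per class for multiclass models
    (class-specific attention) and a single head for binary models.
    """

    n_heads: Optional[int] = None
    aggregation: str = "mean"  # mean | sum | dynamic
    dynamic_second: str = "mean"  # aggregation of the second round
    attention_l1: float = 0.05
    instance_dropout: float = 0.0
    instance_dim: Optional[int] = 32
    instance_feature_dropout: float = 0.0
    hidden: tuple = (64,)
    hidden_dropout: float = 0.0
    l2: float = 0.0
    freeze_attention: bool = False
    class_weights: bool = True
    lr: float = 3e-3
    epochs: int = 60
    batch_size: int = 32
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.instance_dropout < 1.0:
            raise ValueError("instance_dropout must be in [0, 1)")
        if self.attention_l1 < 0:
            raise ValueError("attention_l1 must be >= 0")
        if self.aggregation not in ("mean", "sum", "dynamic"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.dynamic_second not in ("mean", "sum"):
            raise ValueError(f"unknown dynamic_second {self.dynamic_second!r}")


def msi_reference_config(**overrides) -> ModelConfig:
    """The reference binary architecture used for microsatellite status.

    Single-head ASU attention with 0.05 L1 activity regularization,
    instance (data) dropout 0.4, sequence kernels fused to 128 with ReLU
    and 0.01 L2, 0.5 feature dropout, then a 256/0.5-dropout/128/0.5-dropout
    head to a single logit. Aggregation is the attention-weighted mean,
    whose scale-invariance keeps training stable under the attention L1
    at small sample sizes.
    """
    cfg = dict(
        n_heads=1,
        aggregation="mean",
        attention_l1=0.05,
        instance_dropout=0.4,
        instance_dim=None,  # the sequence encoder's fused output is used directly
        instance_feature_dropout=0.5,
        hidden=(256, 128),
        hidden_dropout=0.5,
        l2=0.0,
    )
    cfg.update(overrides)
    return ModelConfig(**cfg)


# concept specs ---------------------------------------------------------------


@dataclass(frozen=True)
class CategoricalConcept:
    """Integer-coded concept (SBS96 index, position bin, gene) -> embedding."""

    name: str
    vocab_size: int
    dim: int = 16


@dataclass(frozen=True)
class IdentityConcept:
    """A float feature block passed through unchanged (e.g. one-hot codes)."""

    name: str
    dim: int


@dataclass(frozen=True)
class SequenceConceptSpec:
    """Encoder for the (n, 8, W) stacked sequence-concept arrays.

    ``mode="conv"``: each of the four components (5', 3', ref, alt) gets
    its own bank of ``n_kernels`` convolution filters with ARU activation,
    shared between the forward and reverse-complement orientations and
    max-pooled over positions; pooled vectors are fused with a ReLU dense
    layer. ``mode="dense"`` flattens the one-hot stack and applies a
    single ARU dense layer — position-sensitive, which suits tasks where
    the variant-adjacent alignment carries the signal (e.g. codon frame).
    """

    name: str = "sequence"
    W: int = 20
    n_kernels: int = 8
    kernel_size: int = 5
    fuse_dim: int = 128
    mode: str = "conv"
    l2: float = 0.01


# ---------------------------------------------------------------------------
# layers


class _Dense:
    def __init__(self, rng, n_in, n_out, activation=None, l2=0.0, zero_init=False):
        scale = np.sqrt(2.0 / n_in) if activation in ("relu", "aru") else np.sqrt(1.0 / n_in)
        w = np.zeros((n_in, n_out)) if zero_init else rng.normal(0.0, scale, (n_in, n_out))
        self.W = Tensor.param(w)
        self.b = Tensor.param(np.zeros(n_out))
        self.activation = activation
        self.l2 = l2
        self.alpha = None
        self.alpha_upper = None
        if activation == "aru":
            self.alpha = Tensor.param(np.full(n_out, ARU_ALPHA0))
        elif activation == "asu":
            self.alpha = Tensor.param(np.full(n_out, ASU_ALPHA0))
            self.alpha_upper = Tensor.param(np.full(n_out, ASU_ALPHA0))

    def __call__(self, x: Tensor) -> Tensor:
        z = x @ self.W + self.b
        if self.activation == "relu":
            return z.relu()
        if self.activation == "aru":
            return aru(z, self.alpha)
        if self.activation == "asu":
            return asu(z, self.alpha, self.alpha_upper)
        return z

    def params(self):
        out = [self.W, self.b]
        if self.alpha is not None:
            out.append(self.alpha)
        if self.alpha_upper is not None:
            out.append(self.alpha_upper)
        return out


class _Embedding:
    def __init__(self, rng, vocab, dim):
        self.table = Tensor.param(rng.normal(0.0, 0.1, (vocab, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.table.take(np.asarray(idx, dtype=np.int64))

    def params(self):
        return [self.table]


class _ConvBank:
    """1D convolution over one-hot nucleotides with ARU, max-pooled."""

    def __init__(self, rng, W, k, n_filters):
        self.W_len, self.k = W, k
        self.kernel = Tensor.param(rng.normal(0.0, np.sqrt(2.0 / (k * 4)), (k * 4, n_filters)))
        self.b = Tensor.param(np.zeros(n_filters))
        self.alpha = Tensor.param(np.full(n_filters, ARU_ALPHA0))
        self.n_pos = W - k + 1

    def __call__(self, onehot: np.ndarray) -> Tensor:
        # onehot: (N, W, 4) constant input -> im2col on numpy
        n = onehot.shape[0]
        win = np.lib.stride_tricks.sliding_window_view(onehot, (self.k, 4), axis=(1, 2))
        cols = win.reshape(n * self.n_pos, self.k * 4)
        z = Tensor(cols) @ self.kernel + self.b
        z = aru(z, self.alpha)
        return z.reshape(n, self.n_pos, -1).amax(axis=1)

    def params(self):
        return [self.kernel, self.b, self.alpha]


class _SequenceEncoder:
    def __init__(self, rng, spec: SequenceConceptSpec):
        self.spec = spec
        if spec.mode == "conv":
            k = min(spec.kernel_size, spec.W)
            self.banks = [_ConvBank(rng, spec.W, k, spec.n_kernels) for _ in range(4)]
            self.fuse = _Dense(rng, 8 * spec.n_kernels, spec.fuse_dim, "relu", l2=spec.l2)
        elif spec.mode == "dense":
            self.banks = None
            self.fuse = _Dense(rng, 8 * spec.W * 4, spec.fuse_dim, "aru", l2=spec.l2)
        else:
            raise ValueError(f"unknown sequence encoder mode {spec.mode!r}")

    @property
    def out_dim(self):
        return self.spec.fuse_dim

    def __call__(self, seqs: np.ndarray) -> Tensor:
        onehot = one_hot_sequences(seqs)  # (N, 8, W, 4)
        if self.banks is None:
            flat = onehot.reshape(onehot.shape[0], -1)
            return self.fuse(Tensor(flat))
        pooled = []
        for comp in range(4):  # kernels shared between orientations
            bank = self.banks[comp]
            pooled.append(bank(onehot[:, comp]))       # forward
            pooled.append(bank(onehot[:, 4 + comp]))   # reverse complement
        return self.fuse(concat(pooled, axis=1))

    def params(self):
        out = []
        if self.banks is not None:
            for b in self.banks:
                out.extend(b.params())
        out.extend(self.fuse.params())
        return out


def _dropout(x: Tensor, p: float, rng, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


# ---------------------------------------------------------------------------
# ragged dataset


class _BagData:
    """Instance-major arrays for a list of bags, with per-bag row slices."""

    def __init__(self, bags: Sequence[Bag], concept_names: Sequence[str]):
        if not bags:
            raise ValueError("no bags given")
        self.bags = list(bags)
        sizes = np.array([b.n_instances for b in bags], dtype=np.int64)
        if (sizes == 0).any():
            bad = bags[int(np.argmin(sizes))].sample_id
            raise ValueError(f"bag {bad!r} has no instances")
        self.sizes = sizes
        self.starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
        self.arrays = {
            name: np.concatenate([np.asarray(b.instances[name]) for b in bags])
            for name in concept_names
        }
        if bags[0].sample_features is not None:
            self.sample_features = np.stack([b.sample_features for b in bags]).astype(float)
        else:
            self.sample_features = None
        if all(b.label is not None for b in bags):
            self.labels = np.array([b.label for b in bags], dtype=np.int64)
        else:
            self.labels = None

    def __len__(self):
        return len(self.bags)

    def gather(self, bag_idx: np.ndarray, kept: Optional[list] = None):
        """Row indices + per-bag counts for a batch of bags.

        ``kept`` optionally lists, per bag in the batch, the local indices
        of the instances to keep (MIL instance dropout).
        """
        rows = []
        counts = []
        for j, i in enumerate(bag_idx):
            local = (
                np.arange(self.sizes[i])
                if kept is None
                else np.asarray(kept[j], dtype=np.int64)
            )
            rows.append(self.starts[i] + local)
            counts.append(len(local))
        return np.concatenate(rows), np.array(counts, dtype=np.int64)


# ---------------------------------------------------------------------------
# the model


class MILClassifier:
    """Attention-MIL classifier over bags of featurized mutations.

    Parameters
    ----------
    bags:
        Training bags; every bag must carry the instance arrays named by
        the concept specs, and a label unless `labels` is given.
    concepts:
        Concept specs (:class:`CategoricalConcept`, :class:`IdentityConcept`,
        :class:`SequenceConceptSpec`) describing the instance inputs.
    config:
        :class:`ModelConfig`; defaults are sensible for desk-scale tasks.
    n_classes:
        Inferred from labels when omitted. Two classes use a single-logit
        ASU head; more use a softmax head.
    """

    def __init__(
        self,
        bags: Sequence[Bag],
        concepts: Sequence,
        config: Optional[ModelConfig] = None,
        n_classes: Optional[int] = None,
        labels: Optional[np.ndarray] = None,
    ):
        self.config = config or ModelConfig()
        self.concepts = list(concepts)
        for c in self.concepts:
            if not isinstance(
                c, (CategoricalConcept, IdentityConcept, SequenceConceptSpec)
            ):
                raise TypeError(f"unknown concept spec {c!r}")
        self.concept_names = [c.name for c in self.concepts]
        self.data = _BagData(bags, self.concept_names)
        if labels is not None:
            self.data.labels = np.asarray(labels, dtype=np.int64)
        if self.data.labels is None:
            raise ValueError("bags must carry labels (or pass labels=)")
        self.labels = self.data.labels
        self.n_classes = int(n_classes or self.labels.max() + 1)
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        self.binary = self.n_classes == 2
        self.n_heads = self.config.n_heads or (1 if self.binary else self.n_classes)

        rng = np.random.default_rng(self.config.seed)
        self._build(rng)

    # -- construction ---------------------------------------------------------

    def _build(self, rng):
        cfg = self.config
        self.encoders = {}
        enc_dim = 0
        for spec in self.concepts:
            if isinstance(spec, CategoricalConcept):
                self.encoders[spec.name] = _Embedding(rng, spec.vocab_size, spec.dim)
                enc_dim += spec.dim
            elif isinstance(spec, IdentityConcept):
                self.encoders[spec.name] = None
                enc_dim += spec.dim
            elif isinstance(spec, SequenceConceptSpec):
                self.encoders[spec.name] = _SequenceEncoder(rng, spec)
                enc_dim += spec.fuse_dim
            else:
                raise TypeError(f"unknown concept spec {spec!r}")

        if cfg.instance_dim is not None:
            self.fuse = _Dense(rng, enc_dim, cfg.instance_dim, "aru", l2=cfg.l2)
            feat_dim = cfg.instance_dim
        else:
            self.fuse = None
            feat_dim = enc_dim
        self.feat_dim = feat_dim

        self.attn = _Dense(rng, feat_dim, self.n_heads, "asu")
        self.attn2 = (
            _Dense(rng, feat_dim + self.n_heads * feat_dim, self.n_heads, "asu")
            if cfg.aggregation == "dynamic"
            else None
        )

        agg_dim = self.n_heads * feat_dim
        if self.data.sample_features is not None:
            agg_dim += self.data.sample_features.shape[1]
        self.head_layers = []
        d = agg_dim
        for h in cfg.hidden:
            self.head_layers.append(_Dense(rng, d, h, "relu", l2=cfg.l2))
            d = h
        out_dim = 1 if self.binary else self.n_classes
        # small init so gradients reach attention/encoders from step one;
        # zeroing out.W/out.b recovers exactly-uniform untrained predictions
        self.out = _Dense(rng, d, out_dim, None)
        self.out.W.data *= 0.1
        
        self.out_asu = (
            (Tensor.param(np.full(1, ASU_ALPHA0)), Tensor.param(np.full(1, ASU_ALPHA0)))
            if self.binary
            else None
        )

    def parameters(self) -> list[Tensor]:
        out = []
        for name in self.concept_names:
            enc = self.encoders[name]
            if enc is not None:
                out.extend(enc.params())
        if self.fuse is not None:
            out.extend(self.fuse.params())
        if not self.config.freeze_attention:
            out.extend(self.attn.params())
            if self.attn2 is not None:
                out.extend(self.attn2.params())
        for layer in self.head_layers:
            out.extend(layer.params())
        out.extend(self.out.params())
        if self.out_asu is not None:
            out.extend(self.out_asu)
        return out

    def l2_penalty(self) -> Tensor:
        terms = []
        layers = [*self.head_layers, self.out]
        if self.fuse is not None:
            layers.append(self.fuse)
        for name in self.concept_names:
            enc = self.encoders[name]
            if isinstance(enc, _SequenceEncoder):
                layers.append(enc.fuse)
        for layer in layers:
            if layer.l2 > 0:
                terms.append((layer.W * layer.W).sum() * layer.l2)
        total = Tensor(0.0)
        for t in terms:
            total = total + t
        return total

    # -- forward --------------------------------------------------------------

    def _encode(self, data: _BagData, rows: np.ndarray, training, rng) -> Tensor:
        parts = []
        for spec in self.concepts:
            arr = data.arrays[spec.name][rows]
            enc = self.encoders[spec.name]
            if enc is None:
                parts.append(Tensor(np.asarray(arr, dtype=float)))
            else:
                parts.append(enc(arr))
        x = parts[0] if len(parts) == 1 else concat(parts, axis=1)
        if self.fuse is not None:
            x = self.fuse(x)
        return _dropout(x, self.config.instance_feature_dropout, rng, training)

    def _attention(self, layer, f: Tensor) -> Tensor:
        if self.config.freeze_attention:
            return Tensor(np.ones((f.shape[0], self.n_heads)))
        return layer(f)

    def _aggregate_heads(self, f: Tensor, a: Tensor, counts, mode: str) -> Tensor:
        heads = []
        for h in range(self.n_heads):
            ah = a[:, h : h + 1]
            s = segment_sum(f * ah, counts)
            if mode == "mean":
                heads.append(s / segment_sum(ah, counts))
            else:  # weighted sum, logged on the graph
                heads.append(s.log1p())
        return heads[0] if len(heads) == 1 else concat(heads, axis=1)

    def _forward(self, data, bag_idx, kept=None, training=False, rng=None):
        rng = rng or np.random.default_rng(0)
        rows, counts = data.gather(bag_idx, kept)
        f = self._encode(data, rows, training, rng)
        cfg = self.config
        attn_outputs = []
        if cfg.aggregation == "dynamic":
            a1 = self._attention(self.attn, f)
            attn_outputs.append(a1)
            s1 = self._aggregate_heads(f, a1, counts, "mean")
            ctx = concat([f, repeat_rows(s1, counts)], axis=1)
            a = self._attention(self.attn2, ctx)
            attn_outputs.append(a)
            agg = self._aggregate_heads(f, a, counts, cfg.dynamic_second)
        else:
            a = self._attention(self.attn, f)
            attn_outputs.append(a)
            agg = self._aggregate_heads(f, a, counts, cfg.aggregation)
        if data.sample_features is not None:
            agg = concat([agg, Tensor(data.sample_features[bag_idx])], axis=1)
        z = agg
        for layer in self.head_layers:
            z = _dropout(layer(z), cfg.hidden_dropout, rng, training)
        logits = self.out(z)
        return logits, a, attn_outputs, counts

    # -- losses / predictions -------------------------------------------------

    def _probs_from_logits(self, logits: Tensor) -> np.ndarray:
        z = logits.data
        if self.binary:
            al, au = self.out_asu
            p = asu(z[:, 0], al.data, au.data)
            return np.column_stack([1 - p, p])
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _nll(self, logits: Tensor, y: np.ndarray, w: np.ndarray) -> Tensor:
        wt = Tensor(w / w.sum())
        if self.binary:
            al, au = self.out_asu
            p = asu(logits[:, 0], al, au)
            y = y.astype(float)
            ll = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
            return -(wt * ll).sum()
        m = Tensor(logits.data.max(axis=1, keepdims=True))
        zs = logits - m
        lse = zs.exp().sum(axis=1, keepdims=True).log()
        logp = zs - lse
        onehot = np.eye(self.n_classes)[y]
        per = -(Tensor(onehot) * logp).sum(axis=1)
        return (wt * per).sum()

    def _loss(self, data, bag_idx, kept, sample_w, training, rng) -> Tensor:
        logits, _, attn_outputs, _ = self._forward(data, bag_idx, kept, training, rng)
        loss = self._nll(logits, data.labels[bag_idx], sample_w)
        if self.config.attention_l1 > 0 and not self.config.freeze_attention:
            for a in attn_outputs:
                loss = loss + self.config.attention_l1 * a.mean()
        loss = loss + self.l2_penalty()
        return loss

    def predict_proba(self, bags: Optional[Sequence[Bag]] = None) -> np.ndarray:
        """(n_bags, n_classes) class probabilities with all instances used."""
        data = self.data if bags is None else _BagData(bags, self.concept_names)
        idx = np.arange(len(data))
        logits, _, _, _ = self._forward(data, idx, training=False)
        return self._probs_from_logits(logits)

    def predict(self, bags: Optional[Sequence[Bag]] = None) -> np.ndarray:
        return self.predict_proba(bags).argmax(axis=1)

    def attention(self, bags: Optional[Sequence[Bag]] = None) -> list[np.ndarray]:
        """Per-bag (n_instances, n_heads) attention weights (final round)."""
        data = self.data if bags is None else _BagData(bags, self.concept_names)
        idx = np.arange(len(data))
        _, a, _, counts = self._forward(data, idx, training=False)
        splits = np.cumsum(counts)[:-1]
        return np.split(a.data, splits, axis=0)

    # -- fitting --------------------------------------------------------------

    def fit(
        self,
        val_bags: Optional[Sequence[Bag]] = None,
        val_fraction: float = 0.15,
        verbose: bool = False,
    ) -> "MILResults":
        """Train with instance dropout, stratified batches, early stopping."""
        rng = np.random.default_rng(self.config.seed)
        n = len(self.data)
        if val_bags is not None:
            val_data = _BagData(val_bags, self.concept_names)
            train_idx = np.arange(n)
        elif val_fraction > 0 and n >= 10:
            train_idx, val_idx = _training.stratified_split(
                self.labels, val_fraction, rng
            )
            val_data = (self.data, val_idx)
        else:
            train_idx = np.arange(n)
            val_data = None
        history = _training.train(self, train_idx, val_data, rng, verbose=verbose)
        return MILResults(self, history)

    # -- persistence ----------------------------------------------------------

    def save_weights(self, path):
        np.savez_compressed(path, **{f"p{i}": p.data for i, p in enumerate(self.parameters())})

    def load_weights(self, path):
        with np.load(path) as npz:
            params = self.parameters()
            if len(npz.files) != len(params):
                raise ValueError("checkpoint does not match this architecture")
            for i, p in enumerate(params):
                p.data[...] = npz[f"p{i}"]


class MILResults:
    """Fitted-model results: training history, predictions, attention."""

    def __init__(self, model: MILClassifier, history):
        self.model = model
        self.history = history
        if history is not None and len(history):
            monitor = "val_loss" if "val_loss" in history else "train_loss"
            self.best_epoch = int(history[monitor].idxmin())
            self.best_loss = float(history[monitor].min())
        else:
            self.best_epoch = None
            self.best_loss = None

    def predict_proba(self, bags=None):
        return self.model.predict_proba(bags)

    def predict(self, bags=None):
        return self.model.predict(bags)

    def attention(self, bags=None):
        return self.model.attention(bags)

    def summary(self) -> str:
        m = self.model
        n_params = sum(p.data.size for p in m.parameters())
        lines = [
            "Attention-MIL classifier",
            "=" * 40,
            f"bags (train):        {len(m.data)}",
            f"classes:             {m.n_classes}" + ("  (binary)" if m.binary else ""),
            f"attention heads:     {m.n_heads}",
            f"aggregation:         {m.config.aggregation}",
            f"instance features:   {m.feat_dim}",
            f"trainable params:    {n_params}",
            f"attention L1 weight: {m.config.attention_l1}",
            f"instance dropout:    {m.config.instance_dropout}",
        ]
        if self.best_epoch is not None:
            lines.append(f"best epoch:          {self.best_epoch}")
            lines.append(f"best monitored loss: {self.best_loss:.4f}")
        return "\n".join(lines)
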