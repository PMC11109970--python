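"""Three-step training schedule for the gene set autoencoder.

Step 1 initializes each bottleneck neuron by training a one-neuron
autoencoder on its gene set alone, so every score starts as the best
single-direction summary of its member genes. Step 2 freezes the encoder
and trains the decoder, letting the fully connected reconstruction settle
without disturbing the score definitions. Step 3 unfreezes everything and
fine-tunes the whole network. All steps minimize the mean squared
reconstruction error with Adam; the encoder mask is preserved bit-exactly
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._nn import Adam, Dense, act_backward, act_forward
from .expression import ExpressionMatrix, standardize
from .genesets import GeneSetCollection
from .network import ArchitectureConfig, GsasModel, build_model

__all__ = [
    "TrainingConfig",
    "TrainingTrace",
    "split_train_validation",
    "train_step1",
    "train_step2",
    "train_step3",
    "train_full",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Epochs, learning rates, batching and split options for the three steps.

    Setting a step's epochs to 0 skips that step. Defaults are sensible
    desk-scale values, configurable per run.
    """

    step1_epochs: int = 100
    step2_epochs: int = 50
    step3_epochs: int = 100
    step1_lr: float = 1e-2
    step2_lr: float = 1e-3
    step3_lr: float = 1e-4
    batch_size: int = 64
    validation_fraction: float = 0.2
    strata: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("step1_epochs", "step2_epochs", "step3_epochs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.strata is not None:
            object.__setattr__(self, "strata", tuple(map(str, self.strata)))


@dataclass
class TrainingTrace:
    """Per-step, per-epoch reconstruction MSE (training and validation)."""

    step1_train: list[float] = field(default_factory=list)
    step1_val: list[float] = field(default_factory=list)
    step2_train: list[float] = field(default_factory=list)
    step2_val: list[float] = field(default_factory=list)
    step3_train: list[float] = field(default_factory=list)
    step3_val: list[float] = field(default_factory=list)
    final_val_mse: float = float("nan")


def split_train_validation(
    x: ExpressionMatrix, cfg: TrainingConfig
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Seeded (optionally stratified) split into train and validation sets.

    The validation fraction is honored within each stratum to the nearest
    sample. ``validation_fraction=0`` puts every sample in the training set.
    """
    n = x.n_samples
    strata = cfg.strata if cfg.strata is not None else ("all",) * n
    if len(strata) != n:
        raise ValueError(f"{len(strata)} stratum labels for {n} samples")
    frac = cfg.validation_fraction
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    labels = np.asarray(strata, dtype=object)
    val_idx: list[int] = []
    for lab in dict.fromkeys(labels):  # preserve first-appearance order
        idx = np.flatnonzero(labels == lab)
        if frac > 0 and len(idx) < 2:
            raise ValueError(f"stratum {lab!r} has a single sample; cannot split")
        n_val = int(round(frac * len(idx)))
        perm = rng.permutation(idx)
        val_idx.extend(perm[:n_val].tolist())
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_idx] = True
    return x.subset_samples(~val_mask), x.subset_samples(val_mask)


def _mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def _forward_eval(enc: list[Dense], dec: list[Dense], act: str, x: np.ndarray) -> np.ndarray:
    h = x
    for layer in enc[:-1]:
        h = layer.forward(h, cache=False)
    s = enc[-1].forward(h, cache=False)
    a = act_forward(s, act)
    for layer in dec:
        a = layer.forward(a, cache=False)
    return a


def _fit_autoencoder(
    enc: list[Dense],
    dec: list[Dense],
    act: str,
    x: np.ndarray,
    x_val: np.ndarray | None,
    epochs: int,
    lr: float,
    batch_size: int,
    rng: np.random.Generator,
    *,
    train_encoder: bool = True,
    dropout_rate: float = 0.0,
) -> tuple[list[float], list[float]]:
    """Mini-batch Adam on reconstruction MSE; returns per-epoch train/val MSE.

    ``train_encoder=False`` freezes the encoder exactly: its parameters are
    simply not registered with the optimizer. Dropout (inverted scaling) is
    applied to the decoder input when ``dropout_rate > 0``.
    """
    trainable = (enc if train_encoder else []) + dec
    params: list[np.ndarray] = []
    for layer in trainable:
        params.extend(layer.params())
    if not params or epochs == 0:
        return [], []
    opt = Adam(params, lr=lr)
    n = x.shape[0]
    train_trace: list[float] = []
    val_trace: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            xb = x[order[start : start + batch_size]]
            # forward with caches
            h = xb
            for layer in enc[:-1]:
                h = layer.forward(h, cache=True)
            s = enc[-1].forward(h, cache=True)
            a = act_forward(s, act)
            if dropout_rate > 0.0:
                keep = rng.random(a.shape) >= dropout_rate
                a = a * keep / (1.0 - dropout_rate)
            out = a
            for layer in dec:
                out = layer.forward(out, cache=True)
            # backward
            grads: dict[int, list[np.ndarray]] = {}
            d = 2.0 * (out - xb) / out.size
            for layer in reversed(dec):
                d, dW, db = layer.backward(d)
                grads[id(layer)] = [dW] if db is None else [dW, db]
            if train_encoder:
                if dropout_rate > 0.0:
                    d = d * keep / (1.0 - dropout_rate)
                d = d * act_backward(s, act)
                # bottleneck layer is linear; backward through encoder stack
                carry = d
                for layer in reversed(enc):
                    carry, dW, db = layer.backward(carry)
                    grads[id(layer)] = [dW] if db is None else [dW, db]
            flat: list[np.ndarray] = []
            for layer in trainable:
                flat.extend(grads[id(layer)])
            opt.step(flat)
            for layer in trainable:
                layer.apply_mask()
        train_trace.append(_mse(_forward_eval(enc, dec, act, x), x))
        val_trace.append(
            _mse(_forward_eval(enc, dec, act, x_val), x_val) if x_val is not None and len(x_val) else float("nan")
        )
    return train_trace, val_trace


def train_step1(
    model: GsasModel,
    train: ExpressionMatrix,
    cfg: TrainingConfig,
    val: ExpressionMatrix | None = None,
    trace: TrainingTrace | None = None,
) -> GsasModel:
    """Initialize the encoder by training a tiny autoencoder per gene set.

    Each gene set's autoencoder sees only its member genes and has a single
    bottleneck neuron (or the per-set hidden block for ``dense_*``
    variants); the learned encoder weights are written into the
    corresponding masked column of the model. Mini-decoders are discarded
    and the main decoder is untouched. Per-set random streams are derived
    from the master seed, so sets can be trained in any order.
    """
    if cfg.step1_epochs == 0:
        return model
    arch = model.arch
    act = arch.hidden_activation
    k = arch.encoder_neurons_per_set
    per_set_train: list[list[float]] = []
    per_set_val: list[list[float]] = []
    for j in range(model.n_sets):
        rows = np.flatnonzero(model.mask[:, j])
        xj = train.values[:, rows]
        vj = val.values[:, rows] if val is not None else None
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1, j]))
        m = len(rows)
        if arch.has_encoder_hidden:
            enc = [
                Dense(m, k, bias=arch.encoder_bias, activation=act, rng=rng),
                Dense(k, 1, bias=arch.encoder_bias, activation="linear", rng=rng),
            ]
        else:
            enc = [Dense(m, 1, bias=arch.encoder_bias, activation="linear", rng=rng)]
        dec = [Dense(1, m, bias=True, activation="linear", rng=rng)]
        tr, vl = _fit_autoencoder(
            enc, dec, act, xj, vj, cfg.step1_epochs, cfg.step1_lr, cfg.batch_size, rng
        )
        per_set_train.append(tr)
        per_set_val.append(vl)
        if arch.has_encoder_hidden:
            model.encoder_hidden.W[np.ix_(rows, np.arange(j * k, (j + 1) * k))] = enc[0].W
            model.encoder_out.W[j * k : (j + 1) * k, j] = enc[1].W[:, 0]
            if arch.encoder_bias:
                model.encoder_hidden.b[j * k : (j + 1) * k] = enc[0].b
                model.encoder_out.b[j] = enc[1].b[0]
        else:
            model.encoder_out.W[rows, j] = enc[0].W[:, 0]
            if arch.encoder_bias:
                model.encoder_out.b[j] = enc[0].b[0]
    model.encoder_out.apply_mask()
    if model.encoder_hidden is not None:
        model.encoder_hidden.apply_mask()
    if trace is not None:
        trace.step1_train = np.mean(per_set_train, axis=0).tolist()
        trace.step1_val = np.nanmean(per_set_val, axis=0).tolist() if val is not None else []
    return model


def train_step2(
    model: GsasModel,
    train: ExpressionMatrix,
    cfg: TrainingConfig,
    val: ExpressionMatrix | None = None,
    trace: TrainingTrace | None = None,
) -> GsasModel:
    """Train the decoder with the encoder frozen (bit-exact freeze)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 2]))
    tr, vl = _fit_autoencoder(
        model.encoder_layers(),
        model.decoder_layers(),
        model.arch.hidden_activation,
        train.values,
        val.values if val is not None else None,
        cfg.step2_epochs,
        cfg.step2_lr,
        cfg.batch_size,
        rng,
        train_encoder=False,
    )
    if trace is not None:
        trace.step2_train, trace.step2_val = tr, vl
    return model


def train_step3(
    model: GsasModel,
    train: ExpressionMatrix,
    cfg: TrainingConfig,
    val: ExpressionMatrix | None = None,
    trace: TrainingTrace | None = None,
) -> GsasModel:
    """Fine-tune the whole network; dropout (if configured) is active here."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 3]))
    tr, vl = _fit_autoencoder(
        model.encoder_layers(),
        model.decoder_layers(),
        model.arch.hidden_activation,
        train.values,
        val.values if val is not None else None,
        cfg.step3_epochs,
        cfg.step3_lr,
        cfg.batch_size,
        rng,
        train_encoder=True,
        dropout_rate=model.arch.dropout_rate,
    )
    if trace is not None:
        trace.step3_train, trace.step3_val = tr, vl
    return model


def train_full(
    col: GeneSetCollection,
    x: ExpressionMatrix,
    arch: ArchitectureConfig | None = None,
    cfg: TrainingConfig | None = None,
) -> tuple[GsasModel, TrainingTrace]:
    """Split, build and run the full three-step schedule; deterministic under seed.

    The model is built over the genes of ``x`` that belong to at least one
    gene set (in the matrix's gene order); ``x`` is standardized first if it
    is not already.
    """
    arch = arch or ArchitectureConfig()
    cfg = cfg or TrainingConfig()
    if not x.standardized:
        x = standardize(x)
    universe = set(col.gene_universe)
    model_genes = [g for g in x.gene_ids if g in universe]
    if not model_genes:
        raise ValueError("no gene of the expression matrix appears in any gene set")
    keep = [i for i, g in enumerate(x.gene_ids) if g in universe]
    x_model = ExpressionMatrix(
        x.values[:, keep], x.sample_ids, tuple(model_genes), standardized=True
    )
    train, val = split_train_validation(x_model, cfg)
    model = build_model(col, model_genes, arch, seed=cfg.seed)
    trace = TrainingTrace()
    val_or_none = val if val.n_samples else None
    train_step1(model, train, cfg, val_or_none, trace)
    train_step2(model, train, cfg, val_or_none, trace)
    train_step3(model, train, cfg, val_or_none, trace)
    from .network import reconstruction_mse

    trace.final_val_mse = (
        reconstruction_mse(model, val.values) if val.n_samples else reconstruction_mse(model, train.values)
    )
    model.provenance.update(
        {
            "seed": int(cfg.seed),
            "training": {
                "step1_epochs": cfg.step1_epochs,
                "step2_epochs": cfg.step2_epochs,
                "step3_epochs": cfg.step3_epochs,
                "step1_lr": cfg.step1_lr,
                "step2_lr": cfg.step2_lr,
                "step3_lr": cfg.step3_lr,
                "batch_size": cfg.batch_size,
                "validation_fraction": cfg.validation_fraction,
            },
            "n_train_samples": train.n_samples,
            "n_validation_samples": val.n_samples,
            "final_val_mse": trace.final_val_mse,
        }
    )
    return model, trace
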