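"""The masked autoencoder whose bottleneck neurons are gene sets.

The encoder maps the standardized expression vector x in R^n to p gene set
activity scores (GSAS); each bottleneck neuron is connected only to the
genes of its gene set, enforced by a binary mask on the encoder weights.
GSAS are the *pre-activation* outputs of the bottleneck. The decoder is a
fully connected layer (optionally with a hidden layer) that reconstructs x
from the activated scores.

Variants
--------
``geneset``             masked encoder -> p scores -> dense decoder (main model)
``geneset_dense``       adds a dense hidden layer (default 1000 units) in the decoder
``dense_geneset``       adds a per-set hidden layer (default 10 neurons per set,
                        block-masked) in the encoder
``dense_geneset_dense`` both of the above
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Sequence

import h5py
import numpy as np

from ._nn import ACTIVATIONS, Dense, act_forward
from .expression import ExpressionMatrix
from .genesets import GeneSetCollection

__all__ = [
    "ArchitectureConfig",
    "GsasModel",
    "build_model",
    "build_mask",
    "encode",
    "decode",
    "reconstruct",
    "save_model",
    "load_model",
]

_VARIANTS = ("geneset", "geneset_dense", "dense_geneset", "dense_geneset_dense")
_BUNDLE_VERSION = 1


@dataclass(frozen=True)
class ArchitectureConfig:
    """Network architecture options.

    ``decoder_hidden_units`` is consulted only for ``*_dense`` variants and
    ``encoder_neurons_per_set`` only for ``dense_*`` variants. The dropout
    layer sits on the decoder input and is active only during the
    fine-tuning step of training.
    """

    variant: str = "geneset"
    decoder_hidden_units: int = 1000
    encoder_neurons_per_set: int = 10
    dropout_rate: float = 0.0
    hidden_activation: str = "tanh"
    encoder_bias: bool = False
    decoder_bias: bool = True

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {_VARIANTS}")
        if self.hidden_activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.hidden_activation!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def has_encoder_hidden(self) -> bool:
        return self.variant in ("dense_geneset", "dense_geneset_dense")

    @property
    def has_decoder_hidden(self) -> bool:
        return self.variant in ("geneset_dense", "dense_geneset_dense")


def build_mask(col: GeneSetCollection, gene_ids: Sequence[str]) -> np.ndarray:
    """n_genes x n_sets binary membership mask; errors on empty intersections."""
    pos = {g: i for i, g in enumerate(gene_ids)}
    mask = np.zeros((len(gene_ids), len(col)), dtype=np.float64)
    for j, s in enumerate(col.sets):
        rows = [pos[g] for g in s.genes if g in pos]
        if not rows:
            raise ValueError(f"gene set {s.id!r} has no gene present in the expression data")
        mask[rows, j] = 1.0
    return mask


@dataclass
class GsasModel:
    """Trained (or initialized) gene set autoencoder.

    ``encoder_weights`` (genes x sets) always satisfies
    ``encoder_weights * (1 - mask) == 0`` exactly, at every point of training.
    """

    gene_ids: tuple[str, ...]
    set_ids: tuple[str, ...]
    mask: np.ndarray
    arch: ArchitectureConfig
    encoder_hidden: Dense | None
    encoder_out: Dense
    decoder_hidden: Dense | None
    decoder_out: Dense
    provenance: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_sets(self) -> int:
        return len(self.set_ids)

    @property
    def encoder_weights(self) -> np.ndarray:
        """Gene -> gene set weights (genes x sets) of the bottleneck layer.

        For ``dense_*`` variants these are the weights of the first (gene
        facing) encoder layer aggregated over each set's hidden neurons via
        the second-layer weights, giving an effective gene->set linear map
        in the small-signal regime.
        """
        if not self.arch.has_encoder_hidden:
            return self.encoder_out.weight
        return self.encoder_hidden.weight @ self.encoder_out.weight

    @property
    def decoder_weights(self) -> np.ndarray:
        return self.decoder_out.weight

    @property
    def decoder_bias(self) -> np.ndarray | None:
        return self.decoder_out.b

    def encoder_layers(self) -> list[Dense]:
        layers = [] if self.encoder_hidden is None else [self.encoder_hidden]
        return layers + [self.encoder_out]

    def decoder_layers(self) -> list[Dense]:
        layers = [] if self.decoder_hidden is None else [self.decoder_hidden]
        return layers + [self.decoder_out]

    def all_layers(self) -> list[Dense]:
        return self.encoder_layers() + self.decoder_layers()

    def check_mask(self) -> float:
        """Max |encoder weight| outside the mask; must be exactly 0."""
        viol = float(np.max(np.abs(self.encoder_out.W * (1.0 - self.encoder_out.mask))))
        if self.encoder_hidden is not None:
            viol = max(
                viol,
                float(np.max(np.abs(self.encoder_hidden.W * (1.0 - self.encoder_hidden.mask)))),
            )
        return viol

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for layer in self.all_layers():
            h.update(np.ascontiguousarray(layer.W).tobytes())
            if layer.b is not None:
                h.update(np.ascontiguousarray(layer.b).tobytes())
        h.update("\n".join(self.gene_ids).encode())
        h.update("\n".join(self.set_ids).encode())
        return h.hexdigest()

    def canonicalize_signs(self) -> np.ndarray:
        """Flip each gene set column so its largest-|weight| gene is positive.

        GSAS signs are arbitrary (they depend on the weight initialization);
        this makes them deterministic. Decoder columns are flipped with the
        encoder so reconstructions are unchanged. Returns the vector of
        applied signs (+-1 per set). Not available for ``dense_*`` encoders.
        """
        if self.arch.has_encoder_hidden:
            raise NotImplementedError("sign canonicalization requires a single encoder layer")
        W = self.encoder_out.W
        top = np.abs(W).argmax(axis=0)
        signs = np.sign(W[top, np.arange(self.n_sets)])
        signs[signs == 0] = 1.0
        self.encoder_out.W *= signs[None, :]
        if self.arch.hidden_activation in ("tanh", "linear"):  # odd activation: exact inverse
            if self.decoder_hidden is not None:
                self.decoder_hidden.W *= signs[:, None]
            else:
                self.decoder_out.W *= signs[:, None]
        return signs


def build_model(
    col: GeneSetCollection,
    gene_ids: Sequence[str],
    arch: ArchitectureConfig | None = None,
    seed: int = 0,
) -> GsasModel:
    """Assemble a freshly initialized model over ``gene_ids``.

    Weights use a seeded Glorot-style uniform scheme on unmasked entries;
    masked entries are exactly 0.
    """
    arch = arch or ArchitectureConfig()
    gene_ids = tuple(map(str, gene_ids))
    set_ids = tuple(col.ids)
    n, p = len(gene_ids), len(set_ids)
    if p >= n:
        warnings.warn(f"{p} gene sets >= {n} genes: the bottleneck is not compressive", stacklevel=2)
    mask = build_mask(col, gene_ids)
    rng = np.random.default_rng(np.random.SeedSequence([2**31 - 1, int(seed)]))

    enc_hidden = None
    if arch.has_encoder_hidden:
        k = arch.encoder_neurons_per_set
        mask1 = np.repeat(mask, k, axis=1)  # n x (k*p)
        mask2 = np.zeros((k * p, p))
        for j in range(p):
            mask2[j * k : (j + 1) * k, j] = 1.0
        enc_hidden = Dense(n, k * p, mask=mask1, bias=arch.encoder_bias,
                           activation=arch.hidden_activation, rng=rng)
        enc_out = Dense(k * p, p, mask=mask2, bias=arch.encoder_bias, activation="linear", rng=rng)
    else:
        enc_out = Dense(n, p, mask=mask, bias=arch.encoder_bias, activation="linear", rng=rng)

    dec_hidden = None
    if arch.has_decoder_hidden:
        h = arch.decoder_hidden_units
        dec_hidden = Dense(p, h, bias=arch.decoder_bias, activation=arch.hidden_activation, rng=rng)
        dec_out = Dense(h, n, bias=arch.decoder_bias, activation="linear", rng=rng)
    else:
        dec_out = Dense(p, n, bias=arch.decoder_bias, activation="linear", rng=rng)

    return GsasModel(
        gene_ids=gene_ids,
        set_ids=set_ids,
        mask=mask,
        arch=arch,
        encoder_hidden=enc_hidden,
        encoder_out=enc_out,
        decoder_hidden=dec_hidden,
        decoder_out=dec_out,
        provenance={"seed": int(seed)},
    )


def _check_aligned(model: GsasModel, x: ExpressionMatrix) -> None:
    if tuple(x.gene_ids) != tuple(model.gene_ids):
        raise ValueError("expression matrix genes are not aligned to the model; "
                         "use expression.align_to_model first")
    if not x.standardized:
        raise ValueError("expression matrix must be standardized")


def encode(model: GsasModel, x: ExpressionMatrix):
    """Gene set activity scores: pre-activation bottleneck outputs (samples x sets)."""
    from .scoring import ScoreMatrix  # local import: scoring builds on network

    _check_aligned(model, x)
    values = encode_values(model, x.values)
    return ScoreMatrix(values, x.sample_ids, model.set_ids, model.fingerprint())


def encode_values(model: GsasModel, values: np.ndarray) -> np.ndarray:
    """Encoder forward pass on a raw (already aligned/standardized) array."""
    h = values
    if model.encoder_hidden is not None:
        h = model.encoder_hidden.forward(h, cache=False)
    return model.encoder_out.forward(h, cache=False)  # linear output = pre-activation scores


def decode(model: GsasModel, scores: np.ndarray) -> np.ndarray:
    """Reconstruction from scores: activation, then the decoder stack."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[1] != model.n_sets:
        raise ValueError(f"scores must be samples x {model.n_sets}, got {scores.shape}")
    a = act_forward(scores, model.arch.hidden_activation)
    if model.decoder_hidden is not None:
        a = model.decoder_hidden.forward(a, cache=False)
    return model.decoder_out.forward(a, cache=False)


def reconstruct(model: GsasModel, values: np.ndarray) -> np.ndarray:
    return decode(model, encode_values(model, values))


def reconstruction_mse(model: GsasModel, values: np.ndarray) -> float:
    r = reconstruct(model, values)
    return float(np.mean((r - values) ** 2))


def save_model(model: GsasModel, path) -> None:
    """Serialize to an HDF5 bundle (weights, ids, memberships, config, provenance)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = _BUNDLE_VERSION
        fh.attrs["arch"] = json.dumps(asdict(model.arch))
        fh.attrs["provenance"] = json.dumps(model.provenance, default=str)
        fh.create_dataset("gene_ids", data=np.array(model.gene_ids, dtype="S"))
        fh.create_dataset("set_ids", data=np.array(model.set_ids, dtype="S"))
        fh.create_dataset("mask", data=model.mask.astype(np.uint8))
        for name, layer in _named_layers(model):
            grp = fh.create_group(name)
            grp.create_dataset("W", data=layer.W)
            if layer.b is not None:
                grp.create_dataset("b", data=layer.b)
            if layer.mask is not None:
                grp.create_dataset("mask", data=layer.mask.astype(np.uint8))
            grp.attrs["activation"] = layer.activation


def _named_layers(model: GsasModel):
    pairs = []
    if model.encoder_hidden is not None:
        pairs.append(("encoder_hidden", model.encoder_hidden))
    pairs.append(("encoder_out", model.encoder_out))
    if model.decoder_hidden is not None:
        pairs.append(("decoder_hidden", model.decoder_hidden))
    pairs.append(("decoder_out", model.decoder_out))
    return pairs


def _load_layer(grp) -> Dense:
    W = np.asarray(grp["W"], dtype=np.float64)
    mask = np.asarray(grp["mask"], dtype=np.float64) if "mask" in grp else None
    layer = Dense(W.shape[0], W.shape[1], mask=mask, bias="b" in grp,
                  activation=grp.attrs["activation"])
    layer.W = W
    if "b" in grp:
        layer.b = np.asarray(grp["b"], dtype=np.float64)
    return layer


def load_model(path) -> GsasModel:
    """Load an HDF5 bundle written by :func:`save_model`; validates consistency."""
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("format_version")
        if version != _BUNDLE_VERSION:
            raise ValueError(f"unsupported bundle version {version!r}")
        arch = ArchitectureConfig(**json.loads(fh.attrs["arch"]))
        provenance = json.loads(fh.attrs["provenance"])
        gene_ids = tuple(g.decode() for g in fh["gene_ids"][()])
        set_ids = tuple(s.decode() for s in fh["set_ids"][()])
        mask = np.asarray(fh["mask"], dtype=np.float64)
        layers = {name: _load_layer(fh[name]) for name in
                  ("encoder_hidden", "encoder_out", "decoder_hidden", "decoder_out")
                  if name in fh}
    if mask.shape != (len(gene_ids), len(set_ids)):
        raise ValueError(
            f"corrupted bundle: mask shape {mask.shape} inconsistent with "
            f"{len(gene_ids)} genes x {len(set_ids)} sets"
        )
    model = GsasModel(
        gene_ids=gene_ids,
        set_ids=set_ids,
        mask=mask,
        arch=arch,
        encoder_hidden=layers.get("encoder_hidden"),
        encoder_out=layers["encoder_out"],
        decoder_hidden=layers.get("decoder_hidden"),
        decoder_out=layers["decoder_out"],
        provenance=provenance,
    )
    if model.check_mask() != 0.0:
        raise ValueError("corrupted bundle: nonzero encoder weight outside the mask")
    n_in = model.encoder_hidden.W.shape[0] if model.encoder_hidden else model.encoder_out.W.shape[0]
    if n_in != len(gene_ids):
        raise ValueError("corrupted bundle: encoder input size inconsistent with gene list")
    return model
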