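"""Autoencoder representation learning and classical baselines.

Four autoencoder families learn low-dimensional embeddings of profile
matrices by minimizing reconstruction error:

* SAE — shallow autoencoder: input → latent → output, linear latent and
  output activations; latent sizes 32…512.
* DAE — deep autoencoder: 1 or 2 ReLU hidden layers inserted on each
  side of the latent layer, widths doubling outward (e.g. latent 512
  with two inserted layers gives 2048/1024/512/1024/2048).
* VAE — variational autoencoder with one ReLU intermediate layer, a
  diagonal-Gaussian posterior over a 4/8/16-dimensional latent, trained
  on the negative evidence lower bound (squared-error reconstruction
  plus closed-form KL to a standard-normal prior) with the
  reparameterization trick.
* CAE — convolutional autoencoder on the input vector reshaped to a
  d × d image (d = ⌊√n⌋ + 1, zero-padded), strided valid convolutions
  whose filter sizes are percentages of the incoming width, mirrored by
  transposed convolutions; the flattened last encoder layer is the
  representation.

Training uses Adam (learning rate 0.001, epsilon 1e-07), minibatches of
32, and early stopping: stop after 20 epochs without validation-loss
improvement and restore the best epoch's weights.

PCA (components explaining 99% of training variance) and Gaussian
random projection (target dimension from the Johnson–Lindenstrauss
bound at eps = 0.5) are provided as non-learned baselines.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.random_projection import (
    GaussianRandomProjection,
    johnson_lindenstrauss_min_dim,
)

from . import _nn
from ._nn import TrainingLog

__all__ = [
    "AEKind",
    "AEArchitecture",
    "ArchitectureError",
    "TrainedEncoder",
    "VAEOutputs",
    "enumerate_ae_grid",
    "dae_layer_schedule",
    "reshape_to_square",
    "square_side",
    "flatten_from_square",
    "cae_filter_schedule",
    "cae_geometry",
    "vae_objective",
    "train_autoencoder",
    "encode",
    "pca_reduce",
    "rp_reduce",
]

LATENT_GRID = (32, 64, 128, 256, 512)
VAE_LATENT_GRID = (4, 8, 16)
VAE_INTERMEDIATE_GRID = (32, 64, 128, 256, 512)
CAE_FILTER_GRID = (4, 8, 16, 32, 64)
CAE_DEPTH_GRID = (2, 3)


class ArchitectureError(ValueError):
    """An autoencoder architecture is inconsistent or infeasible."""


class AEKind(str, enum.Enum):
    SAE = "SAE"
    DAE = "DAE"
    VAE = "VAE"
    CAE = "CAE"


@dataclass(frozen=True)
class AEArchitecture:
    """A fully resolved autoencoder design.

    Only the fields relevant to ``kind`` are meaningful: ``latent_dim``
    and ``n_added_layers`` for SAE/DAE, ``latent_dim`` and
    ``intermediate_units`` for VAE, ``n_conv_layers`` and
    ``first_filters`` for CAE (whose representation size is determined
    by the convolution geometry, not chosen directly).
    """

    kind: AEKind
    input_dim: int
    latent_dim: int | None = None
    n_added_layers: int = 0
    intermediate_units: int | None = None
    n_conv_layers: int | None = None
    first_filters: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "kind", AEKind(self.kind))
        if self.input_dim < 1:
            raise ArchitectureError("input_dim must be positive")
        k = self.kind
        if k in (AEKind.SAE, AEKind.DAE):
            if self.latent_dim is None or self.latent_dim < 1:
                raise ArchitectureError(f"{k.value} requires a positive latent_dim")
            if k is AEKind.SAE and self.n_added_layers != 0:
                raise ArchitectureError("SAE has no added layers")
            if k is AEKind.DAE and self.n_added_layers not in (1, 2):
                raise ArchitectureError("DAE n_added_layers must be 1 or 2")
        elif k is AEKind.VAE:
            if self.latent_dim not in VAE_LATENT_GRID:
                raise ArchitectureError(f"VAE latent_dim must be in {VAE_LATENT_GRID}")
            if self.intermediate_units not in VAE_INTERMEDIATE_GRID:
                raise ArchitectureError(
                    f"VAE intermediate_units must be in {VAE_INTERMEDIATE_GRID}"
                )
        else:  # CAE
            if self.n_conv_layers not in CAE_DEPTH_GRID:
                raise ArchitectureError(f"CAE n_conv_layers must be in {CAE_DEPTH_GRID}")
            if self.first_filters not in CAE_FILTER_GRID:
                raise ArchitectureError(f"CAE first_filters must be in {CAE_FILTER_GRID}")

    def describe(self) -> str:
        k = self.kind
        if k is AEKind.SAE:
            return f"SAE(latent={self.latent_dim})"
        if k is AEKind.DAE:
            return f"DAE(latent={self.latent_dim}, added={self.n_added_layers})"
        if k is AEKind.VAE:
            return f"VAE(latent={self.latent_dim}, intermediate={self.intermediate_units})"
        return f"CAE(first_filters={self.first_filters}, conv_layers={self.n_conv_layers})"

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "input_dim": self.input_dim,
            "latent_dim": self.latent_dim,
            "n_added_layers": self.n_added_layers,
            "intermediate_units": self.intermediate_units,
            "n_conv_layers": self.n_conv_layers,
            "first_filters": self.first_filters,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AEArchitecture":
        return cls(**d)


def enumerate_ae_grid(kind, input_dim: int) -> list[AEArchitecture]:
    """The hyper-parameter grid of architectures for one family.

    Grid sizes: SAE 5, DAE 10, VAE 15, CAE 10.
    """
    kind = AEKind(kind)
    archs: list[AEArchitecture] = []
    if kind is AEKind.SAE:
        for latent in LATENT_GRID:
            archs.append(AEArchitecture(kind, input_dim, latent_dim=latent))
    elif kind is AEKind.DAE:
        for latent in LATENT_GRID:
            for added in (1, 2):
                archs.append(
                    AEArchitecture(kind, input_dim, latent_dim=latent, n_added_layers=added)
                )
    elif kind is AEKind.VAE:
        for inter in VAE_INTERMEDIATE_GRID:
            for latent in VAE_LATENT_GRID:
                archs.append(
                    AEArchitecture(
                        kind, input_dim, latent_dim=latent, intermediate_units=inter
                    )
                )
    else:
        for depth in CAE_DEPTH_GRID:
            for filters in CAE_FILTER_GRID:
                archs.append(
                    AEArchitecture(
                        kind, input_dim, n_conv_layers=depth, first_filters=filters
                    )
                )
    return archs


def dae_layer_schedule(latent_dim: int, n_added_layers: int) -> list[int]:
    """Hidden-layer widths encoder → latent → decoder, doubling outward.

    ``(512, 2)`` gives ``[2048, 1024, 512, 1024, 2048]``; ``(x, 0)``
    degenerates to the shallow case ``[x]``.
    """
    if latent_dim < 1:
        raise ArchitectureError("latent_dim must be positive")
    if n_added_layers < 0:
        raise ArchitectureError("n_added_layers must be non-negative")
    enc = [latent_dim * 2**j for j in range(n_added_layers, 0, -1)]
    return enc + [latent_dim] + enc[::-1]


def square_side(n: int) -> int:
    """Side d of the zero-padded square image for an n-vector: ⌊√n⌋ + 1."""
    if n < 1:
        raise ArchitectureError("n must be positive")
    return math.isqrt(n) + 1


def reshape_to_square(x: np.ndarray) -> np.ndarray:
    """Reshape a length-n vector to a d × d grid, d = ⌊√n⌋ + 1, row-major,
    zero-padding the d² − n trailing cells."""
    x = np.asarray(x).ravel()
    d = square_side(x.size)
    out = np.zeros(d * d, dtype=float)
    out[: x.size] = x
    return out.reshape(d, d)


def flatten_from_square(grid: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`reshape_to_square`: first n row-major cells."""
    return np.asarray(grid).ravel()[:n].copy()


def cae_filter_schedule(first_filters: int, n_conv_layers: int) -> list[int]:
    """Per-encoder-layer filter counts, halving at each layer."""
    schedule = [first_filters // 2**k for k in range(n_conv_layers)]
    if any(f < 1 for f in schedule):
        raise ArchitectureError(
            f"filter schedule {schedule} reaches zero filters "
            f"(first_filters={first_filters}, n_conv_layers={n_conv_layers})"
        )
    return schedule


def cae_geometry(input_d: int, n_conv_layers: int) -> list[tuple[int, int]]:
    """(filter_size, stride) per encoder conv layer for a d × d input.

    Layer 1 uses a filter of 10% of the input side with stride 25% of the
    filter; each later layer uses 10% of the preceding output size with
    stride 50% of its filter. All sizes floor with a minimum of 1; a
    layer whose output size would fall below 1 is a configuration error.
    """
    if input_d < 10:
        raise ArchitectureError(f"CAE needs input side >= 10, got {input_d}")
    geometry: list[tuple[int, int]] = []
    size = input_d
    for layer in range(n_conv_layers):
        filt = max(1, int(0.1 * size))
        stride = max(1, int((0.25 if layer == 0 else 0.5) * filt))
        out = _nn.conv_output_size(size, filt, stride)
        if out < 1:
            raise ArchitectureError(
                f"CAE layer {layer + 1} output size {out} < 1 "
                f"(input side {size}, filter {filt}, stride {stride})"
            )
        geometry.append((filt, stride))
        size = out
    return geometry


@dataclass(frozen=True)
class VAEOutputs:
    """One VAE forward pass: posterior parameters, sample, reconstruction."""

    mu: np.ndarray
    log_var: np.ndarray
    z_sample: np.ndarray
    reconstruction: np.ndarray


def vae_objective(x: np.ndarray, outputs: VAEOutputs) -> tuple[float, float, float]:
    """Negative ELBO for one input: (total, reconstruction_term, kl_term).

    reconstruction = ‖x − x̂‖²; kl = −½ Σ_j (1 + log σ²_j − μ²_j − σ²_j),
    the closed-form KL divergence from the diagonal-Gaussian posterior to
    the standard-normal prior (non-negative, zero iff μ = 0, log σ² = 0).
    """
    x = np.asarray(x, dtype=float).ravel()
    mu = np.asarray(outputs.mu, dtype=float).ravel()
    log_var = np.asarray(outputs.log_var, dtype=float).ravel()
    recon = float(np.sum((x - np.asarray(outputs.reconstruction).ravel()) ** 2))
    kl = float(-0.5 * np.sum(1.0 + log_var - mu**2 - np.exp(log_var)))
    return recon + kl, recon, kl


# ---------------------------------------------------------------------------
# model construction


class _DenseAE:
    """SAE/DAE: fully connected encoder/decoder, MSE reconstruction."""

    def __init__(self, arch: AEArchitecture, rng: np.random.Generator):
        widths = dae_layer_schedule(arch.latent_dim, arch.n_added_layers)
        half = len(widths) // 2
        enc_widths = widths[: half + 1]  # ...down to latent
        enc_layers: list[_nn.Layer] = []
        prev = arch.input_dim
        for i, w in enumerate(enc_widths):
            enc_layers.append(_nn.Dense(prev, w, rng))
            if i < len(enc_widths) - 1:
                enc_layers.append(_nn.ReLU())  # inserted layers are ReLU
            prev = w
        dec_layers: list[_nn.Layer] = []
        for w in widths[half + 1 :]:
            dec_layers.append(_nn.Dense(prev, w, rng))
            dec_layers.append(_nn.ReLU())
            prev = w
        dec_layers.append(_nn.Dense(prev, arch.input_dim, rng))  # linear output
        self.encoder = _nn.Sequential(enc_layers)
        self.decoder = _nn.Sequential(dec_layers)
        self.latent_dim = arch.latent_dim

    def params(self):
        return self.encoder.params() + self.decoder.params()

    def grads(self):
        return self.encoder.grads() + self.decoder.grads()

    def _forward(self, x, training):
        return self.decoder.forward(self.encoder.forward(x, training), training)

    def training_step(self, x) -> float:
        out = self._forward(x, True)
        diff = out - x
        loss = float(np.mean(diff**2))
        self.encoder.backward(self.decoder.backward(2.0 * diff / diff.size))
        return loss

    def evaluate(self, x) -> float:
        out = self._forward(x, False)
        return float(np.mean((out - x) ** 2))

    def encode(self, x):
        return self.encoder.forward(x, False)


class _VAENet:
    """VAE: ReLU intermediate layer, Gaussian posterior, negative-ELBO loss.

    The training loss is the per-sample negative ELBO (summed over
    features/latent dimensions) averaged over the minibatch; validation
    uses the deterministic z = μ pass so early stopping is noise-free.
    """

    def __init__(self, arch: AEArchitecture, rng: np.random.Generator, eps_rng):
        d, h, k = arch.input_dim, arch.intermediate_units, arch.latent_dim
        self.enc_h = _nn.Dense(d, h, rng)
        self.enc_act = _nn.ReLU()
        self.enc_mu = _nn.Dense(h, k, rng)
        self.enc_lv = _nn.Dense(h, k, rng)
        self.dec_h = _nn.Dense(k, h, rng)
        self.dec_act = _nn.ReLU()
        self.dec_out = _nn.Dense(h, d, rng)
        self.eps_rng = eps_rng
        self.latent_dim = k

    def params(self):
        layers = (self.enc_h, self.enc_mu, self.enc_lv, self.dec_h, self.dec_out)
        return [p for l in layers for p in l.params()]

    def grads(self):
        layers = (self.enc_h, self.enc_mu, self.enc_lv, self.dec_h, self.dec_out)
        return [g for l in layers for g in l.grads()]

    def _encode_forward(self, x, training):
        h = self.enc_act.forward(self.enc_h.forward(x, training), training)
        return self.enc_mu.forward(h, training), self.enc_lv.forward(h, training)

    def _decode_forward(self, z, training):
        return self.dec_out.forward(
            self.dec_act.forward(self.dec_h.forward(z, training), training), training
        )

    def training_step(self, x) -> float:
        n = x.shape[0]
        mu, lv = self._encode_forward(x, True)
        eps = self.eps_rng.standard_normal(mu.shape)
        std = np.exp(0.5 * lv)
        z = mu + std * eps
        out = self._decode_forward(z, True)
        diff = out - x
        recon = float(np.sum(diff**2)) / n
        kl = float(-0.5 * np.sum(1.0 + lv - mu**2 - np.exp(lv))) / n
        # backward: reconstruction path through the decoder to z
        dz = self.dec_h.backward(
            self.dec_act.backward(self.dec_out.backward(2.0 * diff / n))
        )
        dmu = dz + mu / n  # KL: d/dμ of mean KL is μ/n
        dlv = dz * eps * 0.5 * std + 0.5 * (np.exp(lv) - 1.0) / n
        dh = self.enc_mu.backward(dmu) + self.enc_lv.backward(dlv)
        self.enc_h.backward(self.enc_act.backward(dh))
        return recon + kl

    def evaluate(self, x) -> float:
        n = x.shape[0]
        mu, lv = self._encode_forward(x, False)
        out = self._decode_forward(mu, False)
        recon = float(np.sum((out - x) ** 2)) / n
        kl = float(-0.5 * np.sum(1.0 + lv - mu**2 - np.exp(lv))) / n
        return recon + kl

    def encode(self, x):
        # posterior mean: deterministic representation
        return self._encode_forward(x, False)[0]


class _ConvAE:
    """CAE over the zero-padded square image; latent = flattened last
    encoder conv layer; decoder mirrors with transposed convolutions and
    a final crop/pad back to d × d."""

    def __init__(self, arch: AEArchitecture, rng: np.random.Generator):
        n = arch.input_dim
        d = square_side(n)
        geometry = cae_geometry(d, arch.n_conv_layers)
        filters = cae_filter_schedule(arch.first_filters, arch.n_conv_layers)
        self.d = d
        enc: list[_nn.Layer] = [_nn.Reshape((d, d, 1))]
        size, c_in = d, 1
        sizes = []
        for (filt, stride), c_out in zip(geometry, filters):
            enc.append(_nn.Conv2D(c_in, c_out, filt, stride, rng))
            enc.append(_nn.ReLU())
            size = _nn.conv_output_size(size, filt, stride)
            sizes.append(size)
            c_in = c_out
        self.encoder = _nn.Sequential(enc)
        self.latent_dim = sizes[-1] * sizes[-1] * filters[-1]
        dec: list[_nn.Layer] = []
        channels_out = [1] + filters[:-1]  # mirror target channels
        for i in range(arch.n_conv_layers - 1, -1, -1):
            filt, stride = geometry[i]
            dec.append(
                _nn.ConvTranspose2D(filters[i], channels_out[i], filt, stride, rng)
            )
            if i > 0:
                dec.append(_nn.ReLU())
        dec.append(_nn.CropPad2D(d))
        dec.append(_nn.Flatten())
        self.decoder = _nn.Sequential(dec)

    def params(self):
        return self.encoder.params() + self.decoder.params()

    def grads(self):
        return self.encoder.grads() + self.decoder.grads()

    def _square(self, x):
        n = x.shape[0]
        d2 = self.d * self.d
        out = np.zeros((n, d2))
        out[:, : x.shape[1]] = x
        return out

    def training_step(self, x) -> float:
        target = self._square(x)
        feat = self.encoder.forward(target, True)
        out = self.decoder.forward(feat, True)
        diff = out - target
        loss = float(np.mean(diff**2))
        self.encoder.backward(self.decoder.backward(2.0 * diff / diff.size))
        return loss

    def evaluate(self, x) -> float:
        target = self._square(x)
        out = self.decoder.forward(self.encoder.forward(target, False), False)
        return float(np.mean((out - target) ** 2))

    def encode(self, x):
        feat = self.encoder.forward(self._square(x), False)
        return feat.reshape(feat.shape[0], -1)


def _build_model(arch: AEArchitecture, seed: int):
    init_rng = np.random.default_rng([seed, 1])
    if arch.kind in (AEKind.SAE, AEKind.DAE):
        return _DenseAE(arch, init_rng)
    if arch.kind is AEKind.VAE:
        return _VAENet(arch, init_rng, np.random.default_rng([seed, 3]))
    return _ConvAE(arch, init_rng)


@dataclass
class TrainedEncoder:
    """The encoder half of a fitted autoencoder.

    ``transform`` maps an (m × input_dim) matrix to the (m × output_dim)
    latent matrix deterministically (for VAE it returns the posterior
    mean μ, not a sample). ``best_epoch`` indexes the epoch whose
    validation loss is minimal in ``training_log``.
    """

    architecture: AEArchitecture
    training_log: TrainingLog
    _model: object = field(repr=False)

    @property
    def best_epoch(self) -> int:
        return self.training_log.best_epoch

    @property
    def output_dim(self) -> int:
        return self._model.latent_dim

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.architecture.input_dim:
            raise ArchitectureError(
                f"expected (m, {self.architecture.input_dim}) input, got {x.shape}"
            )
        return self._model.encode(x)

    def save(self, path) -> None:
        """Serialize architecture + weights to a single .npz archive."""
        meta = json.dumps(
            {
                "architecture": self.architecture.to_dict(),
                "train_loss": list(map(float, self.training_log.train_loss)),
                "val_loss": list(map(float, self.training_log.val_loss)),
            }
        )
        weights = {f"w{i}": p for i, p in enumerate(self._model.params())}
        np.savez(path, meta=np.array(meta), **weights)

    @classmethod
    def load(cls, path) -> "TrainedEncoder":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            weights = [archive[f"w{i}"] for i in range(len(archive.files) - 1)]
        arch = AEArchitecture.from_dict(meta["architecture"])
        model = _build_model(arch, seed=0)
        _nn.set_weights(model, weights)
        log = TrainingLog(meta["train_loss"], meta["val_loss"])
        return cls(architecture=arch, training_log=log, _model=model)


def train_autoencoder(
    arch: AEArchitecture,
    train: np.ndarray,
    validation: np.ndarray,
    seed: int,
    *,
    batch_size: int = 32,
    max_epochs: int = 2000,
    patience: int = 20,
    lr: float = 1e-3,
) -> TrainedEncoder:
    """Fit one autoencoder; returns its encoder at the best-validation epoch.

    ``train`` and ``validation`` are row matrices over the same feature
    space and must not share samples; the validation rows drive early
    stopping only and never receive gradient updates.
    """
    train = np.asarray(train, dtype=float)
    validation = np.asarray(validation, dtype=float)
    if train.shape[1] != validation.shape[1]:
        raise ArchitectureError("train and validation feature spaces differ")
    if train.shape[1] != arch.input_dim:
        raise ArchitectureError(
            f"architecture input_dim {arch.input_dim} != data dim {train.shape[1]}"
        )
    model = _build_model(arch, seed)
    log = _nn.train_reconstruction(
        model,
        train,
        validation,
        np.random.default_rng([seed, 2]),
        batch_size=batch_size,
        max_epochs=max_epochs,
        patience=patience,
        lr=lr,
    )
    return TrainedEncoder(architecture=arch, training_log=log, _model=model)


def encode(encoder: TrainedEncoder, data: np.ndarray) -> np.ndarray:
    """Deterministic latent representation of ``data`` rows."""
    return encoder.transform(data)


def pca_reduce(train: np.ndarray, other: np.ndarray):
    """Project onto the leading principal components of the training rows.

    Keeps the smallest number of components whose cumulative explained
    variance ratio reaches 0.99; the same train-fitted projection is
    applied to ``other`` (never refit), so no information flows from
    held-out rows into the axes.
    """
    train = np.asarray(train, dtype=float)
    other = np.asarray(other, dtype=float)
    pca = PCA(svd_solver="full").fit(train)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cumvar, 0.99) + 1)
    k = min(k, len(cumvar))
    comps = pca.components_[:k]
    return (train - pca.mean_) @ comps.T, (other - pca.mean_) @ comps.T


def rp_reduce(train: np.ndarray, other: np.ndarray, eps: float = 0.5, seed: int = 0):
    """Gaussian random projection to the Johnson–Lindenstrauss dimension.

    The target dimension is 4·ln(n_samples) / (eps²/2 − eps³/3) (floored);
    if that bound does not reduce the dimensionality the data pass
    through unchanged with a warning.
    """
    train = np.asarray(train, dtype=float)
    other = np.asarray(other, dtype=float)
    n_components = int(johnson_lindenstrauss_min_dim(train.shape[0], eps=eps))
    if n_components >= train.shape[1]:
        warnings.warn(
            f"JL dimension {n_components} >= input dimension {train.shape[1]}; "
            "passing data through unchanged",
            stacklevel=2,
        )
        return train, other
    rp = GaussianRandomProjection(n_components=n_components, random_state=seed)
    rp.fit(train)
    return rp.transform(train), rp.transform(other)
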