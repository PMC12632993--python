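"""Feature representations: trained encoders and ingested embeddings.

Provides a dense autoencoder (mean-squared-error reconstruction) and a
beta-VAE whose objective

    L = reconstruction error (binary cross-entropy) + beta * KL[q(z|x) || p(z)]

traces a rate-distortion trade-off as beta varies: the mean KL term is the
rate R (nats per image) and the reconstruction error the distortion D.
Sweeping beta yields a per-image rate-distortion curve whose semi-log slope
(log10 R against D) is the "normalized rate" -- the amount of information
discarded per unit of distortion; more negative slopes mean more aggressive
compression.

Networks are small fully connected stacks trained with Adam in numpy, sized
for the low-resolution parametric stimuli this package generates.
Externally computed embeddings (e.g. activations of pretrained vision
networks) enter through :func:`encode_external`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf, expit

from .containers import EmbeddingSet, ImageSet, ValidationError


class ConfigurationError(ValueError):
    """Encoder spec is inconsistent with the data."""


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


class EstimationError(RuntimeError):
    """Too little usable data for the requested estimate."""


# --------------------------------------------------------------------------
# spec and small dense-network machinery


@dataclass
class EncoderSpec:
    """Architecture and training configuration for the dense encoders.

    ``input_size`` is the image side in pixels (inputs are flattened
    size*size*3 vectors); ``hidden`` lists the widths of the encoder's
    hidden layers (mirrored in the decoder).
    """

    input_size: int = 16
    hidden: tuple[int, ...] = (128,)
    latent_dim: int = 16
    activation: str = "gelu"
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    loss: str = "mse"          # autoencoder reconstruction loss
    l1_latent: float = 0.0     # sparse variant: L1 penalty on latent magnitude
    holdout_frac: float = 0.2  # train/test split for rate/distortion reporting

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ConfigurationError("latent dimension must be >= 1")
        if self.activation not in _ACTS:
            raise ConfigurationError(f"unknown activation {self.activation!r}")

    @property
    def input_dim(self) -> int:
        return self.input_size * self.input_size * 3


def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))


def _gelu_grad(x):
    phi = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
    return 0.5 * (1.0 + erf(x / math.sqrt(2.0))) + x * phi


_ACTS = {
    "gelu": (_gelu, _gelu_grad),
    "relu": (lambda x: np.maximum(x, 0.0), lambda x: (x > 0).astype(float)),
    "identity": (lambda x: x, lambda x: np.ones_like(x)),
}


class _Dense:
    """Fully connected layer with optional activation and Adam state."""

    def __init__(self, rng, n_in, n_out, activation="identity"):
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.act, self.act_grad = _ACTS[activation]
        self._adam = [
            np.zeros_like(self.W),
            np.zeros_like(self.b),
            np.zeros_like(self.W),
            np.zeros_like(self.b),
        ]
        self._t = 0

    def forward(self, x):
        self.x = x
        self.pre = x @ self.W + self.b
        return self.act(self.pre)

    def backward(self, grad_out):
        grad_pre = grad_out * self.act_grad(self.pre)
        self.gW = self.x.T @ grad_pre
        self.gb = grad_pre.sum(axis=0)
        return grad_pre @ self.W.T

    def step(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._t += 1
        mW, mb, vW, vb = self._adam
        for p, g, m, v in ((self.W, self.gW, mW, vW), (self.b, self.gb, mb, vb)):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**self._t)
            vhat = v / (1 - beta2**self._t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


def _split(n: int, frac: float, rng) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.permutation(n)
    n_test = max(1, int(round(frac * n))) if frac > 0 and n > 1 else 0
    return idx[n_test:], idx[:n_test]


def _check_images(images: ImageSet, spec: EncoderSpec) -> np.ndarray:
    if images.images.shape[1] != spec.input_size or images.images.shape[2] != spec.input_size:
        raise ConfigurationError(
            f"images are {images.images.shape[1]}x{images.images.shape[2]} but the spec "
            f"expects {spec.input_size}x{spec.input_size}; rescale first"
        )
    return images.flat()


def rescale_images(images: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbour rescale of an (n, H, W, 3) stack to (n, size, size, 3)."""
    n, h, w, _ = images.shape
    ri = (np.arange(size) * h / size).astype(int)
    ci = (np.arange(size) * w / size).astype(int)
    return images[:, ri][:, :, ci]


# --------------------------------------------------------------------------
# autoencoder


@dataclass
class AutoencoderResult:
    """Trained autoencoder: deterministic encoder plus training history."""

    layers_enc: list
    layers_dec: list
    latents: np.ndarray
    history: list[float]
    spec: EncoderSpec

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Deterministic map from flattened images (n, D) to latents."""
        h = np.atleast_2d(np.asarray(x, float))
        for layer in self.layers_enc:
            h = layer.forward(h)
        return h

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        h = self.encode(x)
        for layer in self.layers_dec:
            h = layer.forward(h)
        return expit(h)


def train_autoencoder(images: ImageSet, spec: EncoderSpec, seed: int = 0) -> AutoencoderResult:
    """Train a dense autoencoder under mean-squared-error reconstruction.

    Returns the trained encoder (a pure function after training), the latent
    vector of every input image, and the per-epoch training loss.
    """
    if spec.loss != "mse":
        raise ConfigurationError("autoencoder requires spec.loss == 'mse'")
    x = _check_images(images, spec)
    rng = np.random.default_rng(seed)
    sizes_enc = (spec.input_dim, *spec.hidden, spec.latent_dim)
    sizes_dec = (spec.latent_dim, *spec.hidden[::-1], spec.input_dim)
    enc = [
        _Dense(rng, a, b, spec.activation if i < len(spec.hidden) else "identity")
        for i, (a, b) in enumerate(zip(sizes_enc[:-1], sizes_enc[1:]))
    ]
    dec = [
        _Dense(rng, a, b, spec.activation if i < len(spec.hidden) else "identity")
        for i, (a, b) in enumerate(zip(sizes_dec[:-1], sizes_dec[1:]))
    ]
    n, d = x.shape
    history = []
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            xb = x[order[start : start + spec.batch_size]]
            h = xb
            for layer in enc + dec:
                h = layer.forward(h)
            y = expit(h)
            err = y - xb
            losses.append(float(np.mean(err**2)))
            # d(mse)/d(logits): 2 err/(B*D) * sigmoid'
            grad = 2.0 * err * y * (1.0 - y) / err.size
            for layer in reversed(enc + dec):
                grad = layer.backward(grad)
            for layer in enc + dec:
                layer.step(spec.learning_rate)
        epoch_loss = float(np.mean(losses))
        if not math.isfinite(epoch_loss):
            raise TrainingError("autoencoder loss diverged")
        history.append(epoch_loss)
    result = AutoencoderResult(layers_enc=enc, layers_dec=dec, latents=np.empty(0), history=history, spec=spec)
    result.latents = result.encode(x)
    return result


# --------------------------------------------------------------------------
# beta-VAE


@dataclass
class VAETrainRecord:
    """Rate/distortion bookkeeping for one trained beta-VAE."""

    beta: float
    rate: float          # mean KL per image, nats, held-out split
    distortion: float    # mean binary cross-entropy per image, held-out split
    seed: int
    train_loss: float
    test_loss: float

    def __post_init__(self) -> None:
        if self.beta < 0 or self.rate < 0 or self.distortion < 0:
            raise ValidationError("beta, rate and distortion must be >= 0")


class _VAEModel:
    """Dense beta-VAE: encoder trunk, (mu, logvar) heads, decoder."""

    def __init__(self, spec: EncoderSpec, rng):
        self.spec = spec
        sizes = (spec.input_dim, *spec.hidden)
        self.trunk = [
            _Dense(rng, a, b, spec.activation) for a, b in zip(sizes[:-1], sizes[1:])
        ]
        last = sizes[-1]
        self.head_mu = _Dense(rng, last, spec.latent_dim)
        self.head_lv = _Dense(rng, last, spec.latent_dim)
        dsizes = (spec.latent_dim, *spec.hidden[::-1])
        self.dec_hidden = [
            _Dense(rng, a, b, spec.activation) for a, b in zip(dsizes[:-1], dsizes[1:])
        ]
        self.dec_out = _Dense(rng, dsizes[-1], spec.input_dim)

    @property
    def _all_layers(self):
        return [*self.trunk, self.head_mu, self.head_lv, *self.dec_hidden, self.dec_out]

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = np.atleast_2d(np.asarray(x, float))
        for layer in self.trunk:
            h = layer.forward(h)
        return self.head_mu.forward(h), self.head_lv.forward(h)

    def decode(self, z: np.ndarray) -> np.ndarray:
        h = z
        for layer in self.dec_hidden:
            h = layer.forward(h)
        return expit(self.dec_out.forward(h))

    def losses(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-image (bce, kl) at the posterior mean (deterministic)."""
        mu, lv = self.encode(x)
        y = np.clip(self.decode(mu), 1e-7, 1 - 1e-7)
        bce = -np.sum(x * np.log(y) + (1 - x) * np.log(1 - y), axis=1)
        kl = 0.5 * np.sum(np.exp(lv) + mu**2 - 1.0 - lv, axis=1)
        return bce, kl

    def train_step(self, xb: np.ndarray, beta: float, rng) -> float:
        B = xb.shape[0]
        mu, lv = self.encode(xb)
        lv = np.clip(lv, -10.0, 10.0)
        eps = rng.standard_normal(mu.shape)
        std = np.exp(0.5 * lv)
        z = mu + eps * std
        y = np.clip(self.decode(z), 1e-7, 1 - 1e-7)

        bce = -np.sum(xb * np.log(y) + (1 - xb) * np.log(1 - y))
        kl = 0.5 * np.sum(np.exp(lv) + mu**2 - 1.0 - lv)
        l1 = np.sum(np.abs(z))
        loss = (bce + beta * kl + self.spec.l1_latent * l1) / B

        # decoder backward; BCE-with-sigmoid gradient is (y - x)
        grad = (y - xb) / B
        grad = self.dec_out.backward(grad)
        for layer in reversed(self.dec_hidden):
            grad = layer.backward(grad)
        gz = grad + self.spec.l1_latent * np.sign(z) / B
        # reparameterization: z = mu + eps*exp(lv/2)
        gmu = gz + beta * mu / B
        glv = gz * eps * std * 0.5 + beta * 0.5 * (np.exp(lv) - 1.0) / B
        gh = self.head_mu.backward(gmu) + self.head_lv.backward(glv)
        for layer in reversed(self.trunk):
            gh = layer.backward(gh)
        for layer in self._all_layers:
            layer.step(self.spec.learning_rate)
        return float(loss)


def train_beta_vae(
    images: ImageSet, beta: float, spec: EncoderSpec, seed: int = 0
) -> tuple[VAETrainRecord, _VAEModel]:
    """Train one beta-VAE and record its rate and distortion.

    Rate is the mean per-image KL divergence (nats) and distortion the mean
    per-image binary cross-entropy, both on a held-out split (80/20 by
    default) at the posterior mean.
    """
    if beta < 0:
        raise ValidationError("beta must be >= 0")
    x = _check_images(images, spec)
    if x.min() < 0 or x.max() > 1:
        raise ValidationError("images must lie in [0, 1] for binary cross-entropy")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = _split(x.shape[0], spec.holdout_frac, rng)
    model = _VAEModel(spec, rng)
    last = math.inf
    for _ in range(spec.epochs):
        order = rng.permutation(len(train_idx))
        for start in range(0, len(order), spec.batch_size):
            xb = x[train_idx[order[start : start + spec.batch_size]]]
            last = model.train_step(xb, beta, rng)
            if not math.isfinite(last):
                raise TrainingError(f"beta-VAE diverged at beta={beta}")
    bce_tr, kl_tr = model.losses(x[train_idx])
    eval_idx = test_idx if len(test_idx) else train_idx
    bce_te, kl_te = model.losses(x[eval_idx])
    record = VAETrainRecord(
        beta=float(beta),
        rate=float(np.mean(kl_te)),
        distortion=float(np.mean(bce_te)),
        seed=seed,
        train_loss=float(np.mean(bce_tr + beta * kl_tr)),
        test_loss=float(np.mean(bce_te + beta * kl_te)),
    )
    return record, model


# --------------------------------------------------------------------------
# rate-distortion curves


@dataclass
class RateDistortionCurve:
    """Per-image (beta, rate, distortion) triples from a beta sweep."""

    image_id: str
    points: list[tuple[float, float, float]]
    selected_seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValidationError("a rate-distortion curve needs >= 3 points")
        arr = np.asarray(self.points, float)
        if not np.isfinite(arr).all() or (arr[:, 1:] < 0).any():
            raise ValidationError("rates and distortions must be finite and >= 0")

    @property
    def rates(self) -> np.ndarray:
        return np.asarray([p[1] for p in self.points])

    @property
    def distortions(self) -> np.ndarray:
        return np.asarray([p[2] for p in self.points])


def default_beta_grid(n: int = 22, low: float = 1e-6, high: float = 10.0) -> np.ndarray:
    """Logarithmically spaced beta sweep (rates span orders of magnitude)."""
    return np.logspace(math.log10(low), math.log10(high), n)


def estimate_rd_curve(
    images: ImageSet,
    betas,
    seeds,
    spec: EncoderSpec,
) -> tuple[dict[str, RateDistortionCurve], int]:
    """Per-image rate-distortion curves from a beta sweep of beta-VAEs.

    One model is trained per (beta, seed); per-image KL and reconstruction
    error are evaluated at the posterior mean. The seed with the lowest
    total train/test loss across the sweep is selected and its curves
    returned, tagged with the selected seed.
    """
    betas = sorted(float(b) for b in betas)
    seeds = list(seeds)
    if len(betas) < 3:
        raise ValidationError("need at least 3 beta values")
    if not seeds:
        raise ValidationError("need at least 1 seed")
    x = _check_images(images, spec)
    per_seed: dict[int, list[tuple[float, np.ndarray, np.ndarray]]] = {}
    seed_loss: dict[int, float] = {}
    failures = 0
    for seed in seeds:
        try:
            rows = []
            total = 0.0
            for beta in betas:
                record, model = train_beta_vae(images, beta, spec, seed=seed)
                bce_i, kl_i = model.losses(x)
                rows.append((beta, kl_i, bce_i))
                total += record.train_loss + record.test_loss
            per_seed[seed] = rows
            seed_loss[seed] = total
        except TrainingError:
            failures += 1
    if not per_seed:
        raise EstimationError(f"all {failures} seeds diverged")
    best_seed = min(seed_loss, key=seed_loss.get)
    curves = {}
    for i, image_id in enumerate(images.ids):
        pts = [
            (beta, float(max(kl_i[i], 0.0)), float(max(bce_i[i], 0.0)))
            for beta, kl_i, bce_i in per_seed[best_seed]
        ]
        curves[image_id] = RateDistortionCurve(image_id, pts, selected_seed=best_seed)
    return curves, best_seed


def variational_lossiness(
    curves: dict[str, RateDistortionCurve], pairs: list[tuple[str, str]]
) -> dict[tuple[str, str], float]:
    """Per-pair lossiness: mean reconstruction error of target and lure
    across the whole beta sweep."""
    out = {}
    for t, l in pairs:
        d = np.concatenate([curves[t].distortions, curves[l].distortions])
        out[(t, l)] = float(np.mean(d))
    return out


def normalized_rate(curve) -> float:
    """Semi-log slope of a rate-distortion curve: OLS of log10(R) on D.

    Accepts a :class:`RateDistortionCurve` or an array-like of
    (beta, rate, distortion) rows; points with non-positive rate are
    filtered with a warning. Invariant to point order.
    """
    if isinstance(curve, RateDistortionCurve):
        pts = np.asarray(curve.points, float)
    else:
        pts = np.asarray(curve, float)
    rates, dist = pts[:, 1], pts[:, 2]
    usable = rates > 0
    if not usable.all():
        warnings.warn(f"{int((~usable).sum())} points with R <= 0 filtered", stacklevel=2)
    if usable.sum() < 2:
        raise EstimationError("fewer than 2 usable points for the slope")
    d_u, r_u = dist[usable], rates[usable]
    order = np.lexsort((r_u, d_u))  # canonical order: point-order invariant
    slope, _ = np.polyfit(d_u[order], np.log10(r_u[order]), 1)
    return float(slope)


# --------------------------------------------------------------------------
# external embeddings


def encode_external(matrix: np.ndarray, ids: list[str], pairs=None) -> EmbeddingSet:
    """Wrap externally computed activations as an :class:`EmbeddingSet`.

    Convolutional activation tensors (n, ...) are flattened row-wise in C
    order, i.e. ``matrix.reshape(n, -1)``: the last axis varies fastest.
    """
    arr = np.asarray(matrix, float)
    if arr.ndim < 2:
        raise ValidationError("matrix must be at least 2-D")
    arr = arr.reshape(arr.shape[0], -1)
    if arr.shape[0] != len(ids):
        raise ValidationError("row count must equal id count")
    if not np.isfinite(arr).all():
        raise ValidationError("NaN/Inf entries in external embeddings")
    return EmbeddingSet(items=arr, ids=list(ids), pairs=list(pairs or []))
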