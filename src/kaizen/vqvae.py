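"""The single-cell generative predictor: a vector-quantized autoencoder.

The network maps a square multi-cell patch to a reconstruction of only the
cell touching the patch's central pixel (an empty image when the center is
background). Its latent grid is snapped to the nearest entries of a finite
codebook; the codebook is updated with exponential moving averages of the
assigned encoder outputs rather than by gradient, the encoder receives the
straight-through gradient plus a commitment pull toward its assigned codes,
and the reconstruction objective is the L1 loss, minimized with Adam.

Layer stack (stride/kernel/unit counts follow the reference configuration;
per-layer paddings are chosen so encode -> decode preserves the patch size,
see docs/methods.md):

* encoder: three 4x4 stride-2 convs, a 4x4 stride-1 conv, a 3x3 stride-1
  conv, two residual blocks, then a 1x1 projection down to the embedding
  dimension ``D``;
* decoder: a 1x1 expansion from ``D``, a 4x4 stride-1 conv, two residual
  blocks, three 4x4 stride-2 transposed convs, and a final 3x3 stride-1
  transposed conv emitting the image channel (linear output, clamped to
  >= 0 at predict time).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Iterator, Optional, Tuple

import numpy as np

from . import nn
from .patches import TrainingPair, extract_patch

__all__ = ["VQVAEConfig", "VectorQuantizerEMA", "VQVAE", "train_vqvae"]


@dataclass
class VQVAEConfig:
    """Hyperparameters. Defaults are the full-scale reference configuration
    (40-pixel patches, 128 codes of dimension 2, 500k Adam steps); use
    :meth:`toy` for the small configuration the test suite trains."""

    patch_size: int = 40
    in_channels: int = 1
    codebook_size: int = 128
    embedding_dim: int = 2
    commitment_cost: float = 0.25
    ema_decay: float = 0.99
    ema_epsilon: float = 1e-5
    dead_code_threshold: float = 1e-3
    enc_channels: Tuple[int, ...] = (64, 64, 128, 128, 128)
    dec_t_channels: Tuple[int, ...] = (64, 64, 64)
    res_hidden: int = 32
    learning_rate: float = 1e-4
    batch_size: int = 32
    train_steps: int = 500_000
    # number of initial steps trained with a quadratic penalty before the
    # L1 objective takes over; pure sign-gradient L1 training from a cold
    # start collapses sparse targets onto the all-zero output
    warmup_steps: int = 300
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size % 8 != 0:
            raise ValueError("patch_size must be a multiple of 8 (three halvings)")
        if self.codebook_size < 1 or self.embedding_dim < 1:
            raise ValueError("codebook_size and embedding_dim must be >= 1")
        if not 0.0 < self.ema_decay < 1.0:
            raise ValueError("ema_decay must be in (0, 1)")
        if self.commitment_cost < 0:
            raise ValueError("commitment_cost must be >= 0")
        if len(self.enc_channels) != 5 or len(self.dec_t_channels) != 3:
            raise ValueError("expected 5 encoder and 3 transposed-conv channel counts")

    @classmethod
    def toy(cls, **overrides) -> "VQVAEConfig":
        """Small configuration that trains in minutes on one CPU core."""
        defaults = dict(
            patch_size=32,
            codebook_size=32,
            enc_channels=(32, 32, 64, 64, 64),
            dec_t_channels=(32, 32, 32),
            res_hidden=16,
            train_steps=3000,
            learning_rate=1e-3,
        )
        defaults.update(overrides)
        return cls(**defaults)


class VectorQuantizerEMA:
    """Nearest-neighbor vector quantization with EMA codebook updates."""

    def __init__(self, config: VQVAEConfig, rng: np.random.Generator):
        k, d = config.codebook_size, config.embedding_dim
        self.embeddings = rng.normal(0.0, 1.0, size=(k, d))
        self.ema_cluster_size = np.zeros(k)
        self.ema_embed_sum = self.embeddings.copy() * 0.0
        self.decay = config.ema_decay
        self.epsilon = config.ema_epsilon
        self.dead_threshold = config.dead_code_threshold

    @property
    def codebook_size(self) -> int:
        return self.embeddings.shape[0]

    def quantize(self, latents: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Snap each D-vector to its nearest codebook entry (Euclidean).

        ``latents`` is (..., D); returns (indices (...,), quantized (..., D)).
        Ties resolve to the lowest code index.
        """
        flat = latents.reshape(-1, self.embeddings.shape[1])
        d2 = (
            (flat ** 2).sum(axis=1, keepdims=True)
            - 2.0 * flat @ self.embeddings.T
            + (self.embeddings ** 2).sum(axis=1)[None, :]
        )
        idx = np.argmin(d2, axis=1)
        quantized = self.embeddings[idx].reshape(latents.shape)
        return idx.reshape(latents.shape[:-1]), quantized

    def ema_update(self, latents: np.ndarray, indices: np.ndarray) -> None:
        """Move codes toward the mean of their assigned vectors."""
        k, d = self.embeddings.shape
        flat = latents.reshape(-1, d)
        idx = indices.reshape(-1)
        counts = np.bincount(idx, minlength=k).astype(np.float64)
        sums = np.zeros((k, d))
        np.add.at(sums, idx, flat)
        self.ema_cluster_size = self.decay * self.ema_cluster_size + (1 - self.decay) * counts
        self.ema_embed_sum = self.decay * self.ema_embed_sum + (1 - self.decay) * sums
        total = self.ema_cluster_size.sum()
        smoothed = (
            (self.ema_cluster_size + self.epsilon)
            / (total + k * self.epsilon)
            * total
        )
        active = smoothed > 0
        self.embeddings[active] = self.ema_embed_sum[active] / smoothed[active, None]

    def reseed_dead_codes(self, latents: np.ndarray, rng: np.random.Generator) -> int:
        """Replace codes whose EMA usage collapsed with random batch vectors."""
        flat = latents.reshape(-1, self.embeddings.shape[1])
        dead = np.nonzero(self.ema_cluster_size < self.dead_threshold)[0]
        for k in dead:
            v = flat[rng.integers(flat.shape[0])]
            self.embeddings[k] = v
            self.ema_embed_sum[k] = v * max(self.ema_cluster_size[k], self.epsilon)
        return dead.size


def _build_encoder(cfg: VQVAEConfig, rng: np.random.Generator) -> nn.Sequential:
    c = cfg.enc_channels
    dt = np.dtype(cfg.dtype)
    return nn.Sequential([
        nn.Conv2d(cfg.in_channels, c[0], 4, stride=2, pad=1, rng=rng, dtype=dt),
        nn.LeakyReLU(),
        nn.Conv2d(c[0], c[1], 4, stride=2, pad=1, rng=rng, dtype=dt),
        nn.LeakyReLU(),
        nn.Conv2d(c[1], c[2], 4, stride=2, pad=1, rng=rng, dtype=dt),
        nn.LeakyReLU(),
        nn.Conv2d(c[2], c[3], 4, stride=1, pad=(1, 2, 1, 2), rng=rng, dtype=dt),
        nn.LeakyReLU(),
        nn.Conv2d(c[3], c[4], 3, stride=1, pad=1, rng=rng, dtype=dt),
        nn.ResidualBlock(c[4], cfg.res_hidden, rng=rng, dtype=dt),
        nn.ResidualBlock(c[4], cfg.res_hidden, rng=rng, dtype=dt),
        nn.Conv2d(c[4], cfg.embedding_dim, 1, rng=rng, dtype=dt),
    ])


def _build_decoder(cfg: VQVAEConfig, rng: np.random.Generator) -> nn.Sequential:
    base = cfg.enc_channels[4]
    t = cfg.dec_t_channels
    dt = np.dtype(cfg.dtype)
    return nn.Sequential([
        nn.Conv2d(cfg.embedding_dim, base, 1, rng=rng, dtype=dt),
        nn.Conv2d(base, base, 4, stride=1, pad=(1, 2, 1, 2), rng=rng, dtype=dt),
        nn.ResidualBlock(base, cfg.res_hidden, rng=rng, dtype=dt),
        nn.ResidualBlock(base, cfg.res_hidden, rng=rng, dtype=dt),
        nn.ConvTranspose2d(base, t[0], 4, stride=2, pad=1, rng=rng, dtype=dt),
        nn.LeakyReLU(),
        nn.ConvTranspose2d(t[0], t[1], 4, stride=2, pad=1, rng=rng, dtype=dt),
        nn.LeakyReLU(),
        nn.ConvTranspose2d(t[1], t[2], 4, stride=2, pad=1, rng=rng, dtype=dt),
        nn.LeakyReLU(),
        nn.ConvTranspose2d(t[2], cfg.in_channels, 3, stride=1, pad=1, rng=rng, dtype=dt),
    ])


class VQVAE:
    """Single-cell predictor with the fit/predict interface.

    ``fit`` consumes a stream of training pairs; ``predict(point, image)``
    returns the network's single-cell reconstruction for the patch centered
    at ``point`` of a padded image, clamped to nonnegative intensities.
    """

    def __init__(self, config: Optional[VQVAEConfig] = None):
        self.config = config if config is not None else VQVAEConfig()
        self._rng = np.random.default_rng(self.config.seed)
        self.encoder = _build_encoder(self.config, self._rng)
        self.decoder = _build_decoder(self.config, self._rng)
        self.quantizer = VectorQuantizerEMA(self.config, self._rng)
        self.loss_history_: list[float] = []

    # -- core ops ---------------------------------------------------------

    def encode(self, patches: np.ndarray) -> np.ndarray:
        """Patches (N, ps, ps) or (ps, ps) -> continuous latents
        (N, h, w, D)."""
        patches = np.asarray(patches)
        if patches.ndim == 2:
            patches = patches[None]
        if patches.shape[-1] != self.config.patch_size:
            raise ValueError(
                f"expected patch side {self.config.patch_size}, got {patches.shape[-1]}"
            )
        if patches.ndim == 3:  # add the trailing channel axis
            patches = patches[..., None]
        return self.encoder.forward(patches)

    def decode(self, quantized: np.ndarray) -> np.ndarray:
        """Quantized latents (N, h, w, D) -> reconstructions (N, ps, ps, C)."""
        out = self.decoder.forward(np.asarray(quantized))
        if out.shape[-2] != self.config.patch_size:
            raise ValueError("decoder output does not match patch_size")
        return out

    def reconstruct(self, patches: np.ndarray) -> np.ndarray:
        """Patches (N, ps, ps) -> single-cell reconstructions (N, ps, ps)."""
        z = self.encode(patches)
        _, zq = self.quantizer.quantize(z)
        return self.decode(zq)[..., 0]

    # -- training ---------------------------------------------------------

    def _step(self, x: np.ndarray, t: np.ndarray, opt: nn.Adam,
              quadratic: bool = False) -> float:
        cfg = self.config
        z = self.encoder.forward(x)  # (N, h, w, D)
        idx, zq = self.quantizer.quantize(z)
        zq = zq.astype(z.dtype)
        y = self.decoder.forward(zq)
        recon_loss = float(np.mean(np.abs(y - t)))
        if not np.isfinite(recon_loss):
            raise RuntimeError(
                f"non-finite training loss at step {len(self.loss_history_)}"
            )
        opt.zero_grad()
        if quadratic:  # warm-up phase
            dy = 2.0 * (y - t) / y.size
        else:  # the L1 objective
            dy = np.sign(y - t) / y.size
        g_zq = self.decoder.backward(dy)
        # straight-through to the encoder, plus the commitment pull
        g_ze = g_zq + cfg.commitment_cost * 2.0 * (z - zq) / z.size
        self.encoder.backward(g_ze)
        opt.step()
        self.quantizer.ema_update(z, idx)
        self.quantizer.reseed_dead_codes(z, self._rng)
        return recon_loss

    def fit(self, pairs: Iterable[TrainingPair], steps: Optional[int] = None) -> "VQVAE":
        """Train on a stream of pairs for ``steps`` batches (config default)."""
        cfg = self.config
        steps = cfg.train_steps if steps is None else int(steps)
        opt = nn.Adam(
            self.encoder.parameters() + self.decoder.parameters(),
            lr=cfg.learning_rate,
        )
        it: Iterator[TrainingPair] = iter(pairs)
        start = len(self.loss_history_)
        for step in range(start, start + steps):
            xs, ts = [], []
            for _ in range(cfg.batch_size):
                pair = next(it)
                xs.append(pair.input_patch)
                ts.append(pair.target_patch)
            dt = np.dtype(cfg.dtype)
            x = np.asarray(xs, dtype=dt)[..., None]
            t = np.asarray(ts, dtype=dt)[..., None]
            self.loss_history_.append(
                self._step(x, t, opt, quadratic=step < cfg.warmup_steps)
            )
        return self

    def holdout_l1(self, pairs: Iterable[TrainingPair]) -> Tuple[float, float]:
        """(model L1, zero-predictor L1) on a finite set of held-out pairs."""
        xs = np.asarray([p.input_patch for p in pairs], dtype=np.float64)
        ts = np.asarray([p.target_patch for p in pairs], dtype=np.float64)
        y = np.clip(self.reconstruct(xs), 0.0, None)
        return float(np.mean(np.abs(y - ts))), float(np.mean(np.abs(ts)))

    # -- inference --------------------------------------------------------

    def predict(self, point: Tuple[int, int], image: np.ndarray) -> np.ndarray:
        """Single-cell reconstruction for the window centered at ``point``
        (padded image coordinates); negatives clamped to zero."""
        patch = extract_patch(image, point, self.config.patch_size)
        out = self.reconstruct(patch[None])[0]
        return np.clip(out.astype(np.float64), 0.0, None)

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for i, p in enumerate(self.encoder.parameters()):
            arrays[f"enc_{i}"] = p.value
        for i, p in enumerate(self.decoder.parameters()):
            arrays[f"dec_{i}"] = p.value
        arrays["embeddings"] = self.quantizer.embeddings
        arrays["ema_cluster_size"] = self.quantizer.ema_cluster_size
        arrays["ema_embed_sum"] = self.quantizer.ema_embed_sum
        arrays["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "VQVAE":
        data = np.load(path)
        cfg_dict = json.loads(bytes(data["config_json"]).decode())
        cfg_dict["enc_channels"] = tuple(cfg_dict["enc_channels"])
        cfg_dict["dec_t_channels"] = tuple(cfg_dict["dec_t_channels"])
        model = cls(VQVAEConfig(**cfg_dict))
        for i, p in enumerate(model.encoder.parameters()):
            p.value[...] = data[f"enc_{i}"]
        for i, p in enumerate(model.decoder.parameters()):
            p.value[...] = data[f"dec_{i}"]
        model.quantizer.embeddings = data["embeddings"]
        model.quantizer.ema_cluster_size = data["ema_cluster_size"]
        model.quantizer.ema_embed_sum = data["ema_embed_sum"]
        return model


def train_vqvae(pairs: Iterable[TrainingPair], config: VQVAEConfig,
                steps: Optional[int] = None) -> VQVAE:
    """Convenience wrapper: build a model from ``config`` and fit it."""
    return VQVAE(config).fit(pairs, steps=steps)
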