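"""Paired (siamese) embedding network trained with contrastive loss.

Two pileup images — one from the actual reads, one simulated under a
candidate genotype — are mapped by the *same* convolutional encoder into a
d-dimensional embedding space. Training minimizes the contrastive loss

    L(Y, D) = Y * D^2 + (1 - Y) * max(m - D, 0)^2

over actual/simulated pairs, where D is the Euclidean embedding distance and
Y = 1 iff the simulated genotype matches the truth genotype: matched pairs are
pulled together, mismatched pairs pushed beyond the margin m.

The encoder (conv -> relu -> pool, twice; height collapse; adaptive width
pooling; linear projection; L2 normalization) and its backward pass are
implemented directly on numpy arrays, with Adam as the optimizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from svembed.pileup import ImageTensor
from svembed.variants import GenotypeHypothesis, SVRecord


# ---------------------------------------------------------------------------
# loss


@dataclass
class LossConfig:
    """Contrastive-loss margin; mismatched pairs are pushed to distance >= m."""

    margin: float = 1.0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")


def contrastive_loss(Y, D, m: float = 1.0):
    """L = Y*D^2 + (1-Y)*max(m-D, 0)^2, elementwise over arrays or scalars."""
    Y = np.asarray(Y, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("embedding distances must be non-negative")
    if m <= 0:
        raise ValueError("margin must be positive")
    loss = Y * D**2 + (1.0 - Y) * np.maximum(m - D, 0.0) ** 2
    return float(loss) if loss.ndim == 0 else loss


def pair_distance(e_actual: np.ndarray, e_sim: np.ndarray) -> float:
    """Euclidean distance between two embeddings of equal length."""
    e_actual = np.asarray(e_actual, dtype=float)
    e_sim = np.asarray(e_sim, dtype=float)
    if e_actual.shape != e_sim.shape:
        raise ValueError(
            f"embedding length mismatch: {e_actual.shape} vs {e_sim.shape}"
        )
    return float(np.linalg.norm(e_actual - e_sim))


# ---------------------------------------------------------------------------
# layers (forward + backward on numpy arrays)


def _im2col(x: np.ndarray, k: int = 3, pad: int = 1) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, k, k, h, w),
        strides=(s[0], s[1], s[2], s[3], s[2], s[3]),
        writeable=False,
    )
    return np.ascontiguousarray(win).reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, xshape: Tuple[int, ...], k: int = 3, pad: int = 1) -> np.ndarray:
    n, c, h, w = xshape
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
    return dx[:, :, pad : pad + h, pad : pad + w]


def _width_pool_matrix(w_in: int, w_out: int, dtype=np.float32) -> np.ndarray:
    """Area-weighted averaging matrix A (w_in x w_out): out = x @ A."""
    a = np.zeros((w_in, w_out), dtype=dtype)
    edges = np.linspace(0.0, w_in, w_out + 1)
    for j in range(w_out):
        lo, hi = edges[j], edges[j + 1]
        for i in range(int(np.floor(lo)), int(np.ceil(hi))):
            a[i, j] = min(hi, i + 1) - max(lo, i)
    return a / (w_in / w_out)


@dataclass
class ModelConfig:
    """Encoder geometry and capacity."""

    height: int = 100
    width: int = 300
    channels: int = 9
    embedding_dim: int = 512
    conv_channels: Tuple[int, int] = (12, 24)
    pool_columns: int = 16

    def geometry(self) -> Tuple[int, int, int]:
        return (self.height, self.width, self.channels)


class EmbeddingModel:
    """Shared-weight convolutional encoder: pileup image -> unit-norm embedding."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.training_seed = seed
        self.training_curve: List[float] = []
        rng = np.random.default_rng(seed)
        c, (f1, f2), d = config.channels, config.conv_channels, config.embedding_dim
        h2, w2 = config.height // 2, config.width // 2
        self._h4, self._w4 = h2 // 2, w2 // 2
        if self._h4 < 1 or self._w4 < 1:
            raise ValueError("image geometry too small for two 2x2 pooling stages")
        k_cols = min(config.pool_columns, self._w4)
        self._pool_a = _width_pool_matrix(self._w4, k_cols)
        flat = f2 * k_cols

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        self.params: Dict[str, np.ndarray] = {
            "w1": he((f1, c * 9), c * 9),
            "b1": np.zeros(f1, dtype=np.float32),
            "w2": he((f2, f1 * 9), f1 * 9),
            "b2": np.zeros(f2, dtype=np.float32),
            "wd": he((flat, d), flat),
            "bd": np.zeros(d, dtype=np.float32),
        }

    # -- forward -----------------------------------------------------------

    def _check_geometry(self, images: np.ndarray) -> None:
        expected = self.config.geometry()
        if images.shape[1:] != expected:
            raise ValueError(
                f"image geometry {images.shape[1:]} does not match model geometry {expected}"
            )

    def _forward(self, images: np.ndarray, want_cache: bool = False):
        self._check_geometry(images)
        p = self.params
        x = np.ascontiguousarray(images.transpose(0, 3, 1, 2)).astype(np.float32)
        n, c, h, w = x.shape

        cols1 = _im2col(x)
        z1 = (p["w1"] @ cols1 + p["b1"][None, :, None]).reshape(n, -1, h, w)
        a1 = np.maximum(z1, 0.0)
        h2, w2 = h // 2, w // 2
        pool1 = a1[:, :, : h2 * 2, : w2 * 2].reshape(n, -1, h2, 2, w2, 2).mean(axis=(3, 5))

        cols2 = _im2col(pool1)
        z2 = (p["w2"] @ cols2 + p["b2"][None, :, None]).reshape(n, -1, h2, w2)
        a2 = np.maximum(z2, 0.0)
        h4, w4 = h2 // 2, w2 // 2
        pool2 = a2[:, :, : h4 * 2, : w4 * 2].reshape(n, -1, h4, 2, w4, 2).mean(axis=(3, 5))

        hmean = pool2.mean(axis=2)  # (n, f2, w4)
        wpool = hmean @ self._pool_a  # (n, f2, k)
        flat = wpool.reshape(n, -1)
        z = flat @ p["wd"] + p["bd"]
        norm = np.linalg.norm(z, axis=1, keepdims=True)
        norm = np.maximum(norm, 1e-8)
        e = z / norm

        if not want_cache:
            return e
        cache = dict(
            x=x, cols1=cols1, z1=z1, pool1=pool1, cols2=cols2, z2=z2,
            pool2=pool2, hmean=hmean, flat=flat, z=z, norm=norm, e=e,
            shapes=(n, c, h, w, h2, w2, h4, w4),
        )
        return e, cache

    def embed(self, image) -> np.ndarray:
        """Embed one ImageTensor/array (returns (d,)) or a batch (returns (n, d))."""
        if isinstance(image, ImageTensor):
            image = image.data
        image = np.asarray(image, dtype=np.float32)
        single = image.ndim == 3
        if single:
            image = image[None]
        e = self._forward(image)
        return e[0] if single else e

    # -- backward ----------------------------------------------------------

    def _backward(self, cache: dict, de: np.ndarray) -> Dict[str, np.ndarray]:
        p = self.params
        n, c, h, w, h2, w2, h4, w4 = cache["shapes"]
        e, z, norm = cache["e"], cache["z"], cache["norm"]

        # through L2 normalization
        dz = (de - e * np.sum(e * de, axis=1, keepdims=True)) / norm
        grads = {
            "wd": cache["flat"].T @ dz,
            "bd": dz.sum(axis=0),
        }
        dflat = dz @ p["wd"].T
        f2 = self.config.conv_channels[1]
        dwpool = dflat.reshape(n, f2, -1)
        dhmean = dwpool @ self._pool_a.T
        dpool2 = np.repeat(dhmean[:, :, None, :], h4, axis=2) / h4

        da2 = np.zeros_like(cache["z2"])
        expand2 = np.repeat(np.repeat(dpool2, 2, axis=2), 2, axis=3) / 4.0
        da2[:, :, : h4 * 2, : w4 * 2] = expand2
        dz2 = da2 * (cache["z2"] > 0)
        dz2f = dz2.reshape(n, f2, -1)
        grads["w2"] = np.einsum("nfp,ncp->fc", dz2f, cache["cols2"])
        grads["b2"] = dz2f.sum(axis=(0, 2))
        dcols2 = np.einsum("fc,nfp->ncp", p["w2"], dz2f)
        dpool1 = _col2im(dcols2, cache["pool1"].shape)

        f1 = self.config.conv_channels[0]
        da1 = np.zeros_like(cache["z1"])
        expand1 = np.repeat(np.repeat(dpool1, 2, axis=2), 2, axis=3) / 4.0
        da1[:, :, : h2 * 2, : w2 * 2] = expand1
        dz1 = da1 * (cache["z1"] > 0)
        dz1f = dz1.reshape(n, f1, -1)
        grads["w1"] = np.einsum("nfp,ncp->fc", dz1f, cache["cols1"])
        grads["b1"] = dz1f.sum(axis=(0, 2))
        return grads


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingPair:
    """One actual/simulated image pair with its contrastive label."""

    actual_image: ImageTensor
    sim_image: ImageTensor
    label: int  # 1 iff the simulated genotype equals the truth genotype
    sv_id: str
    hypothesis: GenotypeHypothesis


@dataclass
class TrainConfig:
    epochs: int = 12
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0


def make_training_pairs(
    sv: SVRecord,
    actual_image: ImageTensor,
    sim_images_by_hypothesis: Dict[GenotypeHypothesis, Sequence[ImageTensor]],
    truth: Optional[Tuple[int, int]] = None,
) -> List[TrainingPair]:
    """One pair per (hypothesis, replicate), sharing the actual image.

    Exactly the replicates of the true genotype are labeled Y=1.
    """
    truth = truth if truth is not None else sv.truth_genotype
    if truth is None:
        raise ValueError(f"SV {sv.id}: truth genotype required to label training pairs")
    truth_hyp = GenotypeHypothesis(tuple(truth))
    pairs = []
    for hyp, images in sim_images_by_hypothesis.items():
        if not images:
            raise ValueError(f"SV {sv.id}: hypothesis {hyp.label} has no replicates")
        for img in images:
            pairs.append(
                TrainingPair(
                    actual_image=actual_image,
                    sim_image=img,
                    label=int(hyp == truth_hyp),
                    sv_id=sv.id,
                    hypothesis=hyp,
                )
            )
    return pairs


class _Adam:
    def __init__(self, params: Dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + eps)).astype(params[k].dtype)


def train(
    pairs: Sequence[TrainingPair],
    loss_config: LossConfig = LossConfig(),
    train_config: TrainConfig = TrainConfig(),
    model_config: Optional[ModelConfig] = None,
) -> EmbeddingModel:
    """Fit the shared encoder on actual/simulated pairs with contrastive loss.

    Training is stochastic (shuffled minibatches); reproducibility is at the
    level of the recorded per-epoch loss curve under a fixed seed. Raises on
    NaN loss (divergence).
    """
    if not pairs:
        raise ValueError("training requires at least one pair")
    h, w, c = pairs[0].actual_image.data.shape
    if model_config is None:
        model_config = ModelConfig(height=h, width=w, channels=c)
    model = EmbeddingModel(model_config, seed=train_config.seed)

    a = np.stack([p.actual_image.data for p in pairs]).astype(np.float32)
    s = np.stack([p.sim_image.data for p in pairs]).astype(np.float32)
    y = np.array([p.label for p in pairs], dtype=np.float32)
    m = loss_config.margin

    rng = np.random.default_rng(train_config.seed)
    opt = _Adam(model.params, train_config.learning_rate)
    n = len(pairs)
    bs = min(train_config.batch_size, n)

    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        losses = []
        for i0 in range(0, n, bs):
            idx = order[i0 : i0 + bs]
            ea, ca = model._forward(a[idx], want_cache=True)
            es, cs = model._forward(s[idx], want_cache=True)
            diff = ea - es
            d = np.linalg.norm(diff, axis=1)
            yb = y[idx]
            hinge = np.maximum(m - d, 0.0)
            batch_loss = float(np.mean(yb * d**2 + (1 - yb) * hinge**2))
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={batch_loss}, "
                    f"lr={train_config.learning_rate}, batch={bs}"
                )
            losses.append(batch_loss)
            # dL/dD then dD/d(e_a - e_s)
            dl_dd = (2 * yb * d - 2 * (1 - yb) * hinge) / len(idx)
            safe_d = np.maximum(d, 1e-8)
            ddiff = diff * (dl_dd / safe_d)[:, None]
            ga = model._backward(ca, ddiff.astype(np.float32))
            gs = model._backward(cs, (-ddiff).astype(np.float32))
            grads = {k: ga[k] + gs[k] for k in ga}
            opt.step(model.params, grads)
        model.training_curve.append(float(np.mean(losses)))
    return model


def ensemble_distance(models: Sequence[EmbeddingModel], image_pair: Tuple) -> float:
    """Average the per-model distances for one actual/simulated image pair."""
    if not models:
        raise ValueError("ensemble requires at least one model")
    actual, sim = image_pair
    return float(
        np.mean([pair_distance(mod.embed(actual), mod.embed(sim)) for mod in models])
    )


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: EmbeddingModel, path: str) -> None:
    """Save parameters plus geometry/config; loadable with :func:`load_model`."""
    meta = {
        "config": asdict(model.config),
        "training_seed": model.training_seed,
        "training_curve": model.training_curve,
        "channels": model.config.channels,
    }
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=json.dumps(meta), **model.params)


def load_model(path: str, expect_geometry: Optional[Tuple[int, int, int]] = None) -> EmbeddingModel:
    """Load a checkpoint; refuses geometry mismatches against the runtime config."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        cfg = meta["config"]
        cfg["conv_channels"] = tuple(cfg["conv_channels"])
        config = ModelConfig(**cfg)
        if expect_geometry is not None and tuple(expect_geometry) != config.geometry():
            raise ValueError(
                f"checkpoint geometry {config.geometry()} does not match "
                f"runtime geometry {tuple(expect_geometry)}"
            )
        model = EmbeddingModel(config, seed=meta.get("training_seed", 0))
        model.training_curve = list(meta.get("training_curve", []))
        for k in model.params:
            model.params[k] = data[k]
    return model
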