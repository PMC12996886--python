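"""The adversarial convolution network (ACN) and its losses.

The model is a 3D convolutional encoder producing a "stratified feature"
embedding, a 90-way softmax age head trained against distributional (soft)
age labels with an L1 + KL loss, and one linear "mixed module" per confound
factor (gender, data site) reached only through a gradient reversal layer.
The confound heads minimise a cross-entropy while — through the reversed
gradient — the encoder maximises it, so the embedding is pushed towards
confound invariance while remaining predictive of age.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, grad_reverse
from .soft_labels import BIN_CENTERS, N_BINS, ages_to_soft_labels

__all__ = [
    "ACNConfig",
    "ModelOutputs",
    "ACNModel",
    "build_model",
    "grad_reverse",
    "lambda_schedule",
    "age_loss",
    "confound_loss",
    "total_loss",
]

PROB_FLOOR = 1e-12  # floor under predicted probabilities before any log
CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ACNConfig:
    """Architecture and optimisation settings.

    Real-scale defaults follow the published training recipe (Adam, learning
    rate 1e-4, batch size 12, 200 epochs); the phantom-scale profile used in
    the tests overrides epochs and learning rate for desk-size grids.
    """

    conv_blocks: int = 3
    channels_per_block: Optional[Tuple[int, ...]] = None
    embedding_dim: int = 32
    confound_factors: Tuple[Tuple[str, int], ...] = (("gender", 2), ("site", 2))
    sigma: float = 2.0
    lambda_max: float = 1.0
    learning_rate: float = 1e-4
    weight_decay: float = 0.0
    batch_size: int = 12
    epochs: int = 200

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (0 <= self.lambda_max <= 1):
            raise ValueError(f"lambda_max must be in [0, 1], got {self.lambda_max}")
        for name, n_classes in self.confound_factors:
            if n_classes < 2:
                raise ValueError(f"confound factor {name!r} needs >= 2 classes, got {n_classes}")
        if self.channels_per_block is not None and len(self.channels_per_block) != self.conv_blocks:
            raise ValueError("channels_per_block length must equal conv_blocks")

    @property
    def channels(self) -> Tuple[int, ...]:
        if self.channels_per_block is not None:
            return tuple(self.channels_per_block)
        return tuple(4 * 2 ** i for i in range(self.conv_blocks))

    @staticmethod
    def phantom_profile(**overrides) -> "ACNConfig":
        """Desk-scale profile: 3 blocks, 30 epochs, lr 1e-3 on a 32x40x32 grid.

        The 16-unit embedding is a deliberate middle ground: narrow enough
        that adversarial pressure can sweep confound directions out of it,
        wide enough that a baseline trained without mixed modules still
        carries them (the contrast the confound-removal evaluation probes).
        """
        base = dict(conv_blocks=3, embedding_dim=16, learning_rate=1e-3, epochs=30)
        base.update(overrides)
        return ACNConfig(**base)


@dataclass
class ModelOutputs:
    """Per-batch forward results (numpy arrays)."""

    age_probs: np.ndarray                       # (N, 90), rows sum to 1
    age_point: np.ndarray                       # (N,) expectation decode
    confound_probs: Dict[str, np.ndarray]       # factor -> (N, C_i)
    features: np.ndarray                        # (N, embedding_dim)

    def __post_init__(self) -> None:
        for name, p in [("age", self.age_probs)] + list(self.confound_probs.items()):
            if np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-6):
                raise ValueError(f"{name} probabilities do not sum to 1 within 1e-6")


def lambda_schedule(progress: float, lambda_max: float = 1.0) -> float:
    """DANN ramp: lambda_max * (2 / (1 + exp(-10 p)) - 1), nondecreasing in p."""
    if progress < 0 or progress > 1:
        warnings.warn(f"training progress {progress} outside [0, 1]; clamped", stacklevel=2)
        progress = min(max(progress, 0.0), 1.0)
    return lambda_max * (2.0 / (1.0 + np.exp(-10.0 * progress)) - 1.0)


class ACNModel:
    """Encoder + age head + gradient-reversed confound heads.

    Parameters live in a flat name->Tensor dict; batch-norm running statistics
    are plain arrays updated during training forwards and used at inference.
    """

    def __init__(self, config: ACNConfig, grid_shape: Tuple[int, int, int], seed: int = 0) -> None:
        if min(grid_shape) < 2 ** config.conv_blocks:
            raise ValueError(
                f"grid {grid_shape} too small for {config.conv_blocks} downsampling blocks; "
                f"minimum shape is {(2 ** config.conv_blocks,) * 3}"
            )
        self.config = config
        self.grid_shape = tuple(grid_shape)
        self.seed = seed
        self.params: Dict[str, Tensor] = {}
        self.bn_stats: Dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(seed))

    # ----------------------------------------------------------------- params
    def _add_param(self, name: str, value: np.ndarray) -> None:
        self.params[name] = Tensor(value, requires_grad=True, name=name)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        c_in = 1
        for b, c_out in enumerate(cfg.channels):
            fan_in = c_in * 27
            self._add_param(f"conv{b}.w", rng.normal(0, np.sqrt(2.0 / fan_in), (c_out, c_in, 3, 3, 3)))
            self._add_param(f"conv{b}.b", np.zeros(c_out))
            self._add_param(f"bn{b}.gamma", np.ones(c_out))
            self._add_param(f"bn{b}.beta", np.zeros(c_out))
            self.bn_stats[f"bn{b}.mean"] = np.zeros(c_out)
            self.bn_stats[f"bn{b}.var"] = np.ones(c_out)
            c_in = c_out
        self._add_param("embed.w", rng.normal(0, np.sqrt(2.0 / c_in), (c_in, cfg.embedding_dim)))
        self._add_param("embed.b", np.zeros(cfg.embedding_dim))
        self._add_param("age.w", rng.normal(0, np.sqrt(1.0 / cfg.embedding_dim), (cfg.embedding_dim, N_BINS)))
        self._add_param("age.b", np.zeros(N_BINS))
        for name, n_classes in cfg.confound_factors:
            # mixed module: feature standardisation + linear classifier, so the
            # adversary sees the embedding the way a downstream probe would
            self._add_param(f"head_{name}.gamma", np.ones(cfg.embedding_dim))
            self._add_param(f"head_{name}.beta", np.zeros(cfg.embedding_dim))
            self.bn_stats[f"head_{name}.mean"] = np.zeros(cfg.embedding_dim)
            self.bn_stats[f"head_{name}.var"] = np.ones(cfg.embedding_dim)
            self._add_param(f"head_{name}.w",
                            rng.normal(0, np.sqrt(1.0 / cfg.embedding_dim), (cfg.embedding_dim, n_classes)))
            self._add_param(f"head_{name}.b", np.zeros(n_classes))

    def parameters(self, include_encoder: bool = True) -> List[Tensor]:
        names = sorted(self.params)
        if not include_encoder:
            names = [n for n in names if n.startswith(("age.", "head_"))]
        return [self.params[n] for n in names]

    # ---------------------------------------------------------------- forward
    def _batchnorm(self, x: Tensor, key: str, train: bool, momentum: float = 0.1) -> Tensor:
        """Batch normalisation over all axes except the channel axis.

        5D inputs (N, C, D, H, W) normalise per channel; 2D inputs (N, F)
        normalise per feature.  Batch statistics feed the running averages
        used at inference.
        """
        nd = len(x.shape)
        if nd == 5:
            axes, bshape = (0, 2, 3, 4), (1, -1, 1, 1, 1)
        else:
            axes, bshape = (0,), (1, -1)
        gamma = self.params[f"{key}.gamma"].reshape(*bshape)
        beta = self.params[f"{key}.beta"].reshape(*bshape)
        eps = 1e-5
        if train:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            xhat = xc * (var + eps).pow(-0.5)
            self.bn_stats[f"{key}.mean"] = (1 - momentum) * self.bn_stats[f"{key}.mean"] + momentum * mu.data.ravel()
            self.bn_stats[f"{key}.var"] = (1 - momentum) * self.bn_stats[f"{key}.var"] + momentum * var.data.ravel()
        else:
            rm = self.bn_stats[f"{key}.mean"].reshape(*bshape)
            rv = self.bn_stats[f"{key}.var"].reshape(*bshape)
            xhat = (x - rm) * (1.0 / np.sqrt(rv + eps))
        return gamma * xhat + beta

    def encode(self, x: np.ndarray, train: bool = False) -> Tensor:
        """Volumes (N, D, H, W) -> stratified features (N, embedding_dim)."""
        if x.ndim != 4 or x.shape[1:] != self.grid_shape:
            raise ValueError(f"expected batch of shape (N, {self.grid_shape}), got {x.shape}")
        h = Tensor(x.reshape(x.shape[0], 1, *self.grid_shape))
        for b in range(self.config.conv_blocks):
            h = ad.conv3d(h, self.params[f"conv{b}.w"], self.params[f"conv{b}.b"], stride=2, pad=1)
            h = self._batchnorm(h, f"bn{b}", train)
            h = h.relu()
        pooled = h.mean(axis=(2, 3, 4))  # global average pool -> (N, C_last)
        return (pooled @ self.params["embed.w"] + self.params["embed.b"]).relu()

    def forward_graph(self, x: np.ndarray, lam: float, train: bool = True) -> Dict[str, Tensor]:
        """Full forward with autodiff graph; confound heads sit behind grad_reverse."""
        feats = self.encode(x, train=train)
        age_probs = (feats @ self.params["age.w"] + self.params["age.b"]).softmax(axis=-1)
        out: Dict[str, Tensor] = {"features": feats, "age_probs": age_probs}
        for name, _ in self.config.confound_factors:
            rev = grad_reverse(feats, lam)
            h = self._batchnorm(rev, f"head_{name}", train)
            out[f"confound_{name}"] = (h @ self.params[f"head_{name}.w"] + self.params[f"head_{name}.b"]).softmax(axis=-1)
        return out

    def forward(self, x: np.ndarray, batch_size: int = 32) -> ModelOutputs:
        """Inference-mode forward in chunks; deterministic, no graph retained."""
        ages, probs, feats = [], [], []
        conf: Dict[str, List[np.ndarray]] = {name: [] for name, _ in self.config.confound_factors}
        for i in range(0, x.shape[0], batch_size):
            out = self.forward_graph(x[i:i + batch_size], lam=0.0, train=False)
            q = out["age_probs"].data
            probs.append(q)
            ages.append(q @ BIN_CENTERS)
            feats.append(out["features"].data)
            for name, _ in self.config.confound_factors:
                conf[name].append(out[f"confound_{name}"].data)
        return ModelOutputs(
            age_probs=np.concatenate(probs),
            age_point=np.concatenate(ages),
            confound_probs={k: np.concatenate(v) for k, v in conf.items()},
            features=np.concatenate(feats),
        )

    # ------------------------------------------------------------- state dict
    def state_arrays(self) -> Dict[str, np.ndarray]:
        d = {f"param:{k}": v.data.copy() for k, v in self.params.items()}
        d.update({f"stat:{k}": v.copy() for k, v in self.bn_stats.items()})
        return d

    def load_state_arrays(self, arrays: Mapping[str, np.ndarray]) -> None:
        for k, v in arrays.items():
            kind, name = k.split(":", 1)
            if kind == "param":
                self.params[name].data = np.array(v)
            else:
                self.bn_stats[name] = np.array(v)


def build_model(config: ACNConfig, grid_shape: Tuple[int, int, int], seed: int = 0) -> ACNModel:
    """Construct a seeded ACN model for the given voxel grid."""
    return ACNModel(config, grid_shape, seed=seed)


# ------------------------------------------------------------------- losses

def _check_probs(p: np.ndarray, what: str) -> None:
    if np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-6):
        raise ValueError(f"{what} probabilities not normalised")


def age_loss(true_ages: Sequence[float], outputs: ModelOutputs, sigma: float) -> float:
    """Distributional age loss: sum_i ( |y_i - yhat_i| + KL(p_i || q_i) ).

    p_i is the soft label of the true age, q_i the predicted distribution
    (floored at 1e-12 before the log) and yhat_i its expectation decode.  The
    KL term is nonnegative, zero iff p = q, so the loss is bounded below by
    the batch L1 error.
    """
    true_ages = np.asarray(true_ages, dtype=np.float64)
    if true_ages.size == 0:
        raise ValueError("empty batch")
    q = np.asarray(outputs.age_probs, dtype=np.float64)
    _check_probs(q, "predicted age")
    p = ages_to_soft_labels(true_ages, sigma)
    qf = np.maximum(q, PROB_FLOOR)
    plogp = np.where(p > 0, p * np.log(np.maximum(p, PROB_FLOOR)), 0.0)
    kl = (plogp - p * np.log(qf)).sum(axis=-1)
    yhat = q @ BIN_CENTERS
    return float(np.sum(np.abs(true_ages - yhat) + kl))


def confound_loss(true_labels: Mapping[str, Sequence[int]], outputs: ModelOutputs) -> float:
    """Summed per-factor mean cross-entropy of the mixed modules."""
    total = 0.0
    for name, labels in true_labels.items():
        if name not in outputs.confound_probs:
            raise ValueError(f"factor {name!r} missing from model outputs")
        d = np.asarray(outputs.confound_probs[name], dtype=np.float64)
        _check_probs(d, name)
        labels = np.asarray(labels, dtype=int)
        if labels.min() < 0 or labels.max() >= d.shape[1]:
            raise ValueError(f"labels for {name!r} outside [0, {d.shape[1]})")
        picked = np.maximum(d[np.arange(len(labels)), labels], PROB_FLOOR)
        total += float(-np.mean(np.log(picked)))
    return total


def total_loss(age_loss_value: float, confound_loss_value: float) -> float:
    """L_total = L_age + L_c.

    The adversarial sign is carried by the gradient reversal layer, not by
    this sum: the confound heads descend on L_c while the encoder ascends it.
    """
    return age_loss_value + confound_loss_value


# ------------------------------------------------------ graph-building losses

def age_loss_graph(true_ages: np.ndarray, age_probs: Tensor, sigma: float) -> Tensor:
    """Autodiff version of `age_loss` for training."""
    p = ages_to_soft_labels(true_ages, sigma)
    qf = age_probs.clip_min(PROB_FLOOR)
    plogp = float(np.sum(np.where(p > 0, p * np.log(np.maximum(p, PROB_FLOOR)), 0.0)))
    cross = (Tensor(p) * qf.log()).sum()
    yhat = age_probs @ Tensor(BIN_CENTERS.reshape(-1, 1))
    l1 = (Tensor(np.asarray(true_ages, dtype=np.float64).reshape(-1, 1)) - yhat).abs().sum()
    return l1 + plogp - cross


def confound_loss_graph(true_labels: Mapping[str, np.ndarray], outputs: Mapping[str, Tensor]) -> Tensor:
    """Autodiff version of `confound_loss` for training."""
    total: Optional[Tensor] = None
    for name in sorted(true_labels):
        d = outputs[f"confound_{name}"]
        labels = np.asarray(true_labels[name], dtype=int)
        onehot = np.zeros(d.shape)
        onehot[np.arange(len(labels)), labels] = 1.0
        ce = (Tensor(onehot) * d.clip_min(PROB_FLOOR).log()).sum() * (-1.0 / len(labels))
        total = ce if total is None else total + ce
    if total is None:
        return Tensor(0.0)
    return total


# ---------------------------------------------------------------- checkpoints

def save_checkpoint(model: ACNModel, path: str | Path) -> None:
    """Save parameters, batch-norm stats and config in one .npz archive."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "grid_shape": list(model.grid_shape),
        "seed": model.seed,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.state_arrays())


def load_checkpoint(path: str | Path) -> ACNModel:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        cfg_d = meta["config"]
        cfg_d["confound_factors"] = tuple((n, c) for n, c in cfg_d["confound_factors"])
        if cfg_d.get("channels_per_block") is not None:
            cfg_d["channels_per_block"] = tuple(cfg_d["channels_per_block"])
        config = ACNConfig(**cfg_d)
        model = ACNModel(config, tuple(meta["grid_shape"]), seed=meta["seed"])
        model.load_state_arrays({k: npz[k] for k in npz.files if k != "__meta__"})
    return model
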