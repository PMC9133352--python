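"""PointNet-style extractor for the 1,024-d hemodynamic cloud feature.

Architecture (per subject, N x 8 region points): an 8x8 input T-net aligns
the channel vectors, a shared MLP lifts 8 -> 64, a 64x64 feature T-net
aligns point features, a second shared MLP lifts 64 -> 128 -> 1,024, and
channel-wise max-pooling over the N points yields the 1,024-d hemodynamic
cloud feature.  Max-pooling is a symmetric function, so the feature is
exactly invariant to point order and to duplicating points.

Training attaches a small classification head (1024 -> 512 -> 256 -> 2) on
the rupture label with class-weighted cross-entropy and the usual
orthogonality penalty on the feature T-net; the feature is the pre-head
pooled vector with the head detached.  There is no batch normalisation or
dropout — at this scale plain affine layers train stably and keep
inference deterministic.

Inputs are standardised with fixed physical scales (not per-batch
statistics): coordinates are centred per cloud and divided by 5 mm; WSS
and TAWSS by 5 Pa; OSI by 0.25; pressure centred per cloud and divided by
30 Pa; velocity by 0.3 m/s.  Per-cloud centring uses the mean over rows,
which is unchanged by row permutation or whole-cloud duplication, so the
symmetry properties survive preprocessing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..types import CloudFeature, ContractError, RegionPointSet
from .autodiff import Adam, Tensor, softmax_cross_entropy

FEATURE_DIM = 1024
CHECKPOINT_VERSION = 1


@dataclass
class NetConfig:
    """Architecture and training hyperparameters of the extractor."""

    in_channels: int = 8
    tnet1_dim: int = 8
    mlp1_widths: Tuple[int, ...] = (64, 64)
    tnet2_dim: int = 64
    mlp2_widths: Tuple[int, ...] = (64, 128, 1024)
    head_widths: Tuple[int, ...] = (512, 256, 2)
    tnet_hidden: Tuple[int, ...] = (32, 64)  # shared-MLP widths inside each T-net
    tnet_fc: int = 32  # post-pool hidden width inside each T-net
    seed: int = 0
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    tnet_reg: float = 1e-3  # orthogonality penalty weight on the feature T-net

    def __post_init__(self) -> None:
        if self.in_channels != 8 or self.tnet1_dim != 8:
            raise ContractError("the extractor consumes 8-channel region points")
        if self.mlp2_widths[-1] != FEATURE_DIM:
            raise ContractError("the final shared-MLP width must be 1024")


@dataclass
class PointNetWeights:
    """Trained parameters plus the config and training-loss history."""

    params: Dict[str, np.ndarray]
    config: NetConfig
    loss_history: List[float] = field(default_factory=list)


# fixed physical scales for input standardisation (see module docstring)
_SCALES = np.array([5.0, 5.0, 5.0, 5.0, 0.25, 30.0, 0.3, 5.0])
_CENTERED = np.array([True, True, True, False, False, True, False, False])


def _preprocess(points: np.ndarray) -> np.ndarray:
    """(B, N, 8) raw region points -> standardised network input."""
    x = np.array(points, dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    x = np.where(_CENTERED, x - mean, x)
    return x / _SCALES


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def init_params(config: NetConfig) -> Dict[str, np.ndarray]:
    """Seeded parameter initialisation; T-net output layers start at identity."""
    rng = np.random.default_rng(config.seed)
    p: Dict[str, np.ndarray] = {}

    def linear(name: str, n_in: int, n_out: int, zero: bool = False) -> None:
        p[f"{name}.W"] = np.zeros((n_in, n_out)) if zero else _glorot(rng, n_in, n_out)
        p[f"{name}.b"] = np.zeros(n_out)

    def tnet(name: str, k: int) -> None:
        h1, h2 = config.tnet_hidden
        linear(f"{name}.mlp0", k, h1)
        linear(f"{name}.mlp1", h1, h2)
        linear(f"{name}.fc", h2, config.tnet_fc)
        linear(f"{name}.out", config.tnet_fc, k * k, zero=True)
        p[f"{name}.out.b"] = np.eye(k).ravel().copy()

    tnet("t1", config.tnet1_dim)
    w_in = config.in_channels
    for i, w_out in enumerate(config.mlp1_widths):
        linear(f"mlp1.{i}", w_in, w_out)
        w_in = w_out
    if w_in != config.tnet2_dim:
        raise ContractError("mlp1 output width must equal tnet2_dim")
    tnet("t2", config.tnet2_dim)
    for i, w_out in enumerate(config.mlp2_widths):
        linear(f"mlp2.{i}", w_in, w_out)
        w_in = w_out
    for i, w_out in enumerate(config.head_widths):
        linear(f"head.{i}", w_in, w_out)
        w_in = w_out
    return p


def _as_tensors(params: Dict[str, np.ndarray], trainable: bool) -> Dict[str, Tensor]:
    return {k: Tensor(v, requires_grad=trainable) for k, v in params.items()}


def _linear(x: Tensor, t: Dict[str, Tensor], name: str) -> Tensor:
    return x @ t[f"{name}.W"] + t[f"{name}.b"]


def _tnet_forward(x: Tensor, t: Dict[str, Tensor], name: str, k: int) -> Tensor:
    h = _linear(x, t, f"{name}.mlp0").relu()
    h = _linear(h, t, f"{name}.mlp1").relu()
    g = h.max(axis=1)  # symmetric pool over points
    g = _linear(g, t, f"{name}.fc").relu()
    m = _linear(g, t, f"{name}.out")
    return m.reshape(-1, k, k)


def _forward(x: Tensor, t: Dict[str, Tensor], config: NetConfig):
    """Returns (pooled 1024-d features, logits, feature T-net matrix)."""
    t1 = _tnet_forward(x, t, "t1", config.tnet1_dim)
    x = x @ t1
    for i in range(len(config.mlp1_widths)):
        x = _linear(x, t, f"mlp1.{i}").relu()
    t2 = _tnet_forward(x, t, "t2", config.tnet2_dim)
    x = x @ t2
    for i in range(len(config.mlp2_widths)):
        x = _linear(x, t, f"mlp2.{i}").relu()
    feat = x.max(axis=1)  # (B, 1024) channel-wise max over points
    h = feat
    n_head = len(config.head_widths)
    for i in range(n_head):
        h = _linear(h, t, f"head.{i}")
        if i < n_head - 1:
            h = h.relu()
    return feat, h, t2


def _orthogonality_penalty(t2: Tensor) -> Tensor:
    k = t2.shape[-1]
    eye = Tensor(np.eye(k))
    delta = (t2 @ t2.transpose_last()) + (eye * -1.0)
    return delta.square().sum() * (1.0 / t2.shape[0])


def _stack_regions(regions: Sequence[RegionPointSet]) -> np.ndarray:
    sizes = {r.n_points for r in regions}
    if len(sizes) != 1:
        raise ContractError("all region point sets must have the same size")
    return np.stack([r.points for r in regions])


def forward_features(region: RegionPointSet, weights: PointNetWeights) -> CloudFeature:
    """The 1,024-d hemodynamic cloud feature of one subject."""
    x = _preprocess(region.points[None, :, :])
    t = _as_tensors(weights.params, trainable=False)
    feat, _, _ = _forward(Tensor(x), t, weights.config)
    return CloudFeature(values=feat.data[0], subject_id=region.subject_id)


def extract_features(regions: Sequence[RegionPointSet],
                     weights: PointNetWeights) -> pd.DataFrame:
    """(n_subjects, 1024) feature table, one row per region point set."""
    x = _preprocess(_stack_regions(regions))
    t = _as_tensors(weights.params, trainable=False)
    out = []
    for start in range(0, x.shape[0], 64):  # bound peak memory
        feat, _, _ = _forward(Tensor(x[start:start + 64]), t, weights.config)
        out.append(feat.data)
    mat = np.vstack(out)
    cols = [f"cf_{i + 1:04d}" for i in range(FEATURE_DIM)]
    df = pd.DataFrame(mat, index=[r.subject_id for r in regions], columns=cols)
    df.index.name = "subject_id"
    return df


def head_predict_proba(regions: Sequence[RegionPointSet],
                       weights: PointNetWeights) -> np.ndarray:
    """Rupture probability from the training head (column 1 = ruptured)."""
    x = _preprocess(_stack_regions(regions))
    t = _as_tensors(weights.params, trainable=False)
    _, logits, _ = _forward(Tensor(x), t, weights.config)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def train_extractor(
    regions: Sequence[RegionPointSet],
    labels: Sequence[int],
    config: Optional[NetConfig] = None,
) -> PointNetWeights:
    """Train the extractor with a rupture-label head; returns the weights.

    Labels are 0 (unruptured) / 1 (ruptured).  Cross-entropy is weighted by
    inverse class frequency so the minority ruptured class is not ignored.
    Deterministic for a fixed seed and thread count.
    """
    config = config or NetConfig()
    y = np.asarray(labels, dtype=int)
    if len(regions) != y.size:
        raise ContractError("regions and labels must align")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ContractError("training requires both rupture classes")
    class_w = y.size / (classes.size * counts.astype(float))
    sample_w = class_w[np.searchsorted(classes, y)]

    x_all = _preprocess(_stack_regions(regions))
    params = init_params(config)
    tensors = _as_tensors(params, trainable=True)
    opt = Adam(list(tensors.values()), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    history: List[float] = []
    n = x_all.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = Tensor(x_all[idx])
            _, logits, t2 = _forward(xb, tensors, config)
            loss = softmax_cross_entropy(logits, y[idx], sample_w[idx])
            if config.tnet_reg > 0:
                loss = loss + _orthogonality_penalty(t2) * config.tnet_reg
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * idx.size
        history.append(epoch_loss / n)

    final = {k: t.data.copy() for k, t in tensors.items()}
    return PointNetWeights(params=final, config=config, loss_history=history)


def save_weights(weights: PointNetWeights, path) -> None:
    """Single-file versioned checkpoint (.npz)."""
    meta = json.dumps({"version": CHECKPOINT_VERSION, "config": asdict(weights.config)})
    np.savez(
        path,
        __meta__=np.array(meta),
        __loss__=np.array(weights.loss_history),
        **weights.params,
    )


def load_weights(path) -> PointNetWeights:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ContractError("unsupported checkpoint version")
        cfg_dict = meta["config"]
        for key in ("mlp1_widths", "mlp2_widths", "head_widths", "tnet_hidden"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = NetConfig(**cfg_dict)
        params = {k: data[k] for k in data.files if not k.startswith("__")}
        history = [float(v) for v in data["__loss__"]]
    return PointNetWeights(params=params, config=config, loss_history=history)
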