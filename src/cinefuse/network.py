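"""The multi-view cine-series attention-fusion regression network.

Architecture
------------
A single shared frame encoder maps every 2-D frame (4 views x 20 phases =
80 frames per exam) to a D-dimensional feature vector.  A shared Attention
Feature Fusion Block (AFFB) — an affine scorer f -> a, softmax over the
group, weighted sum — fuses features in two stages:

* stage 1: a view-wise fusion per phase (4 components -> one *spatial
  summary*, 20 of them) and a phase-wise fusion per view (20 components ->
  one *temporal summary*, 4 of them);
* stage 2: the 24 summaries are fused into the final feature.

Because fusion is dimension-preserving, the single shared regression layer
(affine, D -> 1) can score any of the 80 frame features, 24 summaries, or
the final feature, which is what the per-feature explainability uses.  The
parameter count is independent of the number of views and phases — encoder,
AFFB and head are each one shared parameter set.

The default encoder is a lightweight strided convolutional network
(average-pool to 64 px, two patch-convolution stages with leaky-ReLU
activations, global average pooling, and a layer-normalised linear
projection to D); deeper encoders can be substituted via
``ModelConfig.encoder``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import Tensor, concatenate, softmax
from .exam import FRAME_SIZE, N_PHASES, VIEWS
from .nn import (Adam, Conv2d, LayerNorm, Linear, Module, avg_pool2d,
                 global_avg_pool)

__all__ = ["ModelConfig", "AttentionWeights", "FusionTrace", "BatchTrace",
           "AFFB", "SmallConvEncoder", "MultiViewCineNet",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``input_size``/``encoder_pool`` default to the full 256-px frames with a
    4x input pool; the test profile uses 64-px inputs with no pooling so the
    whole pipeline runs on a CPU in seconds.
    """

    views: tuple[str, ...] = VIEWS
    n_phases: int = N_PHASES
    input_size: int = FRAME_SIZE
    feature_dim: int = 64
    encoder: str = "conv_small"
    encoder_pool: int = 4
    encoder_channels: tuple[int, ...] = (8, 16)
    scorer_bias: bool = True
    shared_affb: bool = True  # one AFFB for both stages (the reference design)
    strict: bool = True  # enforce the full views x phases grid
    target: str = "mPAP"

    def __post_init__(self):
        if len(self.views) < 1 or self.n_phases < 1:
            raise ValueError("need at least one view and one phase")

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def n_summaries(self) -> int:
        return self.n_phases + self.n_views

    @property
    def n_features(self) -> int:
        """Frame features + summaries + final feature (105 for 4 x 20)."""
        return self.n_views * self.n_phases + self.n_summaries + 1


@dataclass(frozen=True)
class AttentionWeights:
    """Raw scores a_i and their softmax-normalised weights alpha_i."""

    raw: np.ndarray
    normalized: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.normalized, dtype=np.float64)
        if np.any(a < 0) or abs(a.sum() - 1.0) > 1e-6:
            raise ValueError("normalized weights must be nonnegative and sum to 1")


class SmallConvEncoder(Module):
    """Strided conv encoder: pool -> 4x4 patch conv -> 2x2 patch conv ->
    global average pool -> linear projection to D.

    Activations are leaky ReLUs: with plain ReLUs the narrow encoder is
    prone to irreversible unit death early in training (constant features,
    flat loss); the small negative slope keeps gradients alive.  The
    output is layer-normalised: global average pooling shrinks feature
    variance far below the unit-variance target scale, and without the
    normalisation the affine head spends thousands of optimiser steps
    merely rescaling.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.pool = config.encoder_pool
        c1, c2 = config.encoder_channels
        self.conv1 = Conv2d(1, c1, k=4, stride=4, pad=0, rng=rng)
        self.conv2 = Conv2d(c1, c2, k=2, stride=2, pad=0, rng=rng)
        self.proj = Linear(c2, config.feature_dim, rng=rng)
        self.norm = LayerNorm(config.feature_dim)

    def __call__(self, x: Tensor) -> Tensor:
        if self.pool > 1:
            x = avg_pool2d(x, self.pool)
        x = self.conv1(x).leaky_relu(0.01)
        x = self.conv2(x).leaky_relu(0.01)
        return self.norm(self.proj(global_avg_pool(x)))


_ENCODERS = {"conv_small": SmallConvEncoder}


class AFFB(Module):
    """Attention Feature Fusion Block.

    A shared affine scorer maps each D-dim component feature to a raw
    attention score; softmax over the group gives weights summing to one;
    the fused feature is the weighted sum, so fusion is dimension-preserving
    and accepts any number of components.
    """

    def __init__(self, feature_dim: int, rng: np.random.Generator, bias: bool = True):
        self.scorer = Linear(feature_dim, 1, rng=rng, bias=bias)
        self.feature_dim = feature_dim

    def scores(self, feats: Tensor) -> Tensor:
        """Raw attention scores for a (..., D) tensor -> (...)."""
        lead = feats.shape[:-1]
        flat = feats.reshape(-1, self.feature_dim)
        return self.scorer(flat).reshape(lead)

    def fuse_along(self, feats: Tensor, axis: int) -> tuple[Tensor, Tensor, Tensor]:
        """Fuse a (..., N, ..., D) tensor along `axis`; returns (fused, raw, alpha)."""
        raw = self.scores(feats)  # (..., N, ...)
        alpha = softmax(raw, axis=axis)
        expanded = alpha.reshape(alpha.shape + (1,))
        fused = (expanded * feats).sum(axis=axis)
        return fused, raw, alpha

    def fuse(self, components: np.ndarray) -> tuple[np.ndarray, AttentionWeights]:
        """Fuse an (N, D) stack of component features (inference path).

        Raises on an empty stack or mismatched dimensions.
        """
        components = np.asarray(components, dtype=np.float32)
        if components.ndim != 2 or components.shape[0] < 1:
            raise ValueError("components must be a nonempty (N, D) stack")
        if components.shape[1] != self.feature_dim:
            raise ValueError(
                f"component dimension {components.shape[1]} != D={self.feature_dim}"
            )
        fused, raw, alpha = self.fuse_along(Tensor(components), axis=0)
        return fused.data.copy(), AttentionWeights(raw=raw.data.copy(),
                                                   normalized=alpha.data.copy())


@dataclass
class FusionTrace:
    """Every intermediate of one exam's forward pass, for explainability.

    Shapes use V = number of views, P = phases, D = feature dim.  Stage-2
    components are ordered [20 spatial summaries, then 4 temporal summaries].
    """

    frame_features: np.ndarray      # (V, P, D)
    spatial_summaries: np.ndarray   # (P, D) — per phase, fused across views
    temporal_summaries: np.ndarray  # (V, D) — per view, fused across phases
    final_feature: np.ndarray       # (D,)
    view_weights: list[AttentionWeights]   # P groups of N=V
    phase_weights: list[AttentionWeights]  # V groups of N=P
    stage2_weights: AttentionWeights       # one group of N=P+V
    frame_predictions: np.ndarray     # (V, P)
    spatial_predictions: np.ndarray   # (P,)
    temporal_predictions: np.ndarray  # (V,)
    final_prediction: float

    @property
    def n_features(self) -> int:
        v, p, _ = self.frame_features.shape
        return v * p + p + v + 1

    def all_predictions(self) -> np.ndarray:
        """The per-feature prediction surface, flattened (frames, spatial,
        temporal, final) — 105 values for the 4-view 20-phase model."""
        return np.concatenate([
            self.frame_predictions.ravel(), self.spatial_predictions,
            self.temporal_predictions, [self.final_prediction],
        ])


@dataclass
class BatchTrace:
    """Batched forward intermediates; `exam(i)` extracts one FusionTrace."""

    frame_features: np.ndarray      # (B, V, P, D)
    spatial_summaries: np.ndarray   # (B, P, D)
    temporal_summaries: np.ndarray  # (B, V, D)
    final_feature: np.ndarray       # (B, D)
    view_raw: np.ndarray            # (B, V, P)
    view_alpha: np.ndarray          # (B, V, P) — softmax over views
    phase_raw: np.ndarray           # (B, V, P)
    phase_alpha: np.ndarray         # (B, V, P) — softmax over phases
    stage2_raw: np.ndarray          # (B, P+V)
    stage2_alpha: np.ndarray        # (B, P+V)
    frame_predictions: np.ndarray   # (B, V, P)
    spatial_predictions: np.ndarray   # (B, P)
    temporal_predictions: np.ndarray  # (B, V)
    final_prediction: np.ndarray      # (B,)

    def exam(self, i: int) -> FusionTrace:
        n_p = self.spatial_summaries.shape[1]
        view_w = [AttentionWeights(self.view_raw[i, :, p], self.view_alpha[i, :, p])
                  for p in range(n_p)]
        phase_w = [AttentionWeights(self.phase_raw[i, v], self.phase_alpha[i, v])
                   for v in range(self.temporal_summaries.shape[1])]
        return FusionTrace(
            frame_features=self.frame_features[i],
            spatial_summaries=self.spatial_summaries[i],
            temporal_summaries=self.temporal_summaries[i],
            final_feature=self.final_feature[i],
            view_weights=view_w,
            phase_weights=phase_w,
            stage2_weights=AttentionWeights(self.stage2_raw[i], self.stage2_alpha[i]),
            frame_predictions=self.frame_predictions[i],
            spatial_predictions=self.spatial_predictions[i],
            temporal_predictions=self.temporal_predictions[i],
            final_prediction=float(self.final_prediction[i]),
        )


class MultiViewCineNet(Module):
    """Shared encoder + shared AFFB two-stage fusion + shared regression layer."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        self.encoder = _ENCODERS[self.config.encoder](self.config, rng)
        self.affb = AFFB(self.config.feature_dim, rng, bias=self.config.scorer_bias)
        if self.config.shared_affb:
            self.affb2 = None
        else:
            self.affb2 = AFFB(self.config.feature_dim, rng, bias=self.config.scorer_bias)
        self.head = Linear(self.config.feature_dim, 1, rng=rng)

    # -- pieces ---------------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        b, v, p, h, w = x.shape
        size = self.config.input_size
        if (h, w) != (size, size):
            raise ValueError(f"frames must be {size}x{size}, got {h}x{w}")
        if self.config.strict and (v, p) != (self.config.n_views, self.config.n_phases):
            raise ValueError(
                f"strict mode expects {self.config.n_views} views x "
                f"{self.config.n_phases} phases, got {v} x {p}"
            )

    def encode_frames(self, x: np.ndarray) -> Tensor:
        """Encode a (B, V, P, H, W) stack into (B, V, P, D) frame features."""
        b, v, p, h, w = x.shape
        flat = Tensor(np.ascontiguousarray(x, dtype=np.float32).reshape(b * v * p, 1, h, w))
        feats = self.encoder(flat)
        return feats.reshape(b, v, p, self.config.feature_dim)

    def encode_frame(self, frame: np.ndarray) -> np.ndarray:
        """Encode a single (H, W) frame; rejects wrong spatial sizes."""
        frame = np.asarray(frame, dtype=np.float32)
        size = self.config.input_size
        if frame.shape != (size, size):
            raise ValueError(f"frame must be {size}x{size}, got {frame.shape}")
        return self.encoder(Tensor(frame[None, None])).data[0].copy()

    def two_stage_fuse(self, feats: Tensor):
        """Fuse (B, V, P, D) frame features into the (B, D) final feature.

        Returns (final, stage-wise intermediates) — all Tensors on the tape
        so the whole fusion is differentiable.
        """
        affb2 = self.affb if self.affb2 is None else self.affb2
        spatial, view_raw, view_alpha = self.affb.fuse_along(feats, axis=1)   # (B,P,D)
        temporal, phase_raw, phase_alpha = self.affb.fuse_along(feats, axis=2)  # (B,V,D)
        comps = concatenate([spatial, temporal], axis=1)  # (B, P+V, D)
        final, s2_raw, s2_alpha = affb2.fuse_along(comps, axis=1)  # (B,D)
        return (final, spatial, temporal,
                (view_raw, view_alpha, phase_raw, phase_alpha, s2_raw, s2_alpha))

    def regress(self, feature: np.ndarray) -> np.ndarray:
        """Shared regression layer applied to any (..., D) feature array."""
        feature = np.asarray(feature, dtype=np.float32)
        lead = feature.shape[:-1]
        out = self.head(Tensor(feature.reshape(-1, self.config.feature_dim)))
        return out.data.reshape(lead).copy()

    # -- forward paths --------------------------------------------------------
    def forward_batch(self, x: np.ndarray) -> Tensor:
        """Differentiable training path: (B, V, P, H, W) -> predictions (B,)."""
        self._check_input(x)
        feats = self.encode_frames(x)
        final, *_ = self.two_stage_fuse(feats)
        return self.head(final).reshape(x.shape[0])

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Inference predictions for a (B, V, P, H, W) stack."""
        self._check_input(x)
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(self.forward_batch(x[i:i + batch_size]).data)
        return np.concatenate(out)

    def forward_trace(self, x: np.ndarray) -> tuple[np.ndarray, BatchTrace]:
        """Inference with every intermediate captured (explainability path)."""
        self._check_input(x)
        feats = self.encode_frames(x)
        final, spatial, temporal, w = self.two_stage_fuse(feats)
        view_raw, view_alpha, phase_raw, phase_alpha, s2_raw, s2_alpha = w
        preds = self.head(final).reshape(x.shape[0]).data
        trace = BatchTrace(
            frame_features=feats.data.copy(),
            spatial_summaries=spatial.data.copy(),
            temporal_summaries=temporal.data.copy(),
            final_feature=final.data.copy(),
            view_raw=view_raw.data.copy(), view_alpha=view_alpha.data.copy(),
            phase_raw=phase_raw.data.copy(), phase_alpha=phase_alpha.data.copy(),
            stage2_raw=s2_raw.data.copy(), stage2_alpha=s2_alpha.data.copy(),
            frame_predictions=self.regress(feats.data),
            spatial_predictions=self.regress(spatial.data),
            temporal_predictions=self.regress(temporal.data),
            final_prediction=preds.copy(),
        )
        return preds.copy(), trace

    def forward(self, exam_array: np.ndarray) -> tuple[float, FusionTrace]:
        """Single-exam forward: (V, P, H, W) -> (prediction, FusionTrace)."""
        preds, trace = self.forward_trace(exam_array[None])
        return float(preds[0]), trace.exam(0)

    def make_optimizer(self, lr: float = 1e-4, weight_decay: float = 1e-8) -> Adam:
        return Adam(self.parameters(), lr=lr, weight_decay=weight_decay)


def save_checkpoint(path, net: MultiViewCineNet, metadata: dict | None = None) -> None:
    """Serialize config + weights + metadata to a single .npz file."""
    cfg = asdict(net.config)
    payload = {f"param/{k}": v for k, v in net.state_dict().items()}
    payload["__config__"] = np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8
    )
    payload["__meta__"] = np.frombuffer(
        json.dumps(metadata or {}).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[MultiViewCineNet, dict]:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    for key in ("views", "encoder_channels"):
        cfg[key] = tuple(cfg[key])
    net = MultiViewCineNet(ModelConfig(**cfg))
    net.load_state_dict(state)
    return net, meta
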