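"""MSE training loop: Adam, per-series augmentation, early stopping.

Defaults follow the reference protocol — Adam with learning rate 1e-4 and
weight decay 1e-8, batch size 10, up to 1000 epochs with early stopping on
validation MSE — and every stochastic ingredient (shuffling, augmentation,
weight initialisation) is driven by one seed, so a run is reproducible
bit-for-bit.

Targets are z-scored on the training split before optimisation and the
affine regression head is rescaled back to target units once training ends,
so user-facing predictions (including per-feature predictions) are always
in mmHg / Wood units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .network import MultiViewCineNet
from .preprocessing import AugmentationParams, augment_batch

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainHistory", "mse_loss", "train_model",
           "assert_disjoint_splits"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-8
    batch_size: int = 10
    max_epochs: int = 1000
    early_stop_patience: int = 50
    seed: int = 0
    target: str = "mPAP"
    augment: AugmentationParams | None = None  # applied to training data only
    # occlusion robustness (training only): blank whole views / regions
    view_dropout_prob: float = 0.0
    occlusion_prob: float = 0.0
    keep_one_view_prob: float = 0.0
    standardize_targets: bool = True
    log_every: int = 0  # epochs between log lines; 0 = silent

    def __post_init__(self):
        if min(self.learning_rate, self.weight_decay) < 0:
            raise ValueError("learning rate and weight decay must be nonnegative")
        if min(self.batch_size, self.max_epochs, self.early_stop_patience) < 1:
            raise ValueError("batch size, epochs, and patience must be positive")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")
        probs = (self.view_dropout_prob, self.occlusion_prob,
                 self.keep_one_view_prob)
        if not all(0 <= p <= 1 for p in probs):
            raise ValueError("dropout/occlusion probabilities must be in [0, 1]")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    val_pcc: list[float] = field(default_factory=list)
    val_r2: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def mse_loss(predictions, targets) -> float:
    """Mean squared error between two equal-length scalar sequences."""
    predictions = np.asarray(predictions, dtype=np.float64).ravel()
    targets = np.asarray(targets, dtype=np.float64).ravel()
    if predictions.size == 0:
        raise ValueError("empty batch")
    if predictions.shape != targets.shape:
        raise ValueError("predictions and targets differ in length")
    return float(np.mean((predictions - targets) ** 2))


def assert_disjoint_splits(*id_lists) -> None:
    """Fail if any identifier appears in more than one split."""
    seen: dict[str, int] = {}
    for split_idx, ids in enumerate(id_lists):
        for i in ids:
            if i in seen and seen[i] != split_idx:
                raise ValueError(f"identifier {i!r} appears in two splits")
            seen[i] = split_idx


def _occlude_batch(xb: np.ndarray, config: "TrainConfig",
                   rng: np.random.Generator,
                   regions: list[dict] | None = None) -> None:
    """Blank whole views, single-view exams, or regions in place (training only).

    Three mechanisms, all drawn from the one generator so runs are
    reproducible:

    * *view dropout* (per view) emulates a missing acquisition;
    * *keep-one-view* (per exam) blacks out all but one random view —
      the extreme missing-view case the fusion design claims to tolerate;
    * *region erasing* (per exam): with probability ``occlusion_prob``,
      one region — a random ellipse, or with equal chance one of the
      exam's own chamber regions when ``regions`` is supplied — is
      blanked in every view (shared across the 20 phases).

    Erasing all views of an exam together matters: if only one view were
    erased at a time, the attention scorer could satisfy the loss by
    simply discarding any partially occluded series instead of learning
    to read what remains visible in it.  Chamber-shaped regions are
    applied symmetrically over all chambers, so this teaches tolerance to
    anatomy-shaped holes without preferring any chamber.  Together the
    mechanisms keep the mask/paste perturbations used by the
    chamber-importance analysis within the training distribution.
    """
    n, n_views, _, h, w = xb.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    def erase_ellipse(i, v):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a = rng.uniform(h / 10, h / 3)
        b = rng.uniform(h / 10, h / 3)
        t = rng.uniform(0, np.pi)
        du = (yy - cy) * np.cos(t) + (xx - cx) * np.sin(t)
        dv = -(yy - cy) * np.sin(t) + (xx - cx) * np.cos(t)
        xb[i, v] *= (du / a) ** 2 + (dv / b) ** 2 > 1.0

    from .exam import VIEWS

    for i in range(n):
        r_exam = rng.random()
        if r_exam < config.keep_one_view_prob:
            # single-view exam: everything except one random view is black
            keep = int(rng.integers(0, n_views))
            for v in range(n_views):
                if v != keep:
                    xb[i, v] = 0.0
            continue
        occlude_exam = r_exam < config.keep_one_view_prob + config.occlusion_prob
        use_chamber = regions is not None and rng.random() < 0.5
        for v in range(n_views):
            if rng.random() < config.view_dropout_prob:
                xb[i, v] = 0.0
            elif occlude_exam and rng.random() < 0.6:
                # per-view erasure is probabilistic so both patterns occur:
                # one view occluded with the rest intact (what the
                # chamber-importance analysis applies) and several views
                # occluded at once (which blocks the shortcut of simply
                # discarding any occluded series)
                if use_chamber:
                    view_regions = regions[i][VIEWS[v]]
                    pick = int(rng.integers(0, len(view_regions)))
                    xb[i, v] *= 1 - view_regions[pick]
                else:
                    erase_ellipse(i, v)


def _safe_metrics(truth: np.ndarray, pred: np.ndarray):
    from .evaluation import mae, pearson_corr, r_squared

    m = mae(truth, pred)
    try:
        pcc = pearson_corr(truth, pred)
        r2 = r_squared(truth, pred)
    except ValueError:
        pcc, r2 = float("nan"), float("nan")
    return m, pcc, r2


def train_model(net: MultiViewCineNet,
                train_data: tuple[np.ndarray, np.ndarray],
                val_data: tuple[np.ndarray, np.ndarray],
                config: TrainConfig | None = None,
                occlusion_regions: list[dict] | None = None,
                fold_scale_into_head: bool = True,
                ) -> tuple[MultiViewCineNet, TrainHistory]:
    """Fit the network by minimising MSE; returns the best-validation model.

    ``train_data``/``val_data`` are ``(X, y)`` with X of shape
    (n, V, P, H, W) and y in target units.  ``occlusion_regions`` supplies
    optional per-exam anatomy-shaped erasure regions (aligned with the
    training exams) for the occlusion augmentation.  The checkpoint with
    the lowest validation MSE is restored before returning.
    """
    config = config or TrainConfig()
    x_tr, y_tr = train_data
    x_va, y_va = val_data
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("training and validation splits must be nonempty")
    y_tr = np.asarray(y_tr, dtype=np.float64)
    y_va = np.asarray(y_va, dtype=np.float64)

    if config.standardize_targets:
        mu, sd = float(y_tr.mean()), float(y_tr.std())
        sd = sd if sd > 0 else 1.0
    else:
        mu, sd = 0.0, 1.0
    z_tr = ((y_tr - mu) / sd).astype(np.float32)
    z_va = ((y_va - mu) / sd).astype(np.float32)

    rng = np.random.default_rng(config.seed)
    opt = net.make_optimizer(lr=config.learning_rate, weight_decay=config.weight_decay)
    history = TrainHistory()
    best_loss, best_state, since_improve = np.inf, net.state_dict(), 0

    for epoch in range(config.max_epochs):
        perm = rng.permutation(len(x_tr))
        epoch_losses = []
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb = x_tr[idx]
            if config.augment is not None:
                xb = augment_batch(xb, config.augment, rng)
            if config.view_dropout_prob or config.occlusion_prob:
                batch_regions = (None if occlusion_regions is None
                                 else [occlusion_regions[j] for j in idx])
                _occlude_batch(xb, config, rng, batch_regions)
            preds = net.forward_batch(xb)
            residual = preds - Tensor(z_tr[idx])
            loss = (residual * residual).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        history.train_loss.append(float(np.mean(epoch_losses)))

        val_pred_z = net.predict(x_va)
        val_loss = mse_loss(val_pred_z, z_va)
        history.val_loss.append(val_loss)
        m, pcc, r2 = _safe_metrics(y_va, val_pred_z * sd + mu)
        history.val_mae.append(m)
        history.val_pcc.append(pcc)
        history.val_r2.append(r2)

        if val_loss < best_loss - 1e-12:
            best_loss, best_state, since_improve = val_loss, net.state_dict(), 0
            history.best_epoch = epoch
        else:
            since_improve += 1
        if config.log_every and (epoch + 1) % config.log_every == 0:
            logger.info("epoch %d: train %.4f val %.4f (best %.4f)",
                        epoch + 1, history.train_loss[-1], val_loss, best_loss)
        if since_improve >= config.early_stop_patience:
            break

    net.load_state_dict(best_state)
    if config.standardize_targets and fold_scale_into_head:
        # fold the target scaling into the shared regression head so every
        # downstream prediction (final or per-feature) is in target units;
        # deferred (fold_scale_into_head=False) when another training phase
        # on the standardized scale follows
        net.head.weight.data = net.head.weight.data * sd
        net.head.bias.data = net.head.bias.data * sd + mu
    return net, history
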