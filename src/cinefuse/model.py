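"""Model/Results interface over the multi-view fusion network.

`CineFusionModel` is built from data (arrays or a synthetic cohort);
`fit()` trains the network and returns a `CineFusionResults` carrying the
trained weights, the training history, evaluation metrics, a `summary()`
table, and the three explainability analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import RegressionReport, bland_altman, regression_report
from .explainability import (PerturbationGrid, chamber_importance,
                             mean_attention_weights, per_feature_performance)
from .network import (ModelConfig, MultiViewCineNet, load_checkpoint,
                      save_checkpoint)
from .training import TrainConfig, TrainHistory, train_model

__all__ = ["CineFusionModel", "CineFusionResults"]


class CineFusionModel:
    """Multi-view cine-series attention-fusion regression model.

    Parameters
    ----------
    endog : (n,) array of target values (mmHg or Wood units).
    exog : (n, V, P, H, W) array of preprocessed cine frames in [0, 1].
    validation : optional ``(exog, endog)`` pair used for early stopping;
        if omitted, a tail fraction of the training data is held out.
    config : architecture configuration; inferred frame size by default.
    """

    def __init__(self, endog, exog, validation=None,
                 config: ModelConfig | None = None, target: str = "mPAP"):
        self.endog = np.asarray(endog, dtype=np.float64)
        self.exog = np.asarray(exog, dtype=np.float32)
        if self.exog.ndim != 5:
            raise ValueError("exog must be (n, views, phases, H, W)")
        if len(self.endog) != len(self.exog):
            raise ValueError("endog and exog lengths differ")
        if config is None:
            n, v, p, h, w = self.exog.shape
            pool = max(h // 64, 1)
            config = ModelConfig(input_size=h, encoder_pool=pool, target=target)
        self.config = config
        self.target = target
        self.validation = validation
        #: optional per-exam chamber regions for occlusion augmentation
        self.occlusion_regions: list[dict] | None = None

    @classmethod
    def from_cohort(cls, cohort, target: str = "mPAP", pool: int = 4,
                    config: ModelConfig | None = None,
                    with_chamber_regions: bool = False) -> "CineFusionModel":
        """Build from a :class:`~cinefuse.synthetic.SyntheticCohort`."""
        if with_chamber_regions:
            x_tr, y_tr, regions = cohort.load_arrays(
                "train", target=target, pool=pool, with_chamber_regions=True)
        else:
            x_tr, y_tr = cohort.load_arrays("train", target=target, pool=pool)
            regions = None
        x_va, y_va = cohort.load_arrays("val", target=target, pool=pool)
        model = cls(y_tr, x_tr, validation=(x_va, y_va), config=config,
                    target=target)
        model.occlusion_regions = regions
        model._cohort = cohort
        model._pool = pool
        return model

    def _split_validation(self):
        if self.validation is not None:
            return (self.exog, self.endog), self.validation
        n_val = max(1, int(round(0.2 * len(self.endog))))
        return ((self.exog[:-n_val], self.endog[:-n_val]),
                (self.exog[-n_val:], self.endog[-n_val:]))

    def fit(self, train_config: TrainConfig | None = None,
            seed: int | None = None) -> "CineFusionResults":
        """Train with Adam/MSE and early stopping; returns the Results."""
        train_config = train_config or TrainConfig(target=self.target)
        if seed is not None:
            train_config.seed = seed
        net = MultiViewCineNet(self.config, seed=train_config.seed)
        train_data, val_data = self._split_validation()
        net, history = train_model(net, train_data, val_data, train_config,
                                   occlusion_regions=self.occlusion_regions)
        return CineFusionResults(model=self, net=net, history=history,
                                 train_config=train_config)


@dataclass
class CineFusionResults:
    """Trained-model results: estimates, diagnostics, and explainability."""

    model: CineFusionModel
    net: MultiViewCineNet
    history: TrainHistory
    train_config: TrainConfig
    _cache: dict = field(default_factory=dict, repr=False)

    # -- prediction & evaluation ---------------------------------------------
    def predict(self, exog: np.ndarray) -> np.ndarray:
        """Predictions in target units for an (n, V, P, H, W) stack."""
        return self.net.predict(np.asarray(exog, dtype=np.float32))

    def evaluate(self, exog, endog) -> RegressionReport:
        return regression_report(endog, self.predict(exog))

    def bland_altman(self, exog, endog):
        return bland_altman(endog, self.predict(exog))

    # -- explainability -------------------------------------------------------
    def per_feature_performance(self, exog, endog) -> pd.DataFrame:
        return per_feature_performance(self.net, np.asarray(exog, np.float32),
                                       endog)

    def attention_weights(self, exog) -> dict[str, np.ndarray]:
        return mean_attention_weights(self.net, np.asarray(exog, np.float32))

    def chamber_importance(self, exams, truth, pool: int = 1,
                           ) -> PerturbationGrid:
        return chamber_importance(self.net, exams, truth, pool=pool)

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        h = self.history
        best = h.best_epoch
        cfg = self.net.config
        lines = [
            "Multi-view cine attention-fusion regression",
            "=" * 51,
            f"Target:            {self.train_config.target}",
            f"Views x phases:    {cfg.n_views} x {cfg.n_phases}"
            f"  ({cfg.n_views * cfg.n_phases} frame features,"
            f" {cfg.n_summaries} summaries)",
            f"Feature dim (D):   {cfg.feature_dim}",
            f"Trainable params:  {self.net.n_parameters()}",
            f"Epochs run:        {h.n_epochs} (best at epoch {best + 1})",
            f"Val MSE (z):       {h.val_loss[best]:.4f}",
            f"Val MAE:           {h.val_mae[best]:.3f}",
            f"Val PCC:           {h.val_pcc[best]:.3f}",
            f"Val R2:            {h.val_r2[best]:.3f}",
            "=" * 51,
        ]
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "target": self.train_config.target,
            "seed": self.train_config.seed,
            "best_epoch": self.history.best_epoch,
            "val_loss": self.history.val_loss,
            "train_loss": self.history.train_loss,
        }
        save_checkpoint(path, self.net, meta)

    @staticmethod
    def load_net(path) -> tuple[MultiViewCineNet, dict]:
        return load_checkpoint(path)
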