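"""Model/Results interface tying the pipeline together.

``HierarchicalAttentionClassifier`` is built from a feature tensor and a
label vector (or directly from long-format event/static tables via
``from_tables``); ``fit()`` runs the split / (optional) grid-search / merged
retrain protocol and returns a ``HierarchicalAttentionResults`` carrying the
trained network, training history, test-set predictions, attention maps and
a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import evaluation
from .attention_maps import PopulationMap, population_map
from .nn import HierAttnNet, ModelConfig
from .nn.network import ForwardOutput
from .schema import FeatureSchema, build_default_schema
from .tensorize import (
    EligibilityConfig,
    FeatureTensor,
    apply_normalizer,
    fit_normalizer,
    tensorize_cohort,
)
from .training import (
    FitResult,
    GridResult,
    SplitPlan,
    TrainingConfig,
    final_fit,
    grid_search,
    make_splits,
    train_model,
)


class HierarchicalAttentionClassifier:
    """Hierarchical attention recurrent classifier for one binary outcome.

    Parameters
    ----------
    tensor : FeatureTensor
        Doubly-masked, zero-padded patient histories (unnormalized; the fit
        normalizes internally using non-test patients only).
    labels : array-like or pandas.Series
        Binary outcome aligned with ``tensor.patient_ids`` (a Series is
        realigned by patient id).
    outcome : str
        Name used in reports.
    config : ModelConfig, optional
        Architecture; dimensions default to the tensor's. When ``fit`` runs a
        grid search, this supplies the non-grid fields (embedding size, seed).
    """

    def __init__(self, tensor: FeatureTensor, labels, outcome: str = "outcome",
                 config: Optional[ModelConfig] = None,
                 schema: Optional[FeatureSchema] = None):
        self.tensor = tensor
        if isinstance(labels, pd.Series):
            labels = labels.reindex(tensor.patient_ids).values
        self.y = np.asarray(labels, dtype=int)
        if len(self.y) != tensor.n_patients:
            raise ValueError("labels must align with tensor patients")
        self.outcome = outcome
        self.schema = schema or build_default_schema()
        self.config = config or ModelConfig(
            n_variables=tensor.n_variables, n_static=tensor.S.shape[1],
            t_max=tensor.t_max)

    @classmethod
    def from_tables(cls, events: pd.DataFrame, statics: pd.DataFrame,
                    outcome: str = "mortality", window: int = 1,
                    schema: Optional[FeatureSchema] = None,
                    eligibility: Optional[EligibilityConfig] = None,
                    config: Optional[ModelConfig] = None
                    ) -> "HierarchicalAttentionClassifier":
        schema = schema or build_default_schema()
        elig = eligibility or EligibilityConfig(prediction_window=window)
        tensor, labels, report = tensorize_cohort(events, statics, schema, elig)
        obj = cls(tensor, labels[outcome].values, outcome=outcome,
                  config=config, schema=schema)
        obj.tensorize_report = report
        return obj

    def fit(self, split: Optional[SplitPlan] = None, split_seed: int = 0,
            training: Optional[TrainingConfig] = None,
            grid: Optional[list[dict]] = None
            ) -> "HierarchicalAttentionResults":
        """Split, optionally grid-search, then retrain merged; returns Results.

        With ``grid=None`` the classifier's own ``config`` is trained with
        early stopping on the validation set, then retrained on
        train+validation for the early-stopped number of epochs.
        """
        training = training or TrainingConfig()
        plan = split or make_splits(self.tensor.patient_ids, split_seed)

        # normalization fitted on non-test patients only
        stats = fit_normalizer(
            self.tensor, np.concatenate([plan.train_ids, plan.val_ids]), self.schema)
        normed = apply_normalizer(self.tensor, stats)

        grid_result = None
        if grid is not None:
            grid_result = grid_search(normed, self.y, plan, grid, training,
                                      base_cfg=self.config)
            best_cfg = grid_result.best_config
            probe = next(r for r in grid_result.results
                         if r.get("config") == _cfg_key(best_cfg) or
                         r.get("config") == {"rnn_type": best_cfg.rnn_type,
                                             "units": best_cfg.units,
                                             "dense_before_output": best_cfg.dense_before_output})
            n_epochs = probe.get("best_epoch", training.max_epochs)
        else:
            best_cfg = self.config
            probe_fit = train_model(normed, self.y, plan.train_ids,
                                    plan.val_ids, best_cfg, training)
            n_epochs = probe_fit.best_epoch
        fit = final_fit(normed, self.y, plan, best_cfg, training,
                        n_epochs=max(1, n_epochs))
        return HierarchicalAttentionResults(
            model=self, net=fit.net, split=plan, history=fit.history,
            grid_result=grid_result, normalized_tensor=normed,
            training_config=training)


def _cfg_key(cfg: ModelConfig) -> dict:
    return {"rnn_type": cfg.rnn_type, "units": cfg.units,
            "dense_before_output": cfg.dense_before_output}


@dataclass
class HierarchicalAttentionResults:
    model: HierarchicalAttentionClassifier
    net: HierAttnNet
    split: SplitPlan
    history: list[dict]
    grid_result: Optional[GridResult]
    normalized_tensor: FeatureTensor
    training_config: TrainingConfig
    _test_output: Optional[ForwardOutput] = field(default=None, repr=False)

    # ------------------------------------------------------------ predict
    def predict(self, tensor: Optional[FeatureTensor] = None) -> ForwardOutput:
        """Probabilities and attention for a tensor (default: all patients).

        An external tensor is normalized with the training statistics first.
        """
        if tensor is None:
            tensor = self.normalized_tensor
        elif tensor.normalization is None:
            tensor = apply_normalizer(tensor, self.normalized_tensor.normalization)
        return self.net.predict(tensor)

    def _test_rows(self) -> np.ndarray:
        return self.normalized_tensor.rows_for(self.split.test_ids)

    def predict_test(self) -> ForwardOutput:
        if self._test_output is None:
            rows = self._test_rows()
            t = self.normalized_tensor
            out, _ = self.net.forward(t.X[rows], t.value_mask[rows],
                                      t.period_mask[rows], t.S[rows])
            self._test_output = out
        return self._test_output

    @property
    def y_test(self) -> np.ndarray:
        return self.model.y[self._test_rows()]

    # ----------------------------------------------------------- evaluate
    def evaluate(self, threshold: float = evaluation.DEFAULT_THRESHOLD,
                 n_bootstrap: int = 1000, seed: int = 0) -> evaluation.MetricsReport:
        out = self.predict_test()
        return evaluation.bootstrap_report(self.y_test, out.p,
                                           threshold=threshold,
                                           n_bootstrap=n_bootstrap, seed=seed)

    def calibration(self) -> pd.DataFrame:
        out = self.predict_test()
        return evaluation.calibration_table(self.y_test, out.p)

    def population_attention(self, top_k: int = 10,
                             weight_by_beta: bool = False) -> PopulationMap:
        out = self.predict_test()
        rows = self._test_rows()
        t = self.normalized_tensor
        return population_map(out.alpha, out.beta, t.value_mask[rows],
                              t.period_mask[rows], t.variable_index,
                              top_k=top_k, weight_by_beta=weight_by_beta)

    # ------------------------------------------------------------ summary
    def summary(self, threshold: float = evaluation.DEFAULT_THRESHOLD,
                n_bootstrap: int = 200, seed: int = 0) -> str:
        cfg = self.net.config
        rep = evaluation.bootstrap_report(self.y_test, self.predict_test().p,
                                          threshold=threshold,
                                          n_bootstrap=n_bootstrap, seed=seed)
        lines = [
            "Hierarchical Attention Classifier Results",
            "=" * 45,
            f"outcome:            {self.model.outcome}",
            f"architecture:       {cfg.rnn_type}, U={cfg.units}, "
            f"dense={cfg.dense_before_output}",
            f"parameters:         {self.net.n_parameters():,}",
            f"patients:           train={len(self.split.train_ids)} "
            f"val={len(self.split.val_ids)} test={len(self.split.test_ids)}",
            f"epochs trained:     {len(self.history)}",
            f"prevalence (test):  {self.y_test.mean():.3f}",
            "-" * 45,
            f"test metrics (threshold={threshold}, {n_bootstrap} bootstrap resamples):",
        ]
        for name, ci in rep.metrics.items():
            if ci.point is None:
                lines.append(f"  {name:<14} undefined ({ci.missing_reason})")
            else:
                lines.append(f"  {name:<14} {ci.point:.3f} "
                             f"[{ci.ci_low:.3f}, {ci.ci_high:.3f}]")
        if self.grid_result is not None:
            b = self.grid_result.best_config
            lines.append("-" * 45)
            lines.append(f"grid winner:        {b.rnn_type}, U={b.units}, "
                         f"dense={b.dense_before_output}")
        return "\n".join(lines)
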