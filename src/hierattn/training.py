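"""Split / tune / retrain protocol.

A patient-level holdout split reserves 10% for testing; 15% of the remainder
forms a validation set for hyperparameter tuning over the grid (RNN type x
units x dense-layer presence, 16 configurations), targeting validation
ROC-AUC. The winning configuration is retrained from a fresh seeded
initialization on the merged training + validation set; the test set is
untouched until evaluation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score

from .nn import Adam, HierAttnNet, ModelConfig
from .nn.network import enumerate_grid
from .tensorize import FeatureTensor, apply_normalizer, fit_normalizer

logger = logging.getLogger(__name__)

TEST_FRACTION = 0.10
VAL_FRACTION_OF_TRAIN = 0.15


@dataclass
class SplitPlan:
    train_ids: np.ndarray
    val_ids: np.ndarray
    test_ids: np.ndarray
    seed: int
    test_fraction: float = TEST_FRACTION
    val_fraction_of_train: float = VAL_FRACTION_OF_TRAIN

    def __post_init__(self) -> None:
        a = set(map(int, self.train_ids))
        b = set(map(int, self.val_ids))
        c = set(map(int, self.test_ids))
        if (a & b) or (a & c) or (b & c):
            raise ValueError("split memberships must be disjoint")

    @property
    def all_ids(self) -> np.ndarray:
        return np.concatenate([self.train_ids, self.val_ids, self.test_ids])

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps({
            "seed": self.seed,
            "test_fraction": self.test_fraction,
            "val_fraction_of_train": self.val_fraction_of_train,
            "train_ids": [int(i) for i in self.train_ids],
            "val_ids": [int(i) for i in self.val_ids],
            "test_ids": [int(i) for i in self.test_ids],
        }, indent=0)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, s: str | Path) -> "SplitPlan":
        if isinstance(s, Path) or (isinstance(s, str) and s.lstrip()[:1] != "{"):
            s = Path(s).read_text()
        d = json.loads(s)
        return cls(np.asarray(d["train_ids"]), np.asarray(d["val_ids"]),
                   np.asarray(d["test_ids"]), d["seed"],
                   d["test_fraction"], d["val_fraction_of_train"])


def make_splits(patient_ids, seed: int,
                test_fraction: float = TEST_FRACTION,
                val_fraction_of_train: float = VAL_FRACTION_OF_TRAIN) -> SplitPlan:
    """Seeded patient-level shuffle into test / validation / training sets.

    1000 ids with the default fractions give 100 test, 135 validation and
    765 training patients.
    """
    ids = np.asarray(patient_ids)
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    n_val = int(round(val_fraction_of_train * (n - n_test)))
    test = ids[perm[:n_test]]
    val = ids[perm[n_test:n_test + n_val]]
    train = ids[perm[n_test + n_val:]]
    return SplitPlan(train_ids=train, val_ids=val, test_ids=test, seed=seed,
                     test_fraction=test_fraction,
                     val_fraction_of_train=val_fraction_of_train)


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-2
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 5                     # early stopping on validation ROC-AUC
    grid_max_epochs: Optional[int] = None  # defaults to max_epochs // 2
    seed: int = 0

    @property
    def grid_epochs(self) -> int:
        return self.grid_max_epochs if self.grid_max_epochs is not None else max(
            1, self.max_epochs // 2)


@dataclass
class FitResult:
    net: HierAttnNet
    history: list[dict]
    batch_patient_ids: set[int]           # audit: ids seen in gradient batches
    best_epoch: int
    val_auc: Optional[float]


def train_model(
    tensor: FeatureTensor,
    y: np.ndarray,
    train_ids,
    val_ids,
    model_cfg: ModelConfig,
    train_cfg: TrainingConfig,
    max_epochs: Optional[int] = None,
) -> FitResult:
    """Train one network on ``train_ids`` with early stopping on validation
    ROC-AUC (skipped when ``val_ids`` is empty: fixed epoch budget).

    ``y`` is aligned with ``tensor.patient_ids``.
    """
    max_epochs = max_epochs or train_cfg.max_epochs
    rows_tr = tensor.rows_for(train_ids)
    rows_va = tensor.rows_for(val_ids) if len(val_ids) else np.array([], dtype=int)
    y = np.asarray(y, dtype=np.float64)

    net = HierAttnNet(model_cfg)
    opt = Adam(net.params, lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)
    history: list[dict] = []
    audit: set[int] = set()
    best_auc = -np.inf
    best_params = None
    best_epoch = 0
    bad_epochs = 0

    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(rows_tr))
        losses = []
        for lo in range(0, len(order), train_cfg.batch_size):
            rows = rows_tr[order[lo:lo + train_cfg.batch_size]]
            audit.update(int(i) for i in tensor.patient_ids[rows])
            loss, grads, _ = net.loss_and_grads(
                tensor.X[rows], tensor.value_mask[rows],
                tensor.period_mask[rows], tensor.S[rows], y[rows])
            opt.step(grads)
            losses.append(loss)
        rec = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if len(rows_va):
            out = net.predict(subset_tensor(tensor, rows_va))
            val_auc = float(roc_auc_score(y[rows_va], out.p)) \
                if len(np.unique(y[rows_va])) > 1 else float("nan")
            rec["val_roc_auc"] = val_auc
            history.append(rec)
            if val_auc > best_auc:
                best_auc, best_epoch, bad_epochs = val_auc, epoch, 0
                best_params = {k: v.copy() for k, v in net.params.items()}
            else:
                bad_epochs += 1
                if bad_epochs >= train_cfg.patience:
                    logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                    break
        else:
            history.append(rec)
            best_epoch = epoch
    if best_params is not None:
        net.params = best_params
        opt.params = net.params
    return FitResult(net=net, history=history, batch_patient_ids=audit,
                     best_epoch=best_epoch,
                     val_auc=float(best_auc) if np.isfinite(best_auc) else None)


def subset_tensor(tensor: FeatureTensor, rows: np.ndarray) -> FeatureTensor:
    """View of a tensor restricted to the given row positions."""
    return FeatureTensor(
        X=tensor.X[rows], period_mask=tensor.period_mask[rows],
        value_mask=tensor.value_mask[rows], S=tensor.S[rows],
        variable_index=tensor.variable_index, static_index=tensor.static_index,
        patient_ids=tensor.patient_ids[rows], entry_year=tensor.entry_year[rows],
        index_year=tensor.index_year[rows], schema_hash=tensor.schema_hash,
        normalization=tensor.normalization,
    )


@dataclass
class GridResult:
    results: list[dict]                   # per config: config, val_roc_auc / error
    best_config: ModelConfig

    def to_dict(self) -> dict:
        return {"results": self.results,
                "best_config": json.loads(self.best_config.to_json())}


def grid_search(
    tensor: FeatureTensor,
    y: np.ndarray,
    plan: SplitPlan,
    grid: Optional[list[dict]] = None,
    train_cfg: Optional[TrainingConfig] = None,
    base_cfg: Optional[ModelConfig] = None,
) -> GridResult:
    """Train one model per grid configuration; select by validation ROC-AUC.

    Ties break toward fewer parameters, then grid order. Configurations that
    fail to train are recorded and excluded.
    """
    train_cfg = train_cfg or TrainingConfig()
    grid = grid if grid is not None else enumerate_grid()
    if not grid:
        raise ValueError("empty grid")
    base_cfg = base_cfg or ModelConfig(
        n_variables=tensor.n_variables, n_static=tensor.S.shape[1],
        t_max=tensor.t_max)
    results = []
    candidates = []
    for order, spec in enumerate(grid):
        try:
            cfg = ModelConfig(
                rnn_type=spec["rnn_type"], units=spec["units"],
                dense_before_output=spec["dense_before_output"],
                n_variables=base_cfg.n_variables, n_static=base_cfg.n_static,
                t_max=base_cfg.t_max, embed_dim=base_cfg.embed_dim,
                attn_dim=base_cfg.attn_dim, seed=train_cfg.seed)
            fit = train_model(tensor, y, plan.train_ids, plan.val_ids, cfg,
                              train_cfg, max_epochs=train_cfg.grid_epochs)
            n_par = fit.net.n_parameters()
            results.append({"config": spec, "val_roc_auc": fit.val_auc,
                            "n_parameters": n_par, "best_epoch": fit.best_epoch})
            if fit.val_auc is not None and np.isfinite(fit.val_auc):
                candidates.append((-fit.val_auc, n_par, order, cfg))
        except Exception as err:  # noqa: BLE001 — a failed config must not kill the run
            logger.warning("grid config %s failed: %s", spec, err)
            results.append({"config": spec, "error": str(err)})
    if not candidates:
        raise RuntimeError("no grid configuration trained successfully")
    candidates.sort(key=lambda t: t[:3])
    return GridResult(results=results, best_config=candidates[0][3])


def final_fit(
    tensor: FeatureTensor,
    y: np.ndarray,
    plan: SplitPlan,
    best_config: ModelConfig,
    train_cfg: Optional[TrainingConfig] = None,
    n_epochs: Optional[int] = None,
) -> FitResult:
    """Retrain from a fresh seeded init on train + validation; the test set
    never enters a gradient batch."""
    train_cfg = train_cfg or TrainingConfig()
    merged = np.concatenate([plan.train_ids, plan.val_ids])
    fit = train_model(tensor, y, merged, [], best_config, train_cfg,
                      max_epochs=n_epochs or train_cfg.max_epochs)
    leaked = fit.batch_patient_ids & set(map(int, plan.test_ids))
    if leaked:
        raise RuntimeError(f"test patients leaked into training batches: {sorted(leaked)[:5]}")
    return fit


def normalize_for_training(
    tensor: FeatureTensor, plan: SplitPlan, schema, include_val: bool = True
) -> FeatureTensor:
    """Fit normalization on training patients only (optionally + validation,
    for the merged final fit) and apply it to the full tensor."""
    ids = np.concatenate([plan.train_ids, plan.val_ids]) if include_val else plan.train_ids
    stats = fit_normalizer(tensor, ids, schema)
    return apply_normalizer(tensor, stats)
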