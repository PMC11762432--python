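"""The hierarchical attention recurrent network.

Per observed year, the V annually-aggregated variables enter a recurrent
layer as an ordered sequence (each scalar lifted by a learned per-variable
embedding); additive attention over the per-variable outputs — restricted by
the value mask — yields variable weights alpha and a period context vector.
The period contexts traverse a bidirectional recurrent layer over years
(respecting the period mask, so padding is inert); a second additive
attention over the per-year outputs gives time weights beta and a patient
summary, which is concatenated with the static variables, optionally passed
through one dense ReLU layer, and mapped to an outcome probability by a
sigmoid unit.

Everything is NumPy; the backward pass is hand-derived and checked against
finite differences in the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .cells import RecurrentCell, glorot
from .functional import masked_softmax, masked_softmax_backward, sigmoid

logger = logging.getLogger(__name__)

GRID_RNN_TYPES = ("GRU", "LSTM")
GRID_UNITS = (64, 128, 256, 512)
GRID_DENSE = (0, 1)


@dataclass(frozen=True)
class ModelConfig:
    """One point of the hyperparameter grid plus fixed dimensions."""
    rnn_type: str = "GRU"
    units: int = 64
    dense_before_output: int = 0
    n_variables: int = 246
    n_static: int = 2
    t_max: int = 9
    embed_dim: int = 8
    attn_dim: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rnn_type not in ("GRU", "LSTM"):
            raise ValueError("rnn_type must be GRU or LSTM")
        if self.units <= 0:
            raise ValueError("units must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


@dataclass
class AttentionMap:
    """Per-patient attention: alpha (T x V) over variables within each real
    period, beta (T,) over periods. Zero on masked slots; each real period's
    alpha row and the beta vector sum to 1 over unmasked entries."""
    alpha: np.ndarray
    beta: np.ndarray


@dataclass
class ForwardOutput:
    p: np.ndarray                    # (N,) outcome probabilities
    alpha: np.ndarray                # (N, T, V)
    beta: np.ndarray                 # (N, T)

    def patient(self, i: int) -> AttentionMap:
        return AttentionMap(alpha=self.alpha[i], beta=self.beta[i])


class HierAttnNet:
    def __init__(self, config: ModelConfig, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        cfg = config
        self.var_cell = RecurrentCell(cfg.rnn_type, cfg.embed_dim, cfg.units, "var_rnn")
        self.time_fw = RecurrentCell(cfg.rnn_type, cfg.units, cfg.units, "time_fw")
        self.time_bw = RecurrentCell(cfg.rnn_type, cfg.units, cfg.units, "time_bw")
        self.params: dict[str, np.ndarray] = {}
        self.init_params(np.random.default_rng(cfg.seed))

    # ------------------------------------------------------------- params
    def init_params(self, rng: np.random.Generator) -> None:
        cfg, dt = self.config, self.dtype
        p: dict[str, np.ndarray] = {}
        U, A, V, d = cfg.units, cfg.attn_dim, cfg.n_variables, cfg.embed_dim
        p["embed_W"] = (rng.standard_normal((V, d)) * 0.2).astype(dt)
        p["embed_b"] = (rng.standard_normal((V, d)) * 0.05).astype(dt)
        self.var_cell.init_params(rng, p, dt)
        self.time_fw.init_params(rng, p, dt)
        self.time_bw.init_params(rng, p, dt)
        p["var_attn_W"] = glorot(rng, (U, A), dt)
        p["var_attn_b"] = np.zeros(A, dtype=dt)
        p["var_attn_v"] = glorot(rng, (A, 1), dt)[:, 0]
        p["time_attn_W"] = glorot(rng, (2 * U, A), dt)
        p["time_attn_b"] = np.zeros(A, dtype=dt)
        p["time_attn_v"] = glorot(rng, (A, 1), dt)[:, 0]
        head_in = 2 * U + cfg.n_static
        if cfg.dense_before_output:
            p["dense_W"] = glorot(rng, (head_in, U), dt)
            p["dense_b"] = np.zeros(U, dtype=dt)
            head_in = U
        p["out_W"] = glorot(rng, (head_in, 1), dt)
        p["out_b"] = np.zeros(1, dtype=dt)
        self.params = p

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # ------------------------------------------------------------ forward
    def forward(self, X, value_mask, period_mask, S, need_cache: bool = False):
        """Forward pass over a batch. Returns (ForwardOutput, cache or None)."""
        p = self.params
        dt = self.dtype
        X = np.ascontiguousarray(X, dtype=dt)
        Mv = np.ascontiguousarray(value_mask, dtype=dt)
        Mt = np.ascontiguousarray(period_mask, dtype=dt)
        S = np.ascontiguousarray(S, dtype=dt)
        N, T, V = X.shape
        U = self.config.units

        if np.any(Mt.sum(axis=1) == 0):
            raise ValueError("every patient needs at least one real period")

        idx = np.flatnonzero(Mt.reshape(N * T) > 0)
        xr = (X * Mv).reshape(N * T, V)[idx]          # values zeroed where unrecorded
        mv = Mv.reshape(N * T, V)[idx]
        degenerate = mv.sum(axis=1) == 0
        if degenerate.any():
            logger.warning("%d real period(s) with all variables missing; "
                           "their context is zero", int(degenerate.sum()))

        # per-variable embedding of the scalar values
        E, Eb = p["embed_W"], p["embed_b"]
        e = xr[:, :, None] * E[None, :, :] + Eb[None, :, :]

        H1, cache1 = self.var_cell.forward(p, e)       # (R, V, U)
        t1 = np.tanh(H1 @ p["var_attn_W"] + p["var_attn_b"])
        s1 = t1 @ p["var_attn_v"]                      # (R, V)
        alpha_r = masked_softmax(s1, mv)
        ctx = np.einsum("rv,rvu->ru", alpha_r, H1)

        C = np.zeros((N * T, U), dtype=dt)
        C[idx] = ctx
        C = C.reshape(N, T, U)
        alpha = np.zeros((N * T, V), dtype=dt)
        alpha[idx] = alpha_r
        alpha = alpha.reshape(N, T, V)

        Gf, cache_f = self.time_fw.forward(p, C, Mt)
        Cr, Mtr = C[:, ::-1], Mt[:, ::-1]
        Gb_r, cache_b = self.time_bw.forward(p, Cr, Mtr)
        G = np.concatenate([Gf, Gb_r[:, ::-1]], axis=2)   # (N, T, 2U)

        t2 = np.tanh(G @ p["time_attn_W"] + p["time_attn_b"])
        s2 = t2 @ p["time_attn_v"]                     # (N, T)
        beta = masked_softmax(s2, Mt)
        summ = np.einsum("nt,ntu->nu", beta, G)        # (N, 2U)

        z = np.concatenate([summ, S], axis=1)
        if self.config.dense_before_output:
            d_pre = z @ p["dense_W"] + p["dense_b"]
            d_act = np.maximum(d_pre, 0.0)
            logit = (d_act @ p["out_W"])[:, 0] + p["out_b"][0]
        else:
            d_pre = d_act = None
            logit = (z @ p["out_W"])[:, 0] + p["out_b"][0]
        prob = sigmoid(logit)

        out = ForwardOutput(p=prob, alpha=alpha, beta=beta)
        if not need_cache:
            return out, None
        cache = {
            "idx": idx, "xr": xr, "mv": mv, "e": e, "H1": H1, "cache1": cache1,
            "t1": t1, "alpha_r": alpha_r, "C": C, "cache_f": cache_f,
            "cache_b": cache_b, "G": G, "t2": t2, "beta": beta, "summ": summ,
            "S": S, "z": z, "d_pre": d_pre, "d_act": d_act, "logit": logit,
            "Mt": Mt, "shape": (N, T, V),
        }
        return out, cache

    # ------------------------------------------------------------ backward
    def backward(self, cache: dict, dlogit: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        grads: dict[str, np.ndarray] = {}
        N, T, V = cache["shape"]
        U = self.config.units
        dlogit = dlogit.astype(self.dtype)

        if self.config.dense_before_output:
            d_act = cache["d_act"]
            grads["out_W"] = d_act.T @ dlogit[:, None]
            grads["out_b"] = np.array([dlogit.sum()], dtype=self.dtype)
            dd_act = dlogit[:, None] @ p["out_W"].T
            dd_pre = dd_act * (cache["d_pre"] > 0)
            grads["dense_W"] = cache["z"].T @ dd_pre
            grads["dense_b"] = dd_pre.sum(axis=0)
            dz = dd_pre @ p["dense_W"].T
        else:
            grads["out_W"] = cache["z"].T @ dlogit[:, None]
            grads["out_b"] = np.array([dlogit.sum()], dtype=self.dtype)
            dz = dlogit[:, None] @ p["out_W"].T

        dsumm = dz[:, :2 * U]
        G, beta, t2, Mt = cache["G"], cache["beta"], cache["t2"], cache["Mt"]
        dbeta = np.einsum("nu,ntu->nt", dsumm, G)
        dG = beta[:, :, None] * dsumm[:, None, :]
        ds2 = masked_softmax_backward(beta, dbeta)
        dt2 = ds2[:, :, None] * p["time_attn_v"][None, None, :]
        grads["time_attn_v"] = np.einsum("nta,nt->a", t2, ds2)
        dpre2 = dt2 * (1.0 - t2 * t2)
        grads["time_attn_W"] = np.einsum("ntu,nta->ua", G, dpre2)
        grads["time_attn_b"] = dpre2.sum(axis=(0, 1))
        dG = dG + dpre2 @ p["time_attn_W"].T

        dGf, dGb = dG[:, :, :U], dG[:, :, U:]
        dC = self.time_fw.backward(p, grads, cache["cache_f"], np.ascontiguousarray(dGf))
        dC_b = self.time_bw.backward(p, grads, cache["cache_b"],
                                     np.ascontiguousarray(dGb[:, ::-1]))
        dC = dC + dC_b[:, ::-1]

        idx = cache["idx"]
        dctx = dC.reshape(N * T, U)[idx]
        H1, alpha_r, t1, mv, xr = (cache["H1"], cache["alpha_r"], cache["t1"],
                                   cache["mv"], cache["xr"])
        dH1 = alpha_r[:, :, None] * dctx[:, None, :]
        dalpha = np.einsum("ru,rvu->rv", dctx, H1)
        ds1 = masked_softmax_backward(alpha_r, dalpha)
        dt1 = ds1[:, :, None] * p["var_attn_v"][None, None, :]
        grads["var_attn_v"] = np.einsum("rva,rv->a", t1, ds1)
        dpre1 = dt1 * (1.0 - t1 * t1)
        grads["var_attn_W"] = np.einsum("rvu,rva->ua", H1, dpre1)
        grads["var_attn_b"] = dpre1.sum(axis=(0, 1))
        dH1 = dH1 + dpre1 @ p["var_attn_W"].T

        de = self.var_cell.backward(p, grads, cache["cache1"], dH1)
        grads["embed_W"] = np.einsum("rv,rvd->vd", xr, de)
        grads["embed_b"] = de.sum(axis=0)
        return grads

    # ---------------------------------------------------------- train step
    def loss_and_grads(self, X, Mv, Mt, S, y):
        """Mean binary cross-entropy and parameter gradients for one batch."""
        out, cache = self.forward(X, Mv, Mt, S, need_cache=True)
        logit = cache["logit"].astype(np.float64)
        y = np.asarray(y, dtype=np.float64)
        # numerically stable BCE-with-logits
        loss = float(np.mean(np.logaddexp(0.0, logit) - y * logit))
        dlogit = ((out.p.astype(np.float64) - y) / len(y))
        grads = self.backward(cache, dlogit)
        return loss, grads, out

    def predict(self, tensor, batch_size: int = 512) -> ForwardOutput:
        """Forward pass over a FeatureTensor (or compatible object), batched."""
        N = tensor.X.shape[0]
        ps, alphas, betas = [], [], []
        for lo in range(0, N, batch_size):
            sl = slice(lo, min(lo + batch_size, N))
            out, _ = self.forward(tensor.X[sl], tensor.value_mask[sl],
                                  tensor.period_mask[sl], tensor.S[sl])
            ps.append(out.p)
            alphas.append(out.alpha)
            betas.append(out.beta)
        return ForwardOutput(p=np.concatenate(ps),
                             alpha=np.concatenate(alphas),
                             beta=np.concatenate(betas))

    # ----------------------------------------------- spec-level operations
    def encode_periods(self, X, value_mask, period_mask):
        """Variable-level encoding only: (contexts (N,T,U), alpha (N,T,V))."""
        out, cache = self.forward(X, value_mask, period_mask,
                                  np.zeros((X.shape[0], self.config.n_static)),
                                  need_cache=True)
        return cache["C"], out.alpha

    def encode_sequence(self, contexts, period_mask):
        """Time-level encoding of precomputed period contexts."""
        p = self.params
        Mt = np.ascontiguousarray(period_mask, dtype=self.dtype)
        if np.any(Mt.sum(axis=1) == 0):
            raise ValueError("every patient needs at least one real period")
        C = np.ascontiguousarray(contexts, dtype=self.dtype)
        Gf, _ = self.time_fw.forward(p, C, Mt)
        Gb_r, _ = self.time_bw.forward(p, C[:, ::-1], Mt[:, ::-1])
        G = np.concatenate([Gf, Gb_r[:, ::-1]], axis=2)
        t2 = np.tanh(G @ p["time_attn_W"] + p["time_attn_b"])
        beta = masked_softmax(t2 @ p["time_attn_v"], Mt)
        summ = np.einsum("nt,ntu->nu", beta, G)
        return summ, beta

    # ------------------------------------------------------------------ io
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), **self.params)
        path.with_suffix(".json").write_text(self.config.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "HierAttnNet":
        path = Path(path)
        config = ModelConfig.from_json(path.with_suffix(".json").read_text())
        net = cls(config)
        arrays = np.load(path.with_suffix(".npz"))
        net.params = {k: arrays[k] for k in arrays.files}
        return net


def enumerate_grid(
    rnn_types=GRID_RNN_TYPES, units=GRID_UNITS, dense=GRID_DENSE
) -> list[dict]:
    """The hyperparameter grid: RNN type x units x dense-layer presence."""
    return [
        {"rnn_type": r, "units": u, "dense_before_output": d}
        for r in rnn_types for u in units for d in dense
    ]
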