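"""GRU and LSTM cells in NumPy with hand-coded backward passes.

Both cells support an optional per-step binary mask with carry semantics:
where the mask is 0 the hidden (and cell) state passes through unchanged, so
left-padded steps leave a zero initial state untouched. This is what makes
the time-level recurrence exactly invariant to the amount of padding.

Gradients are verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from .functional import sigmoid


def glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class RecurrentCell:
    """A GRU or LSTM layer applied over the second axis of (B, L, D) input."""

    def __init__(self, kind: str, input_dim: int, units: int, prefix: str):
        if kind not in ("GRU", "LSTM"):
            raise ValueError(f"unknown recurrent cell kind {kind!r}")
        self.kind = kind
        self.input_dim = input_dim
        self.units = units
        self.prefix = prefix

    @property
    def n_gates(self) -> int:
        return 3 if self.kind == "GRU" else 4

    def param_names(self) -> list[str]:
        return [f"{self.prefix}_{s}" for s in ("Wx", "Wh", "bx")] + (
            [f"{self.prefix}_Whn"] if self.kind == "GRU" else []
        )

    def init_params(self, rng: np.random.Generator, params: dict, dtype=np.float32) -> None:
        D, U, G = self.input_dim, self.units, self.n_gates
        p = self.prefix
        if self.kind == "GRU":
            params[f"{p}_Wx"] = glorot(rng, (D, 3 * U), dtype)
            params[f"{p}_Wh"] = glorot(rng, (U, 2 * U), dtype)      # update+reset
            params[f"{p}_Whn"] = glorot(rng, (U, U), dtype)         # candidate
            params[f"{p}_bx"] = np.zeros(3 * U, dtype=dtype)
        else:
            params[f"{p}_Wx"] = glorot(rng, (D, 4 * U), dtype)
            params[f"{p}_Wh"] = glorot(rng, (U, 4 * U), dtype)
            bx = np.zeros(4 * U, dtype=dtype)
            bx[U:2 * U] = 1.0                                       # forget-gate bias
            params[f"{p}_bx"] = bx

    # ------------------------------------------------------------- forward
    def forward(self, params: dict, X: np.ndarray, step_mask: np.ndarray | None = None):
        """Run the layer over (B, L, D); returns (outputs (B, L, U), cache)."""
        if self.kind == "GRU":
            return self._gru_forward(params, X, step_mask)
        return self._lstm_forward(params, X, step_mask)

    def backward(self, params: dict, grads: dict, cache: dict, dH: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients into ``grads``; return dX."""
        if self.kind == "GRU":
            return self._gru_backward(params, grads, cache, dH)
        return self._lstm_backward(params, grads, cache, dH)

    # ----------------------------------------------------------------- GRU
    def _gru_forward(self, params, X, step_mask):
        p = self.prefix
        B, L, D = X.shape
        U = self.units
        Wx, Wh, Whn, bx = (params[f"{p}_Wx"], params[f"{p}_Wh"],
                           params[f"{p}_Whn"], params[f"{p}_bx"])
        XP = X.reshape(B * L, D) @ Wx
        XP += bx
        XP = XP.reshape(B, L, 3 * U)
        h = np.zeros((B, U), dtype=X.dtype)
        H = np.empty((B, L, U), dtype=X.dtype)
        Z = np.empty((B, L, U), dtype=X.dtype)
        R = np.empty((B, L, U), dtype=X.dtype)
        Cc = np.empty((B, L, U), dtype=X.dtype)
        Hprev = np.empty((B, L, U), dtype=X.dtype)
        for t in range(L):
            Hprev[:, t] = h
            zr = XP[:, t, :2 * U] + h @ Wh
            zr = sigmoid(zr)
            z, r = zr[:, :U], zr[:, U:]
            c = XP[:, t, 2 * U:] + (r * h) @ Whn
            np.tanh(c, out=c)
            h_new = c + z * (h - c)          # == (1-z)*c + z*h
            if step_mask is not None:
                m = step_mask[:, t:t + 1].astype(X.dtype)
                h = h + m * (h_new - h)
            else:
                h = h_new
            Z[:, t], R[:, t], Cc[:, t], H[:, t] = z, r, c, h
        cache = {"X": X, "Z": Z, "R": R, "C": Cc, "Hprev": Hprev,
                 "mask": step_mask}
        return H, cache

    def _gru_backward(self, params, grads, cache, dH):
        p = self.prefix
        X, Z, R, Cc, Hprev = (cache["X"], cache["Z"], cache["R"],
                              cache["C"], cache["Hprev"])
        step_mask = cache["mask"]
        B, L, D = X.shape
        U = self.units
        Wx, Wh, Whn = params[f"{p}_Wx"], params[f"{p}_Wh"], params[f"{p}_Whn"]
        dXP = np.empty((B, L, 3 * U), dtype=X.dtype)
        dh_carry = np.zeros((B, U), dtype=X.dtype)
        for t in range(L - 1, -1, -1):
            dh = dH[:, t] + dh_carry
            if step_mask is not None:
                m = step_mask[:, t:t + 1].astype(X.dtype)
                dh_new = dh * m
                pass_through = dh * (1.0 - m)
            else:
                dh_new = dh
                pass_through = 0.0
            z, r, c, h_prev = Z[:, t], R[:, t], Cc[:, t], Hprev[:, t]
            dc = dh_new - dh_new * z
            dz = dh_new * (h_prev - c)
            dh_prev = dh_new * z
            dcpre = dc * (1.0 - c * c)
            dXP[:, t, 2 * U:] = dcpre
            drh = dcpre @ Whn.T
            dh_prev += drh * r
            dr = drh * h_prev
            dzr = dXP[:, t, :2 * U]
            np.multiply(dz, z - z * z, out=dzr[:, :U])
            np.multiply(dr, r - r * r, out=dzr[:, U:])
            dh_prev += dzr @ Wh.T
            dh_carry = dh_prev + pass_through
        # weight gradients batched over all steps at once
        dXP_flat = dXP.reshape(B * L, 3 * U)
        Hprev_flat = Hprev.reshape(B * L, U)
        grads[f"{p}_Wx"] = grads.get(f"{p}_Wx", 0.0) + X.reshape(B * L, D).T @ dXP_flat
        grads[f"{p}_bx"] = grads.get(f"{p}_bx", 0.0) + dXP_flat.sum(axis=0)
        grads[f"{p}_Wh"] = grads.get(f"{p}_Wh", 0.0) + Hprev_flat.T @ dXP_flat[:, :2 * U]
        grads[f"{p}_Whn"] = grads.get(f"{p}_Whn", 0.0) + (
            (R * Hprev).reshape(B * L, U).T @ dXP_flat[:, 2 * U:])
        return (dXP_flat @ Wx.T).reshape(B, L, D)

    # ---------------------------------------------------------------- LSTM
    def _lstm_forward(self, params, X, step_mask):
        p = self.prefix
        B, L, D = X.shape
        U = self.units
        Wx, Wh, bx = params[f"{p}_Wx"], params[f"{p}_Wh"], params[f"{p}_bx"]
        XP = (X.reshape(B * L, D) @ Wx + bx).reshape(B, L, 4 * U)
        h = np.zeros((B, U), dtype=X.dtype)
        c = np.zeros((B, U), dtype=X.dtype)
        H = np.empty((B, L, U), dtype=X.dtype)
        gates = np.empty((B, L, 4 * U), dtype=X.dtype)
        TanhC = np.empty((B, L, U), dtype=X.dtype)
        Hprev = np.empty((B, L, U), dtype=X.dtype)
        Cprev = np.empty((B, L, U), dtype=X.dtype)
        for t in range(L):
            Hprev[:, t], Cprev[:, t] = h, c
            pre = XP[:, t] + h @ Wh
            i = sigmoid(pre[:, :U])
            f = sigmoid(pre[:, U:2 * U])
            o = sigmoid(pre[:, 2 * U:3 * U])
            g = np.tanh(pre[:, 3 * U:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if step_mask is not None:
                m = step_mask[:, t:t + 1].astype(X.dtype)
                h = m * h_new + (1.0 - m) * h
                c = m * c_new + (1.0 - m) * c
            else:
                h, c = h_new, c_new
            gates[:, t, :U], gates[:, t, U:2 * U] = i, f
            gates[:, t, 2 * U:3 * U], gates[:, t, 3 * U:] = o, g
            TanhC[:, t] = tc
            H[:, t] = h
        cache = {"X": X, "gates": gates, "TanhC": TanhC, "Hprev": Hprev,
                 "Cprev": Cprev, "mask": step_mask}
        return H, cache

    def _lstm_backward(self, params, grads, cache, dH):
        p = self.prefix
        X, gates, TanhC = cache["X"], cache["gates"], cache["TanhC"]
        Hprev, Cprev, step_mask = cache["Hprev"], cache["Cprev"], cache["mask"]
        B, L, D = X.shape
        U = self.units
        Wx, Wh = params[f"{p}_Wx"], params[f"{p}_Wh"]
        dXP = np.empty((B, L, 4 * U), dtype=X.dtype)
        dh_carry = np.zeros((B, U), dtype=X.dtype)
        dc_carry = np.zeros((B, U), dtype=X.dtype)
        for t in range(L - 1, -1, -1):
            dh = dH[:, t] + dh_carry
            if step_mask is not None:
                m = step_mask[:, t:t + 1].astype(X.dtype)
                dh_new = dh * m
                dh_pass = dh * (1.0 - m)
                dc_new_in = dc_carry * m
                dc_pass = dc_carry * (1.0 - m)
            else:
                dh_new, dh_pass = dh, 0.0
                dc_new_in, dc_pass = dc_carry, 0.0
            i = gates[:, t, :U]
            f = gates[:, t, U:2 * U]
            o = gates[:, t, 2 * U:3 * U]
            g = gates[:, t, 3 * U:]
            tc = TanhC[:, t]
            do = dh_new * tc
            dc_new = dc_new_in + dh_new * o * (1.0 - tc * tc)
            di = dc_new * g
            df = dc_new * Cprev[:, t]
            dg = dc_new * i
            dc_prev = dc_new * f
            dpre = np.concatenate(
                [di * i * (1.0 - i), df * f * (1.0 - f),
                 do * o * (1.0 - o), dg * (1.0 - g * g)], axis=1)
            dXP[:, t] = dpre
            dh_prev = dpre @ Wh.T
            dh_carry = dh_prev + dh_pass
            dc_carry = dc_prev + dc_pass
        dXP_flat = dXP.reshape(B * L, 4 * U)
        grads[f"{p}_Wx"] = grads.get(f"{p}_Wx", 0.0) + X.reshape(B * L, D).T @ dXP_flat
        grads[f"{p}_bx"] = grads.get(f"{p}_bx", 0.0) + dXP_flat.sum(axis=0)
        grads[f"{p}_Wh"] = grads.get(f"{p}_Wh", 0.0) + Hprev.reshape(B * L, U).T @ dXP_flat
        return (dXP_flat @ Wx.T).reshape(B, L, D)
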