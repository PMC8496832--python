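"""NumPy implementation of the read classifier network and its gradients.

Architecture, applied to a one-hot read ``x`` of shape ``T x 4``:

* ``n_conv_blocks`` 1-D convolutional blocks (same-padded convolution of
  window ``W`` -> batch normalisation -> ReLU), final output ``T x N_c``;
* a bidirectional LSTM with ``N_h/2`` units per direction, outputs
  concatenated to hidden states ``h_t`` of shape ``T x N_h``;
* a soft-attention scorer ``e_t = w2^T tanh(W1 h_t + b1)`` normalised by a
  softmax over positions to attention weights ``alpha_t``;
* the read embedding ``r = sum_t alpha_t h_t`` and a dense softmax classifier
  over the ``N_y`` phenotype classes.

Everything is dense NumPy with hand-derived backward passes; gradients are
verified against central finite differences in the test suite.  Training
uses Adam.  All randomness flows through a single ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

EPS_BN = 1e-5


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


def glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def orthogonal(rng: np.random.Generator, n: int, m: int, dtype) -> np.ndarray:
    a = rng.standard_normal((max(n, m), min(n, m)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    out = q[:n, :m] if n >= m else q[:m, :n].T
    return np.ascontiguousarray(out, dtype=dtype)


def im2col(x: np.ndarray, window: int) -> np.ndarray:
    """B x T x C -> B x T x (window*C) patches with same-padding."""
    b, t, c = x.shape
    p = window // 2
    xp = np.zeros((b, t + 2 * p, c), dtype=x.dtype)
    xp[:, p: p + t] = x
    cols = np.empty((b, t, window, c), dtype=x.dtype)
    for w in range(window):
        cols[:, :, w, :] = xp[:, w: w + t, :]
    return cols.reshape(b, t, window * c)


def col2im(dcols: np.ndarray, window: int, c: int) -> np.ndarray:
    """Scatter-add adjoint of :func:`im2col`."""
    b, t, _ = dcols.shape
    p = window // 2
    dcols = dcols.reshape(b, t, window, c)
    dxp = np.zeros((b, t + 2 * p, c), dtype=dcols.dtype)
    for w in range(window):
        dxp[:, w: w + t, :] += dcols[:, :, w, :]
    return dxp[:, p: p + t, :]


class ReadNet:
    """The trainable network; parameters live in ``self.params``."""

    def __init__(
        self,
        *,
        window: int,
        n_conv_blocks: int,
        conv_channels: int,
        hidden_units: int,
        attention_units: int,
        n_classes: int,
        dropout: float = 0.0,
        dtype: str = "float32",
        rng: np.random.Generator,
    ) -> None:
        if window % 2 == 0:
            raise ValueError("conv window must be odd")
        if hidden_units % 2:
            raise ValueError("hidden_units must be even (split across directions)")
        self.window = window
        self.n_conv_blocks = n_conv_blocks
        self.conv_channels = conv_channels
        self.hidden_units = hidden_units
        self.attention_units = attention_units
        self.n_classes = n_classes
        self.dropout = float(dropout)
        self.dtype = np.dtype(dtype)
        h = hidden_units // 2
        p: dict[str, np.ndarray] = {}
        c_in = 4
        for i in range(n_conv_blocks):
            p[f"conv{i}_W"] = glorot(rng, (window * c_in, conv_channels), self.dtype)
            p[f"conv{i}_b"] = np.zeros(conv_channels, self.dtype)
            p[f"bn{i}_gamma"] = np.ones(conv_channels, self.dtype)
            p[f"bn{i}_beta"] = np.zeros(conv_channels, self.dtype)
            c_in = conv_channels
        for d in ("fw", "bw"):
            p[f"lstm_{d}_Wx"] = glorot(rng, (c_in, 4 * h), self.dtype)
            p[f"lstm_{d}_Wh"] = orthogonal(rng, h, 4 * h, self.dtype)
            b = np.zeros(4 * h, self.dtype)
            b[h: 2 * h] = 1.0  # unit forget-gate bias
            p[f"lstm_{d}_b"] = b
        p["att_W1"] = glorot(rng, (hidden_units, attention_units), self.dtype)
        p["att_b1"] = np.zeros(attention_units, self.dtype)
        p["att_w2"] = glorot(rng, (attention_units, 1), self.dtype)[:, 0]
        p["out_W"] = glorot(rng, (hidden_units, n_classes), self.dtype)
        p["out_b"] = np.zeros(n_classes, self.dtype)
        self.params = p
        # batch-norm running statistics (inference mode), momentum 0.9
        self.running = {}
        for i in range(n_conv_blocks):
            self.running[f"bn{i}_mean"] = np.zeros(conv_channels, self.dtype)
            self.running[f"bn{i}_var"] = np.ones(conv_channels, self.dtype)
        self.bn_momentum = 0.9

    # ------------------------------------------------------------------ forward

    def _lstm_dir(self, x: np.ndarray, d: str) -> tuple[np.ndarray, dict]:
        """Run one LSTM direction over B x T x C input (already time-ordered)."""
        p = self.params
        wx, wh, bias = p[f"lstm_{d}_Wx"], p[f"lstm_{d}_Wh"], p[f"lstm_{d}_b"]
        b, t, _ = x.shape
        h = wh.shape[0]
        xz = x @ wx + bias  # B x T x 4H, input contribution precomputed
        gi = np.empty((t, b, h), self.dtype)
        gf = np.empty((t, b, h), self.dtype)
        gg = np.empty((t, b, h), self.dtype)
        go = np.empty((t, b, h), self.dtype)
        cs = np.empty((t, b, h), self.dtype)
        hs = np.empty((t, b, h), self.dtype)
        hprev = np.zeros((b, h), self.dtype)
        cprev = np.zeros((b, h), self.dtype)
        for step in range(t):
            z = xz[:, step, :] + hprev @ wh
            i_g = sigmoid(z[:, :h])
            f_g = sigmoid(z[:, h: 2 * h])
            g_g = np.tanh(z[:, 2 * h: 3 * h])
            o_g = sigmoid(z[:, 3 * h:])
            cprev = f_g * cprev + i_g * g_g
            hprev = o_g * np.tanh(cprev)
            gi[step], gf[step], gg[step], go[step] = i_g, f_g, g_g, o_g
            cs[step], hs[step] = cprev, hprev
        cache = {"x": x, "gi": gi, "gf": gf, "gg": gg, "go": go, "cs": cs, "hs": hs}
        return hs.transpose(1, 0, 2), cache  # B x T x H

    def _lstm_dir_backward(self, dh_all: np.ndarray, cache: dict, d: str, grads: dict) -> np.ndarray:
        p = self.params
        wx, wh = p[f"lstm_{d}_Wx"], p[f"lstm_{d}_Wh"]
        x = cache["x"]
        gi, gf, gg, go = cache["gi"], cache["gf"], cache["gg"], cache["go"]
        cs, hs = cache["cs"], cache["hs"]
        b, t, _ = x.shape
        h = wh.shape[0]
        dwx = np.zeros_like(wx)
        dwh = np.zeros_like(wh)
        db = np.zeros_like(p[f"lstm_{d}_b"])
        dx = np.empty_like(x)
        dh_next = np.zeros((b, h), self.dtype)
        dc_next = np.zeros((b, h), self.dtype)
        dh_all = dh_all.transpose(1, 0, 2)  # T x B x H
        dz = np.empty((b, 4 * h), self.dtype)
        for step in range(t - 1, -1, -1):
            dh = dh_all[step] + dh_next
            tc = np.tanh(cs[step])
            do = dh * tc
            dc = dc_next + dh * go[step] * (1.0 - tc * tc)
            cprev = cs[step - 1] if step > 0 else 0.0
            hprev = hs[step - 1] if step > 0 else None
            di = dc * gg[step]
            df = dc * cprev
            dg = dc * gi[step]
            dz[:, :h] = di * gi[step] * (1.0 - gi[step])
            dz[:, h: 2 * h] = df * gf[step] * (1.0 - gf[step])
            dz[:, 2 * h: 3 * h] = dg * (1.0 - gg[step] * gg[step])
            dz[:, 3 * h:] = do * go[step] * (1.0 - go[step])
            dwx += x[:, step, :].T @ dz
            if hprev is not None:
                dwh += hprev.T @ dz
            db += dz.sum(axis=0)
            dx[:, step, :] = dz @ wx.T
            dh_next = dz @ wh.T
            dc_next = dc * gf[step]
        grads[f"lstm_{d}_Wx"] = dwx
        grads[f"lstm_{d}_Wh"] = dwh
        grads[f"lstm_{d}_b"] = db
        return dx

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> dict:
        """Full forward pass on a B x T x 4 batch; returns the cache.

        The cache holds ``alpha`` (B x T attention), ``hidden`` (B x T x N_h),
        ``embedding`` (B x N_h) and ``probs`` (B x N_y).
        """
        x = np.ascontiguousarray(x, dtype=self.dtype)
        p = self.params
        cache: dict = {"input": x, "train": train, "conv": []}
        cur = x
        for i in range(self.n_conv_blocks):
            cols = im2col(cur, self.window)
            pre_bn = cols @ p[f"conv{i}_W"] + p[f"conv{i}_b"]
            if train:
                mu = pre_bn.mean(axis=(0, 1))
                var = pre_bn.var(axis=(0, 1))
                m = self.bn_momentum
                self.running[f"bn{i}_mean"] = m * self.running[f"bn{i}_mean"] + (1 - m) * mu
                self.running[f"bn{i}_var"] = m * self.running[f"bn{i}_var"] + (1 - m) * var
            else:
                mu = self.running[f"bn{i}_mean"]
                var = self.running[f"bn{i}_var"]
            inv_std = 1.0 / np.sqrt(var + EPS_BN)
            xhat = (pre_bn - mu) * inv_std
            bn_out = p[f"bn{i}_gamma"] * xhat + p[f"bn{i}_beta"]
            act = np.maximum(bn_out, 0.0)
            drop_mask = None
            if train and self.dropout > 0.0:
                drop_mask = (rng.random(act.shape) >= self.dropout) / (1.0 - self.dropout)
                act = act * drop_mask.astype(self.dtype)
            cache["conv"].append(
                {"cols": cols, "xhat": xhat, "inv_std": inv_std, "act_pos": bn_out > 0,
                 "in_channels": cur.shape[2], "drop_mask": drop_mask}
            )
            cur = act
        h_fw, cache["lstm_fw"] = self._lstm_dir(cur, "fw")
        h_bw_rev, cache["lstm_bw"] = self._lstm_dir(cur[:, ::-1, :], "bw")
        hidden = np.concatenate([h_fw, h_bw_rev[:, ::-1, :]], axis=2)  # B x T x N_h
        u = np.tanh(hidden @ p["att_W1"] + p["att_b1"])
        scores = u @ p["att_w2"]  # B x T
        alpha = softmax(scores, axis=1)
        embedding = np.einsum("bt,bth->bh", alpha, hidden)
        emb_mask = None
        if train and self.dropout > 0.0:
            emb_mask = (rng.random(embedding.shape) >= self.dropout) / (1.0 - self.dropout)
            embedding = embedding * emb_mask.astype(self.dtype)
        logits = embedding @ p["out_W"] + p["out_b"]
        probs = softmax(logits, axis=1)
        cache.update(
            conv_out=cur, hidden=hidden, att_u=u, alpha=alpha,
            embedding=embedding, emb_mask=emb_mask, probs=probs,
        )
        return cache

    # ----------------------------------------------------------------- backward

    def backward(self, cache: dict, y_index: np.ndarray) -> dict:
        """Gradients of mean cross-entropy loss w.r.t. every parameter."""
        p = self.params
        b = cache["probs"].shape[0]
        grads: dict[str, np.ndarray] = {}
        dlogits = cache["probs"].copy()
        dlogits[np.arange(b), y_index] -= 1.0
        dlogits /= b
        emb = cache["embedding"]
        grads["out_W"] = emb.T @ dlogits
        grads["out_b"] = dlogits.sum(axis=0)
        demb = dlogits @ p["out_W"].T
        if cache["emb_mask"] is not None:
            demb = demb * cache["emb_mask"].astype(self.dtype)
        hidden, alpha, u = cache["hidden"], cache["alpha"], cache["att_u"]
        dalpha = np.einsum("bh,bth->bt", demb, hidden)
        dhidden = alpha[:, :, None] * demb[:, None, :]
        # softmax over positions
        dscores = alpha * (dalpha - (dalpha * alpha).sum(axis=1, keepdims=True))
        grads["att_w2"] = np.einsum("btn,bt->n", u, dscores)
        du = dscores[:, :, None] * p["att_w2"]
        dpre = du * (1.0 - u * u)
        grads["att_W1"] = np.einsum("bth,btn->hn", hidden, dpre)
        grads["att_b1"] = dpre.sum(axis=(0, 1))
        dhidden += dpre @ p["att_W1"].T
        h = self.hidden_units // 2
        dx_fw = self._lstm_dir_backward(dhidden[:, :, :h], cache["lstm_fw"], "fw", grads)
        dx_bw = self._lstm_dir_backward(
            dhidden[:, ::-1, h:], cache["lstm_bw"], "bw", grads
        )
        dcur = dx_fw + dx_bw[:, ::-1, :]
        for i in range(self.n_conv_blocks - 1, -1, -1):
            blk = cache["conv"][i]
            if blk["drop_mask"] is not None:
                dcur = dcur * blk["drop_mask"].astype(self.dtype)
            dbn = dcur * blk["act_pos"]
            xhat = blk["xhat"]
            grads[f"bn{i}_gamma"] = (dbn * xhat).sum(axis=(0, 1))
            grads[f"bn{i}_beta"] = dbn.sum(axis=(0, 1))
            if cache["train"]:
                m = xhat.shape[0] * xhat.shape[1]
                dxhat = dbn * p[f"bn{i}_gamma"]
                dpre_bn = (
                    dxhat
                    - dxhat.mean(axis=(0, 1))
                    - xhat * (dxhat * xhat).mean(axis=(0, 1))
                ) * blk["inv_std"]
            else:
                dpre_bn = dbn * p[f"bn{i}_gamma"] * blk["inv_std"]
            grads[f"conv{i}_W"] = np.einsum("btk,btc->kc", blk["cols"], dpre_bn)
            grads[f"conv{i}_b"] = dpre_bn.sum(axis=(0, 1))
            dcols = dpre_bn @ p[f"conv{i}_W"].T
            dcur = col2im(dcols, self.window, blk["in_channels"])
        return grads

    @staticmethod
    def loss(probs: np.ndarray, y_index: np.ndarray) -> float:
        b = probs.shape[0]
        return float(-np.log(np.clip(probs[np.arange(b), y_index], 1e-12, None)).mean())


class Adam:
    """Adam optimiser with the usual defaults (beta1 0.9, beta2 0.999)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            g = g.astype(params[k].dtype, copy=False)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
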