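"""NumPy neural-network engine for the dose model.

Implements exactly the pieces the dose-prediction architecture needs —
a feedforward branch for fixed covariates, stacked (bi)directional LSTM
layers over visit sequences, masked max pooling over time, a linear
fusion head, mean-squared-error loss and an Adam optimizer — with
hand-written backpropagation.  Gradients are verified against central
finite differences in the test suite.

Shapes: batches are (B, T, I) right-padded sequences with a boolean
validity mask (B, T); hidden size H; D = 2 directions when
bidirectional else 1.
Gate order inside concatenated weight matrices is (input, forget, cell,
output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NetworkSpec", "init_params", "forward", "backward", "Adam", "mse_and_grad"]

Params = dict[str, np.ndarray]


@dataclass(frozen=True)
class NetworkSpec:
    """Structural hyperparameters of the two-branch network."""

    input_size: int  # sequence feature width
    fixed_size: int  # fixed-covariate width
    hidden_size: int = 128
    num_layers: int = 2
    bidirectional: bool = True
    ffn_hidden: int = 64

    @property
    def directions(self) -> int:
        return 2 if self.bidirectional else 1

    @property
    def pooled_width(self) -> int:
        return self.directions * self.hidden_size

    def layer_input(self, layer: int) -> int:
        return self.input_size if layer == 0 else self.pooled_width


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def init_params(spec: NetworkSpec, seed: int) -> Params:
    """Uniform(-1/sqrt(H), 1/sqrt(H)) initialization, seeded."""
    rng = np.random.default_rng(seed)
    H = spec.hidden_size
    bound = 1.0 / np.sqrt(H)
    params: Params = {}

    def u(*shape):
        return rng.uniform(-bound, bound, size=shape)

    fb = 1.0 / np.sqrt(max(spec.fixed_size, 1))
    params["ffn_W"] = rng.uniform(-fb, fb, size=(spec.fixed_size, spec.ffn_hidden))
    params["ffn_b"] = np.zeros(spec.ffn_hidden)
    dirs = ("f", "r") if spec.bidirectional else ("f",)
    for l in range(spec.num_layers):
        for d in dirs:
            params[f"lstm{l}{d}_W"] = u(spec.layer_input(l), 4 * H)
            params[f"lstm{l}{d}_U"] = u(H, 4 * H)
            params[f"lstm{l}{d}_b"] = np.zeros(4 * H)
    head_in = spec.ffn_hidden + spec.pooled_width
    hb = 1.0 / np.sqrt(head_in)
    params["head_W"] = rng.uniform(-hb, hb, size=(head_in, 1))
    params["head_b"] = np.zeros(1)
    return params


def _reverse_padded(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence's valid prefix, leaving right pads in place."""
    out = np.zeros_like(x)
    for b, L in enumerate(lengths):
        out[b, :L] = x[b, :L][::-1]
    return out


def _lstm_layer_forward(x: np.ndarray, W: np.ndarray, U: np.ndarray, b: np.ndarray):
    """Run one unidirectional LSTM layer; returns outputs and cache."""
    B, T, _ = x.shape
    H = U.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    gates = np.empty((B, T, 4 * H))
    cs = np.empty((B, T, H))
    tanhcs = np.empty((B, T, H))
    hs = np.empty((B, T, H))
    xw = x @ W  # precompute input contributions
    for t in range(T):
        z = xw[:, t] + h @ U + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        gates[:, t, :H] = i
        gates[:, t, H : 2 * H] = f
        gates[:, t, 2 * H : 3 * H] = g
        gates[:, t, 3 * H :] = o
        cs[:, t] = c
        tanhcs[:, t] = tc
        hs[:, t] = h
    return hs, (x, gates, cs, tanhcs, hs)


def _lstm_layer_backward(dhs: np.ndarray, cache, W: np.ndarray, U: np.ndarray):
    """BPTT through one unidirectional layer.

    Returns gradients w.r.t. inputs and the three weight tensors.
    """
    x, gates, cs, tanhcs, hs = cache
    B, T, H = hs.shape
    dW = np.zeros_like(W)
    dU = np.zeros_like(U)
    db = np.zeros(4 * H)
    dx = np.zeros_like(x)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i = gates[:, t, :H]
        f = gates[:, t, H : 2 * H]
        g = gates[:, t, 2 * H : 3 * H]
        o = gates[:, t, 3 * H :]
        c_prev = cs[:, t - 1] if t > 0 else np.zeros((B, H))
        h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H))
        tc = tanhcs[:, t]
        dh = dhs[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dW += x[:, t].T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ W.T
        dh_next = dz @ U.T
        dc_next = dc * f
    return dx, dW, dU, db


def forward(
    params: Params,
    spec: NetworkSpec,
    fixed: np.ndarray,
    steps: np.ndarray,
    mask: np.ndarray,
    return_cache: bool = False,
    drop_mask: np.ndarray | None = None,
):
    """Full forward pass; returns predictions (B,) and optionally a cache."""
    if not mask.any(axis=1).all():
        raise ValueError("every sample needs at least one valid time step")
    lengths = mask.sum(axis=1).astype(int)
    B, T, _ = steps.shape
    H = spec.hidden_size

    # fixed branch
    ffn_pre = fixed @ params["ffn_W"] + params["ffn_b"]
    ffn_out = np.maximum(ffn_pre, 0.0)

    # recurrent branch
    layer_caches = []
    layer_in = steps
    for l in range(spec.num_layers):
        hs_f, cache_f = _lstm_layer_forward(
            layer_in, params[f"lstm{l}f_W"], params[f"lstm{l}f_U"], params[f"lstm{l}f_b"]
        )
        if spec.bidirectional:
            rev_in = _reverse_padded(layer_in, lengths)
            hs_rr, cache_r = _lstm_layer_forward(
                rev_in, params[f"lstm{l}r_W"], params[f"lstm{l}r_U"], params[f"lstm{l}r_b"]
            )
            hs_r = _reverse_padded(hs_rr, lengths)
            out = np.concatenate([hs_f, hs_r], axis=2)
        else:
            cache_r = None
            out = hs_f
        layer_caches.append((layer_in, cache_f, cache_r))
        layer_in = out

    # masked max pooling over time
    neg = np.where(mask[:, :, None], layer_in, -np.inf)
    argmax = np.argmax(neg, axis=1)  # (B, DH)
    pooled = np.take_along_axis(layer_in, argmax[:, None, :], axis=1)[:, 0, :]

    concat = np.concatenate([ffn_out, pooled], axis=1)
    if drop_mask is not None:
        concat = concat * drop_mask  # inverted dropout on the fused representation
    preds = (concat @ params["head_W"] + params["head_b"])[:, 0]
    if not np.all(np.isfinite(preds)):
        raise FloatingPointError("non-finite predictions (diverged parameters?)")
    if not return_cache:
        return preds
    cache = {
        "lengths": lengths,
        "ffn_pre": ffn_pre,
        "ffn_out": ffn_out,
        "fixed": fixed,
        "layer_caches": layer_caches,
        "seq_out": layer_in,
        "argmax": argmax,
        "pooled": pooled,
        "concat": concat,
        "drop_mask": drop_mask,
        "mask": mask,
    }
    return preds, cache


def backward(params: Params, spec: NetworkSpec, cache, dpreds: np.ndarray) -> Params:
    """Backpropagate d(loss)/d(preds) to every parameter."""
    grads: Params = {}
    lengths = cache["lengths"]
    concat = cache["concat"]
    B = concat.shape[0]

    dconcat = dpreds[:, None] @ params["head_W"].T  # (B, head_in)
    grads["head_W"] = concat.T @ dpreds[:, None]
    grads["head_b"] = np.array([dpreds.sum()])
    if cache["drop_mask"] is not None:
        dconcat = dconcat * cache["drop_mask"]

    Hf = cache["ffn_out"].shape[1]
    dffn_out = dconcat[:, :Hf]
    dpooled = dconcat[:, Hf:]

    dffn_pre = dffn_out * (cache["ffn_pre"] > 0)
    grads["ffn_W"] = cache["fixed"].T @ dffn_pre
    grads["ffn_b"] = dffn_pre.sum(axis=0)

    # scatter pooled grads to argmax time positions
    seq_out = cache["seq_out"]
    dseq = np.zeros_like(seq_out)
    np.put_along_axis(dseq, cache["argmax"][:, None, :], dpooled[:, None, :], axis=1)

    H = spec.hidden_size
    dlayer_out = dseq
    for l in range(spec.num_layers - 1, -1, -1):
        layer_in, cache_f, cache_r = cache["layer_caches"][l]
        if spec.bidirectional:
            d_f = dlayer_out[:, :, :H]
            d_r = dlayer_out[:, :, H:]
            dx_f, dWf, dUf, dbf = _lstm_layer_backward(
                d_f, cache_f, params[f"lstm{l}f_W"], params[f"lstm{l}f_U"]
            )
            d_rr = _reverse_padded(d_r, lengths)
            dx_rr, dWr, dUr, dbr = _lstm_layer_backward(
                d_rr, cache_r, params[f"lstm{l}r_W"], params[f"lstm{l}r_U"]
            )
            dx = dx_f + _reverse_padded(dx_rr, lengths)
            grads[f"lstm{l}r_W"] = dWr
            grads[f"lstm{l}r_U"] = dUr
            grads[f"lstm{l}r_b"] = dbr
        else:
            dx, dWf, dUf, dbf = _lstm_layer_backward(
                dlayer_out, cache_f, params[f"lstm{l}f_W"], params[f"lstm{l}f_U"]
            )
        grads[f"lstm{l}f_W"] = dWf
        grads[f"lstm{l}f_U"] = dUf
        grads[f"lstm{l}f_b"] = dbf
        dlayer_out = dx
    return grads


def mse_and_grad(preds: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. predictions."""
    if preds.shape != targets.shape:
        raise ValueError("prediction/target length mismatch")
    if preds.size == 0:
        raise ValueError("empty prediction vector")
    diff = preds - targets
    loss = float(np.mean(diff * diff))
    return loss, 2.0 * diff / preds.size


class Adam:
    """Plain Adam with bias correction."""

    def __init__(self, params: Params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
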