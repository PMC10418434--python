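"""Numpy implementation of the three-layer convolutional network.

The network consumes a (batch, planes, 4, window) tensor: plane 0 is the
one-hot sequence, planes 1..N the TF binding-affinity layers.  The first
convolution slides along the sequence axis with a receptive field spanning
all 4 nucleotide channels and is applied with a shared filter bank to every
plane; the first max-pool then takes the maximum over windows of 4 sequence
positions x all planes, collapsing the plane axis.  The two following
convolutions run along the sequence only, each followed by the thresholded
ReLU, a stride-4 max-pool and dropout.  A fully connected layer feeds a
per-feature sigmoid output.

The activation is a thresholded ReLU: negative (and zero) pre-activations
are replaced by a small floor (1e-6) instead of 0.  Its backward pass uses
a small leak (derivative ``leak`` where the pre-activation is <= 0, 1
elsewhere): with an exact-zero sub-threshold derivative, the aggressive
max-pooling and the small desk-scale sample sizes let whole layers die
irreversibly in the first epochs.  Gradient updates are clipped to a global
norm for the same reason.

Everything — initialization, shuffling, dropout — draws from a single
seeded numpy Generator, so training is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
from typing import Mapping

import numpy as np

ACTIVATION_FLOOR = 1e-6


def thresholded_relu(x: np.ndarray | float, floor: float = ACTIVATION_FLOOR):
    """x where x > 0, else the floor (1e-6)."""
    return np.where(np.asarray(x) > 0, x, floor)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, L) -> (B, Lout, C*k) patch matrix."""
    b, c, l = x.shape
    lout = l - k + 1
    cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # (B, C, Lout, k)
    return np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(b, lout, c * k)


class _Conv1d:
    """Valid-mode 1-D convolution over the sequence axis, all channels."""

    def __init__(self, c_in: int, f: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = (rng.standard_normal((f, c_in * k)) * scale).astype(np.float32)
        self.b = np.zeros(f, dtype=np.float32)
        self.k, self.c_in = k, c_in

    def forward(self, x: np.ndarray, cache: dict) -> np.ndarray:
        cols = _im2col(x, self.k)
        cache["cols"] = cols
        cache["l_in"] = x.shape[2]
        y = cols @ self.W.T + self.b
        return np.ascontiguousarray(y.transpose(0, 2, 1))  # (B, F, Lout)

    def backward(self, dy: np.ndarray, cache: dict, grads: dict, name: str) -> np.ndarray:
        cols = cache["cols"]
        b, f, lout = dy.shape
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 1))  # (B, Lout, F)
        grads[name + ".W"] = dyt.reshape(-1, f).T @ cols.reshape(-1, cols.shape[2])
        grads[name + ".b"] = dy.sum(axis=(0, 2))
        dcols = (dyt @ self.W).reshape(b, lout, self.c_in, self.k)
        dx = np.zeros((b, self.c_in, cache["l_in"]), dtype=np.float32)
        for k in range(self.k):
            dx[:, :, k : k + lout] += dcols[:, :, :, k].transpose(0, 2, 1)
        return dx


class _InputConv1d(_Conv1d):
    """First-layer convolution exploiting input sparsity.

    TF binding-affinity planes are zero away from predicted sites, and a
    convolution window of zeros contributes only the bias.  Only windows
    overlapping a nonzero column are scored (exactly equivalent to the dense
    computation), and — being the first layer — no input gradient is needed:
    the weight gradient likewise only receives terms from nonzero windows.
    """

    def forward(self, x: np.ndarray, cache: dict) -> np.ndarray:
        b, c, l = x.shape
        k = self.k
        lout = l - k + 1
        f = self.W.shape[0]
        cover = (x != 0).any(axis=1)  # (B, L)
        cs = np.zeros((b, l + 1), dtype=np.int32)
        np.cumsum(cover, axis=1, out=cs[:, 1:])
        win_cov = (cs[:, k:] - cs[:, :-k]) > 0  # (B, Lout): window holds a nonzero
        rows, cols_sel = np.nonzero(win_cov)
        sw = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # (B, C, Lout, K)
        patches = sw[rows, :, cols_sel].reshape(len(rows), c * k)
        vals = patches @ self.W.T + self.b
        y = np.empty((b, f, lout), dtype=np.float32)
        y[:] = self.b[None, :, None]
        y[rows, :, cols_sel] = vals
        cache["rows"], cache["cols_sel"], cache["patches"] = rows, cols_sel, patches
        return y

    def backward(self, dy: np.ndarray, cache: dict, grads: dict, name: str):
        rows, cols_sel, patches = cache["rows"], cache["cols_sel"], cache["patches"]
        dvals = dy[rows, :, cols_sel]  # (n_sel, F)
        grads[name + ".W"] = dvals.T @ patches
        grads[name + ".b"] = dy.sum(axis=(0, 2))
        return None  # first layer: no input gradient required


class _PerPlaneConv1d:
    """First-layer variant: an independent filter bank per input plane.

    x: (B, P, C, L) -> (B, P, F, Lout).
    """

    def __init__(self, planes: int, c_in: int, f: int, k: int, rng: np.random.Generator):
        self.banks = [_InputConv1d(c_in, f, k, rng) for _ in range(planes)]
        self.planes = planes

    def forward(self, x: np.ndarray, cache: dict) -> np.ndarray:
        outs = []
        cache["plane_caches"] = []
        for p in range(self.planes):
            cp: dict = {}
            outs.append(self.banks[p].forward(x[:, p], cp))
            cache["plane_caches"].append(cp)
        return np.stack(outs, axis=1)

    def backward(self, dy: np.ndarray, cache: dict, grads: dict, name: str):
        for p in range(self.planes):
            self.banks[p].backward(dy[:, p], cache["plane_caches"][p], grads, f"{name}.p{p}")
        return None  # first layer: no input gradient required

    def parameters(self, name: str) -> dict:
        out = {}
        for p, bank in enumerate(self.banks):
            out[f"{name}.p{p}.W"] = bank.W
            out[f"{name}.p{p}.b"] = bank.b
        return out


def _plane_maxpool_forward(x: np.ndarray, pool: int, cache: dict) -> np.ndarray:
    """(B, P, F, L) -> (B, F, L//pool): max over the plane axis and pool-sized
    sequence windows jointly."""
    b, p, f, l = x.shape
    lw = l // pool
    xr = x[:, :, :, : lw * pool].reshape(b, p, f, lw, pool)
    xf = np.ascontiguousarray(xr.transpose(0, 2, 3, 1, 4)).reshape(b, f, lw, p * pool)
    am = xf.argmax(axis=-1)
    cache["am"], cache["shape"] = am, (b, p, f, l, lw, pool)
    return np.take_along_axis(xf, am[..., None], axis=-1)[..., 0]


def _plane_maxpool_backward(dy: np.ndarray, cache: dict) -> np.ndarray:
    b, p, f, l, lw, pool = cache["shape"]
    dxf = np.zeros((b, f, lw, p * pool), dtype=np.float32)
    np.put_along_axis(dxf, cache["am"][..., None], dy[..., None], axis=-1)
    dxr = dxf.reshape(b, f, lw, p, pool).transpose(0, 3, 1, 2, 4)
    dx = np.zeros((b, p, f, l), dtype=np.float32)
    dx[:, :, :, : lw * pool] = dxr.reshape(b, p, f, lw * pool)
    return dx


class DeepSATANet:
    """The network; ``planes`` is N+1 for the 3-D encoding, 1 for the one-hot
    baseline and for the flattened ablation encoding (which widens
    ``in_channels`` to 4+N instead)."""

    def __init__(
        self,
        planes: int,
        n_features: int,
        in_channels: int = 4,
        conv_filters: tuple[int, int, int] = (320, 480, 960),
        conv_widths: tuple[int, int, int] = (8, 8, 8),
        pool: int = 4,
        dropout: tuple[float, float, float] = (0.2, 0.2, 0.5),
        hidden_units: int = 925,
        seq_len: int = 1000,
        activation_floor: float = ACTIVATION_FLOOR,
        seed: int = 0,
        per_plane: bool = False,
        leak: float = 0.1,
    ):
        if len(conv_filters) != 3 or any(f <= 0 for f in conv_filters):
            raise ValueError("conv_filters must be exactly three positive integers")
        if any(not (0 <= d < 1) for d in dropout):
            raise ValueError("dropout rates must be in [0, 1)")
        rng = np.random.default_rng(seed)
        f1, f2, f3 = conv_filters
        k1, k2, k3 = conv_widths
        self.planes, self.pool, self.dropout = planes, pool, dropout
        self.floor = activation_floor
        self.leak = leak
        self.seq_len, self.in_channels = seq_len, in_channels
        l1 = seq_len - k1 + 1
        p1 = l1 // pool
        l2 = p1 - k2 + 1
        p2 = l2 // pool
        l3 = p2 - k3 + 1
        p3 = l3 // pool
        if min(l1, l2, l3, p3) < 1:
            raise ValueError(f"sequence length {seq_len} too short for the stacked pooling")
        self.flat_dim = f3 * p3
        self.per_plane = per_plane
        if per_plane:
            self.conv1 = _PerPlaneConv1d(planes, in_channels, f1, k1, rng)
        else:
            self.conv1 = _InputConv1d(in_channels, f1, k1, rng)
        self.conv2 = _Conv1d(f1, f2, k2, rng)
        self.conv3 = _Conv1d(f2, f3, k3, rng)
        sc_h = np.sqrt(2.0 / self.flat_dim)
        self.Wh = (rng.standard_normal((hidden_units, self.flat_dim)) * sc_h).astype(np.float32)
        self.bh = np.zeros(hidden_units, dtype=np.float32)
        sc_o = np.sqrt(2.0 / hidden_units)
        self.Wo = (rng.standard_normal((n_features, hidden_units)) * sc_o).astype(np.float32)
        self.bo = np.zeros(n_features, dtype=np.float32)
        self.n_features = n_features

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        if self.per_plane:
            conv1_params = self.conv1.parameters("conv1")
        else:
            conv1_params = {"conv1.W": self.conv1.W, "conv1.b": self.conv1.b}
        return {
            **conv1_params,
            "conv2.W": self.conv2.W, "conv2.b": self.conv2.b,
            "conv3.W": self.conv3.W, "conv3.b": self.conv3.b,
            "fc1.W": self.Wh, "fc1.b": self.bh,
            "fc2.W": self.Wo, "fc2.b": self.bo,
        }

    def set_parameters(self, params: Mapping[str, np.ndarray]) -> None:
        if self.per_plane:
            for p, bank in enumerate(self.conv1.banks):
                bank.W = params[f"conv1.p{p}.W"].copy()
                bank.b = params[f"conv1.p{p}.b"].copy()
        else:
            self.conv1.W = params["conv1.W"].copy()
            self.conv1.b = params["conv1.b"].copy()
        self.conv2.W, self.conv2.b = params["conv2.W"].copy(), params["conv2.b"].copy()
        self.conv3.W, self.conv3.b = params["conv3.W"].copy(), params["conv3.b"].copy()
        self.Wh, self.bh = params["fc1.W"].copy(), params["fc1.b"].copy()
        self.Wo, self.bo = params["fc2.W"].copy(), params["fc2.b"].copy()

    def digest(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.parameters()):
            h.update(np.ascontiguousarray(self.parameters()[name]).tobytes())
        return h.hexdigest()

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """x: (B, planes, C, L) -> per-feature probabilities (B, n_features)."""
        if x.ndim != 4 or x.shape[1] != self.planes or x.shape[2] != self.in_channels:
            raise ValueError(
                f"input shape {x.shape} incompatible with (B, {self.planes}, "
                f"{self.in_channels}, {self.seq_len})"
            )
        b, p = x.shape[0], x.shape[1]
        cache: dict = {}

        c1: dict = {}
        # the thresholded ReLU is monotone non-decreasing, so pooling the raw
        # convolution outputs first and applying the activation to the pooled
        # values gives identical results on much smaller arrays
        floor = np.float32(self.floor)
        if self.per_plane:
            z1 = self.conv1.forward(x, c1)  # (B, P, F1, L1)
        else:
            z1 = self.conv1.forward(x.reshape(b * p, x.shape[2], x.shape[3]), c1)
            z1 = z1.reshape(b, p, z1.shape[1], z1.shape[2])
        pp: dict = {}
        pz1 = _plane_maxpool_forward(z1, self.pool, pp)
        m1 = pz1 > 0
        pooled1 = np.where(m1, pz1, floor)
        d1, dm1 = self._dropout(pooled1, self.dropout[0], train, rng)

        c2: dict = {}
        z2 = self.conv2.forward(d1, c2)
        pp2: dict = {}
        pz2 = _plane_maxpool_forward(z2[:, None], self.pool, pp2)
        m2 = pz2 > 0
        pooled2 = np.where(m2, pz2, floor)
        d2, dm2 = self._dropout(pooled2, self.dropout[1], train, rng)

        c3: dict = {}
        z3 = self.conv3.forward(d2, c3)
        pp3: dict = {}
        pz3 = _plane_maxpool_forward(z3[:, None], self.pool, pp3)
        m3 = pz3 > 0
        pooled3 = np.where(m3, pz3, floor)
        d3, dm3 = self._dropout(pooled3, self.dropout[2], train, rng)

        flat = d3.reshape(b, -1)
        zh = flat @ self.Wh.T + self.bh
        mh = zh > 0
        h = np.where(mh, zh, floor)
        logits = h @ self.Wo.T + self.bo
        probs = sigmoid(logits)

        cache.update(
            x_shape=x.shape, c1=c1, m1=m1, pp=pp, dm1=dm1, c2=c2, m2=m2, pp2=pp2,
            dm2=dm2, c3=c3, m3=m3, pp3=pp3, dm3=dm3, flat=flat, mh=mh, h=h,
        )
        return probs, cache

    @staticmethod
    def _dropout(x, rate, train, rng):
        if not train or rate == 0:
            return x, None
        mask = (rng.random(x.shape, dtype=np.float32) >= rate).astype(np.float32)
        mask /= np.float32(1.0 - rate)
        return x * mask, mask

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        b, p = cache["x_shape"][0], cache["x_shape"][1]
        grads: dict[str, np.ndarray] = {}
        h, mh, flat = cache["h"], cache["mh"], cache["flat"]
        grads["fc2.W"] = dlogits.T @ h
        grads["fc2.b"] = dlogits.sum(axis=0)
        leak = np.float32(self.leak)
        dh = (dlogits @ self.Wo) * np.where(mh, np.float32(1.0), leak)
        grads["fc1.W"] = dh.T @ flat
        grads["fc1.b"] = dh.sum(axis=0)
        dflat = dh @ self.Wh
        dd3 = dflat.reshape(b, self.conv3.W.shape[0], -1)
        if cache["dm3"] is not None:
            dd3 = dd3 * cache["dm3"]
        dp3 = dd3 * np.where(cache["m3"], np.float32(1.0), leak)
        dz3 = _plane_maxpool_backward(dp3, cache["pp3"])[:, 0]
        dd2 = self.conv3.backward(dz3, cache["c3"], grads, "conv3")
        if cache["dm2"] is not None:
            dd2 = dd2 * cache["dm2"]
        dp2 = dd2 * np.where(cache["m2"], np.float32(1.0), leak)
        dz2 = _plane_maxpool_backward(dp2, cache["pp2"])[:, 0]
        dd1 = self.conv2.backward(dz2, cache["c2"], grads, "conv2")
        if cache["dm1"] is not None:
            dd1 = dd1 * cache["dm1"]
        dp1 = dd1 * np.where(cache["m1"], np.float32(1.0), leak)
        dz1 = _plane_maxpool_backward(dp1, cache["pp"])
        if not self.per_plane:
            dz1 = dz1.reshape(b * p, dz1.shape[2], dz1.shape[3])
        self.conv1.backward(dz1, cache["c1"], grads, "conv1")
        return grads


class SGD:
    """SGD with momentum, weight decay, and global-norm gradient clipping."""

    def __init__(self, net: DeepSATANet, lr: float, momentum: float = 0.9,
                 weight_decay: float = 1e-6, grad_clip: float | None = 1.0):
        self.net, self.lr, self.momentum, self.wd = net, lr, momentum, weight_decay
        self.grad_clip = grad_clip
        self.vel = {k: np.zeros_like(v) for k, v in net.parameters().items()}

    def step(self, grads: Mapping[str, np.ndarray]) -> None:
        if self.grad_clip is not None:
            gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
            if gnorm > self.grad_clip:
                scale = self.grad_clip / gnorm
                grads = {k: g * scale for k, g in grads.items()}
        params = self.net.parameters()
        for name, p in params.items():
            g = grads[name].astype(np.float32) + self.wd * p
            v = self.vel[name]
            v *= self.momentum
            v -= self.lr * g
            p += v


def bce_loss_and_grad(
    probs: np.ndarray, y: np.ndarray, feature_mask: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy across (batch, features) and its gradient
    with respect to the logits.  ``feature_mask`` excludes features from the
    loss (e.g. single-class features)."""
    eps = 1e-7
    p = np.clip(probs, eps, 1 - eps)
    terms = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    if feature_mask is not None:
        terms = terms * feature_mask[None, :]
        denom = probs.shape[0] * max(int(feature_mask.sum()), 1)
    else:
        denom = probs.size
    loss = float(terms.sum() / denom)
    dlogits = (probs - y) / denom
    if feature_mask is not None:
        dlogits = dlogits * feature_mask[None, :]
    return loss, dlogits.astype(np.float32)
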