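"""The functional graph discriminative network (FGDN).

A five-layer spectral graph network run twice per subject with shared
weights: once on the ASD-template graph and once on the HC-template graph.
Each pass is

    ChebConv(K) -> PReLU -> dropout -> ChebConv(K) -> PReLU -> dropout
    -> flatten -> dense -> PReLU -> dense(2) -> sigmoid

and the subject's class score for class c is the c-th output unit of the
pass that used class c's template. Graph convolutions are K-order Chebyshev
polynomial filters of the rescaled normalized Laplacian, evaluated by the
three-term recursion on the feature matrix (never by materializing matrix
powers). The whole model is plain NumPy; gradients are derived analytically
(see ``backward_batch``) and the optimizer is a self-contained Adam with
decoupled-from-nothing classic L2 weight decay added to the gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_template import FunctionalGraph

EPS_PROB = 1e-7  # probability clip keeping the cross-entropy finite


# ---------------------------------------------------------------------------
# Laplacians
# ---------------------------------------------------------------------------

@dataclass
class LaplacianPair:
    laplacian: np.ndarray  # L = I - D^{-1/2} W D^{-1/2}
    rescaled: np.ndarray  # Lt = 2 L / lambda_max - I
    lambda_max: float


def normalized_laplacian(weights: np.ndarray) -> LaplacianPair:
    """Symmetric normalized Laplacian and its [-1, 1]-rescaled version.

    Isolated nodes (zero degree) get L_ii = 1 with zero off-diagonals, so the
    spectrum stays in [0, 2]. lambda_max is computed exactly by
    eigendecomposition (graphs here have at most a few hundred nodes).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.abs(w - w.T).max() > 1e-10:
        raise ValueError("weight matrix must be symmetric")
    if w.min() < 0:
        raise ValueError("weight matrix must be nonnegative")
    n = w.shape[0]
    deg = w.sum(axis=1)
    inv_sqrt = np.zeros(n)
    nz = deg > 0
    inv_sqrt[nz] = deg[nz] ** -0.5
    lap = np.eye(n) - (inv_sqrt[:, None] * w * inv_sqrt[None, :])
    lap = 0.5 * (lap + lap.T)
    lam_max = float(np.linalg.eigvalsh(lap).max())
    if lam_max <= 0:  # only for the empty graph, where L = I
        lam_max = 1.0
    rescaled = (2.0 / lam_max) * lap - np.eye(n)
    return LaplacianPair(laplacian=lap, rescaled=0.5 * (rescaled + rescaled.T),
                         lambda_max=lam_max)


# ---------------------------------------------------------------------------
# Chebyshev convolution
# ---------------------------------------------------------------------------

def _cheb_stack(lt: np.ndarray, x: np.ndarray, order: int) -> list[np.ndarray]:
    """[T_0(Lt) X, ..., T_{K-1}(Lt) X] by the recursion T_k = 2 Lt T_{k-1} - T_{k-2}.

    ``x`` may be (N, d) or batched (B, N, d); Lt is applied along the node axis.
    """
    out = [x]
    if order > 1:
        out.append(np.einsum("nm,...md->...nd", lt, x))
    for _ in range(2, order):
        out.append(2.0 * np.einsum("nm,...md->...nd", lt, out[-1]) - out[-2])
    return out


def cheb_conv(x: np.ndarray, rescaled: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """K-order Chebyshev spectral convolution sum_k T_k(Lt) X theta_k.

    ``theta`` has shape (K, d_in, d_out); ``x`` is (N, d_in) or (B, N, d_in).
    """
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 3:
        raise ValueError("theta must have shape (K, d_in, d_out)")
    if x.shape[-1] != theta.shape[1]:
        raise ValueError(
            f"feature dimension {x.shape[-1]} does not match theta d_in {theta.shape[1]}"
        )
    if x.shape[-2] != rescaled.shape[0]:
        raise ValueError("node count does not match the Laplacian")
    tx = _cheb_stack(rescaled, x, theta.shape[0])
    return sum(np.einsum("...nd,do->...no", t, th) for t, th in zip(tx, theta))


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class FgdnParams:
    """All trainable tensors of the network, keyed for the optimizer."""

    theta1: np.ndarray  # (K, N, C)
    theta2: np.ndarray  # (K, C, C)
    w_fc: np.ndarray  # (N*C, H)
    b_fc: np.ndarray  # (H,)
    w_out: np.ndarray  # (H, 2)
    b_out: np.ndarray  # (2,)
    a1: np.ndarray  # PReLU slopes, scalar arrays
    a2: np.ndarray
    a3: np.ndarray
    order: int = 3
    channels: int = 64
    hidden: int = 128

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "theta1": self.theta1, "theta2": self.theta2,
            "w_fc": self.w_fc, "b_fc": self.b_fc,
            "w_out": self.w_out, "b_out": self.b_out,
            "a1": self.a1, "a2": self.a2, "a3": self.a3,
        }

    def copy(self) -> "FgdnParams":
        return FgdnParams(
            **{k: v.copy() for k, v in self.as_dict().items()},
            order=self.order, channels=self.channels, hidden=self.hidden,
        )

    @property
    def n_rois(self) -> int:
        return self.theta1.shape[1]


def init_params(
    n_rois: int,
    rng: np.random.Generator,
    order: int = 3,
    channels: int = 64,
    hidden: int = 128,
    prelu_init: float = 0.25,
) -> FgdnParams:
    """Glorot-uniform initialization; Chebyshev tensors count K*d_in as fan-in."""

    def glorot(shape, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    return FgdnParams(
        theta1=glorot((order, n_rois, channels), order * n_rois, channels),
        theta2=glorot((order, channels, channels), order * channels, channels),
        w_fc=glorot((n_rois * channels, hidden), n_rois * channels, hidden),
        b_fc=np.zeros(hidden),
        w_out=glorot((hidden, 2), hidden, 2),
        b_out=np.zeros(2),
        a1=np.array(prelu_init), a2=np.array(prelu_init), a3=np.array(prelu_init),
        order=order, channels=channels, hidden=hidden,
    )


def _prelu(z: np.ndarray, a: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, a * z)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------

def _to_cols(x: np.ndarray) -> np.ndarray:
    """(B, N, d) -> (N, B*d) so Laplacian products are single GEMMs."""
    return np.ascontiguousarray(x.transpose(1, 0, 2)).reshape(x.shape[1], -1)


def _from_cols(y: np.ndarray, b: int, d: int) -> np.ndarray:
    return y.reshape(y.shape[0], b, d).transpose(1, 0, 2)


def _cheb_flat(lt: np.ndarray, x: np.ndarray, order: int) -> np.ndarray:
    """Concatenated Chebyshev basis [T_0 X | ... | T_{K-1} X] as (B*N, K*d).

    Same three-term recursion as :func:`_cheb_stack`, in the column layout;
    the k-major block order matches theta.reshape(K*d, d_out).
    """
    b, n, d = x.shape
    cols = [_to_cols(x)]
    if order > 1:
        cols.append(lt @ cols[0])
    for _ in range(2, order):
        cols.append(2.0 * (lt @ cols[-1]) - cols[-2])
    stacked = np.stack([_from_cols(c, b, d) for c in cols], axis=2)  # (B,N,K,d)
    return stacked.reshape(b * n, order * d)


def _cheb_clenshaw_cols(lt: np.ndarray, terms: list[np.ndarray]) -> np.ndarray:
    """sum_k T_k(lt) C_k with C_k in (N, cols) layout (generalized Clenshaw)."""
    order = len(terms)
    if order == 1:
        return terms[0]
    b_next = np.zeros_like(terms[0])
    b_cur = terms[order - 1]
    for k in range(order - 2, 0, -1):
        b_cur, b_next = terms[k] + 2.0 * (lt @ b_cur) - b_next, b_cur
    return terms[0] + lt @ b_cur - b_next


def _pass_forward(
    x: np.ndarray,  # (B, N, d)
    lt: np.ndarray,
    p: FgdnParams,
    masks: tuple[np.ndarray, np.ndarray] | None,
) -> dict:
    """One template pass; ``masks`` are inverted-dropout multipliers or None."""
    b, n, _ = x.shape
    k, c = p.order, p.channels
    tx1 = _cheb_flat(lt, x, k)  # (B*N, K*d_in)
    z1 = (tx1 @ p.theta1.reshape(-1, c)).reshape(b, n, c)
    h1 = _prelu(z1, p.a1)
    d1 = h1 * masks[0] if masks is not None else h1
    tx2 = _cheb_flat(lt, d1, k)  # (B*N, K*C)
    z2 = (tx2 @ p.theta2.reshape(-1, c)).reshape(b, n, c)
    h2 = _prelu(z2, p.a2)
    d2 = h2 * masks[1] if masks is not None else h2
    flat = d2.reshape(b, -1)
    z3 = flat @ p.w_fc + p.b_fc
    h3 = _prelu(z3, p.a3)
    z4 = h3 @ p.w_out + p.b_out
    probs = _sigmoid(z4)
    return {
        "lt": lt, "tx1": tx1, "z1": z1, "d1": d1, "tx2": tx2, "z2": z2,
        "masks": masks, "flat": flat, "z3": z3, "h3": h3, "probs": probs,
    }


def _pass_backward(cache: dict, p: FgdnParams, d_z4: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of one pass given dLoss/dZ4 (pre-sigmoid output)."""
    lt = cache["lt"]
    b, n, c = cache["z2"].shape
    k = p.order
    grads: dict[str, np.ndarray] = {}
    grads["w_out"] = cache["h3"].T @ d_z4
    grads["b_out"] = d_z4.sum(axis=0)
    d_h3 = d_z4 @ p.w_out.T
    z3 = cache["z3"]
    grads["a3"] = np.asarray(np.sum(d_h3 * np.where(z3 > 0, 0.0, z3)))
    d_z3 = d_h3 * np.where(z3 > 0, 1.0, p.a3)
    grads["w_fc"] = cache["flat"].T @ d_z3
    grads["b_fc"] = d_z3.sum(axis=0)
    d_d2 = (d_z3 @ p.w_fc.T).reshape(b, n, c)
    d_h2 = d_d2 * cache["masks"][1] if cache["masks"] is not None else d_d2
    z2 = cache["z2"]
    grads["a2"] = np.asarray(np.sum(d_h2 * np.where(z2 > 0, 0.0, z2)))
    d_z2 = d_h2 * np.where(z2 > 0, 1.0, p.a2)
    d_z2_flat = d_z2.reshape(b * n, c)
    grads["theta2"] = (cache["tx2"].T @ d_z2_flat).reshape(k, c, c)
    # adjoint through the Chebyshev filter: sum_k T_k(Lt) (dZ2 theta_k^T)
    d_d1 = _from_cols(
        _cheb_clenshaw_cols(lt, [_to_cols(d_z2 @ th.T) for th in p.theta2]), b, c
    )
    d_h1 = d_d1 * cache["masks"][0] if cache["masks"] is not None else d_d1
    z1 = cache["z1"]
    grads["a1"] = np.asarray(np.sum(d_h1 * np.where(z1 > 0, 0.0, z1)))
    d_z1 = (d_h1 * np.where(z1 > 0, 1.0, p.a1)).reshape(b * n, c)
    d_in = p.theta1.shape[1]
    grads["theta1"] = (cache["tx1"].T @ d_z1).reshape(k, d_in, c)
    return grads


def forward_batch(
    x: np.ndarray,  # (B, N, d) shared node features
    lt_asd: np.ndarray,
    lt_hc: np.ndarray,
    params: FgdnParams,
    dropout: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Both template passes. Returns (p_asd, p_hc) per subject and the caches.

    p_asd is output unit 0 of the ASD-template pass; p_hc is unit 1 of the
    HC-template pass. Dropout (inverted scaling) is drawn independently per
    pass and only when ``training``.
    """

    def draw_masks():
        if not training or dropout <= 0:
            return None
        keep = 1.0 - dropout
        m1 = (rng.random(x.shape[:2] + (params.channels,)) < keep) / keep
        m2 = (rng.random(x.shape[:2] + (params.channels,)) < keep) / keep
        return (m1, m2)

    cache_a = _pass_forward(x, lt_asd, params, draw_masks())
    cache_h = _pass_forward(x, lt_hc, params, draw_masks())
    return cache_a["probs"][:, 0], cache_h["probs"][:, 1], (cache_a, cache_h)


def backward_batch(
    caches: tuple,
    params: FgdnParams,
    y_asd: np.ndarray,  # (B,) 1.0 for ASD subjects, 0.0 for HC
) -> dict[str, np.ndarray]:
    """Gradients of the summed cross-entropy loss for one batch.

    Through the sigmoid + binary cross-entropy pair, dLoss/dz = p - y on the
    unit that the loss reads (unit 0 of the ASD pass, unit 1 of the HC pass);
    the unread unit of each pass receives no gradient. Shared parameters
    accumulate over both passes.
    """
    cache_a, cache_h = caches
    b = y_asd.shape[0]
    d_z4_a = np.zeros((b, 2))
    d_z4_a[:, 0] = cache_a["probs"][:, 0] - y_asd
    d_z4_h = np.zeros((b, 2))
    d_z4_h[:, 1] = cache_h["probs"][:, 1] - (1.0 - y_asd)
    ga = _pass_backward(cache_a, params, d_z4_a)
    gh = _pass_backward(cache_h, params, d_z4_h)
    return {k: ga[k] + gh[k] for k in ga}


def fgdn_forward(
    asd_graph: FunctionalGraph,
    hc_graph: FunctionalGraph,
    params: FgdnParams,
    dropout: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Single-subject forward pass returning (p_asd, p_hc) in (0, 1)."""
    if not np.array_equal(asd_graph.node_features, hc_graph.node_features):
        raise ValueError("the two graphs of one subject must share node features")
    lt_a = normalized_laplacian(asd_graph.template.weights).rescaled
    lt_h = normalized_laplacian(hc_graph.template.weights).rescaled
    x = asd_graph.node_features[None, :, :]
    p_asd, p_hc, _ = forward_batch(
        x, lt_a, lt_h, params, dropout=dropout, training=training, rng=rng
    )
    return float(p_asd[0]), float(p_hc[0])


def classify(p_asd: float, p_hc: float) -> str:
    """ASD iff the ASD output exceeds the HC output; ties go to HC."""
    return "ASD" if p_asd > p_hc else "HC"


def fgdn_loss(preds: list[tuple[float, float]], labels: list[str]) -> float:
    """Summed two-unit binary cross-entropy over a batch.

    Targets are (1, 0) for ASD and (0, 1) for HC; each unit contributes both
    its log p and log(1-p) terms; probabilities are clipped to
    [1e-7, 1 - 1e-7].
    """
    if len(preds) == 0:
        raise ValueError("empty batch")
    if len(preds) != len(labels):
        raise ValueError("predictions and labels misaligned")
    p = np.clip(np.asarray(preds, dtype=float), EPS_PROB, 1.0 - EPS_PROB)
    y = np.array([[1.0, 0.0] if lab == "ASD" else [0.0, 1.0] for lab in labels])
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum())


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Classic Adam with L2 weight decay folded into the gradients.

    PReLU slopes and biases are exempt from weight decay, as is conventional.
    """

    _NO_DECAY = {"a1", "a2", "a3", "b_fc", "b_out"}

    def __init__(self, params: FgdnParams, lr: float = 1e-4, weight_decay: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.as_dict().items()}
        self.v = {k: np.zeros_like(v) for k, v in params.as_dict().items()}

    def step(self, params: FgdnParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        tensors = params.as_dict()
        for k, g in grads.items():
            if self.weight_decay and k not in self._NO_DECAY:
                g = g + self.weight_decay * tensors[k]
            m, v = self.m[k], self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            tensors[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
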