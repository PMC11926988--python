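"""Training losses: discrete-time censored NLL, representation alignment.

The survival head predicts per-interval hazards T_1..T_t.  With
S(0) = 1 and S(j) = Π_{u≤j} (1 − h_u), an observed death in interval y
contributes −[log S(y−1) + log h_y] to the negative log-likelihood; a
patient censored in interval y contributes −log S(y).  The alignment
loss is an L1 distance (per dimension) between pooled intra-modal
representations (h, g) and their cross-modal reconstructions (ĥ, ĝ):

    L_sim = (1/d) (‖h−ĥ‖₁ + ‖g−ĝ‖₁ + ‖h−g‖₁ + ‖ĥ−ĝ‖₁)

and the total objective is L_total = L_sur + α·L_sim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor


@dataclass
class LossBundle:
    l_sur: float
    l_sim: float
    l_total: float
    alpha: float


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def nll_survival_loss(hazards, bin_label, censor, eps: float = 1e-7) -> Tensor:
    """Discrete-time censored negative log-likelihood (batch mean).

    hazards: (B, t) in (0,1) (clamped to [eps, 1-eps]); bin_label: (B,)
    integers in 1..t; censor: (B,) with 0 = death observed, 1 = censored.
    """
    h = _as_tensor(hazards)
    if h.ndim == 1:
        h = h.reshape(1, -1)
    B, t = h.shape
    y = np.atleast_1d(np.asarray(bin_label, dtype=int))
    s = np.atleast_1d(np.asarray(censor, dtype=int))
    if y.shape != (B,) or s.shape != (B,):
        raise ValueError("bin_label / censor must have one entry per row")
    if np.any((y < 1) | (y > t)):
        raise ValueError(f"bin_label outside 1..{t}")
    if np.any((s != 0) & (s != 1)):
        raise ValueError("censor must be 0 or 1")

    h = h.clamp(eps, 1.0 - eps)
    log_h = h.log()
    log_1mh = (1.0 - h).log()
    # cumulative log-survival via lower-triangular ones: logS_j = Σ_{u<=j}
    tri = np.tril(np.ones((t, t)))
    logS = log_1mh @ Tensor(tri.T)          # (B, t); column j = log S(j+1)

    onehot_y = np.zeros((B, t))
    onehot_y[np.arange(B), y - 1] = 1.0
    onehot_prev = np.zeros((B, t))
    has_prev = y > 1
    onehot_prev[np.nonzero(has_prev)[0], y[has_prev] - 2] = 1.0

    uncens = (s == 0).astype(float)
    # death in y: log S(y-1) + log h_y ; censored at y: log S(y)
    ll_death = (logS * Tensor(onehot_prev)).sum(axis=1) \
        + (log_h * Tensor(onehot_y)).sum(axis=1)
    ll_cens = (logS * Tensor(onehot_y)).sum(axis=1)
    ll = ll_death * Tensor(uncens) + ll_cens * Tensor(1.0 - uncens)
    return -(ll.mean())


def alignment_loss(h, h_hat, g, g_hat, mode: str = "all",
                   metric: str = "l1") -> Tensor:
    """Distance between intra-modal and cross-modal pooled representations.

    mode selects which of the four pair terms are kept: ``all`` (both
    intra- and cross-modal), ``intra_only`` (h↔ĥ, g↔ĝ), ``cross_only``
    (h↔g, ĥ↔ĝ), ``none`` (constant zero).  metric: ``l1`` (default),
    ``mse`` (squared Euclidean per dimension), or ``kl`` (softmax each
    vector, then symmetrized KL; no 1/d factor since KL is already a
    distribution-level quantity).
    """
    h, h_hat, g, g_hat = map(_as_tensor, (h, h_hat, g, g_hat))
    d = h.shape[0]
    for v in (h_hat, g, g_hat):
        if v.shape != h.shape:
            raise ValueError("all four representations must share a dimension")
    if mode == "none":
        return Tensor(0.0)
    pairs = {
        "all": [(h, h_hat), (g, g_hat), (h, g), (h_hat, g_hat)],
        "intra_only": [(h, h_hat), (g, g_hat)],
        "cross_only": [(h, g), (h_hat, g_hat)],
    }.get(mode)
    if pairs is None:
        raise ValueError(f"unknown alignment mode {mode!r}")

    if metric == "l1":
        term = lambda a, b: (a - b).abs().sum() / float(d)
    elif metric == "mse":
        term = lambda a, b: ((a - b) * (a - b)).sum() / float(d)
    elif metric == "kl":
        def term(a, b):
            p = a.softmax(axis=-1).clamp(1e-12, 1.0)
            q = b.softmax(axis=-1).clamp(1e-12, 1.0)
            return ((p * (p.log() - q.log())).sum()
                    + (q * (q.log() - p.log())).sum())
    else:
        raise ValueError(f"unknown sim metric {metric!r}")

    total = None
    for a, b in pairs:
        t = term(a, b)
        total = t if total is None else total + t
    return total


def total_loss(l_sur: float, l_sim: float, alpha: float) -> LossBundle:
    """Combine the two loss components: L_total = L_sur + α·L_sim."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    l_sur = float(l_sur)
    l_sim = float(l_sim)
    return LossBundle(l_sur=l_sur, l_sim=l_sim,
                      l_total=l_sur + alpha * l_sim, alpha=alpha)
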