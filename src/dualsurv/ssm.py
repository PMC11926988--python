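"""State-space model primitives and the bidirectional selective-scan block.

A linear time-invariant SSM maps an input sequence x through a hidden
state h via h'(t) = D h(t) + E x(t), y(t) = F h(t).  Discretizing with a
timescale Δ under zero-order hold gives

    D̄ = exp(Δ D),    Ē = (Δ D)^{-1} (exp(Δ D) − I) · Δ E,

and the discrete recurrence h_t = D̄ h_{t−1} + Ē x_t, y_t = F h_t, which
for time-invariant parameters is equivalently a causal convolution with
kernel K̄ = (F Ē, F D̄ Ē, …, F D̄^{M−1} Ē).  The functions below implement
these forms for diagonal state matrices and serve as the reference
oracles for the selective (input-dependent) scan used by `BiMamba`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, depthwise_conv1d, selective_scan

_ZOH_SMALL = 1e-6  # |ΔD| below this uses the removable-singularity limit


@dataclass
class SSMParams:
    """Continuous diagonal SSM: D (diag, length N_s), E, F, timescale Δ."""

    D: np.ndarray      # (N_s,) diagonal of the state matrix
    E: np.ndarray      # (N_s,) input map
    F: np.ndarray      # (N_s,) output map
    delta: np.ndarray  # scalar or per-timestep (L,) positive timescale

    def __post_init__(self):
        self.D = np.atleast_1d(np.asarray(self.D, dtype=float))
        self.E = np.atleast_1d(np.asarray(self.E, dtype=float))
        self.F = np.atleast_1d(np.asarray(self.F, dtype=float))
        self.delta = np.asarray(self.delta, dtype=float)
        if np.any(self.delta <= 0):
            raise ValueError("timescale delta must be positive")


@dataclass
class DiscreteSSM:
    """Discrete diagonal SSM: D̄ and Ē from zero-order hold."""

    Dbar: np.ndarray
    Ebar: np.ndarray

    def __post_init__(self):
        if not (np.all(np.isfinite(self.Dbar)) and np.all(np.isfinite(self.Ebar))):
            raise ValueError("discretized parameters must be finite")


def zoh_discretize(params: SSMParams) -> DiscreteSSM:
    """Zero-order-hold discretization of a diagonal SSM.

    Elementwise on the diagonal: D̄ = exp(ΔD) and
    Ē = (ΔD)^{-1}(exp(ΔD) − 1) · ΔE, with the continuous limit Ē → ΔE
    taken where |ΔD| < 1e-6.
    """
    delta = params.delta
    if np.ndim(delta) == 0:
        dD = delta * params.D
    else:
        dD = np.multiply.outer(delta, params.D)  # (L, N_s)
    Dbar = np.exp(dD)
    safe = np.where(np.abs(dD) < _ZOH_SMALL, 1.0, dD)
    factor = np.where(np.abs(dD) < _ZOH_SMALL, 1.0, (Dbar - 1.0) / safe)
    Ebar = factor * (np.asarray(delta)[..., None] if np.ndim(delta) else delta) \
        * params.E
    return DiscreteSSM(Dbar=Dbar, Ebar=Ebar)


def ssm_scan(disc: DiscreteSSM, F: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Run the discrete recurrence h_t = D̄_t h_{t−1} + Ē_t x_t, y_t = F_t·h_t.

    `disc.Dbar`/`disc.Ebar` may be time-invariant (N_s,) or per-timestep
    (L, N_s) for the selective case; `F` likewise. h_0 = 0.
    """
    x = np.asarray(x, dtype=float)
    L = x.shape[0]
    Dbar = np.asarray(disc.Dbar, dtype=float)
    Ebar = np.asarray(disc.Ebar, dtype=float)
    F = np.atleast_1d(np.asarray(F, dtype=float))
    if Dbar.ndim == 2 and Dbar.shape[0] != L:
        raise ValueError("per-timestep parameters must match len(x)")

    def at(p, t):
        return p[t] if p.ndim == 2 else p

    h = np.zeros(Dbar.shape[-1])
    y = np.empty(L)
    for t in range(L):
        h = at(Dbar, t) * h + at(Ebar, t) * x[t]
        y[t] = at(F, t) @ h
    return y


def ssm_conv_kernel(disc: DiscreteSSM, F: np.ndarray, M: int) -> np.ndarray:
    """Global-convolution kernel K̄ = (F Ē, F D̄ Ē, …, F D̄^{M−1} Ē)."""
    if M < 1:
        raise ValueError("kernel length M must be >= 1")
    Dbar = np.atleast_1d(np.asarray(disc.Dbar, dtype=float))
    Ebar = np.atleast_1d(np.asarray(disc.Ebar, dtype=float))
    F = np.atleast_1d(np.asarray(F, dtype=float))
    if Dbar.ndim != 1:
        raise ValueError("ssm_conv_kernel needs time-invariant parameters")
    kernel = np.empty(M)
    power = Ebar.copy()
    for m in range(M):
        kernel[m] = F @ power
        power = Dbar * power
    return kernel


def ssm_conv_apply(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution y_t = Σ_m K̄_m x_{t−m} (zero-padded left)."""
    x = np.asarray(x, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    return np.convolve(x, kernel)[: x.shape[0]]


# ---------------------------------------------------------------------------
# Bidirectional selective-scan (Mamba) block
# ---------------------------------------------------------------------------

class BiMamba:
    """Bidirectional Mamba block over a token sequence (L, C).

    The input is linearly projected to a feature path x and a gate path z
    (inner width = expand · C).  Per direction o ∈ {forward, backward}: a
    causal depthwise convolution + SiLU gives x'_o; linear projections of
    x'_o produce the per-timestep timescale Δ_o (softplus, so Δ > 0) and
    the input/output maps B_o, C_o; the diagonal state matrix A_o is
    discretized per timestep by zero-order hold and the selective scan is
    run; the scan output is gated by SiLU(z).  The backward direction
    runs the same algorithm on the reversed sequence and re-reverses its
    output.  The two direction outputs are summed and projected back to
    width C.

    A is parameterized as −exp(A_log) (negative real diagonal, the
    standard stable initialization −1…−N_s per channel).
    """

    DIRECTIONS = ("fwd", "bwd")

    def __init__(self, dim: int, d_state: int = 16, conv_width: int = 4,
                 expand: int = 2, rng: np.random.Generator | None = None,
                 tie_directions: bool = False, prefix: str = "bimamba"):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.dim = dim
        self.d_state = d_state
        self.conv_width = conv_width
        self.d_inner = expand * dim
        self.tie_directions = tie_directions
        self.prefix = prefix
        di, ns = self.d_inner, d_state

        def param(shape, scale):
            return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

        p = {}
        p["in_w"] = param((dim, 2 * di), 1.0 / np.sqrt(dim))
        p["in_b"] = Tensor(np.zeros(2 * di), requires_grad=True)
        dirs = ("fwd",) if tie_directions else self.DIRECTIONS
        for o in dirs:
            p[f"{o}_conv_w"] = param((di, conv_width), 1.0 / np.sqrt(conv_width))
            p[f"{o}_conv_b"] = Tensor(np.zeros(di), requires_grad=True)
            p[f"{o}_proj_w"] = param((di, di + 2 * ns), 1.0 / np.sqrt(di))
            # bias chosen so softplus(delta) starts near 0.5
            bias = np.zeros(di + 2 * ns)
            bias[:di] = np.log(np.expm1(0.5))
            p[f"{o}_proj_b"] = Tensor(bias, requires_grad=True)
            p[f"{o}_A_log"] = Tensor(
                np.log(np.tile(np.arange(1.0, ns + 1.0), (di, 1))),
                requires_grad=True)
        p["out_w"] = param((di, dim), 1.0 / np.sqrt(di))
        p["out_b"] = Tensor(np.zeros(dim), requires_grad=True)
        self.params = p

    def parameters(self) -> dict:
        return {f"{self.prefix}.{k}": v for k, v in self.params.items()}

    def _dir_params(self, o: str):
        key = "fwd" if self.tie_directions else o
        p = self.params
        return (p[f"{key}_conv_w"], p[f"{key}_conv_b"], p[f"{key}_proj_w"],
                p[f"{key}_proj_b"], p[f"{key}_A_log"])

    def _direction(self, x: Tensor, z: Tensor, o: str) -> Tensor:
        conv_w, conv_b, proj_w, proj_b, A_log = self._dir_params(o)
        xd = x.flip0() if o == "bwd" else x
        xc = (depthwise_conv1d(xd, conv_w, mode="causal") + conv_b).silu()
        proj = xc @ proj_w + proj_b
        di, ns = self.d_inner, self.d_state
        delta = proj[:, :di].softplus()
        B = proj[:, di:di + ns]
        C = proj[:, di + ns:]
        A = -A_log.exp()
        y = selective_scan(xc, delta, A, B, C)
        if o == "bwd":
            y = y.flip0()
        return y * z.silu()

    def forward(self, tokens: Tensor, return_directions: bool = False):
        if not np.all(np.isfinite(tokens.data)):
            raise ValueError("BiMamba input contains non-finite values")
        xz = tokens @ self.params["in_w"] + self.params["in_b"]
        x, z = xz[:, :self.d_inner], xz[:, self.d_inner:]
        y_f = self._direction(x, z, "fwd")
        y_b = self._direction(x, z, "bwd")
        out = (y_f + y_b) @ self.params["out_w"] + self.params["out_b"]
        if return_directions:
            return out, (y_f, y_b)
        return out

    __call__ = forward


def bimamba_reference(block: BiMamba, tokens: np.ndarray) -> np.ndarray:
    """Naive per-timestep recurrence oracle for `BiMamba.forward`.

    Re-implements the block with explicit python loops over timesteps,
    channels and directions, using `zoh_discretize` + `ssm_scan` per
    channel.  Used only in tests.
    """
    p = {k: v.data for k, v in block.params.items()}
    di, ns = block.d_inner, block.d_state
    xz = tokens @ p["in_w"] + p["in_b"]
    x, z = xz[:, :di], xz[:, di:]
    sil = lambda a: a / (1.0 + np.exp(-a))
    outs = []
    for o in BiMamba.DIRECTIONS:
        key = "fwd" if block.tie_directions else o
        xd = x[::-1] if o == "bwd" else x
        L = xd.shape[0]
        w, b = p[f"{key}_conv_w"], p[f"{key}_conv_b"]
        M = w.shape[1]
        xpad = np.pad(xd, ((M - 1, 0), (0, 0)))
        xc = np.zeros_like(xd)
        for j in range(M):
            xc += xpad[j:j + L] * w[:, j]
        xc = sil(xc + b)
        proj = xc @ p[f"{key}_proj_w"] + p[f"{key}_proj_b"]
        delta = np.logaddexp(0.0, proj[:, :di])
        B, C = proj[:, di:di + ns], proj[:, di + ns:]
        A = -np.exp(p[f"{key}_A_log"])
        y = np.zeros((L, di))
        for c in range(di):
            disc = zoh_discretize(
                SSMParams(D=A[c], E=np.ones(ns), F=np.ones(ns),
                          delta=delta[:, c]))
            # selective case: Ē_t scales B_t; output map is C_t
            h = np.zeros(ns)
            for t in range(L):
                h = disc.Dbar[t] * h + disc.Ebar[t] * B[t] * xc[t, c]
                y[t, c] = C[t] @ h
        if o == "bwd":
            y = y[::-1]
        outs.append(y * sil(z))
    return (outs[0] + outs[1]) @ p["out_w"] + p["out_b"]
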