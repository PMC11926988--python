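"""Convolutional-Mamba token mixer.

Each modality's token sequence (patch or pathway embeddings, shape L×C)
is split along channels; one half goes through a bidirectional selective
state-space block (global, order-sensitive mixing), the other through an
input-dependent depthwise convolution (local, input-adaptive mixing);
the halves are re-concatenated and passed through a squeezed token
enhancer (depthwise conv + pointwise bottleneck + residual).

The upstream formulation uses 2-D feature maps; token bags here are 1-D,
so the token axis plays the spatial role: depthwise convolutions are
width-M (IDConv) / width-3 (STE) 1-D convs with symmetric zero padding,
and the adaptive pooling compresses the token axis to M taps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, depthwise_conv1d
from .ssm import BiMamba


@dataclass
class MixerConfig:
    """Hyperparameters of one mixer block.

    channels: token embedding width C (must be even — it is split in two).
    attention_groups: number A of softmax groups in IDConv.
    kernel_size: depthwise tap count M (odd).
    reduction: bottleneck ratio r of the IDConv kernel generator.
    ste_reduction: bottleneck ratio of the squeezed token enhancer.
    """

    channels: int
    attention_groups: int = 2
    kernel_size: int = 3
    reduction: int = 4
    ste_reduction: int = 4
    d_state: int = 16
    conv_width: int = 4
    expand: int = 2
    use_bimamba: bool = True
    use_idconv: bool = True
    use_ste: bool = True

    def __post_init__(self):
        if self.channels % 2:
            raise ValueError("channel count must be even (split in halves)")
        if self.attention_groups < 1:
            raise ValueError("attention_groups must be >= 1")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.channels % self.reduction:
            raise ValueError("reduction must divide channels")


def channel_split(F: Tensor) -> tuple:
    """Split (L, C) into first/last C/2 channels; concat inverts it."""
    C = F.shape[1]
    if C % 2:
        raise ValueError("channel_split needs an even channel count")
    return F[:, : C // 2], F[:, C // 2:]


def adaptive_pool_matrix(L: int, M: int) -> np.ndarray:
    """(M, L) averaging matrix of 1-D adaptive average pooling L → M."""
    P = np.zeros((M, L))
    for i in range(M):
        lo = (i * L) // M
        hi = -(-((i + 1) * L) // M)  # ceil
        P[i, lo:hi] = 1.0 / (hi - lo)
    return P


class IDConv:
    """Input-dependent depthwise convolution over the token axis.

    The token sequence is adaptively average-pooled to M summary taps,
    passed through a pointwise bottleneck C → C/r → A·C producing group
    logits G' of shape (A, C, M); a softmax across the A groups (per
    channel and tap) yields weights G; the effective per-channel kernel
    is W = Σ_j Q_j ⊙ G_j over the learnable tap bank Q (A, C, M).  The
    sequence is then convolved depthwise with W (same-length output).
    """

    def __init__(self, channels: int, attention_groups: int = 2,
                 kernel_size: int = 3, reduction: int = 4,
                 rng: np.random.Generator | None = None,
                 prefix: str = "idconv"):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.C = channels
        self.A = attention_groups
        self.M = kernel_size
        self.prefix = prefix
        cr = max(1, channels // reduction)
        self.params = {
            "w1": Tensor(rng.normal(0, 1 / np.sqrt(channels), (channels, cr)),
                         requires_grad=True),
            "b1": Tensor(np.zeros(cr), requires_grad=True),
            "w2": Tensor(rng.normal(0, 1 / np.sqrt(cr),
                                    (cr, self.A * channels)),
                         requires_grad=True),
            "b2": Tensor(np.zeros(self.A * channels), requires_grad=True),
            "Q": Tensor(rng.normal(0, 0.5, (self.A, channels, self.M)),
                        requires_grad=True),
        }

    def parameters(self) -> dict:
        return {f"{self.prefix}.{k}": v for k, v in self.params.items()}

    def weights(self, F2: Tensor) -> Tensor:
        """Generate the input-dependent per-channel kernel W (C, M)."""
        L = F2.shape[0]
        pool = Tensor(adaptive_pool_matrix(L, self.M))
        P = pool @ F2                                   # (M, C)
        h = P @ self.params["w1"] + self.params["b1"]   # (M, C/r)
        logits = h @ self.params["w2"] + self.params["b2"]  # (M, A*C)
        G = logits.T.reshape(self.A, self.C, self.M).softmax(axis=0)
        return (self.params["Q"] * G).sum(axis=0)       # (C, M)

    def __call__(self, F2: Tensor) -> Tensor:
        return depthwise_conv1d(F2, self.weights(F2), mode="same")


class STE:
    """Squeezed token enhancer: DWConv3 → C→C/r → C/r→C, plus residual."""

    def __init__(self, channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None, prefix: str = "ste"):
        rng = rng if rng is not None else np.random.default_rng(0)
        cr = max(1, channels // reduction)
        taps = np.zeros((channels, 3))
        taps[:, 1] = 1.0  # start near identity
        self.params = {
            "dw": Tensor(taps + rng.normal(0, 0.05, (channels, 3)),
                         requires_grad=True),
            "w1": Tensor(rng.normal(0, 1 / np.sqrt(channels), (channels, cr)),
                         requires_grad=True),
            "b1": Tensor(np.zeros(cr), requires_grad=True),
            "w2": Tensor(rng.normal(0, 1 / np.sqrt(cr), (cr, channels)),
                         requires_grad=True),
            "b2": Tensor(np.zeros(channels), requires_grad=True),
        }
        self.prefix = prefix

    def parameters(self) -> dict:
        return {f"{self.prefix}.{k}": v for k, v in self.params.items()}

    def __call__(self, Fp: Tensor) -> Tensor:
        x = depthwise_conv1d(Fp, self.params["dw"], mode="same")
        x = x @ self.params["w1"] + self.params["b1"]
        x = x @ self.params["w2"] + self.params["b2"]
        return x + Fp


class ConvMambaMixer:
    """Split → (BiMamba ∥ IDConv) → concat → STE, with ablation toggles.

    Disabled stages become identity maps, so with every toggle off the
    mixer is the identity.
    """

    def __init__(self, config: MixerConfig,
                 rng: np.random.Generator | None = None,
                 prefix: str = "mixer"):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        self.prefix = prefix
        half = config.channels // 2
        self.bimamba = BiMamba(half, d_state=config.d_state,
                               conv_width=config.conv_width,
                               expand=config.expand, rng=rng,
                               prefix=f"{prefix}.bimamba")
        self.idconv = IDConv(half, config.attention_groups,
                             config.kernel_size, config.reduction, rng=rng,
                             prefix=f"{prefix}.idconv")
        self.ste = STE(config.channels, config.ste_reduction, rng=rng,
                       prefix=f"{prefix}.ste")

    def parameters(self) -> dict:
        out = {}
        out.update(self.bimamba.parameters())
        out.update(self.idconv.parameters())
        out.update(self.ste.parameters())
        return out

    def __call__(self, F: Tensor) -> Tensor:
        cfg = self.config
        F1, F2 = channel_split(F)
        y1 = self.bimamba(F1) if cfg.use_bimamba else F1
        y2 = self.idconv(F2) if cfg.use_idconv else F2
        Fp = concat([y1, y2], axis=1)
        return self.ste(Fp) if cfg.use_ste else Fp
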