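"""The dual-stream cross-modal survival network.

Pipeline per patient (bags are ragged; one patient per forward pass):

1. project the pathology bag (N×768) and genomic bag (K×256) to d_model;
2. a pre-cross token mixer per modality gives intra-modal sequences
   H (N×d) and G (K×d);
3. co-attention exchanges content across modalities: the pathology-
   guided direction yields an N×d sequence whose content comes from
   genomics (pooled: ĥ, the cross-modal counterpart of h), the genomic-
   guided direction a K×d sequence from pathology (pooled: ĝ);
4. a post-cross mixer refines each cross-modal sequence;
5. global average pooling over tokens yields h, ĥ, g, ĝ (all d_model);
6. per-interval hazards = sigmoid(MLP(h + ĥ + g + ĝ)), the survival
   curve is S(j) = Π_{u≤j}(1 − h_u), and the scalar risk is −Σ_j S(j)
   (monotone increasing in every hazard).

Every stage can be ablated through the RunConfig toggles; disabled
stages are identity maps (or zeros, for the cross-modal branch).

Token sequences are layer-normalized (per token, over channels) after
the input projections and after each mixer stage: the mixers themselves
are not residual blocks, and without normalization token representations
can drift to arbitrary scale during training, destabilizing the
alignment loss.  The fused vector is deliberately left unnormalized —
the pooled vectors are already means of normalized tokens, and their
per-patient amplitude is informative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .coattention import CoAttentionBlock
from .io_bags import PatientRecord, RunConfig
from .mixer import ConvMambaMixer, MixerConfig


@dataclass
class Representations:
    """Pooled intra-modal (h, g) and cross-modal (ĥ, ĝ) vectors."""

    h: np.ndarray
    g: np.ndarray
    h_hat: np.ndarray
    g_hat: np.ndarray


@dataclass
class SurvivalPrediction:
    """Per-interval hazards, survival curve, scalar risk and the pooled reps."""

    hazards: np.ndarray
    survival: np.ndarray
    risk: float
    reps: Representations


def survival_function(hazards: np.ndarray) -> np.ndarray:
    """S(j) = Π_{u≤j} (1 − hazard_u) for per-interval hazards in [0, 1]."""
    hazards = np.asarray(hazards, dtype=float)
    if np.any((hazards < 0) | (hazards > 1)) or not np.all(np.isfinite(hazards)):
        raise ValueError("hazards must lie in [0, 1]")
    return np.cumprod(1.0 - hazards)


def risk_score(survival: np.ndarray) -> float:
    """Scalar risk −Σ_j S(j); higher = shorter expected survival."""
    survival = np.asarray(survival, dtype=float)
    return float(-survival.sum())


def _layer_norm(x: Tensor, gain: Tensor, bias: Tensor,
                eps: float = 1e-5) -> Tensor:
    """Normalize over the last (channel) axis, with learnable gain/bias."""
    m = x.mean(axis=-1, keepdims=True)
    centered = x - m
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gain + bias


class SurvivalFusionNet:
    """Full network; parameters live in a flat name → Tensor dict.

    Dropout (rate ``config.dropout``) is applied to the projected token
    sequences and the fused vector during training only; call
    :meth:`train_mode` with a seeded generator before training and
    :meth:`eval_mode` (the initial state) for prediction.
    """

    def __init__(self, config: RunConfig, rng: np.random.Generator | None = None):
        config.validate()
        self.config = config
        self.training = False
        self._drop_rng = None
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        d = config.d_model

        def linear(n_in, n_out, name, zero=False):
            scale = 0.0 if zero else 1.0 / np.sqrt(n_in)
            self._params[f"{name}.w"] = Tensor(
                rng.normal(0, scale, (n_in, n_out)) if not zero
                else np.zeros((n_in, n_out)), requires_grad=True)
            self._params[f"{name}.b"] = Tensor(np.zeros(n_out),
                                               requires_grad=True)

        self._params = {}
        linear(config.d_pathology, d, "proj_p")
        linear(config.d_genomic, d, "proj_g")

        mix_cfg = dict(attention_groups=config.attention_groups,
                       kernel_size=config.kernel_size,
                       reduction=config.reduction,
                       ste_reduction=config.ste_reduction,
                       d_state=config.d_state, conv_width=config.conv_width,
                       expand=config.expand, use_idconv=config.use_idconv,
                       use_bimamba=config.use_bimamba, use_ste=config.use_ste)
        self.mixer_p1 = ConvMambaMixer(MixerConfig(d, **mix_cfg), rng,
                                       prefix="mixer_p1")
        self.mixer_g1 = ConvMambaMixer(MixerConfig(d, **mix_cfg), rng,
                                       prefix="mixer_g1")
        self.coattn = CoAttentionBlock(d, rng)
        self.mixer_p2 = ConvMambaMixer(MixerConfig(d, **mix_cfg), rng,
                                       prefix="mixer_p2")
        self.mixer_g2 = ConvMambaMixer(MixerConfig(d, **mix_cfg), rng,
                                       prefix="mixer_g2")
        for m in (self.mixer_p1, self.mixer_g1, self.mixer_p2, self.mixer_g2):
            self._params.update(m.parameters())
        self._params.update(self.coattn.parameters())

        for site in ("ln_p0", "ln_g0", "ln_p1", "ln_g1", "ln_ph", "ln_gh"):
            self._params[f"{site}.gain"] = Tensor(np.ones(d),
                                                  requires_grad=True)
            self._params[f"{site}.bias"] = Tensor(np.zeros(d),
                                                  requires_grad=True)

        linear(d, d, "head_hidden")
        # zero-init output layer: hazards start at sigmoid(bias) and risk
        # scores start constant, so early ranking is driven entirely by
        # learned signal rather than random projections
        linear(d, config.t_bins, "head_out", zero=True)

    # -- parameter access --------------------------------------------------

    def parameters(self) -> dict:
        return self._params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self._params.values()))

    def _lin(self, x: Tensor, name: str) -> Tensor:
        return x @ self._params[f"{name}.w"] + self._params[f"{name}.b"]

    def _ln(self, x: Tensor, site: str) -> Tensor:
        return _layer_norm(x, self._params[f"{site}.gain"],
                           self._params[f"{site}.bias"])

    def train_mode(self, rng: np.random.Generator):
        self.training = True
        self._drop_rng = rng
        return self

    def eval_mode(self):
        self.training = False
        self._drop_rng = None
        return self

    def _dropout(self, x: Tensor) -> Tensor:
        p = self.config.dropout
        if not self.training or p <= 0.0:
            return x
        keep = (self._drop_rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(keep)

    # -- forward ------------------------------------------------------------

    @staticmethod
    def _check(stage: str, x: Tensor) -> Tensor:
        if not np.all(np.isfinite(x.data)):
            raise FloatingPointError(f"non-finite activations at stage {stage!r}")
        return x

    def forward_tensors(self, pathology: np.ndarray, genomic: np.ndarray) -> dict:
        """Run the pipeline; returns Tensors (for the training graph)."""
        cfg = self.config
        P = Tensor(np.asarray(pathology, dtype=float))
        G = Tensor(np.asarray(genomic, dtype=float))
        self._check("input", P)
        self._check("input", G)

        H = self._check("project_pathology",
                        self._dropout(self._ln(self._lin(P, "proj_p"),
                                               "ln_p0")))
        Gt = self._check("project_genomic",
                         self._dropout(self._ln(self._lin(G, "proj_g"),
                                                "ln_g0")))
        if cfg.use_mixer_pre:
            H = self._check("pre_mixer_pathology",
                            self._ln(self.mixer_p1(H), "ln_p1"))
            Gt = self._check("pre_mixer_genomic",
                             self._ln(self.mixer_g1(Gt), "ln_g1"))

        zeros_vec = Tensor(np.zeros(cfg.d_model))
        if cfg.use_cross:
            h_hat_seq = self.coattn.pca(H, Gt) if cfg.use_pca else None
            g_hat_seq = self.coattn.gca(Gt, H) if cfg.use_gca else None
            if cfg.swap_cross_roles:
                h_hat_seq, g_hat_seq = g_hat_seq, h_hat_seq
            if h_hat_seq is not None:
                if cfg.use_mixer_post:
                    h_hat_seq = self._check(
                        "post_mixer_pathology",
                        self._ln(self.mixer_p2(h_hat_seq), "ln_ph"))
                h_hat = h_hat_seq.mean(axis=0)
            else:
                h_hat = zeros_vec
            if g_hat_seq is not None:
                if cfg.use_mixer_post:
                    g_hat_seq = self._check(
                        "post_mixer_genomic",
                        self._ln(self.mixer_g2(g_hat_seq), "ln_gh"))
                g_hat = g_hat_seq.mean(axis=0)
            else:
                g_hat = zeros_vec
        else:
            h_hat = zeros_vec
            g_hat = zeros_vec

        h = H.mean(axis=0)
        g = Gt.mean(axis=0)

        # no normalization here: the pooled vectors are already O(1) (means
        # of layer-normalized tokens) and per-patient amplitude carries risk
        # information that a LayerNorm would cancel
        fused = self._dropout(h + h_hat + g + g_hat)
        hidden = self._lin(fused, "head_hidden").relu()
        hazards = self._check("head",
                              self._lin(hidden, "head_out").sigmoid())
        return {"hazards": hazards, "h": h, "g": g,
                "h_hat": h_hat, "g_hat": g_hat}

    def predict(self, record_or_bags) -> SurvivalPrediction:
        """Forward pass returning plain-numpy survival quantities."""
        if isinstance(record_or_bags, PatientRecord):
            P, G = record_or_bags.pathology, record_or_bags.genomic
        else:
            P, G = record_or_bags
        out = self.forward_tensors(P, G)
        hazards = out["hazards"].data.copy()
        surv = survival_function(hazards)
        return SurvivalPrediction(
            hazards=hazards, survival=surv, risk=risk_score(surv),
            reps=Representations(h=out["h"].data.copy(),
                                 g=out["g"].data.copy(),
                                 h_hat=out["h_hat"].data.copy(),
                                 g_hat=out["g_hat"].data.copy()))

    # -- checkpointing -------------------------------------------------------

    CHECKPOINT_VERSION = 1

    def save(self, path):
        path = Path(path)
        cfg = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
               for k, v in vars(self.config).items()}
        arrays = {k.replace("/", "|"): v.data for k, v in self._params.items()}
        np.savez(path, __config__=json.dumps(
            {"version": self.CHECKPOINT_VERSION, "config": cfg}), **arrays)
        return path

    @classmethod
    def load(cls, path) -> "SurvivalFusionNet":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__config__"]))
            if meta["version"] != cls.CHECKPOINT_VERSION:
                raise ValueError(
                    f"checkpoint version {meta['version']} not supported")
            model = cls(RunConfig(**meta["config"]))
            for k, p in model._params.items():
                p.data = np.asarray(data[k.replace("/", "|")], dtype=float)
        return model


def build_model(config: RunConfig, rng: np.random.Generator | None = None
                ) -> SurvivalFusionNet:
    """Construct the network; deterministic given config.seed (or rng)."""
    return SurvivalFusionNet(config, rng=rng)
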