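"""Cross-modal co-attention between pathology and genomic token bags.

Two mirrored single-head scaled dot-product attentions bridge the
modalities: pathology-guided co-attention (queries from pathology
tokens, keys/values from genomic tokens) and genomic-guided
co-attention (the mirror image).  Each output row is a convex
combination of the attended modality's value rows, so the module is
permutation-invariant over the attended bag and permutation-equivariant
over the querying bag.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


def scaled_coattention(queries_in: Tensor, keyvals_in: Tensor,
                       Wq: Tensor, Wk: Tensor, Wv: Tensor) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V with Q from one bag, K/V from the other."""
    if queries_in.shape[1] != Wq.shape[0] or keyvals_in.shape[1] != Wk.shape[0]:
        raise ValueError("token dimension does not match projection matrices")
    Q = queries_in @ Wq
    K = keyvals_in @ Wk
    V = keyvals_in @ Wv
    scale = 1.0 / np.sqrt(Wk.shape[1])
    attn = ((Q @ K.T) * scale).softmax(axis=-1)
    return attn @ V


class CoAttentionBlock:
    """Holds both projection triples; `pca` and `gca` are mirror images."""

    def __init__(self, dim: int, rng: np.random.Generator | None = None,
                 prefix: str = "coattn"):
        rng = rng if rng is not None else np.random.default_rng(0)
        scale = 1.0 / np.sqrt(dim)
        names = ["p_q", "g_k", "g_v", "g_q", "p_k", "p_v"]
        self.params = {
            n: Tensor(rng.normal(0, scale, (dim, dim)), requires_grad=True)
            for n in names
        }
        self.prefix = prefix

    def parameters(self) -> dict:
        return {f"{self.prefix}.{k}": v for k, v in self.params.items()}

    def pca(self, path_tokens: Tensor, gen_tokens: Tensor) -> Tensor:
        """Pathology-guided: pathology queries aggregate genomic content."""
        p = self.params
        return scaled_coattention(path_tokens, gen_tokens,
                                  p["p_q"], p["g_k"], p["g_v"])

    def gca(self, gen_tokens: Tensor, path_tokens: Tensor) -> Tensor:
        """Genomic-guided: genomic queries aggregate pathology content."""
        p = self.params
        return scaled_coattention(gen_tokens, path_tokens,
                                  p["g_q"], p["p_k"], p["p_v"])
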