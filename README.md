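# dualsurv

Discrete-time cancer survival prediction from two ragged "bags" per
patient: pathology patch embeddings extracted from a whole-slide image
(N × 768) and genomic pathway embeddings (K × 256).  The package is for
computational-pathology researchers who want a fully testable,
CPU-trainable reference implementation of a dual-stream multimodal
fusion network — plus the survival statistics and a synthetic cohort
simulator so every component can be verified without any clinical data.

## The model

Each modality's token bag is mixed by a **convolutional Mamba token
mixer**: the channels are split in half, one half passes through a
bidirectional selective state-space (Mamba) block

    h_t = Ā_t h_{t−1} + B̄_t x_t,   y_t = C_t h_t,
    Ā = exp(ΔA),   B̄ = (ΔA)^{-1}(exp(ΔA) − I)·ΔB        (zero-order hold)

with input-dependent Δ, B, C, and the other half through an
input-dependent depthwise convolution whose per-channel kernel is a
softmax-weighted mixture of a learnable tap bank; a squeezed token
enhancer (depthwise conv + pointwise bottleneck + residual) recombines
them.  Two co-attention directions bridge the modalities — pathology
queries aggregating genomic content and vice versa — giving pooled
intra-modal representations h, g and cross-modal reconstructions ĥ, ĝ.
The survival head predicts per-interval hazards

    T_1, …, T_t = sigmoid(MLP(h + ĥ + g + ĝ)),
    S(t) = Π_{u≤t} (1 − T_u),     risk = −Σ_t S(t),

trained with the censored discrete-time negative log-likelihood plus an
L1 representation-alignment penalty, L_total = L_sur + α·L_sim with
α = 0.03 by default.  Censoring convention throughout: `censor = 0`
means death observed, `censor = 1` means censored at last follow-up.

The network and its training loop run on a small reverse-mode autodiff
engine over numpy (`dualsurv.autodiff`) with hand-written backward
passes for the selective scan and depthwise convolutions, checked
against finite differences in the test suite.

## Worked example

```bash
dualsurv simulate --n-patients 300 --signal-strength 3 --censor-rate 0.3 \
    --seed 11 --out cohort.h5 --truth-out truth.csv
dualsurv crossval --cohort cohort.h5 --report report.csv
```

The simulator plants a latent per-patient risk r ~ N(0,1) in both
modalities (as the prevalence of "signal" patches in the pathology bag
and as mean shifts of informative pathways in the genomic bag) and
draws event times with hazard λ0·e^{β·r}, so r is the Bayes-optimal
risk ranking and the concordance of the trained model can be compared
with the oracle concordance of r itself.  On the cohort above
(`RunConfig(d_model=32, epochs=10)`, 5-fold cross-validation) this
prints per-fold validation concordances between 0.69 and 0.79 and

    c-index 0.741 ± 0.037 over 5 folds

against an oracle concordance of 0.889 for the latent risks — i.e. a
10-epoch desk-scale run recovers most of the planted ranking signal.  The
`evaluate` command additionally splits patients at the median predicted
risk and reports the Kaplan–Meier curves and log-rank test for the two
groups.

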