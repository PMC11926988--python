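"""Training loop, stratified sampling, k-fold cross-validation, ablations.

Bags are ragged, so "batch size 32" is implemented as gradient
accumulation: one patient per forward/backward pass, parameters updated
after every 32 accumulated patients.  Each epoch draws the patient
order as a weighted permutation — without replacement, with inclusion
order weighted by inverse 8-stratum frequency (4 time bins × 2 censor
states) so rare strata lead each epoch — and subsamples each pathology
bag to at most ``patches_per_wsi`` patches.  Everything is seeded;
fixed seed + single thread reproduces runs bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Adam
from .io_bags import Cohort, RunConfig
from .losses import alignment_loss, nll_survival_loss
from .model import SurvivalFusionNet, build_model
from .stats import (assign_bins, concordance_index, discretize_times,
                    stratum_weights)

log = logging.getLogger("dualsurv")


@dataclass
class TrainHistory:
    """Per-epoch mean loss components (l_total = l_sur + α·l_sim exactly)."""

    epochs: list = field(default_factory=list)

    def append(self, l_sur: float, l_sim: float, alpha: float):
        self.epochs.append({"l_sur": l_sur, "l_sim": l_sim,
                            "l_total": l_sur + alpha * l_sim})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


@dataclass
class FoldResult:
    fold: int
    c_index: float
    history: TrainHistory
    seed: int
    bin_edges: np.ndarray


@dataclass
class CVResult:
    folds: list
    mean: float
    std: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"fold": f.fold, "c_index": f.c_index} for f in self.folds]
        rows.append({"fold": "mean", "c_index": self.mean})
        rows.append({"fold": "std", "c_index": self.std})
        return pd.DataFrame(rows)


def _effective_alpha(config: RunConfig) -> float:
    if not config.use_alignment or config.alignment_mode == "none":
        return 0.0
    return config.alpha


def train_model(cohort: Cohort, config: RunConfig,
                model: SurvivalFusionNet | None = None):
    """Train on a labeled cohort; returns (model, TrainHistory)."""
    config.validate()
    labels = cohort.labels()          # raises if bin labels are unset
    censors = cohort.censors()
    if model is None:
        model = build_model(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    model.train_mode(np.random.default_rng(
        np.random.SeedSequence([config.seed, 15485863])))
    opt = Adam(model.parameters(), lr=config.learning_rate)
    weights = stratum_weights(np.clip(labels, 1, 4), censors)
    probs = weights / weights.sum()
    alpha = _effective_alpha(config)
    n = len(cohort)
    history = TrainHistory()

    for epoch in range(config.epochs):
        order = rng.choice(n, size=n, replace=False, p=probs)
        sur_sum = sim_sum = 0.0
        pending = 0
        opt.zero_grad()
        for idx in order:
            rec = cohort.records[idx]
            bag = rec.pathology
            if bag.shape[0] > config.patches_per_wsi:
                keep = rng.choice(bag.shape[0], size=config.patches_per_wsi,
                                  replace=False)
                bag = bag[keep]
            out = model.forward_tensors(bag, rec.genomic)
            l_sur = nll_survival_loss(out["hazards"].reshape(1, -1),
                                      [labels[idx]], [censors[idx]],
                                      eps=config.hazard_eps)
            l_sim = alignment_loss(out["h"], out["h_hat"], out["g"],
                                   out["g_hat"], mode=config.alignment_mode,
                                   metric=config.sim_metric)
            total = l_sur + alpha * l_sim
            (total / float(config.effective_batch)).backward()
            sur_sum += float(l_sur.data)
            sim_sum += float(l_sim.data)
            pending += 1
            if pending == config.effective_batch:
                opt.step()
                opt.zero_grad()
                pending = 0
        if pending:
            # rescale the partial accumulation to a proper mean
            for p in model.parameters().values():
                if p.grad is not None:
                    p.grad *= config.effective_batch / pending
            opt.step()
            opt.zero_grad()
        history.append(sur_sum / n, sim_sum / n, alpha)
        ep = history.epochs[-1]
        log.info("epoch %d/%d l_sur=%.4f l_sim=%.4f l_total=%.4f",
                 epoch + 1, config.epochs, ep["l_sur"], ep["l_sim"],
                 ep["l_total"])
    model.eval_mode()
    return model, history


def predict_risks(model: SurvivalFusionNet, cohort: Cohort) -> np.ndarray:
    """Scalar risk score per patient (full bags, no subsampling)."""
    return np.array([model.predict(r).risk for r in cohort.records])


def kfold_split(n: int, k: int, seed: int):
    """Seeded patient-level k-fold partition; folds are disjoint, union = all."""
    if k < 2 or k > n:
        raise ValueError("need 2 <= folds <= n")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def _subset(cohort: Cohort, idx) -> Cohort:
    return Cohort(records=[cohort.records[i] for i in idx],
                  t_bins=cohort.t_bins)


def cross_validate(cohort: Cohort, config: RunConfig) -> CVResult:
    """Seeded k-fold CV; discretization edges come from training folds only."""
    config.validate()
    folds = kfold_split(len(cohort), config.folds, config.seed)
    results = []
    for f, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(cohort)), val_idx)
        train_co = _subset(cohort, train_idx)
        val_co = _subset(cohort, val_idx)
        edges, train_labels = discretize_times(
            train_co.times(), train_co.censors(), n_bins=config.t_bins)
        for rec, lab in zip(train_co.records, train_labels):
            rec.bin_label = int(lab)
        for rec, lab in zip(val_co.records,
                            assign_bins(edges, val_co.times())):
            rec.bin_label = int(lab)
        fold_cfg = config.replace(seed=config.seed + f)
        model, history = train_model(train_co, fold_cfg)
        risks = predict_risks(model, val_co)
        ci = concordance_index(val_co.times(), val_co.censors(), risks)
        log.info("fold %d c_index=%.4f", f, ci)
        results.append(FoldResult(fold=f, c_index=ci, history=history,
                                  seed=fold_cfg.seed, bin_edges=edges))
    cis = np.array([r.c_index for r in results])
    return CVResult(folds=results, mean=float(cis.mean()),
                    std=float(cis.std(ddof=1)))


ABLATION_TOGGLES = {
    "no_alignment": {"use_alignment": False},
    "no_idconv": {"use_idconv": False},
    "no_bimamba": {"use_bimamba": False},
    "no_cross": {"use_cross": False},
    "no_pca": {"use_pca": False},
    "no_gca": {"use_gca": False},
    "no_ste": {"use_ste": False},
    "no_mixer_pre": {"use_mixer_pre": False},
    "no_mixer_post": {"use_mixer_post": False},
}


def run_ablation(cohort: Cohort, config: RunConfig, toggle_name: str):
    """Cross-validate the full model and one ablated wiring; return both."""
    if toggle_name not in ABLATION_TOGGLES:
        raise ValueError(
            f"unknown toggle {toggle_name!r}; valid: "
            f"{sorted(ABLATION_TOGGLES)}")
    full = cross_validate(cohort, config)
    ablated = cross_validate(cohort,
                             config.replace(**ABLATION_TOGGLES[toggle_name]))
    return {"full": full, toggle_name: ablated}
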