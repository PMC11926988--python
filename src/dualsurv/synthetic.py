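"""Synthetic multimodal survival cohorts with a known latent risk.

Each simulated patient carries a scalar latent risk r ~ N(0, 1) that is
expressed in both modalities and drives the event time:

* pathology bag — N ~ Uniform(patch_range) patches in R^768; a fraction
  sigmoid(β·r) of them are "signal" patches centered on a fixed unit
  direction, the rest are pure noise.  This emulates how a tumor's
  aggressiveness shows up as the prevalence of a morphological phenotype
  among WSI patches, not in every patch;
* genomic bag — K pathway vectors in R^256, with a subset of informative
  pathways mean-shifted by β·r along fixed unit directions;
* event time ~ Exponential(λ0 · exp(β·r)) (proportional hazards with
  log-hazard slope β, so r is the Bayes-optimal risk ranking and β = 0
  is an exact null); censoring time ~ Exponential(λc) with λc calibrated
  by Gauss–Hermite quadrature so that the expected censored fraction
  matches ``censor_rate``.  Observed time is the
  minimum; censor = 0 iff the event came first.

The latent risks are returned in a separate truth table and are never
written into the cohort container.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_bags import Cohort, D_GENOMIC, D_PATHOLOGY, PatientRecord


@dataclass
class SimParams:
    """Generator settings (defaults = the package's reference conditions)."""

    n_patients: int = 300
    patch_range: tuple = (16, 64)   # min/max patches N per pathology bag
    pathway_count: int = 24         # K pathway vectors per genomic bag
    d_pathology: int = D_PATHOLOGY
    d_genomic: int = D_GENOMIC
    signal_strength: float = 3.0    # β: latent-risk coupling to both modalities
    informative_pathway_count: int = 8
    baseline_rate: float = 0.02     # λ0, events/month at r = 0 (median ≈ 35 mo)
    censor_rate: float = 0.3        # target censored fraction in [0, 1)
    noise_sd: float = 1.0
    decorrelate: bool = False       # sever the genomic link (negative control)
    seed: int = 0

    def validate(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (1 <= self.patch_range[0] <= self.patch_range[1]):
            raise ValueError("patch_range must be 1 <= min <= max")
        if self.pathway_count < 1 or self.informative_pathway_count < 0:
            raise ValueError("pathway counts must be positive")
        if self.informative_pathway_count > self.pathway_count:
            raise ValueError("informative pathways cannot exceed pathway_count")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if self.baseline_rate <= 0 or self.noise_sd <= 0:
            raise ValueError("rates and noise_sd must be positive")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")
        return self


def _censoring_rate_for_target(lam0: float, beta: float,
                               target: float) -> float:
    """λc such that E_r[λc / (λc + λ0 e^{β·r})] = target, r ~ N(0,1)."""
    if target <= 0:
        return 0.0
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    weights = weights / weights.sum()

    def censored_fraction(lam_c):
        rates = lam0 * np.exp(beta * nodes)
        return float((weights * lam_c / (lam_c + rates)).sum())

    hi = lam0
    while censored_fraction(hi) < target:
        hi *= 4.0
    return brentq(lambda lc: censored_fraction(lc) - target,
                  1e-12 * lam0, hi, xtol=1e-12 * lam0)


def generate_cohort(params: SimParams):
    """Draw a cohort; returns (Cohort, truth table with the latent risks)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    beta = params.signal_strength
    sd = params.noise_sd

    # fixed signal directions, drawn once per cohort
    mu_path = rng.normal(size=params.d_pathology)
    mu_path /= np.linalg.norm(mu_path)
    informative = rng.choice(params.pathway_count,
                             size=params.informative_pathway_count,
                             replace=False)
    mu_gen = rng.normal(size=(params.informative_pathway_count,
                              params.d_genomic))
    mu_gen /= np.linalg.norm(mu_gen, axis=1, keepdims=True)

    lam_c = _censoring_rate_for_target(params.baseline_rate, beta,
                                       params.censor_rate)

    records, truth = [], []
    width = len(str(params.n_patients - 1))
    for i in range(params.n_patients):
        r = rng.standard_normal()
        r_gen = rng.standard_normal() if params.decorrelate else r

        n = int(rng.integers(params.patch_range[0], params.patch_range[1] + 1))
        signal_frac = 1.0 / (1.0 + np.exp(-beta * r))
        is_signal = rng.random(n) < signal_frac
        bag = rng.normal(0.0, sd, size=(n, params.d_pathology))
        bag[is_signal] += mu_path

        gen = rng.normal(0.0, sd, size=(params.pathway_count, params.d_genomic))
        gen[informative] += beta * r_gen * mu_gen

        event_t = rng.exponential(
            1.0 / (params.baseline_rate * np.exp(beta * r)))
        if lam_c > 0:
            censor_t = rng.exponential(1.0 / lam_c)
        else:
            censor_t = np.inf
        censored = int(censor_t < event_t)
        time = min(event_t, censor_t)
        time = max(time, 1e-3)  # strictly positive follow-up

        pid = f"synth-{i:0{width}d}"
        records.append(PatientRecord(
            patient_id=pid,
            pathology=bag.astype(np.float32),
            genomic=gen.astype(np.float32),
            time=float(time), censor=censored))
        truth.append((pid, r, signal_frac, event_t))

    cohort = Cohort(records=records).validate()
    truth_table = pd.DataFrame(
        truth, columns=["patient_id", "latent_risk", "signal_fraction",
                        "event_time"])
    return cohort, truth_table


def empirical_censor_rate(cohort: Cohort) -> float:
    """Fraction of records with censor = 1."""
    if len(cohort) < 1:
        raise ValueError("empty cohort")
    return float(np.mean([r.censor for r in cohort.records]))
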