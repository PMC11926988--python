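"""Cohort container and run configuration.

A patient is a quadruple (pathology bag, genomic bag, follow-up time,
censoring status): the pathology bag is an N×768 matrix of patch
embeddings from a whole-slide image, the genomic bag a K×256 matrix of
pathway embeddings.  Bags are ragged (N and K vary per patient) and are
stored without padding.

Censoring convention, used at every boundary of this package:
``censor = 0`` means the death was observed at ``time`` (months);
``censor = 1`` means the patient was alive at last follow-up.  Note this
is the opposite of the "event observed" flag some survival libraries
use.

On-disk layout (HDF5):
    /meta                attrs: layout_version, t_bins, bin_edges
    /patients/<id>/pathology   float32 (N, 768)
    /patients/<id>/genomic     float32 (K, 256)
    /patients/<id>             attrs: time_months, censor[, bin_label]
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

LAYOUT_VERSION = 1

D_PATHOLOGY = 768
D_GENOMIC = 256


class ValidationError(ValueError):
    """A record, cohort or config violates its invariants."""


@dataclass
class PatientRecord:
    """One patient: both bags, follow-up time (months) and censor flag."""

    patient_id: str
    pathology: np.ndarray  # (N, d_p) float32
    genomic: np.ndarray    # (K, d_g) float32
    time: float            # months, > 0
    censor: int            # 0 = death observed, 1 = censored
    bin_label: int | None = None  # discrete interval in 1..t_bins

    def validate(self, t_bins: int | None = None):
        self.pathology = np.asarray(self.pathology, dtype=np.float32)
        self.genomic = np.asarray(self.genomic, dtype=np.float32)
        if self.pathology.ndim != 2 or self.pathology.shape[0] < 1:
            raise ValidationError(
                f"{self.patient_id}: pathology bag must be a non-empty 2-D array")
        if self.genomic.ndim != 2 or self.genomic.shape[0] < 1:
            raise ValidationError(
                f"{self.patient_id}: genomic bag must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pathology)):
            raise ValidationError(f"{self.patient_id}: non-finite pathology values")
        if not np.all(np.isfinite(self.genomic)):
            raise ValidationError(f"{self.patient_id}: non-finite genomic values")
        if not (np.isfinite(self.time) and self.time > 0):
            raise ValidationError(f"{self.patient_id}: time must be > 0")
        if self.censor not in (0, 1):
            raise ValidationError(
                f"{self.patient_id}: censor must be 0 (death) or 1 (censored)")
        if self.bin_label is not None:
            if t_bins is not None and not (1 <= self.bin_label <= t_bins):
                raise ValidationError(
                    f"{self.patient_id}: bin_label {self.bin_label} outside "
                    f"1..{t_bins}")
        return self


@dataclass
class Cohort:
    """Ordered patient records plus the discretization of follow-up time."""

    records: list
    t_bins: int = 4
    bin_edges: np.ndarray | None = None  # ascending, length t_bins - 1

    def validate(self):
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient ids: {dup}")
        if self.t_bins < 2:
            raise ValidationError("t_bins must be >= 2")
        if self.bin_edges is not None:
            self.bin_edges = np.asarray(self.bin_edges, dtype=float)
            if self.bin_edges.shape != (self.t_bins - 1,):
                raise ValidationError("bin_edges must have length t_bins - 1")
            if np.any(np.diff(self.bin_edges) <= 0):
                raise ValidationError("bin_edges must be strictly ascending")
        for r in self.records:
            r.validate(self.t_bins)
        return self

    def __len__(self):
        return len(self.records)

    def times(self):
        return np.array([r.time for r in self.records])

    def censors(self):
        return np.array([r.censor for r in self.records], dtype=int)

    def labels(self):
        if any(r.bin_label is None for r in self.records):
            raise ValidationError("cohort has unset bin labels; discretize first")
        return np.array([r.bin_label for r in self.records], dtype=int)

    def to_table(self) -> pd.DataFrame:
        """Survival table export: patient_id, time_months, censor, bin_label."""
        return pd.DataFrame({
            "patient_id": [r.patient_id for r in self.records],
            "time_months": [r.time for r in self.records],
            "censor": [r.censor for r in self.records],
            "bin_label": [r.bin_label if r.bin_label is not None else -1
                          for r in self.records],
        })


def write_cohort(cohort: Cohort, path) -> Path:
    """Write a cohort to HDF5; round-trips bit-identically."""
    cohort.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["layout_version"] = LAYOUT_VERSION
        meta.attrs["t_bins"] = cohort.t_bins
        if cohort.bin_edges is not None:
            meta.attrs["bin_edges"] = np.asarray(cohort.bin_edges, dtype=float)
        patients = f.create_group("patients")
        for i, r in enumerate(cohort.records):
            g = patients.create_group(r.patient_id)
            g.attrs["order"] = i
            g.attrs["time_months"] = float(r.time)
            g.attrs["censor"] = int(r.censor)
            if r.bin_label is not None:
                g.attrs["bin_label"] = int(r.bin_label)
            g.create_dataset("pathology", data=r.pathology.astype(np.float32))
            g.create_dataset("genomic", data=r.genomic.astype(np.float32))
    return path


def read_cohort(path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`, validating on load."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "meta" not in f or "patients" not in f:
            raise ValidationError(f"{path}: not a cohort container")
        meta = f["meta"]
        version = int(meta.attrs.get("layout_version", -1))
        if version != LAYOUT_VERSION:
            raise ValidationError(
                f"{path}: layout version {version} != {LAYOUT_VERSION}")
        t_bins = int(meta.attrs["t_bins"])
        edges = meta.attrs.get("bin_edges")
        records = []
        groups = sorted(f["patients"].items(),
                        key=lambda kv: kv[1].attrs.get("order", 0))
        if not groups:
            raise ValidationError(f"{path}: no patients in container")
        for pid, g in groups:
            for mod in ("pathology", "genomic"):
                if mod not in g:
                    raise ValidationError(
                        f"patient {pid!r} is missing the /{mod} bag")
            records.append(PatientRecord(
                patient_id=pid,
                pathology=g["pathology"][()],
                genomic=g["genomic"][()],
                time=float(g.attrs["time_months"]),
                censor=int(g.attrs["censor"]),
                bin_label=(int(g.attrs["bin_label"])
                           if "bin_label" in g.attrs else None),
            ))
    cohort = Cohort(records=records, t_bins=t_bins,
                    bin_edges=None if edges is None else np.asarray(edges))
    return cohort.validate()


_TOGGLES = ("use_alignment", "use_cross", "use_pca", "use_gca", "use_idconv",
            "use_bimamba", "use_ste", "use_mixer_pre", "use_mixer_post")

_ALIGNMENT_MODES = ("all", "intra_only", "cross_only", "none")
_SIM_METRICS = ("l1", "mse", "kl")


@dataclass
class RunConfig:
    """Everything a training / evaluation run needs.

    Defaults follow the reference training protocol: alpha = 0.03
    alignment weight, Adam at 5e-4 for 30 epochs with an effective batch
    of 32 ragged bags, 4096 patches subsampled per slide per epoch, four
    discrete survival intervals, 5-fold cross-validation.
    """

    d_model: int = 256
    t_bins: int = 4
    alpha: float = 0.03
    learning_rate: float = 5e-4
    epochs: int = 30
    effective_batch: int = 32
    patches_per_wsi: int = 4096
    folds: int = 5
    seed: int = 0
    d_pathology: int = D_PATHOLOGY
    d_genomic: int = D_GENOMIC
    # mixer / state-space hyperparameters
    d_state: int = 16
    conv_width: int = 4
    expand: int = 2
    attention_groups: int = 2
    kernel_size: int = 3
    reduction: int = 4
    ste_reduction: int = 4
    hazard_eps: float = 1e-7
    dropout: float = 0.25
    sim_metric: str = "l1"
    alignment_mode: str = "all"
    swap_cross_roles: bool = False
    # ablation toggles (all stages on by default)
    use_alignment: bool = True
    use_cross: bool = True
    use_pca: bool = True
    use_gca: bool = True
    use_idconv: bool = True
    use_bimamba: bool = True
    use_ste: bool = True
    use_mixer_pre: bool = True
    use_mixer_post: bool = True

    def validate(self):
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.t_bins < 2:
            raise ValidationError("t_bins must be >= 2")
        for name in ("d_model", "learning_rate", "epochs", "effective_batch",
                     "patches_per_wsi", "d_state", "conv_width", "expand",
                     "attention_groups", "kernel_size", "reduction",
                     "ste_reduction", "hazard_eps"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValidationError("dropout must lie in [0, 1)")
        if self.alignment_mode not in _ALIGNMENT_MODES:
            raise ValidationError(
                f"alignment_mode must be one of {_ALIGNMENT_MODES}")
        if self.sim_metric not in _SIM_METRICS:
            raise ValidationError(f"sim_metric must be one of {_SIM_METRICS}")
        return self

    def replace(self, **kwargs) -> "RunConfig":
        vals = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        vals.update(kwargs)
        return RunConfig(**vals).validate()


def load_config(path) -> RunConfig:
    """Load a YAML key/value run config; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ValidationError("config must be a mapping of key: value pairs")
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValidationError(f"unknown config keys: {unknown}")
    return RunConfig(**raw).validate()
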