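"""The Radiation Pneumonitis Index: scoring, thresholding, splits and evaluation.

The RPI of a sample is the logistic-model probability

    RPI = sigmoid( intercept + sum_i A_i * C_i )

where ``A_i`` is the sample's encoded 0/1/2 dosage at selected site *i* and
``C_i`` the site's fitted coefficient.  Classification uses a strict threshold:
predicted positive iff RPI > threshold (0.5 by default; RPI == 0.5 is
negative).  Display rounding of sensitivity/specificity is one decimal place in
percent, half-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .datatypes import CoefficientTable, EncodedMatrix, ValidationError, VariantRecord

__all__ = ["SplitPlan", "RPIResult", "EvaluationReport", "split_cohort", "score_rpi", "classify", "evaluate"]


@dataclass(frozen=True)
class SplitPlan:
    """A random training/validation partition of the cohort's sample ids."""

    training: tuple[str, ...]
    validation: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.training) & set(self.validation):
            raise ValidationError("training and validation sets overlap")


def split_cohort(sample_ids: list[str], n_train: int = 90, seed: int = 0) -> SplitPlan:
    """Uniform random partition into ``n_train`` training and the remaining validation samples.

    Defaults follow the emulated study design: 90 of 118 samples train the
    model, the other 28 validate it.
    """
    if n_train < 1 or n_train >= len(sample_ids):
        raise ValidationError(f"n_train={n_train} must lie in [1, n_samples)")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError("duplicate sample ids")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(sample_ids))
    ids = np.asarray(sample_ids, dtype=object)
    return SplitPlan(
        training=tuple(ids[perm[:n_train]]),
        validation=tuple(ids[perm[n_train:]]),
        seed=seed,
    )


@dataclass
class RPIResult:
    """Per-sample RPI scores and threshold classification."""

    sample_ids: list[str]
    linear_predictor: np.ndarray
    rpi: np.ndarray
    threshold: float

    @property
    def predicted_class(self) -> np.ndarray:
        return (self.rpi > self.threshold).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "linear_predictor": self.linear_predictor,
                "rpi": self.rpi,
                "predicted_class": self.predicted_class,
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def score_rpi(
    encoded: EncodedMatrix,
    model: CoefficientTable,
    variants: list[VariantRecord] | None = None,
    missing: str = "impute",
) -> RPIResult:
    """Score each sample: sigmoid(intercept + dosage . coefficients).

    Every model site must be present in the encoded matrix; when ``variants``
    are supplied, REF/ALT identity is also checked.  Missing dosages are
    mean-imputed per site (``missing="impute"``) or rejected
    (``missing="error"``); there is no silent zero-fill.
    """
    index = {sid: j for j, sid in enumerate(encoded.site_ids)}
    absent = [sid for sid in model.site_ids if sid not in index]
    if absent:
        raise ValidationError(f"model sites absent from the encoded matrix: {absent}")
    if variants is not None:
        vmap = {v.site_id: v for v in variants}
        for row in model.entries.itertuples():
            v = vmap.get(row.site_id)
            if v is not None and (v.ref_allele != row.ref_allele or row.alt_allele not in v.alt_alleles):
                raise ValidationError(
                    f"allele mismatch at {row.site_id}: model {row.ref_allele}>{row.alt_allele}, "
                    f"matrix {v.ref_allele}>{','.join(v.alt_alleles)}"
                )
    cols = [index[sid] for sid in model.site_ids]
    A = encoded.values[:, cols].copy()
    if np.isnan(A).any():
        if missing == "error":
            bad = [model.site_ids[k] for k in np.unique(np.nonzero(np.isnan(A))[1])]
            raise ValidationError(f"missing dosages at sites {bad}; impute or re-QC")
        if missing != "impute":
            raise ValidationError(f"unknown missing policy {missing!r}")
        means = np.nanmean(A, axis=0)
        means = np.nan_to_num(means)  # all-missing column imputes to 0
        nan_r, nan_c = np.nonzero(np.isnan(A))
        A[nan_r, nan_c] = means[nan_c]
    eta = model.intercept + A @ model.coefficients
    return RPIResult(
        sample_ids=list(encoded.sample_ids),
        linear_predictor=eta,
        rpi=1.0 / (1.0 + np.exp(-eta)),
        threshold=model.threshold,
    )


def classify(rpi: RPIResult, threshold: float | None = None) -> np.ndarray:
    """Binary class per sample: 1 iff RPI strictly exceeds the threshold."""
    thr = rpi.threshold if threshold is None else threshold
    return (rpi.rpi > thr).astype(int)


def _pct_1dp(x: float) -> float:
    return float(Decimal(100 * x).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class EvaluationReport:
    """Confusion counts at the RPI threshold plus sensitivity and specificity."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            return float("nan")  # no positives: undefined
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            return float("nan")
        return self.tn / (self.tn + self.fp)

    @property
    def sensitivity_pct(self) -> float:
        """Sensitivity in percent, one decimal, half-up (display convention)."""
        return _pct_1dp(self.sensitivity)

    @property
    def specificity_pct(self) -> float:
        return _pct_1dp(self.specificity)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tp": [self.tp], "fp": [self.fp], "tn": [self.tn], "fn": [self.fn],
                "sensitivity_pct": [self.sensitivity_pct],
                "specificity_pct": [self.specificity_pct],
            }
        )


def evaluate(predicted, truth) -> EvaluationReport:
    """Confusion counts of binary predictions against the binary endpoint."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValidationError("predicted and truth lengths differ")
    if not (np.isin(predicted, (0, 1)).all() and np.isin(truth, (0, 1)).all()):
        raise ValidationError("predictions and truth must be binary")
    return EvaluationReport(
        tp=int(((predicted == 1) & (truth == 1)).sum()),
        fp=int(((predicted == 1) & (truth == 0)).sum()),
        tn=int(((predicted == 0) & (truth == 0)).sum()),
        fn=int(((predicted == 0) & (truth == 1)).sum()),
    )
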