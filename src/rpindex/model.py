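"""Model/results objects tying the pipeline together, statsmodels-style.

``RadiationPneumonitisModel`` holds the design (encoded SNP dosages plus
penalty-exempt clinical covariates) and the endpoint; ``fit()`` runs
cross-validated elastic-net logistic regression with bootstrap stability
selection, refits the selected markers, and returns an ``RPIResults`` carrying
the coefficient table, inclusion frequencies, cross-validation diagnostics and
a ``summary()``.  Scoring of new cohorts and confusion-matrix evaluation hang
off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import enet
from .datatypes import (
    CONTINUOUS_COVARIATES,
    CoefficientTable,
    EncodedMatrix,
    GenotypeCohort,
    ValidationError,
    validate_phenotypes,
)
from .qc import QCThresholds, apply_qc
from .rpi import EvaluationReport, RPIResult, evaluate, score_rpi

__all__ = ["RadiationPneumonitisModel", "RPIResults"]


class RadiationPneumonitisModel:
    """Penalized logistic model of the grade >=2 pneumonitis endpoint.

    Parameters
    ----------
    encoded:
        QC-passed samples x sites dosage matrix (0/1/2, NaN missing; missing
        entries are mean-imputed per site at fit time).
    phenotypes:
        Phenotype/covariate table indexed by sample id; must cover every
        sample of ``encoded``.
    covariates:
        Covariate columns entered unpenalized (penalty factor 0).  Defaults to
        the study's eight dosimetric/clinical covariates: age, total and
        fractional dose, V5/V10/V20/V30 and mean lung dose.
    alpha:
        Elastic-net mixing parameter in [0, 1] (1 = lasso, 0 = ridge).
    """

    def __init__(
        self,
        encoded: EncodedMatrix,
        phenotypes: pd.DataFrame,
        covariates: list[str] | None = None,
        alpha: float = 0.5,
        variants=None,
    ):
        validate_phenotypes(phenotypes)
        missing = [s for s in encoded.sample_ids if s not in phenotypes.index]
        if missing:
            raise ValidationError(f"samples without phenotype rows: {missing[:5]}")
        self.encoded = encoded
        self.phenotypes = phenotypes.loc[encoded.sample_ids]
        self.covariates = CONTINUOUS_COVARIATES.copy() if covariates is None else list(covariates)
        self.alpha = float(alpha)
        self.variants = variants
        self.endog = self.phenotypes["endpoint"].to_numpy(dtype=float)

        snp = encoded.values.copy()
        col_means = np.nanmean(np.where(np.isnan(snp), np.nan, snp), axis=0)
        col_means = np.nan_to_num(col_means)
        r, c = np.nonzero(np.isnan(snp))
        snp[r, c] = col_means[c]
        cov = self.phenotypes[self.covariates].to_numpy(dtype=float) if self.covariates else np.empty((len(self.endog), 0))
        self.exog = np.ascontiguousarray(np.hstack([snp, cov]))
        self.penalty_factors = np.concatenate(
            [np.ones(snp.shape[1]), np.zeros(cov.shape[1])]
        )
        self.column_names = list(encoded.site_ids) + self.covariates

    @classmethod
    def from_cohort(
        cls,
        cohort: GenotypeCohort,
        phenotypes: pd.DataFrame,
        qc_thresholds: QCThresholds = QCThresholds(),
        **kwargs,
    ) -> "RadiationPneumonitisModel":
        """Apply QC and dosage encoding to a raw cohort, then build the model."""
        filtered, encoded, _report = apply_qc(cohort, thresholds=qc_thresholds)
        return cls(encoded, phenotypes, variants=filtered.variants, **kwargs)

    def fit(
        self,
        n_bootstraps: int = 500,
        seed: int = 0,
        lambda_mode: str = "cv",
        lambda_rule: str = "1se",
        n_folds: int = 10,
        covariate_scoring: str = "fold",
        threshold: float = 0.5,
    ) -> "RPIResults":
        """Run CV, stability selection and the final restricted refit.

        ``lambda_mode="cv"`` re-runs cross-validation inside every bootstrap
        resample (with folds grouped by original sample); ``"fixed"`` uses the
        full-data CV lambda throughout — much faster, near-identical
        selections in practice.  ``covariate_scoring`` controls the genotype-
        only coefficient table: ``"fold"`` absorbs the fitted covariate
        effects, evaluated at the cohort covariate means, into the intercept;
        ``"drop"`` refits without covariates.
        """
        X, y, pf = self.exog, self.endog, self.penalty_factors
        cv = enet.cv_lambda(X, y, alpha=self.alpha, n_folds=n_folds,
                            seed=seed, penalty_factors=pf)
        stability = enet.stability_select(
            X, y, alpha=self.alpha, n_bootstraps=n_bootstraps, seed=seed,
            penalty_factors=pf, lambda_mode=lambda_mode,
            fixed_lambda=cv.chosen(lambda_rule), lambda_rule=lambda_rule,
            n_folds=n_folds,
        )
        return self._finalize(cv, stability, seed, n_folds, covariate_scoring, threshold)

    def _finalize(self, cv, stability, seed, n_folds, covariate_scoring, threshold):
        selected = list(stability.selected)
        cov_cols = list(np.flatnonzero(self.penalty_factors == 0))
        if covariate_scoring == "drop":
            keep = selected
        elif covariate_scoring == "fold":
            keep = selected + cov_cols
        else:
            raise ValidationError(f"unknown covariate_scoring {covariate_scoring!r}")

        n_markers = len(selected)
        if not keep:
            # null model: intercept only, at the outcome's base rate
            ybar = self.endog.mean()
            fit = None
            intercept = float(np.log(ybar / (1 - ybar)))
            marker_coefs = np.empty(0)
            lam = cv.lambda_min
        else:
            Xr = self.exog[:, keep]
            pfr = self.penalty_factors[keep]
            if n_markers:
                cv_r = enet.cv_lambda(Xr, self.endog, alpha=self.alpha,
                                      n_folds=n_folds, seed=seed + 1, penalty_factors=pfr)
                lam = cv_r.lambda_min
            else:
                lam = 0.0
            fit = enet.fit_enet(Xr, self.endog, alpha=self.alpha, lambda_=lam,
                                penalty_factors=pfr)
            marker_coefs = fit.coefficients[:n_markers]
            intercept = fit.intercept
            if covariate_scoring == "fold" and cov_cols:
                cov_vals = self.exog[:, cov_cols]
                intercept += float(fit.coefficients[n_markers:] @ cov_vals.mean(axis=0))

        vmap = {v.site_id: v for v in (self.variants or [])}
        rows = []
        for col, coef in zip(selected, marker_coefs):
            sid = self.column_names[col]
            v = vmap.get(sid)
            rows.append(
                (sid,
                 v.chromosome if v else ".",
                 v.position if v else 0,
                 v.ref_allele if v else "N",
                 v.alt_alleles[0] if v else "N",
                 float(coef))
            )
        table = CoefficientTable(
            entries=pd.DataFrame(rows, columns=CoefficientTable._COLUMNS),
            intercept=float(intercept),
            alpha=self.alpha,
            lambda_=float(lam),
            threshold=threshold,
        )
        return RPIResults(self, cv, stability, fit, table)


@dataclass
class RPIResults:
    """Fit artifacts: coefficient table, stability frequencies, CV diagnostics."""

    model: RadiationPneumonitisModel
    cv: enet.CVResult
    stability: enet.StabilityResult
    final_fit: enet.ElasticNetFit | None
    coefficient_table: CoefficientTable

    @property
    def selected_site_ids(self) -> list[str]:
        return self.coefficient_table.site_ids

    @property
    def inclusion_frequencies(self) -> pd.Series:
        names = [self.model.column_names[c] for c in self.stability.penalized_columns]
        return pd.Series(self.stability.frequencies, index=names, name="inclusion_frequency")

    def predict(self, encoded: EncodedMatrix | None = None) -> RPIResult:
        """RPI scores for a cohort (default: the training matrix)."""
        encoded = self.model.encoded if encoded is None else encoded
        return score_rpi(encoded, self.coefficient_table)

    def evaluate(self, encoded: EncodedMatrix | None = None,
                 endpoint=None) -> EvaluationReport:
        """Confusion counts at the RPI threshold against the observed endpoint."""
        scores = self.predict(encoded)
        if endpoint is None:
            endpoint = self.model.phenotypes.loc[scores.sample_ids, "endpoint"].to_numpy()
        return evaluate(scores.predicted_class, endpoint)

    def summary(self) -> str:
        t = self.coefficient_table
        lines = [
            "Radiation Pneumonitis Index — stability-selected elastic-net logistic model",
            "=" * 76,
            f"Samples: {len(self.model.endog)}    cases (grade >=2): {int(self.model.endog.sum())}",
            f"Candidate markers: {int((self.model.penalty_factors > 0).sum())}"
            f"    covariates (unpenalized): {len(self.model.covariates)}",
            f"alpha: {t.alpha:g}    lambda (final refit): {t.lambda_:.6g}",
            f"CV lambda: min {self.cv.lambda_min:.6g}, 1-SE {self.cv.lambda_1se:.6g}"
            f" ({self.cv.n_folds} folds)",
            f"Bootstraps: {self.stability.n_bootstraps}"
            f"    selected markers (freq > {self.stability.rule_threshold:g}): {len(t.site_ids)}",
            "-" * 76,
            f"{'site':<14}{'chrom':>6}{'position':>12}{'ref>alt':>9}"
            f"{'coef':>12}{'freq':>8}",
        ]
        freqs = self.inclusion_frequencies
        for row in t.entries.itertuples():
            lines.append(
                f"{row.site_id:<14}{row.chromosome:>6}{row.position:>12}"
                f"{row.ref_allele + '>' + row.alt_allele:>9}"
                f"{row.coefficient:>12.5f}{freqs.get(row.site_id, float('nan')):>8.2f}"
            )
        lines.append(f"{'intercept':<14}{'':>6}{'':>12}{'':>9}{t.intercept:>12.5f}")
        lines.append("-" * 76)
        lines.append(f"Classification threshold on RPI: {t.threshold:g} (strict >)")
        return "\n".join(lines)
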