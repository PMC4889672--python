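"""Poisson log-linear count model with exposure offset.

Crossover counts per interval are modeled as Poisson with

    log E[count_i] = log(length_i) + beta0 + beta_side * side_i + sum_j beta_j x_ij

so coefficients describe effects on the per-bp crossover *rate*.  The side
indicator is part of every model because the genotyping design sampled the two
sides of the sorting indel unrepresentatively.  Fitting is iteratively
reweighted least squares (IRLS); deviance accounting is shared by the
uniformity, correlate and motif scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .panel_io import CrossoverTable, ValidationError

MAX_ITER = 100
DEVIANCE_RTOL = 1e-10


@dataclass
class CountModelSpec:
    """Design of one Poisson count model.

    ``covariates`` maps names to numeric vectors; the side indicator should
    always be present (use :func:`spec_from_table`).  ``offset`` is
    log(interval length in bp).
    """

    counts: np.ndarray
    offset: np.ndarray
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        n = len(self.counts)
        if len(self.offset) != n:
            raise ValidationError("offset length mismatch")
        if not np.all(np.isfinite(self.offset)):
            raise ValidationError("non-finite offset")
        if np.any(self.counts < 0) or np.any(self.counts != np.round(self.counts)):
            raise ValidationError("counts must be non-negative integers")
        self.covariates = {k: np.asarray(v, dtype=float) for k, v in self.covariates.items()}
        for name, v in self.covariates.items():
            if len(v) != n:
                raise ValidationError(f"covariate {name!r} length mismatch")

    @property
    def design(self) -> tuple[np.ndarray, list[str]]:
        names = ["intercept", *self.covariates]
        X = np.column_stack([np.ones(len(self.counts)),
                             *self.covariates.values()]) \
            if self.covariates else np.ones((len(self.counts), 1))
        return X, names


@dataclass
class CountModelFit:
    coefficients: dict[str, float]
    log_likelihood: float
    residual_deviance: float
    converged: bool
    n_iter: int
    base_deviance: float | None = None  # deviance of the offset+side model

    def to_dict(self) -> dict:
        return dict(coefficients=self.coefficients,
                    log_likelihood=self.log_likelihood,
                    residual_deviance=self.residual_deviance,
                    base_deviance=self.base_deviance,
                    converged=self.converged, n_iter=self.n_iter)


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Residual deviance 2*(saturated loglik − model loglik)."""
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore"):
        ll = np.where((y == 0) & (mu == 0), 0.0, y * np.log(mu)) - mu \
            - special.gammaln(y + 1)
    return float(np.sum(ll))


def fit_poisson(spec: CountModelSpec, max_iter: int = MAX_ITER,
                tol: float = DEVIANCE_RTOL) -> CountModelFit:
    """Maximum-likelihood fit of the Poisson log-link model by IRLS.

    Convergence is a relative deviance change below ``tol`` (default 1e-10)
    within ``max_iter`` iterations; non-convergence is flagged, never silent.
    """
    X, names = spec.design
    y = spec.counts
    n, p = X.shape
    if n < p + 2:
        raise ValidationError(f"need at least {p + 2} intervals for {p} parameters")
    # start from the pooled rate
    mu = np.full(n, max(y.mean(), 0.5))
    eta = np.log(mu) - spec.offset
    beta = np.zeros(p)
    beta[0] = np.log(y.sum() / np.exp(spec.offset).sum() + 1e-300)
    eta = X @ beta
    mu = np.exp(eta + spec.offset)
    dev = poisson_deviance(y, mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = mu
        z = eta + (y - mu) / np.maximum(mu, 1e-300)
        XtW = X.T * W
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            warnings.warn("singular design in Poisson IRLS", stacklevel=2)
            break
        eta_new = X @ beta_new
        # step-halving guard against overshoot
        for _ in range(20):
            mu_new = np.exp(np.clip(eta_new + spec.offset, -700, 700))
            dev_new = poisson_deviance(y, mu_new)
            if np.isfinite(dev_new) and dev_new <= dev + 1e-8:
                break
            eta_new = (eta_new + eta) / 2.0
            beta_new = (beta_new + beta) / 2.0
        beta, eta, mu = beta_new, eta_new, mu_new
        if abs(dev - dev_new) <= tol * (abs(dev) + 0.1):
            dev = dev_new
            converged = True
            break
        dev = dev_new
    if not converged:
        warnings.warn(f"Poisson IRLS did not converge in {it} iterations",
                      stacklevel=2)
    return CountModelFit(
        coefficients=dict(zip(names, (float(b) for b in beta))),
        log_likelihood=poisson_loglik(y, mu),
        residual_deviance=float(dev),
        converged=converged, n_iter=it)


def spec_from_table(table: CrossoverTable, side: str | None = None,
                    features: dict[str, np.ndarray] | None = None,
                    cross: str | None = None,
                    include_side: bool = True) -> CountModelSpec:
    """Build a model spec over the unmasked intervals of a crossover table.

    Counts default to the sum over both crosses.  ``features`` are appended
    after the side indicator.
    """
    counts = table.counts(side, cross)
    lengths = table.lengths(side)
    cov: dict[str, np.ndarray] = {}
    if include_side and (side is None or side == "both"):
        ind = table.side_indicator(side)
        if ind.min() != ind.max():  # only when both sides present
            cov["side"] = ind
    if features:
        cov.update(features)
    return CountModelSpec(counts, np.log(lengths.astype(float)), cov)


def base_fit(table: CrossoverTable, side: str | None = None,
             cross: str | None = None) -> CountModelFit:
    """Fit of the offset+side base model (the design-only model)."""
    return fit_poisson(spec_from_table(table, side, cross=cross))


def offset_side_deviance(counts: np.ndarray, lengths: np.ndarray,
                         side_indicator: np.ndarray) -> float:
    """Closed-form residual deviance of the offset+side model.

    With only an intercept and a side indicator, the MLE rate on each side is
    the pooled side total divided by the pooled side length, so the deviance
    needs no iteration.  Used to score large simulation ensembles.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    mu = np.empty_like(counts)
    for level in np.unique(side_indicator):
        m = side_indicator == level
        mu[m] = lengths[m] * (counts[m].sum() / lengths[m].sum())
    return poisson_deviance(counts, mu)


def deviance_explained(fit: CountModelFit) -> float:
    """Percent of base-model deviance removed by the fitted covariates.

    The baseline is the offset+side model on the same intervals, so deviance
    attributable to the sampling design is never credited to a feature.
    """
    if fit.base_deviance is None:
        raise ValidationError("fit has no base_deviance; fit the base model first")
    if fit.base_deviance == 0:
        warnings.warn("base deviance is zero; deviance explained defined as 0",
                      stacklevel=2)
        return 0.0
    return 100.0 * (fit.base_deviance - fit.residual_deviance) / fit.base_deviance


def lr_test(fit_null: CountModelFit, fit_alt: CountModelFit,
            df: int | None = None) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits on identical data.

    Returns (statistic, df, chi-square p).  The chi-square p is a reference;
    simulation nulls are authoritative for the heterogeneity tests.
    """
    stat = 2.0 * (fit_alt.log_likelihood - fit_null.log_likelihood)
    if stat < -1e-6:
        raise ValidationError("alternative fits worse than null: models not nested "
                              "or not fitted on identical data")
    stat = max(stat, 0.0)
    if df is None:
        df = len(fit_alt.coefficients) - len(fit_null.coefficients)
    if df <= 0:
        df = 1
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return float(stat), int(df), p
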