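"""Empirical-Bayes batch adjustment: model fits, shrinkage, back-transforms.

The adjustment pipeline follows the classic location/scale batch model for
log2 expression.  Raw data are standardized gene-wise,

    pooled:     Z_ijg = (Y_ijg - alpha_g  - X_j beta_g) / sigma_g
    batchwise:  Z_ijg = (Y_ijg - alpha_ig - X_j beta_g) / sigma_ig

and Z_ijg ~ N(gamma_ig, delta2_ig) with a Normal prior on the additive
batch effect gamma and an Inverse-Gamma prior on the multiplicative batch
variance delta2.  Hyperparameters are estimated across genes by method of
moments, conditional posterior means are found by a joint fixed-point
iteration, and the adjusted data are mapped back either to the grand
mean / pooled scale (ComBat) or to the gene-wise location and scale of a
designated gold-standard reference batch (M-ComBat):

    grand:      Y*_ijg = sigma_g   / delta*_ig (Z_ijg - gamma*_ig) + alpha_g   + X_j beta_g
    reference:  Y*_ijg = sigma_rg  / delta*_ig (Z_ijg - gamma*_ig) + alpha_rg  + X_j beta_g

Denominator conventions (they matter at O(1/n)): sigma2_pooled averages the
squared residuals of the full batch-intercept fit over all N samples;
sigma2_batch and the naive delta2_hat average over the n_i samples of the
batch.  With these conventions batch-wise standardization gives
gamma_hat = 0 and delta2_hat = 1 identically, the cross-gene prior moments
collapse, and the degeneracy guards reduce M-ComBat to an exact gene-wise
location/scale map onto the reference batch -- in particular the reference
batch itself is returned bit-for-bit unchanged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .datatypes import (
    VAR_EPS,
    BatchDesign,
    EBEstimates,
    ExpressionMatrix,
    GeneModelFit,
    StandardizedMatrix,
)
from .exceptions import ConvergenceError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 5000


def _ols(design: BatchDesign, values: np.ndarray):
    """Joint least-squares fit of batch intercepts + covariates, all genes.

    Returns (batch_intercepts (k, G), beta (p, G) or None, residuals (G, N)).
    """
    D = design.model_matrix()
    k = design.n_batches
    coef, *_ = np.linalg.lstsq(D, values.T, rcond=None)
    resid = values - (D @ coef).T
    beta = coef[k:] if coef.shape[0] > k else None
    return coef[:k], beta, resid


def _covariate_term(fit_beta: Optional[np.ndarray], design: BatchDesign) -> float | np.ndarray:
    """X beta as a (G, N) array, or 0.0 when the model has no covariates."""
    if fit_beta is None:
        return 0.0
    X = design.covariate_matrix()
    return (X @ fit_beta).T


def zero_variance_probes(
    Y: ExpressionMatrix, design: BatchDesign, mode: str
) -> np.ndarray:
    """Boolean mask of probes with (numerically) zero variance in scope.

    Pooled scope is the residual variance of the full batch-intercept +
    covariate fit; batch-wise scope requires positive variance of
    (Y - X beta) within every batch.
    """
    design.check_samples(Y)
    _, beta, resid = _ols(design, Y.values)
    if mode == "pooled":
        return (resid**2).mean(axis=1) <= VAR_EPS
    if mode == "batchwise":
        R = Y.values - _covariate_term(beta, design)
        bad = np.zeros(Y.n_probes, dtype=bool)
        for idx in design.batch_indices().values():
            block = R[:, idx]
            bad |= block.var(axis=1) <= VAR_EPS
        return bad
    raise ValidationError(f"unknown mode {mode!r}")


def fit_gene_models(
    Y: ExpressionMatrix, design: BatchDesign, mode: str = "pooled"
) -> GeneModelFit:
    """Gene-wise location/scale estimates by ordinary least squares.

    Covariate coefficients beta are always taken from the pooled joint fit
    (batch intercepts + covariates) and shared by both modes.
    """
    design.check_samples(Y)
    if mode not in ("pooled", "batchwise"):
        raise ValidationError(f"unknown mode {mode!r}")
    batch_int, beta, resid = _ols(design, Y.values)
    sizes = design.batch_sizes
    n = design.n_samples
    weights = np.array([sizes[b] / n for b in design.batch_labels])
    cov_names = () if design.covariates is None else tuple(design.covariates.columns)

    if mode == "pooled":
        alpha = weights @ batch_int                     # (G,)
        sigma2 = (resid**2).mean(axis=1)                # denominator N
        bad = np.flatnonzero(sigma2 <= VAR_EPS)
        if bad.size:
            ids = [Y.probe_ids[i] for i in bad]
            raise ValidationError(
                f"zero residual variance for probes {ids}; drop them or use "
                f"zero_variance='passthrough' in the pipeline entry points"
            )
        return GeneModelFit(
            mode="pooled",
            probe_ids=Y.probe_ids,
            batch_labels=design.batch_labels,
            beta=beta,
            covariate_names=cov_names,
            alpha_pooled=alpha,
            sigma_pooled=np.sqrt(sigma2),
        )

    R = Y.values - _covariate_term(beta, design)        # (G, N)
    B, G = design.n_batches, Y.n_probes
    alpha_b = np.empty((B, G))
    sigma2_b = np.empty((B, G))
    for j, (label, idx) in enumerate(design.batch_indices().items()):
        block = R[:, idx]
        alpha_b[j] = block.mean(axis=1)
        sigma2_b[j] = ((block - alpha_b[j][:, None]) ** 2).mean(axis=1)  # denom n_i
    bad = np.flatnonzero((sigma2_b <= VAR_EPS).any(axis=0))
    if bad.size:
        ids = [Y.probe_ids[i] for i in bad]
        raise ValidationError(
            f"zero within-batch variance for probes {ids}; drop them or use "
            f"zero_variance='passthrough' in the pipeline entry points"
        )
    return GeneModelFit(
        mode="batchwise",
        probe_ids=Y.probe_ids,
        batch_labels=design.batch_labels,
        beta=beta,
        covariate_names=cov_names,
        alpha_batch=alpha_b,
        sigma_batch=np.sqrt(sigma2_b),
    )


def standardize(
    Y: ExpressionMatrix, fit: GeneModelFit, design: BatchDesign
) -> StandardizedMatrix:
    """Center and scale expression to the dimensionless Z used by the EB model."""
    design.check_samples(Y)
    if fit.probe_ids != Y.probe_ids:
        raise ValidationError("fit and matrix disagree on probe ids")
    if fit.batch_labels != design.batch_labels:
        raise ValidationError("fit and design disagree on batches")
    centered = Y.values - _covariate_term(fit.beta, design)
    if fit.mode == "pooled":
        Z = (centered - fit.alpha_pooled[:, None]) / fit.sigma_pooled[:, None]
    else:
        Z = np.empty_like(centered)
        for j, (label, idx) in enumerate(design.batch_indices().items()):
            Z[:, idx] = (centered[:, idx] - fit.alpha_batch[j][:, None]) / fit.sigma_batch[j][:, None]
    return StandardizedMatrix(Z, Y.probe_ids, Y.sample_ids, fit)


def naive_batch_estimates(Z: StandardizedMatrix, design: BatchDesign) -> EBEstimates:
    """Per-gene, per-batch sample moments of Z: gamma_hat (mean) and delta2_hat.

    delta2_hat averages squared deviations over the n_i batch samples
    (denominator n_i); genes with delta2_hat == 0 in some batch are flagged
    and handled by the degenerate-scale guard downstream.
    """
    if tuple(Z.sample_ids) != tuple(design.sample_ids):
        raise ValidationError("standardized matrix and design disagree on samples")
    B, G = design.n_batches, len(Z.probe_ids)
    gamma_hat = np.empty((B, G))
    delta2_hat = np.empty((B, G))
    for j, (label, idx) in enumerate(design.batch_indices().items()):
        block = Z.values[:, idx]
        gamma_hat[j] = block.mean(axis=1)
        delta2_hat[j] = ((block - gamma_hat[j][:, None]) ** 2).mean(axis=1)
    flagged = delta2_hat <= VAR_EPS
    if flagged.any():
        logger.warning(
            "delta2_hat is zero for %d probe/batch cells; the degenerate-scale "
            "guard will apply downstream", int(flagged.sum()),
        )
    return EBEstimates(
        batch_labels=design.batch_labels,
        probe_ids=Z.probe_ids,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        delta2_zero=flagged,
    )


def estimate_hyperparameters(
    est: EBEstimates,
    *,
    eps_location: float = 1e-12,
    eps_scale: float = 1e-12,
) -> EBEstimates:
    """Method-of-moments priors from the cross-gene spread of naive estimates.

    Normal prior on gamma: gamma_bar_i, tau2_bar_i are the cross-gene mean
    and variance of gamma_hat.  Inverse-Gamma prior on delta2: matching the
    prior mean theta/(lambda-1) and variance theta^2/((lambda-1)^2(lambda-2))
    to the cross-gene moments (m, s2) of delta2_hat gives

        lambda_bar = m^2/s2 + 2,    theta_bar = m (m^2/s2 + 1).

    A batch whose cross-gene spread vanishes (tau2_bar < eps_location or
    s2 < eps_scale) is flagged degenerate; shrinkage is bypassed for it.
    """
    G = len(est.probe_ids)
    if G < 2:
        raise ValidationError(
            "hyperparameter estimation needs at least 2 genes "
            "(cross-gene moments are undefined for G = 1)"
        )
    gamma_bar = est.gamma_hat.mean(axis=1)
    tau2_bar = est.gamma_hat.var(axis=1, ddof=1)
    m = est.delta2_hat.mean(axis=1)
    s2 = est.delta2_hat.var(axis=1, ddof=1)

    loc_deg = tau2_bar < eps_location
    scale_deg = s2 < eps_scale
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(scale_deg, np.nan, m**2 / s2 + 2.0)
        theta = np.where(scale_deg, np.nan, m * (m**2 / s2 + 1.0))
    for j, label in enumerate(est.batch_labels):
        if loc_deg[j] or scale_deg[j]:
            logger.info(
                "batch %s: degenerate prior (location=%s, scale=%s); "
                "shrinkage bypassed", label, bool(loc_deg[j]), bool(scale_deg[j]),
            )
    return replace(
        est,
        gamma_bar=gamma_bar,
        tau2_bar=tau2_bar,
        lambda_bar=lam,
        theta_bar=theta,
        location_degenerate=loc_deg,
        scale_degenerate=scale_deg,
    )


def eb_posterior(
    Z: StandardizedMatrix,
    est: EBEstimates,
    design: BatchDesign,
    *,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> EBEstimates:
    """Joint fixed point of the conditional posterior means, per batch.

        gamma*  = (n tau2 gamma_hat + delta2* gamma_bar) / (n tau2 + delta2*)
        delta2* = (theta + 1/2 sum_j (Z_j - gamma*)^2) / (n/2 + lambda - 1)

    initialized at the naive estimates and alternated until the largest
    relative change of both sets falls below ``tol``.  Degenerate batches
    bypass shrinkage: gamma* = gamma_bar (location) and/or delta2* =
    delta2_hat (scale), exactly; when only one side is degenerate the other
    has a closed form and is computed in a single pass.
    """
    if not est.has_hyperparameters:
        raise ValidationError("hyperparameters must be estimated before the posterior")
    if tol <= 0:
        raise ValidationError("tol must be positive")
    B, G = est.gamma_hat.shape
    gamma_star = np.empty((B, G))
    delta2_star = np.empty((B, G))
    iters = np.zeros(B, dtype=int)

    for j, (label, idx) in enumerate(design.batch_indices().items()):
        n = idx.size
        block = Z.values[:, idx]
        sz = block.sum(axis=1)
        szz = (block**2).sum(axis=1)
        g_hat, d_hat = est.gamma_hat[j], est.delta2_hat[j]
        loc_deg = bool(est.location_degenerate[j])
        scale_deg = bool(est.scale_degenerate[j])
        gbar, t2 = est.gamma_bar[j], est.tau2_bar[j]
        lam, theta = est.lambda_bar[j], est.theta_bar[j]

        if not scale_deg:
            if lam <= 1.0 + 1e-9 or (n / 2.0 + lam - 1.0) <= 0:
                raise ValidationError(
                    f"batch {label!r}: lambda_bar={lam:.4g} makes the "
                    f"posterior scale denominator non-positive"
                )
            denom = n / 2.0 + lam - 1.0

        def _ss(gamma: np.ndarray) -> np.ndarray:
            return np.maximum(szz - 2.0 * gamma * sz + n * gamma**2, 0.0)

        if loc_deg and scale_deg:
            gamma_star[j] = gbar
            delta2_star[j] = d_hat
        elif loc_deg:
            gamma_star[j] = gbar
            delta2_star[j] = (theta + 0.5 * _ss(gamma_star[j])) / denom
            iters[j] = 1
        elif scale_deg:
            if np.any(d_hat <= 0):
                raise ValidationError(
                    f"batch {label!r}: scale-degenerate with zero delta2_hat"
                )
            delta2_star[j] = d_hat
            gamma_star[j] = (n * t2 * g_hat + d_hat * gbar) / (n * t2 + d_hat)
            iters[j] = 1
        else:
            g_old, d_old = g_hat.copy(), d_hat.copy()
            for it in range(1, max_iter + 1):
                g_new = (n * t2 * g_hat + d_old * gbar) / (n * t2 + d_old)
                d_new = (theta + 0.5 * _ss(g_new)) / denom
                change_g = np.abs(g_new - g_old) / (np.abs(g_old) + tol)
                change_d = np.abs(d_new - d_old) / (np.abs(d_old) + tol)
                worst = max(change_g.max(), change_d.max())
                g_old, d_old = g_new, d_new
                if worst < tol:
                    break
            else:
                gworst = int(np.argmax(np.maximum(change_g, change_d)))
                raise ConvergenceError(
                    f"EB posterior did not converge in {max_iter} iterations "
                    f"for batch {label!r} (worst probe "
                    f"{est.probe_ids[gworst]!r}, relative change "
                    f"{worst:.3g} > tol {tol:g})"
                )
            gamma_star[j], delta2_star[j] = g_old, d_old
            iters[j] = it

    if np.any(delta2_star <= 0):
        raise ValidationError("posterior scale collapsed to zero")
    return replace(
        est, gamma_star=gamma_star, delta2_star=delta2_star, n_iterations=iters
    )


def backtransform(
    Z: StandardizedMatrix,
    est: EBEstimates,
    fit: GeneModelFit,
    design: BatchDesign,
    anchor: str,
) -> ExpressionMatrix:
    """Map standardized data back to log2 scale at the chosen anchor.

    ``anchor='grand'`` (requires a pooled fit) rescales to the pooled
    sigma_g around the weighted grand mean alpha_g; ``anchor='reference'``
    (requires a batch-wise fit and design.reference) rescales every batch to
    the reference batch's gene-wise sigma_rg and alpha_rg.
    """
    if not est.has_posteriors:
        raise ValidationError("posterior estimates are required for the back-transform")
    if anchor == "grand":
        if fit.mode != "pooled":
            raise ValidationError("anchor='grand' requires a pooled fit")
        loc = fit.alpha_pooled
        scale = fit.sigma_pooled
    elif anchor == "reference":
        if fit.mode != "batchwise":
            raise ValidationError("anchor='reference' requires a batch-wise fit")
        if design.reference is None:
            raise ValidationError("anchor='reference' requires design.reference")
        r = design.batch_labels.index(design.reference)
        loc = fit.alpha_batch[r]
        scale = fit.sigma_batch[r]
    else:
        raise ValidationError(f"unknown anchor {anchor!r}")

    out = np.empty_like(Z.values)
    delta_star = np.sqrt(est.delta2_star)
    for j, (label, idx) in enumerate(design.batch_indices().items()):
        out[:, idx] = (
            (scale / delta_star[j])[:, None]
            * (Z.values[:, idx] - est.gamma_star[j][:, None])
            + loc[:, None]
        )
    out = out + _covariate_term(fit.beta, design)
    return ExpressionMatrix(out, Z.probe_ids, Z.sample_ids)


@dataclass
class AdjustmentReport:
    """Machine-readable record of one adjustment run."""

    method: str
    reference: Optional[str]
    batch_sizes: dict
    n_probes: int
    passthrough_probes: list
    iterations: dict
    location_degenerate: dict
    scale_degenerate: dict
    tol: float
    max_iter: int

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "reference": self.reference,
            "batch_sizes": self.batch_sizes,
            "n_probes": self.n_probes,
            "n_passthrough": len(self.passthrough_probes),
            "passthrough_probes": list(self.passthrough_probes),
            "iterations": self.iterations,
            "location_degenerate": self.location_degenerate,
            "scale_degenerate": self.scale_degenerate,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }


def _run_pipeline(
    Y: ExpressionMatrix,
    design: BatchDesign,
    mode: str,
    anchor: str,
    tol: float,
    max_iter: int,
    zero_variance: str,
):
    if zero_variance not in ("passthrough", "error"):
        raise ValidationError(
            f"zero_variance must be 'passthrough' or 'error', got {zero_variance!r}"
        )
    design.check_samples(Y)
    bad = zero_variance_probes(Y, design, mode)
    passthrough = [p for p, b in zip(Y.probe_ids, bad) if b]
    if passthrough and zero_variance == "error":
        raise ValidationError(
            f"zero-variance probes in {mode} scope: {passthrough}"
        )
    if passthrough:
        logger.warning(
            "%d probes have zero variance in %s scope and are passed through "
            "unchanged: %s", len(passthrough), mode, passthrough[:10],
        )
    retained = ~bad
    if retained.sum() == 0:
        raise ValidationError("no probes with positive variance; nothing to adjust")
    Ysub = Y.subset_probes(retained) if passthrough else Y

    fit = fit_gene_models(Ysub, design, mode)
    Z = standardize(Ysub, fit, design)
    est = naive_batch_estimates(Z, design)
    est = estimate_hyperparameters(est)
    est = eb_posterior(Z, est, design, tol=tol, max_iter=max_iter)
    adjusted = backtransform(Z, est, fit, design, anchor)

    if passthrough:
        out = Y.values.copy()
        out[retained] = adjusted.values
        result = ExpressionMatrix(out, Y.probe_ids, Y.sample_ids)
    else:
        result = adjusted
    report = AdjustmentReport(
        method="mcombat" if anchor == "reference" else "combat",
        reference=design.reference if anchor == "reference" else None,
        batch_sizes=dict(design.batch_sizes),
        n_probes=Y.n_probes,
        passthrough_probes=passthrough,
        iterations={
            b: int(est.n_iterations[j]) for j, b in enumerate(design.batch_labels)
        },
        location_degenerate={
            b: bool(est.location_degenerate[j])
            for j, b in enumerate(design.batch_labels)
        },
        scale_degenerate={
            b: bool(est.scale_degenerate[j])
            for j, b in enumerate(design.batch_labels)
        },
        tol=tol,
        max_iter=max_iter,
    )
    return result, report


def combat(
    Y: ExpressionMatrix,
    design: BatchDesign,
    *,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    zero_variance: str = "passthrough",
    return_report: bool = False,
):
    """Classic empirical-Bayes adjustment anchored at the grand mean.

    Composite of the pooled fit, standardization, naive moments,
    method-of-moments priors, EB posterior, and the grand-anchor
    back-transform.  Returns a matrix with the same probes and samples;
    with ``return_report=True`` also returns an :class:`AdjustmentReport`.
    """
    result, report = _run_pipeline(
        Y, design, "pooled", "grand", tol, max_iter, zero_variance
    )
    return (result, report) if return_report else result


def mcombat(
    Y: ExpressionMatrix,
    design: BatchDesign,
    *,
    reference: Optional[str] = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    zero_variance: str = "passthrough",
    return_report: bool = False,
):
    """Reference-anchored adjustment: map every batch onto the gold standard.

    Same composite as :func:`combat` but with batch-wise standardization and
    the reference-anchor back-transform, so all batches inherit the
    gene-wise location and scale of ``reference`` (default:
    ``design.reference``).  With no covariates the reference batch is
    returned unchanged.
    """
    if reference is not None:
        design = design.with_reference(reference)
    if design.reference is None:
        raise ValidationError("mcombat requires a reference batch")
    result, report = _run_pipeline(
        Y, design, "batchwise", "reference", tol, max_iter, zero_variance
    )
    return (result, report) if return_report else result
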