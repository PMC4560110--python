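"""Gaussian segment log-likelihood under masked (sparse) parameters.

The working quantity is the proportional form of the multivariate normal
log-likelihood,

    L(mu, Sigma | Y) = - sum_t (y(t) - mu)' Sigma^{-1} (y(t) - mu)
                       - T log det Sigma,

i.e. the 1/2 factor and the -(TJ/2) log 2*pi constant are dropped
throughout.  Only likelihood *differences* between candidate segmentations
are ever interpreted, so the dropped constants cancel; users comparing
against textbook values should multiply by 1/2 and add the constant back.

Masked maximum-likelihood fits are obtained by taking the Hadamard product
of the unconstrained MLE with the binary mask -- not by a constrained
refit.  The product can leave the covariance indefinite, so an eigenvalue
repair is applied (only) when a likelihood has to be evaluated; reported
parameters keep their exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import DataValidationError, SingularCovarianceError
from .sparse_estimation import (
    GaussianSegmentParams,
    SparsityMask,
    as_timeseries,
    empirical_moments,
)

__all__ = [
    "LogLikValue",
    "gaussian_loglik",
    "baseline_loglik",
    "masked_mle",
    "repair_psd",
]


@dataclass
class LogLikValue:
    """A segment log-likelihood (proportional form) and its free-parameter count."""

    value: float
    n_params: int


def repair_psd(cov: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Clip the spectrum of a symmetric matrix to make it positive definite.

    Eigenvalues below ``epsilon * lambda_max`` are raised to that floor; the
    eigenvectors are untouched, so the perturbation is bounded and scale
    invariant.  A matrix whose smallest eigenvalue already clears the floor
    is returned unchanged.  Masked-zero patterns are *not* preserved by the
    repair, which is why it is applied only for likelihood evaluation.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise DataValidationError(f"expected a square matrix, got shape {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-10, rtol=1e-8):
        raise DataValidationError("repair_psd requires a symmetric matrix")
    eigval, eigvec = np.linalg.eigh(cov)
    lam_max = eigval[-1]
    if lam_max <= 0.0:
        raise SingularCovarianceError(
            "covariance has no positive eigenvalue; cannot repair"
        )
    floor = epsilon * lam_max
    if eigval[0] >= floor:
        return cov
    repaired = (eigvec * np.maximum(eigval, floor)) @ eigvec.T
    return (repaired + repaired.T) / 2.0


def masked_mle(data, mask: SparsityMask, start: int = 1, end: int | None = None) -> GaussianSegmentParams:
    """Maximum-likelihood fit with the sparsity pattern imposed by Hadamard product.

    Sample mean and ML covariance are multiplied element-wise by the mask;
    masked-out entries are exactly zero and diagonal variances are always
    retained.  No positive-definiteness repair is applied here.
    """
    ts = as_timeseries(data)
    mean, cov = empirical_moments(ts)
    mu = np.where(mask.mean_mask, mean, 0.0)
    sig = np.where(mask.cov_mask, cov, 0.0)
    return GaussianSegmentParams(
        mean=mu, cov=sig, mask=mask, start=start, end=ts.T if end is None else end
    )


def _prepared_cholesky(params: GaussianSegmentParams) -> np.ndarray:
    """Lower Cholesky factor of the (repaired if necessary) covariance."""
    cov = params.cov
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        pass
    try:
        return np.linalg.cholesky(repair_psd(cov))
    except (np.linalg.LinAlgError, SingularCovarianceError) as exc:
        raise SingularCovarianceError(
            f"segment [{params.start}, {params.end}]: covariance singular after repair"
        ) from exc


def gaussian_loglik(data, params: GaussianSegmentParams) -> LogLikValue:
    """Proportional Gaussian log-likelihood of a segment under fixed parameters.

    Computes ``- sum_t (y(t)-mu)' Sigma^{-1} (y(t)-mu) - T log det Sigma``
    directly from the observations.
    """
    ts = as_timeseries(data)
    if ts.T < 1:
        raise DataValidationError("segment is empty")
    chol = _prepared_cholesky(params)
    resid = ts.values - params.mean
    z = linalg.solve_triangular(chol, resid.T, lower=True)
    quad = float(np.sum(z * z))
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return LogLikValue(value=-quad - ts.T * logdet, n_params=params.mask.n_free)


def baseline_loglik(data, params: GaussianSegmentParams) -> LogLikValue:
    """Segment log-likelihood via the trace identity.

    Evaluates ``-T (tr(Sigma^{-1} S) + log det Sigma)`` where ``S`` is the
    normalised scatter matrix about ``params.mean``.  Algebraically identical
    to :func:`gaussian_loglik`; both forms are kept as mutual checks.
    """
    ts = as_timeseries(data)
    if ts.T < 1:
        raise DataValidationError("segment is empty")
    resid = ts.values - params.mean
    scatter = resid.T @ resid / ts.T
    chol = _prepared_cholesky(params)
    half = linalg.solve_triangular(chol, scatter, lower=True)
    inv_s = linalg.solve_triangular(chol, half, lower=True, trans="T")
    trace = float(np.trace(inv_s))
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return LogLikValue(value=-ts.T * (trace + logdet), n_params=params.mask.n_free)
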