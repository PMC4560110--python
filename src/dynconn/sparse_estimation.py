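"""Sparse Gaussian parameter estimation by element-wise adaptive thresholding.

A stationary block of a multivariate (ROI x time) recording is modelled as
i.i.d. draws from :math:`N(\\mu, \\Sigma)`.  Rather than penalising the
precision matrix (GLASSO-style), sparsity is imposed directly on the
covariance matrix: each off-diagonal element is kept only if an asymptotic
z-test rejects the null hypothesis that it is zero.  The variance of the
element estimator is obtained either from the empirical fourth moments of
the cross-product series (the CLT plug-in) or from a delete-1 jackknife.
Zeros in the resulting matrix encode *marginal* independence between
channels, which is what a covariance graph displays.

All estimators use the maximum-likelihood divisor ``T`` (not ``T - 1``);
differences of log-likelihoods computed downstream only make sense when the
same convention is applied on both sides of a candidate split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DataValidationError

logger = logging.getLogger(__name__)

#: Recognised family-wise adjustment modes for the element-wise tests.
MULTIPLICITY_MODES = ("none", "eta-over-J", "bonferroni")

VARIANCE_METHODS = ("clt", "jackknife")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TimeSeriesMatrix:
    """A ``T x J`` observation matrix: rows are time points, columns channels.

    Parameters
    ----------
    values
        Real matrix with ``T`` rows (time) and ``J`` columns (channels/ROIs).
        All entries must be finite.
    channel_names
        Optional list of ``J`` channel labels.
    spike_times
        Optional record of artificially spiked time points (0-based row
        indices), kept for introspection by the simulator.
    """

    values: np.ndarray
    channel_names: list[str] | None = None
    spike_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise DataValidationError(
                f"time series must be a 2-D matrix, got shape {values.shape}"
            )
        if not np.isfinite(values).all():
            t, j = np.argwhere(~np.isfinite(values))[0]
            raise DataValidationError(
                f"non-finite value at time row {t + 1}, channel column {j + 1}"
            )
        if self.channel_names is not None and len(self.channel_names) != values.shape[1]:
            raise DataValidationError(
                f"{len(self.channel_names)} channel names for {values.shape[1]} channels"
            )
        self.values = values

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def J(self) -> int:
        return self.values.shape[1]


def as_timeseries(data) -> TimeSeriesMatrix:
    """Coerce a :class:`TimeSeriesMatrix` or array-like into a validated matrix."""
    if isinstance(data, TimeSeriesMatrix):
        return data
    return TimeSeriesMatrix(np.asarray(data, dtype=float))


@dataclass
class SparsityMask:
    """Binary indicator of the free (non-zero) Gaussian parameters.

    The parameter vector of a ``J``-channel Gaussian block stacks the mean
    with the upper triangle (diagonal included) of the covariance, giving
    ``(J + 1)(J + 2) / 2`` entries in total.  Variances are never pruned, so
    the covariance-mask diagonal is always 1.
    """

    mean_mask: np.ndarray
    cov_mask: np.ndarray

    def __post_init__(self) -> None:
        self.mean_mask = np.asarray(self.mean_mask, dtype=bool)
        self.cov_mask = np.asarray(self.cov_mask, dtype=bool)
        if self.mean_mask.ndim != 1 or self.cov_mask.ndim != 2:
            raise DataValidationError("mean mask must be 1-D and covariance mask 2-D")
        j = self.mean_mask.shape[0]
        if self.cov_mask.shape != (j, j):
            raise DataValidationError(
                f"covariance mask shape {self.cov_mask.shape} does not match J={j}"
            )
        if not np.array_equal(self.cov_mask, self.cov_mask.T):
            raise DataValidationError("covariance mask must be symmetric")
        if not np.diag(self.cov_mask).all():
            raise DataValidationError("covariance mask diagonal must be all ones")

    @property
    def J(self) -> int:
        return self.mean_mask.shape[0]

    @property
    def n_free(self) -> int:
        """Number of free parameters: kept means + kept upper-triangle entries."""
        iu = np.triu_indices(self.J)
        return int(self.mean_mask.sum()) + int(self.cov_mask[iu].sum())

    def intersect(self, other: "SparsityMask") -> "SparsityMask":
        """Element-wise AND with another mask (parent-structure inheritance)."""
        return SparsityMask(
            self.mean_mask & other.mean_mask, self.cov_mask & other.cov_mask
        )

    @classmethod
    def full(cls, j: int) -> "SparsityMask":
        """All-ones mask: every parameter free."""
        return cls(np.ones(j, dtype=bool), np.ones((j, j), dtype=bool))


@dataclass
class ElementStat:
    """Outcome of the z-test for one covariance element.

    ``var_hat`` is the estimated variance of the element *estimator*, i.e. on
    the :math:`\\hat\\delta^2 / T` scale, so that ``z_stat`` equals
    ``|sigma_hat| / sqrt(var_hat)`` whenever ``var_hat > 0``.
    """

    i: int
    j: int
    sigma_hat: float
    var_hat: float
    z_stat: float
    reject: bool


@dataclass
class GaussianSegmentParams:
    """Sparse Gaussian parameters ``(mean, cov, mask)`` for one time segment.

    ``start`` and ``end`` are 1-based inclusive time indices into the parent
    series.  Every parameter at a masked-out position is exactly zero.
    """

    mean: np.ndarray
    cov: np.ndarray
    mask: SparsityMask
    start: int = 1
    end: int | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        j = self.mean.shape[0]
        if self.cov.shape != (j, j):
            raise DataValidationError("covariance shape does not match mean length")
        if not np.allclose(self.cov, self.cov.T, atol=1e-12, rtol=1e-10):
            raise DataValidationError("covariance must be symmetric")
        if np.any(self.mean[~self.mask.mean_mask] != 0.0):
            raise DataValidationError("masked-out mean entries must be exactly zero")
        if np.any(self.cov[~self.mask.cov_mask] != 0.0):
            raise DataValidationError("masked-out covariance entries must be exactly zero")

    @property
    def J(self) -> int:
        return self.mean.shape[0]


# ---------------------------------------------------------------------------
# Moment estimators
# ---------------------------------------------------------------------------


def empirical_moments(data) -> tuple[np.ndarray, np.ndarray]:
    """Column means and ML covariance matrix (divisor ``T``) of a segment.

    Returns the pair ``(mean, cov)``; ``cov`` is exactly symmetric.
    """
    ts = as_timeseries(data)
    if ts.T < 2:
        raise DataValidationError(f"need at least 2 time points, got {ts.T}")
    y = ts.values
    mean = y.mean(axis=0)
    c = y - mean
    cov = c.T @ c / ts.T
    cov = (cov + cov.T) / 2.0
    return mean, cov


def element_variance(data, mean, i: int, j: int) -> float:
    """CLT variance estimate for one covariance element.

    Forms the cross-product series ``X_t = (y_i(t) - mu_i)(y_j(t) - mu_j)``
    and returns its empirical variance ``(1/T) sum (X_t - Xbar)^2``, the
    plug-in for :math:`\\delta_{ij}^2` in the asymptotic normal law
    :math:`\\sqrt{T}(\\hat\\Sigma_{ij} - \\Sigma_{ij}) \\to N(0, \\delta_{ij}^2)`.
    """
    ts = as_timeseries(data)
    mean = np.asarray(mean, dtype=float)
    if not (0 <= i < ts.J and 0 <= j < ts.J):
        raise DataValidationError(f"channel index out of range: ({i}, {j}) with J={ts.J}")
    x = (ts.values[:, i] - mean[i]) * (ts.values[:, j] - mean[j])
    return float(np.mean((x - x.mean()) ** 2))


def _element_variances(y: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """CLT variance estimates for all element pairs at once (J x J)."""
    t = y.shape[0]
    c = y - mean
    sig = c.T @ c / t
    c2 = c * c
    second = c2.T @ c2 / t  # E[X^2] for every pair
    d2 = second - sig**2
    return np.maximum(d2, 0.0)


def jackknife_element_variance(data, i: int, j: int) -> float:
    """Delete-1 jackknife variance of the covariance-element estimator.

    Recomputes the ML covariance element on every leave-one-out sample and
    returns ``(T-1)/T * sum (theta_(t) - theta_bar)^2``.  Asymptotically
    agrees with the CLT plug-in ``delta^2 / T``.
    """
    loo = _jackknife_loo_elements(as_timeseries(data), i, j)
    t = loo.shape[0]
    return float((t - 1) / t * np.sum((loo - loo.mean()) ** 2))


def _jackknife_loo_elements(ts: TimeSeriesMatrix, i: int, j: int) -> np.ndarray:
    """Leave-one-out covariance-element estimates (length-T vector)."""
    if ts.T < 3:
        raise DataValidationError(f"jackknife requires T >= 3, got T={ts.T}")
    yi, yj = ts.values[:, i], ts.values[:, j]
    t = ts.T
    si, sj, sp = yi.sum(), yj.sum(), (yi * yj).sum()
    mi = (si - yi) / (t - 1)
    mj = (sj - yj) / (t - 1)
    return (sp - yi * yj) / (t - 1) - mi * mj


def _jackknife_variances(y: np.ndarray) -> np.ndarray:
    """Jackknife variances of all covariance elements (J x J), vectorised."""
    t, j = y.shape
    if t < 3:
        raise DataValidationError(f"jackknife requires T >= 3, got T={t}")
    s = y.sum(axis=0)
    p = y.T @ y
    m_loo = (s[None, :] - y) / (t - 1)  # T x J leave-one-out means
    # T x J x J leave-one-out covariance elements
    loo = (p[None, :, :] - y[:, :, None] * y[:, None, :]) / (t - 1) - (
        m_loo[:, :, None] * m_loo[:, None, :]
    )
    dev = loo - loo.mean(axis=0)
    return (t - 1) / t * np.einsum("tij,tij->ij", dev, dev)


# ---------------------------------------------------------------------------
# Adaptive thresholding
# ---------------------------------------------------------------------------


def _adjusted_eta(eta: float, multiplicity: str, j: int, n_tested: int) -> float:
    if not 0.0 < eta < 1.0:
        raise DataValidationError(f"eta must be in (0, 1), got {eta}")
    if multiplicity == "none":
        return eta
    if multiplicity == "eta-over-J":
        return eta / j
    if multiplicity == "bonferroni":
        return eta / max(n_tested, 1)
    raise DataValidationError(
        f"unknown multiplicity mode {multiplicity!r}; choose from {MULTIPLICITY_MODES}"
    )


def threshold_covariance(
    data,
    mean: np.ndarray | None = None,
    eta: float = 0.05,
    multiplicity: str = "eta-over-J",
    variance_method: str = "clt",
) -> tuple[np.ndarray, np.ndarray, list[ElementStat]]:
    """Sparse covariance estimate by element-wise z-tests.

    For every off-diagonal pair the hypothesis ``Sigma_ij = 0`` is tested at
    level ``eta*`` (the requested ``eta`` adjusted per the ``multiplicity``
    mode) by comparing ``sqrt(T) |Sigma_hat_ij| / delta_hat_ij`` against the
    two-sided normal quantile.  Elements that fail to reject are set exactly
    to zero.  Diagonal variances are never tested and always kept.

    Returns ``(sparse covariance, covariance mask, element statistics)``.
    """
    ts = as_timeseries(data)
    if ts.T < 2:
        raise DataValidationError(f"need at least 2 time points, got {ts.T}")
    y = ts.values
    t, j = ts.T, ts.J
    if mean is None:
        mean = y.mean(axis=0)
    mean = np.asarray(mean, dtype=float)

    c = y - mean
    sig = c.T @ c / t
    sig = (sig + sig.T) / 2.0

    if variance_method == "clt":
        var_est = _element_variances(y, mean) / t
    elif variance_method == "jackknife":
        var_est = _jackknife_variances(y)
    else:
        raise DataValidationError(
            f"unknown variance method {variance_method!r}; choose from {VARIANCE_METHODS}"
        )

    n_tested = j * (j - 1) // 2
    eta_star = _adjusted_eta(eta, multiplicity, j, n_tested)
    crit = stats.norm.ppf(1.0 - eta_star / 2.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(sig) / np.sqrt(var_est)

    reject = np.zeros((j, j), dtype=bool)
    positive = var_est > 0
    reject[positive] = z[positive] > crit
    # Degenerate variance estimate: an exactly non-zero element with zero
    # estimated sampling variance is infinitely significant; a zero element
    # stays zero.
    degenerate = ~positive & (sig != 0.0)
    if degenerate.any():
        reject |= degenerate
        logger.info(
            "%d covariance elements had zero variance estimate with non-zero "
            "value; kept as infinitely significant",
            int(np.count_nonzero(np.triu(degenerate, k=1))),
        )
    if np.any(~positive & (sig == 0.0)):
        logger.info("degenerate zero-variance, zero-value covariance elements kept at 0")

    mask = reject | reject.T
    np.fill_diagonal(mask, True)

    sparse = np.where(mask, sig, 0.0)
    sparse = np.where(mask, (sparse + sparse.T) / 2.0, 0.0)

    elements = []
    for a in range(j):
        for b in range(a + 1, j):
            zval = float(z[a, b]) if positive[a, b] else (np.inf if sig[a, b] != 0 else 0.0)
            elements.append(
                ElementStat(
                    i=a,
                    j=b,
                    sigma_hat=float(sig[a, b]),
                    var_hat=float(var_est[a, b]),
                    z_stat=zval,
                    reject=bool(mask[a, b]),
                )
            )
    return sparse, mask, elements


def threshold_mean(
    data,
    cov: np.ndarray | None = None,
    eta: float = 0.05,
    multiplicity: str = "eta-over-J",
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse mean estimate: keep element ``j`` iff its z-test rejects zero.

    The variance of each sample-mean element is estimated by the matching
    diagonal element of the (supplied or empirical) covariance matrix, so the
    statistic is ``sqrt(T) |mu_hat_j| / sqrt(Sigma_hat_jj)``.

    Returns ``(sparse mean, mean mask)``.
    """
    ts = as_timeseries(data)
    if ts.T < 2:
        raise DataValidationError(f"need at least 2 time points, got {ts.T}")
    mu = ts.values.mean(axis=0)
    if cov is None:
        _, cov = empirical_moments(ts)
    diag = np.asarray(np.diag(cov), dtype=float)

    eta_star = _adjusted_eta(eta, multiplicity, ts.J, ts.J)
    crit = stats.norm.ppf(1.0 - eta_star / 2.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.sqrt(ts.T) * np.abs(mu) / np.sqrt(diag)

    keep = np.zeros(ts.J, dtype=bool)
    positive = diag > 0
    keep[positive] = z[positive] > crit
    degenerate = ~positive & (mu != 0.0)
    if degenerate.any():
        keep |= degenerate
        logger.info(
            "%d mean elements with zero variance and non-zero value kept",
            int(degenerate.sum()),
        )
    return np.where(keep, mu, 0.0), keep


def estimate_sparse_params(
    data,
    eta: float = 0.05,
    multiplicity: str = "eta-over-J",
    variance_method: str = "clt",
    start: int = 1,
    end: int | None = None,
) -> GaussianSegmentParams:
    """Full sparse Gaussian fit of a segment: thresholded mean and covariance.

    Combines :func:`threshold_mean` and :func:`threshold_covariance` on the
    same segment; the covariance tests centre the cross-products at the
    segment sample mean (plug-in).
    """
    ts = as_timeseries(data)
    mean_raw, cov_raw = empirical_moments(ts)
    sparse_mean, mean_mask = threshold_mean(ts, cov_raw, eta, multiplicity)
    sparse_cov, cov_mask, _ = threshold_covariance(
        ts, mean_raw, eta, multiplicity, variance_method
    )
    return GaussianSegmentParams(
        mean=sparse_mean,
        cov=sparse_cov,
        mask=SparsityMask(mean_mask, cov_mask),
        start=start,
        end=ts.T if end is None else end,
    )
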