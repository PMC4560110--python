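"""Recursive likelihood-based binary segmentation with sparsity-mask inheritance.

A multivariate Gaussian series is split at the candidate time point that
maximises the combined log-likelihood of the two halves, with both halves
fitted under the parent segment's sparsity mask.  The candidate is accepted
only if a family of Welch two-sample t-tests -- one per free parameter,
Bonferroni-corrected -- rejects equality of the parameters on the two
sides.  Accepted splits recurse into both children, each child inheriting
the parent mask, until no further significant split is found.  Finally a
connectivity graph (thresholded covariance adjacency) is estimated for each
terminal segment.

Time indices are 1-based and inclusive throughout: a change point ``t``
splits a segment into ``{1..t}`` and ``{t+1..T}`` in local coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DataValidationError, SingularCovarianceError
from .likelihood import masked_mle, repair_psd
from .sparse_estimation import (
    GaussianSegmentParams,
    SparsityMask,
    TimeSeriesMatrix,
    _element_variances,
    as_timeseries,
    estimate_sparse_params,
    threshold_covariance,
)

__all__ = [
    "DetectionConfig",
    "SplitDecision",
    "SegmentationResult",
    "min_segment_length",
    "find_candidate_split",
    "split_significance_test",
    "detect_change_points",
    "estimate_segment_graphs",
]


# ---------------------------------------------------------------------------
# Configuration and result types
# ---------------------------------------------------------------------------


@dataclass
class DetectionConfig:
    """Tuning parameters of the detector.

    Parameters
    ----------
    alpha
        Type-I error bound for the split-significance tests (family-wise,
        via Bonferroni over the free parameters).
    beta
        Type-II error bound entering the minimum-segment-length power
        analysis.
    eta
        Level for the element-wise sparsity tests.
    effect_size
        Standardised mean difference ``d`` assumed by the power analysis
        that converts ``(alpha, beta)`` into the minimum segment length.
    delta_override
        Explicit minimum segment length; bypasses the power analysis.
    multiplicity
        Adjustment mode for the sparsity tests ("none", "eta-over-J",
        "bonferroni").
    variance_method
        Variance estimator for covariance elements ("clt" or "jackknife").
    split_variance
        Where the Welch denominators of the split tests are estimated:
        "node" (default) plugs in the element variances of the whole segment
        being split; "segment" estimates them separately on each child.
        The node-level plug-in keeps the family-wise level of the tests
        accurate at splits close to the minimum segment length, where the
        child-level fourth-moment estimates are noisy and correlated with
        the tested differences.
    seed
        Seed for any randomised component; the detection scan itself is
        deterministic, so this only matters for downstream consumers.
    graph_estimator
        Optional callable ``(segment values) -> adjacency`` used in place of
        adaptive thresholding for per-segment graphs (e.g. an external
        GLASSO solver).
    """

    alpha: float = 0.05
    beta: float = 0.1
    eta: float = 0.05
    effect_size: float = 0.65
    delta_override: int | None = None
    multiplicity: str = "eta-over-J"
    variance_method: str = "clt"
    split_variance: str = "node"
    seed: int = 0
    graph_estimator: object | None = None

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "eta"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise DataValidationError(f"{name} must be in (0, 1), got {value}")
        if self.effect_size <= 0:
            raise DataValidationError(f"effect_size must be positive, got {self.effect_size}")
        if self.delta_override is not None and self.delta_override < 2:
            raise DataValidationError("delta_override must be at least 2")
        if self.split_variance not in ("node", "segment"):
            raise DataValidationError(
                f"split_variance must be 'node' or 'segment', got {self.split_variance!r}"
            )

    @property
    def delta(self) -> int:
        if self.delta_override is not None:
            return self.delta_override
        return min_segment_length(self.alpha, self.beta, self.effect_size)


@dataclass
class SplitDecision:
    """A candidate split: its location, likelihood gain, and test outcome.

    ``t0`` is in the local 1-based coordinates of the segment being split
    (``None`` when no candidate exists).  ``gain`` is ``L_t0 - L0``.
    """

    t0: int | None
    gain: float
    significant: bool = False
    per_param_p: dict[str, float] = field(default_factory=dict)
    n_tests: int = 0

    @property
    def has_candidate(self) -> bool:
        return self.t0 is not None and self.gain > 0.0


@dataclass
class SegmentationResult:
    """Ordered change points, per-segment sparse parameters, and graphs."""

    change_points: list[int]
    segments: list[GaussianSegmentParams]
    tree: list[dict]
    graphs: list[np.ndarray] = field(default_factory=list)
    delta: int = 2
    channel_names: list[str] | None = None


# ---------------------------------------------------------------------------
# Minimum segment length (two-sample power analysis)
# ---------------------------------------------------------------------------


def min_segment_length(alpha: float, beta: float, effect_size: float) -> int:
    """Minimum partition length from a two-sample t-test power analysis.

    Uses the normal-approximation sample-size formula

        Delta = ceil( 2 (z_{1-alpha/2} + z_{1-beta})^2 / d^2 ),

    the per-group size needed to detect a standardised mean difference ``d``
    with the requested error bounds, floored at 2 (the smallest segment on
    which moments are estimable).
    """
    if not 0.0 < alpha < 1.0 or not 0.0 < beta < 1.0:
        raise DataValidationError("alpha and beta must be in (0, 1)")
    if effect_size <= 0:
        raise DataValidationError(f"effect_size must be positive, got {effect_size}")
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    zb = stats.norm.ppf(1.0 - beta)
    delta = math.ceil(2.0 * (za + zb) ** 2 / effect_size**2)
    return max(delta, 2)


# ---------------------------------------------------------------------------
# Likelihood machinery on running moments
# ---------------------------------------------------------------------------


def _loglik_from_moments(
    p: np.ndarray, s: np.ndarray, n: float, mask: SparsityMask
) -> float:
    """Masked-MLE log-likelihood of a segment from its raw moments.

    ``p`` is ``sum_t y y'``, ``s`` is ``sum_t y`` and ``n`` the segment
    length.  Returns the proportional log-likelihood of the segment under
    the Hadamard-masked ML fit, repairing the masked covariance when it is
    not positive definite.
    """
    m = s / n
    cov = p / n - np.outer(m, m)
    cov = (cov + cov.T) / 2.0
    mu = np.where(mask.mean_mask, m, 0.0)
    sig = np.where(mask.cov_mask, cov, 0.0)
    d = m - mu
    scatter = cov + np.outer(d, d)
    sign, logdet = np.linalg.slogdet(sig)
    if sign <= 0:
        sig = repair_psd(sig)
        sign, logdet = np.linalg.slogdet(sig)
        if sign <= 0:
            raise SingularCovarianceError("masked covariance singular after repair")
    trace = float(np.trace(np.linalg.solve(sig, scatter)))
    return -n * (trace + logdet)


def _stacked_logliks(
    p: np.ndarray, s: np.ndarray, n: np.ndarray, mask: SparsityMask
) -> np.ndarray:
    """Vectorised masked log-likelihoods for a stack of segments.

    ``p`` is ``(k, J, J)`` raw second moments, ``s`` ``(k, J)`` raw sums and
    ``n`` the ``(k,)`` segment lengths.  Segments whose masked covariance is
    not positive definite fall back to the scalar path with spectrum repair;
    irreparable ones get ``-inf`` so they are never selected as candidates.
    """
    nn = n[:, None, None]
    m = s / n[:, None]
    cov = p / nn - m[:, :, None] * m[:, None, :]
    cov = (cov + cov.transpose(0, 2, 1)) / 2.0
    sig = np.where(mask.cov_mask[None, :, :], cov, 0.0)
    d = np.where(mask.mean_mask[None, :], 0.0, m)
    scatter = cov + d[:, :, None] * d[:, None, :]

    sign, logdet = np.linalg.slogdet(sig)
    values = np.full(n.shape[0], -np.inf)
    ok = sign > 0
    if ok.any():
        try:
            solved = np.linalg.solve(sig[ok], scatter[ok])
        except np.linalg.LinAlgError:
            ok = np.zeros_like(ok)
        else:
            trace = np.einsum("kii->k", solved)
            values[ok] = -n[ok] * (trace + logdet[ok])
    for idx in np.nonzero(~ok)[0]:
        try:
            repaired = repair_psd(sig[idx])
            sgn, ld = np.linalg.slogdet(repaired)
            if sgn <= 0:
                continue
            trace = float(np.trace(np.linalg.solve(repaired, scatter[idx])))
            values[idx] = -n[idx] * (trace + ld)
        except (SingularCovarianceError, np.linalg.LinAlgError):
            continue
    return values


def find_candidate_split(segment_data, mask: SparsityMask, delta: int) -> SplitDecision:
    """Best candidate split of a segment under the inherited mask.

    Evaluates ``L_t = L(theta_1t | Y1) + L(theta_2t | Y2)`` for every
    ``t in [delta, T - delta]``, with both child fits Hadamard-masked by the
    parent mask, and returns the argmax together with its gain over the
    whole-segment baseline ``L0`` (fitted under the same mask).  A gain
    ``<= 0``, or a segment shorter than ``2 * delta``, signals "no
    candidate".  Ties in the argmax break to the smallest ``t``.
    """
    ts = as_timeseries(segment_data)
    y = ts.values
    n, j = y.shape
    if delta < 2:
        raise DataValidationError(f"delta must be at least 2, got {delta}")
    if n < 2 * delta:
        return SplitDecision(t0=None, gain=-np.inf, n_tests=mask.n_free)

    total_p = y.T @ y
    total_s = y.sum(axis=0)
    l0 = _loglik_from_moments(total_p, total_s, float(n), mask)

    cum_s = np.cumsum(y, axis=0)
    cum_p = np.cumsum(y[:, :, None] * y[:, None, :], axis=0)

    t_grid = np.arange(delta, n - delta + 1)
    n1 = t_grid.astype(float)
    n2 = n - n1
    s1 = cum_s[t_grid - 1]
    p1 = cum_p[t_grid - 1]
    l1 = _stacked_logliks(p1, s1, n1, mask)
    l2 = _stacked_logliks(total_p[None] - p1, total_s[None] - s1, n2, mask)

    gains = l1 + l2 - l0
    best = int(np.argmax(gains))  # first occurrence: smallest t wins ties
    gain = float(gains[best])
    if not np.isfinite(gain):
        return SplitDecision(t0=None, gain=-np.inf, n_tests=mask.n_free)
    return SplitDecision(t0=int(t_grid[best]), gain=gain, n_tests=mask.n_free)


# ---------------------------------------------------------------------------
# Split significance test
# ---------------------------------------------------------------------------


def _welch(diff: float, v1: float, v2: float, n1: int, n2: int) -> tuple[float, float] | None:
    """Welch statistic and two-sided p-value; None when degenerate."""
    denom = v1 + v2
    if denom <= 0 or n1 < 2 or n2 < 2:
        return None
    stat = diff / math.sqrt(denom)
    df = denom**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    if not np.isfinite(df) or df <= 0:
        return None
    p = 2.0 * float(stats.t.sf(abs(stat), df))
    return stat, p


def split_significance_test(
    left: GaussianSegmentParams,
    right: GaussianSegmentParams,
    left_T: int,
    right_T: int,
    mask: SparsityMask,
    alpha: float,
    *,
    left_data=None,
    right_data=None,
    pooling: str = "node",
) -> SplitDecision:
    """Welch t-tests of parameter equality across a candidate split.

    Each masked-in parameter is tested separately: mean element ``j`` via
    ``(mu1_j - mu2_j) / sqrt(Sigma_jj/T1 + Sigma_jj/T2)`` and covariance
    element ``(i, j)`` via the analogous contrast with the CLT element
    variances ``delta^2_ij`` in the denominators.  Degrees of freedom
    follow Welch-Satterthwaite.  The split is significant iff any two-sided
    p-value falls below ``alpha / sum(mask)`` (Bonferroni over the free
    parameters).

    With ``pooling="node"`` (default) the variance plug-ins
    (``Sigma_jj``, ``delta^2_ij``) are estimated once on the concatenated
    segment being split; with ``pooling="segment"`` each child supplies its
    own.  The node-level plug-ins are stable even when one child sits at
    the minimum segment length, where child-level fourth-moment estimates
    are noisy, skewed, and correlated with the tested difference -- which
    would inflate the far-tail rejection rate well above ``alpha``.

    ``left_data`` and ``right_data`` (the two child segments) are required
    to form the variance estimates.
    """
    if left_data is None or right_data is None:
        raise DataValidationError(
            "split_significance_test requires the child segment data to "
            "estimate covariance-element variances"
        )
    if pooling not in ("node", "segment"):
        raise DataValidationError(
            f"pooling must be 'node' or 'segment', got {pooling!r}"
        )
    yl = as_timeseries(left_data).values
    yr = as_timeseries(right_data).values
    if pooling == "node":
        y = np.vstack([yl, yr])
        mean = y.mean(axis=0)
        d2 = _element_variances(y, mean)
        c = y - mean
        var_diag = np.einsum("tj,tj->j", c, c) / y.shape[0]
        d2l = d2r = d2
        var_l = var_r = var_diag
    else:
        d2l = _element_variances(yl, yl.mean(axis=0))
        d2r = _element_variances(yr, yr.mean(axis=0))
        var_l = np.diag(left.cov)
        var_r = np.diag(right.cov)

    n_tests = mask.n_free
    threshold = alpha / max(n_tests, 1)
    pvals: dict[str, float] = {}

    for j in np.nonzero(mask.mean_mask)[0]:
        res = _welch(
            float(left.mean[j] - right.mean[j]),
            float(var_l[j]) / left_T,
            float(var_r[j]) / right_T,
            left_T,
            right_T,
        )
        if res is None:
            continue
        pvals[f"mu[{j + 1}]"] = res[1]

    iu = np.triu_indices(mask.J)
    for a, b in zip(*iu):
        if not mask.cov_mask[a, b]:
            continue
        res = _welch(
            float(left.cov[a, b] - right.cov[a, b]),
            float(d2l[a, b]) / left_T,
            float(d2r[a, b]) / right_T,
            left_T,
            right_T,
        )
        if res is None:
            continue
        pvals[f"sigma[{a + 1},{b + 1}]"] = res[1]

    significant = bool(pvals) and min(pvals.values()) < threshold
    return SplitDecision(
        t0=None,
        gain=float("nan"),
        significant=significant,
        per_param_p=pvals,
        n_tests=n_tests,
    )


# ---------------------------------------------------------------------------
# Recursive detection
# ---------------------------------------------------------------------------


def detect_change_points(data, config: DetectionConfig | None = None) -> SegmentationResult:
    """Recursive binary change-point search over the full series.

    Depth-first, left child first.  Each node (a) fits a sparse Gaussian to
    its segment and intersects the mask with the inherited parent mask,
    (b) scans for the best-candidate split under that mask, (c) accepts the
    candidate only if the Welch/Bonferroni parameter tests reject equality
    of the two children, and (d) recurses into both children with the
    node's mask as their parent mask.  Segments shorter than ``2 * delta``
    are terminal.  After the recursion, a connectivity graph is estimated
    for every terminal segment (without mask inheritance).
    """
    if config is None:
        config = DetectionConfig()
    ts = as_timeseries(data)
    if ts.T < 2:
        raise DataValidationError(f"need at least 2 time points, got T={ts.T}")
    delta = config.delta

    change_points: list[int] = []
    segments: list[GaussianSegmentParams] = []
    tree: list[dict] = []

    def recurse(a: int, b: int, parent_mask: SparsityMask | None, parent_node: int | None) -> None:
        seg = TimeSeriesMatrix(ts.values[a - 1 : b])
        n = b - a + 1
        params = estimate_sparse_params(
            seg,
            eta=config.eta,
            multiplicity=config.multiplicity,
            variance_method=config.variance_method,
            start=a,
            end=b,
        )
        mask = params.mask if parent_mask is None else params.mask.intersect(parent_mask)
        params = masked_mle(seg, mask, start=a, end=b)

        node = {
            "start": a,
            "end": b,
            "parent": parent_node,
            "mask_mean": mask.mean_mask.copy(),
            "mask_cov": mask.cov_mask.copy(),
            "n_free": mask.n_free,
            "t0": None,
            "gain": None,
            "tested": False,
            "significant": False,
            "min_p": None,
            "n_tests": mask.n_free,
        }
        node_idx = len(tree)
        tree.append(node)

        if n >= 2 * delta:
            cand = find_candidate_split(seg, mask, delta)
            if cand.has_candidate:
                t0 = cand.t0
                node["t0"] = a + t0 - 1
                node["gain"] = cand.gain
                left_seg = TimeSeriesMatrix(seg.values[:t0])
                right_seg = TimeSeriesMatrix(seg.values[t0:])
                left_params = masked_mle(left_seg, mask, start=a, end=a + t0 - 1)
                right_params = masked_mle(right_seg, mask, start=a + t0, end=b)
                decision = split_significance_test(
                    left_params,
                    right_params,
                    t0,
                    n - t0,
                    mask,
                    config.alpha,
                    left_data=left_seg,
                    right_data=right_seg,
                    pooling=config.split_variance,
                )
                node["tested"] = True
                node["significant"] = decision.significant
                node["min_p"] = min(decision.per_param_p.values()) if decision.per_param_p else None
                if decision.significant:
                    cp = a + t0 - 1
                    change_points.append(cp)
                    recurse(a, cp, mask, node_idx)
                    recurse(cp + 1, b, mask, node_idx)
                    return
            elif cand.t0 is not None:
                node["t0"] = a + cand.t0 - 1
                node["gain"] = cand.gain

        segments.append(params)

    recurse(1, ts.T, None, None)
    change_points.sort()

    result = SegmentationResult(
        change_points=change_points,
        segments=segments,
        tree=tree,
        delta=delta,
        channel_names=ts.channel_names,
    )
    result.graphs = estimate_segment_graphs(
        result,
        ts,
        eta=config.eta,
        multiplicity=config.multiplicity,
        graph_estimator=config.graph_estimator,
    )
    return result


def estimate_segment_graphs(
    result: SegmentationResult,
    data,
    eta: float = 0.05,
    multiplicity: str = "eta-over-J",
    graph_estimator=None,
) -> list[np.ndarray]:
    """Binary connectivity adjacency for every terminal segment.

    Re-runs covariance thresholding on each segment's own data -- without
    mask inheritance -- and emits an edge wherever the off-diagonal estimate
    is non-zero.  Self-loops are excluded.  A custom ``graph_estimator``
    callable (segment values -> adjacency) replaces the thresholding step,
    which is how an external precision-matrix solver can be plugged in.
    """
    ts = as_timeseries(data)
    graphs: list[np.ndarray] = []
    for params in result.segments:
        seg = ts.values[params.start - 1 : params.end]
        if graph_estimator is not None:
            adj = np.asarray(graph_estimator(seg))
            adj = (adj != 0).astype(int)
        else:
            _, cov_mask, _ = threshold_covariance(seg, eta=eta, multiplicity=multiplicity)
            adj = cov_mask.astype(int)
        np.fill_diagonal(adj, 0)
        adj = ((adj + adj.T) > 0).astype(int)
        graphs.append(adj)
    return graphs
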