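"""Piecewise-stationary multivariate Gaussian simulator.

Generates multi-subject ROI x time data in which the mean vector and
covariance matrix are constant within segments and switch at user-specified
change points.  Segment dependence can be specified either as covariance
matrices or as precision matrices (inverted once per segment); optional
global spike artifacts imitate the sudden whole-brain signal jumps common
in fMRI recordings.

The built-in scenarios reproduce the sizes and change-point layouts of a
standard battery of connectivity-change benchmarks (20-80 channels, series
of length 200-1000, zero to five change points).  The exact dependency
strengths used in the original benchmarks are not published, so the
scenarios place blocks of connected channels with a configurable precision
off-diagonal (default 0.4) -- a documented reconstruction, not ground
truth.  Means are held at zero in every scenario segment; only the
covariance structure changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataValidationError
from .sparse_estimation import TimeSeriesMatrix

__all__ = [
    "SimulationSpec",
    "generate_piecewise_gaussian",
    "add_spikes",
    "builtin_scenarios",
    "SCENARIO_NAMES",
]


@dataclass
class SimulationSpec:
    """Specification of a piecewise-stationary Gaussian simulation.

    ``change_points`` are 1-based: change point ``t`` ends a segment at ``t``
    (inclusive).  Exactly one of ``covariances`` / ``precisions`` must be
    given per segment list; ``means`` defaults to all-zero vectors.
    ``spikes`` is an optional ``(count, magnitude)`` pair applied per
    subject at uniformly drawn time points.
    """

    n_subjects: int
    T: int
    J: int
    change_points: tuple[int, ...] = ()
    means: list[np.ndarray] | None = None
    covariances: list[np.ndarray] | None = None
    precisions: list[np.ndarray] | None = None
    spikes: tuple[int, float] | None = None
    spike_all_channels: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.T < 2 or self.J < 1:
            raise DataValidationError("need n_subjects >= 1, T >= 2, J >= 1")
        cps = tuple(int(c) for c in self.change_points)
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise DataValidationError("change points must be strictly increasing")
        if cps and (cps[0] < 1 or cps[-1] >= self.T):
            raise DataValidationError("change points must lie strictly inside (1, T)")
        self.change_points = cps
        n_seg = len(cps) + 1
        if (self.covariances is None) == (self.precisions is None):
            raise DataValidationError(
                "specify exactly one of covariances or precisions"
            )
        mats = self.covariances if self.covariances is not None else self.precisions
        if len(mats) != n_seg:
            raise DataValidationError(
                f"{len(mats)} segment matrices for {n_seg} segments"
            )
        if self.means is not None and len(self.means) != n_seg:
            raise DataValidationError(f"{len(self.means)} mean vectors for {n_seg} segments")

    @property
    def n_segments(self) -> int:
        return len(self.change_points) + 1

    def segment_bounds(self) -> list[tuple[int, int]]:
        """1-based inclusive (start, end) bounds of every segment."""
        edges = (0,) + self.change_points + (self.T,)
        return [(a + 1, b) for a, b in zip(edges, edges[1:])]


def _segment_covariances(spec: SimulationSpec) -> list[np.ndarray]:
    """Per-segment covariance matrices, inverting precisions when supplied."""
    out = []
    source = spec.covariances if spec.covariances is not None else spec.precisions
    for k, mat in enumerate(source):
        mat = np.asarray(mat, dtype=float)
        if mat.shape != (spec.J, spec.J):
            raise DataValidationError(
                f"segment {k + 1}: matrix shape {mat.shape} does not match J={spec.J}"
            )
        try:
            np.linalg.cholesky(mat)
        except np.linalg.LinAlgError:
            kind = "covariance" if spec.covariances is not None else "precision"
            raise DataValidationError(
                f"segment {k + 1}: {kind} matrix is not positive definite"
            ) from None
        cov = mat if spec.covariances is not None else np.linalg.inv(mat)
        out.append((cov + cov.T) / 2.0)
    return out


def generate_piecewise_gaussian(spec: SimulationSpec) -> list[TimeSeriesMatrix]:
    """Draw one ``T x J`` series per subject under the segment parameters.

    Observations are independent across time and subjects; each time point
    is drawn from its segment's ``N(mu, Sigma)``.  Spikes, when requested,
    are applied per subject with positions recorded on the returned
    matrices.  Output is reproducible under ``spec.seed``.
    """
    covs = _segment_covariances(spec)
    chols = [np.linalg.cholesky(c) for c in covs]
    means = spec.means
    if means is None:
        means = [np.zeros(spec.J)] * spec.n_segments
    means = [np.asarray(m, dtype=float) for m in means]

    rng = np.random.default_rng(spec.seed)
    bounds = spec.segment_bounds()
    subjects: list[TimeSeriesMatrix] = []
    for _ in range(spec.n_subjects):
        blocks = []
        for (a, b), chol, mu in zip(bounds, chols, means):
            z = rng.standard_normal((b - a + 1, spec.J))
            blocks.append(z @ chol.T + mu)
        ts = TimeSeriesMatrix(np.vstack(blocks))
        if spec.spikes is not None:
            count, magnitude = spec.spikes
            ts = add_spikes(
                ts, count, magnitude, rng=rng, all_channels=spec.spike_all_channels
            )
        subjects.append(ts)
    return subjects


def add_spikes(
    data,
    count: int,
    magnitude: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    all_channels: bool = True,
) -> TimeSeriesMatrix:
    """Add spike artifacts at ``count`` uniformly drawn time points.

    Each spiked row gets ``magnitude`` added to every channel (or to one
    random channel when ``all_channels`` is False).  Positions are drawn
    without replacement and recorded on the returned matrix's
    ``spike_times`` attribute (0-based, sorted).
    """
    if count < 0:
        raise DataValidationError(f"spike count must be non-negative, got {count}")
    ts = data if isinstance(data, TimeSeriesMatrix) else TimeSeriesMatrix(np.asarray(data, float))
    if count > ts.T:
        raise DataValidationError(f"cannot place {count} spikes in {ts.T} time points")
    if count == 0:
        return TimeSeriesMatrix(ts.values.copy(), ts.channel_names, np.array([], dtype=int))
    if rng is None:
        rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(ts.T, size=count, replace=False))
    values = ts.values.copy()
    if all_channels:
        values[positions, :] += magnitude
    else:
        cols = rng.integers(0, ts.J, size=count)
        values[positions, cols] += magnitude
    return TimeSeriesMatrix(values, ts.channel_names, positions)


# ---------------------------------------------------------------------------
# Built-in scenarios
# ---------------------------------------------------------------------------

SCENARIO_NAMES = ("sim1", "sim2", "sim3", "sim4", "sim5", "sim6", "sim2b", "sim4b")

#: (n_subjects, T, J, change_points, informative channels, spikes)
_SCENARIO_TABLE = {
    "sim1": (20, 1000, 20, (), 0, None),
    "sim2": (20, 1000, 20, (200, 400), 20, (5, 15.0)),
    "sim3": (15, 1000, 20, (125, 500, 750), 20, None),
    "sim4": (25, 200, 5, (100,), 5, None),
    "sim5": (20, 1000, 20, (200, 300, 500, 600, 800), 20, None),
    "sim6": (20, 1000, 20, (200, 400, 600, 800), 20, None),
    "sim2b": (50, 1000, 80, (200, 400), 20, (5, 15.0)),
    "sim4b": (50, 200, 70, (100,), 5, None),
}

_BLOCK_SIZE = 4


def _block_precision(j: int, informative: int, offset: int, strength: float) -> np.ndarray:
    """Identity precision with ``strength`` cliques of 4 over the informative channels.

    Blocks start at ``offset`` and tile the informative range; channels
    beyond ``informative`` stay white noise.  Shifting ``offset`` between
    segments changes which channels are connected.
    """
    omega = np.eye(j)
    start = offset
    while start < informative:
        stop = min(start + _BLOCK_SIZE, informative)
        block = np.arange(start, stop)
        if block.size > 1:
            for a in block:
                for b in block:
                    if a != b:
                        omega[a, b] = strength
        start = stop
    return omega


def builtin_scenarios(
    name: str,
    strength: float = 0.4,
    n_subjects: int | None = None,
    seed: int = 0,
) -> SimulationSpec:
    """Ready-made simulation specs matching the benchmark battery layouts.

    Sizes and change-point times follow the published battery; the
    per-segment dependency strengths are a reconstruction (precision blocks
    of four channels with off-diagonal ``strength``, rotated between
    segments so that neighbouring segments differ).  ``strength`` and
    ``n_subjects`` are overridable.
    """
    key = name.lower()
    if key not in _SCENARIO_TABLE:
        raise DataValidationError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    n, t, j, cps, informative, spikes = _SCENARIO_TABLE[key]
    if n_subjects is not None:
        n = n_subjects
    n_seg = len(cps) + 1
    precisions = []
    for s in range(n_seg):
        if informative == 0:
            precisions.append(np.eye(j))
        else:
            offset = (s * 2) % _BLOCK_SIZE
            precisions.append(_block_precision(j, informative, offset, strength))
    return SimulationSpec(
        n_subjects=n,
        T=t,
        J=j,
        change_points=cps,
        precisions=precisions,
        spikes=spikes,
        seed=seed,
    )
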