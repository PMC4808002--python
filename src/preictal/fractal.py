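"""Renyi entropies and generalized fractal dimensions of value distributions.

The value range of a series is divided into ``N = ceil((V_max - V_min) / dV)``
bins; the occupancy weights ``w_i = N_i / sum(N_i)`` define a probability
distribution.  (For a uniformly sampled series, the fraction of samples in a
bin equals the fraction of recording time spent there, so count- and
time-based weights coincide.)  The order-q Renyi entropy is

    E_q = log2(sum_i w_i^q) / (1 - q),        E_1 = -sum_i w_i log2 w_i,

and the order-q generalized dimension is the dV -> 0 scaling exponent of
-E_q against log2 dV, realised here as a log-log regression over a finite
geometric grid of bin sizes.  The dimension as a function of q is the
fractal spectrum; its range (left minus right end) measures multifractality
— zero for a self-similar series, wide for intermittent ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EEGRecord
from .hurst import Trajectory, _loglog_slope

__all__ = [
    "ProbabilityDistribution",
    "DimensionFit",
    "RenyiSpectrum",
    "bin_probabilities",
    "renyi_entropy",
    "generalized_dimension",
    "fractal_spectrum",
    "sliding_fd",
    "auto_delta_v_grid",
    "binomial_cascade_series",
    "binomial_cascade_dimension",
]


@dataclass(frozen=True)
class ProbabilityDistribution:
    """Bin structure and occupancy weights of a series' value range.

    Bins are left-closed/right-open with the final bin closed, so ties at
    ``v_max`` land in the last bin.
    """

    v_min: float
    v_max: float
    delta_v: float
    n_bins: int
    counts: np.ndarray
    weights: np.ndarray
    t_total: float

    def occupied(self) -> np.ndarray:
        """Weights of occupied bins only (zero-weight bins carry no entropy)."""
        return self.weights[self.weights > 0]


@dataclass(frozen=True)
class DimensionFit:
    """A generalized-dimension estimate with its regression diagnostic."""

    d: float
    r2: float
    q: float

    def __float__(self) -> float:
        return self.d


@dataclass
class RenyiSpectrum:
    """Dimensions and entropies on a q grid, plus the spectrum range."""

    q_grid: np.ndarray
    entropies: np.ndarray      # E_q at the finest grid scale, bits
    dimensions: np.ndarray
    fit_r2: np.ndarray
    delta_v_grid: np.ndarray

    @property
    def spectrum_range(self) -> float:
        """Dimension at the most negative q minus at the most positive q."""
        return float(self.dimensions[0] - self.dimensions[-1])


def bin_probabilities(series, delta_v: float, t_total: float | None = None
                      ) -> ProbabilityDistribution:
    """Histogram a series into bins of width ``delta_v``."""
    if delta_v <= 0:
        raise ValueError("delta_v must be positive")
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("series must hold at least one value")
    v_min, v_max = float(x.min()), float(x.max())
    span = v_max - v_min
    n_bins = max(1, int(np.ceil(span / delta_v - 1e-12)))
    # the top edge sits at v_min + n_bins*delta_v >= v_max, so numpy's
    # closed last bin realises the "ties at v_max land in the last bin" rule
    counts, _ = np.histogram(x, bins=n_bins,
                             range=(v_min, max(v_min + n_bins * delta_v, v_max)))
    weights = counts / counts.sum()
    return ProbabilityDistribution(
        v_min=v_min, v_max=v_max, delta_v=delta_v, n_bins=n_bins,
        counts=counts, weights=weights,
        t_total=float(t_total) if t_total is not None else float(x.size))


def renyi_entropy(dist: ProbabilityDistribution | np.ndarray, q: float) -> float:
    """Order-q Renyi entropy in bits; the Shannon limit is used at q = 1.

    Zero-weight bins are skipped at every order, which keeps E_q continuous
    in q (including through q = 0, where E_0 = log2 of the occupied count).
    """
    w = dist.occupied() if isinstance(dist, ProbabilityDistribution) \
        else np.asarray(dist, dtype=float)
    w = w[w > 0]
    if abs(q - 1.0) < 1e-9:
        return float(-np.sum(w * np.log2(w)))
    return float(np.log2(np.sum(w ** q)) / (1.0 - q))


def auto_delta_v_grid(series, n_scales: int = 8, coarsest_bins: int = 2,
                      finest_bins: int = 256) -> np.ndarray:
    """Geometric bin-size grid from span/coarsest to span/finest.

    The finest scale is capped at half the sample count so the smallest
    bins still average at least two samples.
    """
    x = np.asarray(series, dtype=float)
    span = np.ptp(x)
    finest = int(min(finest_bins, max(4, x.size // 2)))
    n_bins = np.unique(np.round(np.geomspace(coarsest_bins, finest, n_scales)).astype(int))
    return span / n_bins[::-1]  # increasing delta_v


def generalized_dimension(series, q: float, delta_v_grid=None,
                          min_count_negative_q: int = 2) -> DimensionFit:
    """Order-q generalized dimension from the bin-size scaling of -E_q.

    At negative q the partition sum is dominated by nearly empty bins, so
    bins holding fewer than ``min_count_negative_q`` samples are dropped
    there (variance control).  A series occupying a single bin at every
    scale (a constant) returns dimension 0 with an undefined diagnostic.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 8:
        raise ValueError("series too short for a dimension estimate")
    if np.ptp(x) == 0:
        return DimensionFit(d=0.0, r2=np.nan, q=q)
    if delta_v_grid is None:
        delta_v_grid = auto_delta_v_grid(x)
    delta_v_grid = np.asarray(delta_v_grid, dtype=float)
    if delta_v_grid.size < 4 or delta_v_grid.max() < 4 * delta_v_grid.min():
        raise ValueError("need >= 4 bin scales spanning >= 2 octaves")
    ys = []
    for dv in delta_v_grid:
        dist = bin_probabilities(x, dv)
        counts = dist.counts
        if q < 0:
            counts = counts[counts >= min_count_negative_q]
            w = counts / counts.sum()
        else:
            w = dist.weights
        ys.append(-renyi_entropy(w, q))
    slope, r2 = _loglog_slope(np.log2(delta_v_grid), np.asarray(ys))
    return DimensionFit(d=slope, r2=r2, q=q)


def fractal_spectrum(series, q_grid=None, delta_v_grid=None) -> RenyiSpectrum:
    """Generalized dimensions on a grid of orders (default -10..10, step 1)."""
    if q_grid is None:
        q_grid = np.arange(-10, 11, dtype=float)
    q_grid = np.asarray(q_grid, dtype=float)
    x = np.asarray(series, dtype=float)
    if delta_v_grid is None and np.ptp(x) > 0:
        delta_v_grid = auto_delta_v_grid(x)
    fits = [generalized_dimension(x, q, delta_v_grid) for q in q_grid]
    if np.ptp(x) == 0:
        entropies = np.zeros(q_grid.size)
        delta_v_grid = np.array([1.0])
    else:
        finest = bin_probabilities(x, float(np.min(delta_v_grid)))
        entropies = np.array([renyi_entropy(finest, q) for q in q_grid])
    return RenyiSpectrum(q_grid=q_grid,
                         entropies=entropies,
                         dimensions=np.array([f.d for f in fits]),
                         fit_r2=np.array([f.r2 for f in fits]),
                         delta_v_grid=np.asarray(delta_v_grid, dtype=float))


def binomial_cascade_series(levels: int = 7, p: float = 0.7,
                            total: int = 1_000_000) -> np.ndarray:
    """Multifractal benchmark: samples distributed as a binomial measure.

    The unit interval is split into ``2**levels`` dyadic cells; a cell
    whose binary address holds ``a`` zeros carries mass
    ``p**a * (1-p)**(levels-a)``.  The returned series visits each cell's
    left edge with multiplicity proportional to its mass (one sample of
    the last cell is placed at exactly 1.0 so the value range spans the
    full unit interval and dyadic bin grids align).  Its value
    distribution has the closed-form dimension spectrum of
    :func:`binomial_cascade_dimension`, making it an exact oracle for
    :func:`generalized_dimension`.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    n_cells = 2 ** levels
    addr = np.arange(n_cells)
    ones = np.array([bin(a).count("1") for a in addr])
    mass = p ** (levels - ones) * (1 - p) ** ones
    counts = np.maximum(np.round(mass * total).astype(int), 1)
    values = np.repeat(addr / n_cells, counts)
    values[-1] = 1.0  # close the range at the top cell
    return values


def binomial_cascade_dimension(q: float, p: float = 0.7) -> float:
    """Closed-form order-q dimension of the binomial measure."""
    if abs(q - 1.0) < 1e-9:
        return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))
    return float(np.log2(p ** q + (1 - p) ** q) / (1 - q))


def sliding_fd(record: EEGRecord, channel: int, window_s: float = 10.0,
               step_s: float = 1.0, q: float = 1.0,
               coarsest_bins: int = 2, finest_bins: int = 16) -> Trajectory:
    """Fractal-dimension trajectory of one channel over sliding windows.

    Per window the order-q dimension is fitted over a deliberately coarse
    bin grid (span/2 ... span/16 by default): a 10 s window holds only a
    few hundred samples, and finer bins are so sparsely occupied that their
    sampling noise drowns the regime changes the trajectory is meant to
    expose.  Estimates are floored at 0 (a constant window is dimension 0).
    """
    x = record.data[channel]
    win = int(round(window_s * record.fs))
    step = int(round(step_s * record.fs))
    if win > x.size:
        raise ValueError("window longer than record")
    if win < 64:
        raise ValueError("window must hold at least 64 samples")
    times, values, flags = [], [], []
    for start in range(0, x.size - win + 1, step):
        times.append((start + win / 2) / record.fs)
        chunk = x[start:start + win]
        if np.ptp(chunk) == 0:
            values.append(0.0)
            flags.append(False)
            continue
        grid = auto_delta_v_grid(chunk, coarsest_bins=coarsest_bins,
                                 finest_bins=finest_bins)
        fit = generalized_dimension(chunk, q, grid)
        values.append(max(fit.d, 0.0))
        flags.append(not np.isfinite(fit.r2))
    return Trajectory(times=np.array(times), values=np.array(values),
                      window_s=window_s, step_s=step_s,
                      measure_name=f"fd_q{q:g}",
                      flags=np.array(flags, dtype=bool))
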