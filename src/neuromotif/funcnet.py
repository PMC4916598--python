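"""Cross-covariance functional networks with surrogate thresholding.

Functional connectivity between neurons is measured as the lag-maximized
Pearson correlation (normalized cross-covariance) of their activity, with
the maximum taken over lags in [−max_lag, +max_lag] frames.  Edges are the
pairs whose correlation exceeds a data-driven threshold: a percentile of
the null distribution of pairwise lag-maxima obtained from circular-shift
surrogates, which preserve each trace's autocorrelation while destroying
cross-correlations.  Neuron identifiers are randomly permuted before any
pairwise computation and restored afterward, so no step can be biased by
the spatial ordering of neuron ids; surrogate shifts are keyed to neuron
identity, making the result invariant to input ordering.

The cell-level network is summarized against distance (binned correlation
profile) and at the population level (mean inter-population cell-pair
correlation and a thresholded population adjacency).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from neuromotif._errors import ValidationError

__all__ = [
    "FunctionalNetwork", "DistanceProfile", "PopulationFunctionalMatrix",
    "correlation_matrix", "build_functional_network", "distance_profile",
    "population_functional_matrix",
]


@dataclass
class FunctionalNetwork:
    """Cell-level correlation matrix with surrogate-thresholded adjacency."""

    correlation: np.ndarray
    adjacency: np.ndarray
    threshold: float
    n_surrogates: int
    percentile: float
    null_quantile: float
    max_lag: int
    neuron_ids: list[int]


@dataclass
class DistanceProfile:
    """Pairwise correlation binned by inter-soma distance."""

    bin_edges: np.ndarray      # μm, length n_bins + 1
    mean: np.ndarray
    sd: np.ndarray
    count: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(self.count.sum())


@dataclass
class PopulationFunctionalMatrix:
    """Mean inter-population cell-pair correlation and derived adjacency.

    ``matrix[(P, Q)]`` is the mean correlation over cell pairs (i ∈ P,
    j ∈ Q, i ≠ j); the diagonal holds mean intra-population correlation.
    ``adjacency`` applies ``cutoff`` to the off-diagonal entries.
    """

    populations: list[str]
    matrix: np.ndarray
    adjacency: np.ndarray
    cutoff: float


def _activity_matrix(activity) -> tuple[np.ndarray, list[int]]:
    if hasattr(activity, "dff"):
        return np.asarray(activity.dff, dtype=float), list(activity.neuron_ids)
    if hasattr(activity, "raster"):
        return (np.asarray(activity.raster, dtype=float),
                list(activity.neuron_ids))
    x = np.asarray(activity, dtype=float)
    return x, list(range(x.shape[0]))


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    out = np.zeros_like(x)
    ok = sd[:, 0] > 0
    out[ok] = (x[ok] - mean[ok]) / sd[ok]
    return out


def correlation_matrix(activity, max_lag: int = 5) -> np.ndarray:
    """Lag-maximized Pearson correlation between all pairs of traces.

    Entry (i, j) is the maximum over lags ℓ ∈ [−max_lag, max_lag] of the
    Pearson correlation between the lag-aligned overlapping segments of
    traces i and j.  Diagonal is 1; zero-variance traces correlate 0 with
    everything.  Accepts ΔF/F0 traces, a spike raster, or a plain
    (neurons × frames) array.
    """
    x, _ = _activity_matrix(activity)
    n, t_len = x.shape
    if n < 2:
        raise ValidationError("correlation_matrix needs >= 2 neurons")
    if t_len < 10:
        raise ValidationError("correlation_matrix needs >= 10 frames")
    if max_lag < 0:
        raise ValidationError("max_lag must be >= 0")
    if max_lag >= t_len - 1:
        raise ValidationError("max_lag too large for the trace length")
    if np.all(x.std(axis=1) == 0):
        warnings.warn("all traces constant: zero correlations", stacklevel=2)

    best = np.full((n, n), -np.inf)
    for lag in range(max_lag + 1):
        a = _zscore_rows(x[:, lag:])
        b = _zscore_rows(x[:, : t_len - lag]) if lag else a
        c = a @ b.T / (t_len - lag)
        np.maximum(best, c, out=best)
        np.maximum(best, c.T, out=best)
    best = np.clip(best, -1.0, 1.0)
    # zero-variance rows produce exact zeros against everything
    dead = x.std(axis=1) == 0
    best[dead, :] = 0.0
    best[:, dead] = 0.0
    np.fill_diagonal(best, 1.0)
    return best


def _surrogate_offsets(seed: int, surrogate: int, neuron_ids: list[int],
                       t_len: int) -> np.ndarray:
    """Per-neuron circular shifts, keyed to neuron identity (order-free)."""
    offs = np.empty(len(neuron_ids), dtype=int)
    for k, nid in enumerate(neuron_ids):
        r = np.random.default_rng(
            np.random.SeedSequence([int(seed), int(surrogate), int(nid)]))
        offs[k] = 1 + r.integers(t_len - 1)
    return offs


def build_functional_network(activity,
                             max_lag: int = 5,
                             n_surrogates: int = 20,
                             percentile: float = 99.0,
                             seed: int = 0) -> FunctionalNetwork:
    """Functional network with a circular-shift surrogate threshold.

    The threshold is the given percentile of the pooled null distribution
    of pairwise lag-maximized correlations across ``n_surrogates``
    surrogate datasets in which each neuron's series is independently
    circularly rotated.  Requires ``n_surrogates >= 19`` (the minimum
    supporting a 95th percentile).
    """
    if n_surrogates < 19:
        raise ValidationError("n_surrogates must be >= 19")
    x, neuron_ids = _activity_matrix(activity)
    n, t_len = x.shape
    rng = np.random.default_rng(seed)

    # permutation guard: shuffle neuron order before pairwise computation
    perm = rng.permutation(n)
    inv = np.argsort(perm)
    xp = x[perm]
    ids_p = [neuron_ids[k] for k in perm]

    corr_p = correlation_matrix(xp, max_lag=max_lag)
    iu = np.triu_indices(n, 1)
    null_values = []
    for s in range(n_surrogates):
        offs = _surrogate_offsets(seed, s, ids_p, t_len)
        sur = np.stack([np.roll(row, off) for row, off in zip(xp, offs)])
        null_values.append(correlation_matrix(sur, max_lag=max_lag)[iu])
    null_values = np.concatenate(null_values)
    threshold = float(np.percentile(null_values, percentile))

    adjacency_p = (corr_p >= threshold).astype(int)
    np.fill_diagonal(adjacency_p, 0)
    # restore the original neuron ordering
    corr = corr_p[np.ix_(inv, inv)]
    adjacency = adjacency_p[np.ix_(inv, inv)]
    return FunctionalNetwork(
        correlation=corr, adjacency=adjacency, threshold=threshold,
        n_surrogates=n_surrogates, percentile=percentile,
        null_quantile=threshold, max_lag=max_lag, neuron_ids=neuron_ids)


def distance_profile(corr: np.ndarray,
                     neurons: pd.DataFrame,
                     n_bins: int = 10) -> DistanceProfile:
    """Bin pairwise correlations by inter-soma Euclidean distance.

    Equal-width bins over [0, max pairwise distance]; returns per-bin mean,
    sd and pair count (counts sum to n(n−1)/2).
    """
    corr = np.asarray(corr)
    n = corr.shape[0]
    if len(neurons) != n:
        raise ValidationError("matrix side must equal neuron table size")
    xy = neurons[["x_um", "y_um"]].to_numpy()
    iu = np.triu_indices(n, 1)
    d = np.linalg.norm(xy[iu[0]] - xy[iu[1]], axis=1)
    c = corr[iu]
    edges = np.linspace(0.0, d.max() if d.size else 1.0, n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        count[b] = sel.sum()
        if count[b]:
            mean[b] = c[sel].mean()
            sd[b] = c[sel].std()
    return DistanceProfile(bin_edges=edges, mean=mean, sd=sd, count=count)


def population_functional_matrix(corr_or_net,
                                 neurons: pd.DataFrame,
                                 cutoff: float) -> PopulationFunctionalMatrix:
    """Population-level summary of the cell-level correlation matrix.

    Entry (P, Q) is the mean correlation over all cell pairs (i ∈ P,
    j ∈ Q, i ≠ j); the population adjacency marks off-diagonal entries
    ≥ cutoff.  ``corr_or_net`` is either a correlation matrix or a
    :class:`FunctionalNetwork`.
    """
    corr = (corr_or_net.correlation
            if isinstance(corr_or_net, FunctionalNetwork)
            else np.asarray(corr_or_net))
    if len(neurons) != corr.shape[0]:
        raise ValidationError("matrix side must equal neuron table size")
    pops = list(dict.fromkeys(neurons["population"]))
    members = {p: np.flatnonzero(neurons["population"].to_numpy() == p)
               for p in pops}
    for p, m in members.items():
        if len(m) < 1:
            raise ValidationError(f"population {p!r} has no neurons")
    k = len(pops)
    mat = np.full((k, k), np.nan)
    for a, pa in enumerate(pops):
        for b, pb in enumerate(pops):
            ia, ib = members[pa], members[pb]
            block = corr[np.ix_(ia, ib)]
            if a == b:
                if len(ia) < 2:
                    mat[a, b] = np.nan
                    continue
                vals = block[~np.eye(len(ia), dtype=bool)]
            else:
                vals = block.ravel()
            mat[a, b] = vals.mean()
    adjacency = np.zeros((k, k), dtype=int)
    off = ~np.eye(k, dtype=bool)
    adjacency[off] = (np.nan_to_num(mat[off], nan=-np.inf) >= cutoff)
    return PopulationFunctionalMatrix(populations=pops, matrix=mat,
                                      adjacency=adjacency, cutoff=cutoff)
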