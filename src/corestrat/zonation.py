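"""Stratigraphically constrained zonation of multivariate core records.

CONISS (constrained incremental sum of squares) is agglomerative Ward
clustering restricted to stratigraphically adjacent clusters: starting
from singletons, the adjacent pair whose fusion least increases the
total within-cluster sum of squares is merged at each step.  For
clusters a, b with sizes n_a, n_b and centroids c_a, c_b the increase is

    d = n_a * n_b / (n_a + n_b) * ||c_a - c_b||^2

and the increments over the full merge tree sum exactly to the total sum
of squares about the grand mean.  Ties are broken in favour of the
stratigraphically uppermost pair, making the output deterministic.

The number of significant zones is read from the merge tree with a
broken-stick criterion: the proportional dispersion reduction of the
split into k zones is compared with the broken-stick expectation
e_k = (1/n) * sum_{j=k}^{n} 1/j, and successive splits are accepted
while they exceed it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["transform", "ConissZonation", "ZonationResult", "coniss",
           "broken_stick_zones", "broken_stick_expectation"]


def transform(raw: pd.DataFrame, log_vars=(), center: bool = True,
              scale_unit_variance: bool = False,
              log_offset: float = 0.0) -> pd.DataFrame:
    """Pre-clustering transform: natural log on selected variables, then
    per-variable centring (and optional unit-variance scaling).

    ``raw`` is a depth-indexed wide matrix.  Logging a non-positive value
    without a positive ``log_offset`` is an error.
    """
    out = raw.astype(float).copy()
    for v in log_vars:
        if v not in out.columns:
            raise KeyError(f"log variable {v!r} not in matrix")
        col = out[v] + log_offset
        if (col <= 0).any():
            raise ValueError(f"log of non-positive value in {v!r}; "
                             "set log_offset")
        out[v] = np.log(col)
    if out.isna().any().any():
        raise ValueError("matrix contains missing values")
    if center:
        out = out - out.mean(axis=0)
    if scale_unit_variance:
        sd = out.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("cannot scale constant variable to unit "
                             "variance")
        out = out / sd
    return out


def broken_stick_expectation(n: int) -> np.ndarray:
    """Expected proportional dispersion reduction e_k for k = 2..n pieces
    under the broken-stick null: e_k = (1/n) * sum_{j=k}^{n} 1/j."""
    inv = 1.0 / np.arange(1, n + 1)
    tail = np.cumsum(inv[::-1])[::-1]       # tail[j-1] = sum_{i=j}^n 1/i
    return tail[1:] / n                     # k = 2..n


@dataclass
class ZonationResult:
    """Full CONISS merge tree plus accepted zonation.

    ``merge_sequence`` holds one tuple per merge, in order:
    ``(upper_pos, increase, boundary_idx)`` where ``upper_pos`` is the
    index of the upper cluster among the clusters existing at that step
    and ``boundary_idx`` is the sample boundary bridged (boundary i lies
    between samples i and i+1).
    """

    merge_sequence: list
    total_ss: float
    n_samples: int
    depths: np.ndarray | None = None
    n_zones: int = 1
    boundaries_idx: list = field(default_factory=list)

    @property
    def increments(self) -> np.ndarray:
        return np.array([m[1] for m in self.merge_sequence])

    def boundaries_for(self, k: int) -> list[int]:
        """Sample boundary indices when the tree is cut into k zones:
        the boundaries bridged by the last k-1 merges."""
        if not 1 <= k <= self.n_samples:
            raise ValueError("k out of range")
        if k == 1:
            return []
        return sorted(m[2] for m in self.merge_sequence[-(k - 1):])

    def boundary_depths(self, k: int | None = None) -> list[float]:
        """Zone-boundary depths (midpoints between bounding samples)."""
        if self.depths is None:
            raise ValueError("no depths attached")
        k = self.n_zones if k is None else k
        return [float(0.5 * (self.depths[i] + self.depths[i + 1]))
                for i in self.boundaries_for(k)]

    def labels_for(self, k: int) -> np.ndarray:
        lab = np.zeros(self.n_samples, dtype=int)
        for b in self.boundaries_for(k):
            lab[b + 1:] += 1
        return lab

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"step": i + 1, "upper_cluster_pos": m[0], "increase": m[1],
              "boundary_idx": m[2]} for i, m in
             enumerate(self.merge_sequence)])


class ConissZonation(BaseEstimator):
    """Sklearn-style CONISS estimator with broken-stick zone selection.

    Parameters
    ----------
    n_zones : int or None
        Fixed number of zones; None (default) selects it with the
        broken-stick criterion.

    Attributes
    ----------
    result_ : ZonationResult
    n_zones_ : int
    boundaries_idx_ : list of int
    labels_ : ndarray of zone ids per sample
    total_ss_ : float
    """

    def __init__(self, n_zones: int | None = None):
        self.n_zones = n_zones

    def fit(self, X, depths=None) -> "ConissZonation":
        if isinstance(X, pd.DataFrame):
            if depths is None:
                depths = X.index.to_numpy(dtype=float)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = X.shape[0]
        if n < 2:
            raise ValueError("need at least 2 samples")
        if np.isnan(X).any():
            raise ValueError("matrix contains missing values")

        sizes = np.ones(n)
        cents = X.copy()
        # first sample index of each live cluster, for boundary bookkeeping
        starts = list(range(n))
        ends = list(range(n))
        merges: list[tuple[int, float, int]] = []
        for _ in range(n - 1):
            na, nb = sizes[:-1], sizes[1:]
            diff = cents[:-1] - cents[1:]
            costs = na * nb / (na + nb) * np.einsum("ij,ij->i", diff, diff)
            p = int(np.argmin(costs))       # argmin -> uppermost on ties
            merges.append((p, float(costs[p]), ends[p]))
            new_n = sizes[p] + sizes[p + 1]
            cents[p] = (sizes[p] * cents[p] + sizes[p + 1] * cents[p + 1]) \
                / new_n
            sizes[p] = new_n
            sizes = np.delete(sizes, p + 1)
            cents = np.delete(cents, p + 1, axis=0)
            ends[p] = ends[p + 1]
            del starts[p + 1], ends[p + 1]

        total_ss = float(((X - X.mean(axis=0)) ** 2).sum())
        res = ZonationResult(
            merge_sequence=merges, total_ss=total_ss, n_samples=n,
            depths=None if depths is None else np.asarray(depths, float))
        if self.n_zones is None:
            res.n_zones = broken_stick_zones(res)[0]
        else:
            res.n_zones = int(self.n_zones)
        res.boundaries_idx = res.boundaries_for(res.n_zones)

        self.result_ = res
        self.n_zones_ = res.n_zones
        self.boundaries_idx_ = res.boundaries_idx
        self.labels_ = res.labels_for(res.n_zones)
        self.total_ss_ = total_ss
        return self

    def fit_predict(self, X, depths=None) -> np.ndarray:
        return self.fit(X, depths).labels_


def coniss(strat: pd.DataFrame | np.ndarray, depths=None) -> ZonationResult:
    """Run CONISS on a (transformed) stratigraphic matrix; returns the
    merge tree with broken-stick zones already applied."""
    return ConissZonation().fit(strat, depths).result_


def broken_stick_zones(result: ZonationResult) -> tuple[int, list[int]]:
    """Number of significant zones and their sample-boundary indices.

    Splits are read from the merge tree in reverse: split k (k zones from
    k-1) reduces the within-zone dispersion by the increment of the
    (n-k+1)-th merge.  Successive splits are accepted while the observed
    proportional reduction exceeds the broken-stick expectation; the
    procedure stops at the first failure (minimum one zone).  Zero total
    dispersion (all samples identical) yields one zone.
    """
    n = result.n_samples
    if result.total_ss <= 0:
        return 1, []
    inc = result.increments
    expect = broken_stick_expectation(n)
    k_accept = 1
    for k in range(2, n + 1):
        p_k = inc[n - k] / result.total_ss
        if p_k > expect[k - 2]:
            k_accept = k
        else:
            break
    return k_accept, result.boundaries_for(k_accept)
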