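"""Multi-temporal-resolution B-spline featurization of binned spike patterns.

Each base learner of the ensemble sees the spike pattern through a
B-spline basis with ``m`` uniform interior knots over the decoding
window of length ``M``; its temporal resolution is ``M / (m + 1)``.
Projecting the binned spikes of every neuron onto each basis function
turns a trials x neurons x bins tensor into a trials x (neurons x
n_basis) feature matrix, linear in the spikes.  Because a clamped
B-spline basis forms a partition of unity, summing a neuron's features
over the basis index recovers its in-window spike count, so coarse and
fine resolutions are different linear summaries of the same mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .exceptions import ConfigurationError, DimensionError

__all__ = ["BSplineBasis", "FeatureMatrix", "build_basis", "featurize", "resolution_ladder"]


@dataclass(frozen=True)
class BSplineBasis:
    """Evaluated B-spline basis over the bin centers of a decoding window.

    ``B[b, j]`` is basis function j evaluated at the center of bin b.
    """

    m: int
    order: int
    window_s: tuple[float, float]
    bin_s: float
    grid: np.ndarray
    B: np.ndarray

    @property
    def n_basis(self) -> int:
        return self.B.shape[1]

    @property
    def resolution_s(self) -> float:
        start, end = self.window_s
        return (end - start) / (self.m + 1)


def build_basis(
    m: int,
    order: int = 4,
    window_s: tuple[float, float] = (-1.0, 1.0),
    bin_s: float = 0.01,
) -> BSplineBasis:
    """Clamped uniform B-spline basis with ``m`` interior knots.

    End knots are repeated ``order`` times so the basis spans constants
    (partition of unity on the whole window).  ``order`` is degree + 1;
    order 1 with m = 0 is the single box function.
    """
    if m < 0:
        raise ConfigurationError(f"knot count must be >= 0, got {m}")
    if order < 1:
        raise ConfigurationError(f"spline order must be >= 1, got {order}")
    start, end = float(window_s[0]), float(window_s[1])
    if not end - start > 0:
        raise ConfigurationError("window must have positive length")
    if bin_s <= 0:
        raise ConfigurationError("bin width must be positive")
    n_bins = int(round((end - start) / bin_s))
    if n_bins < 1:
        raise ConfigurationError("window shorter than one bin")
    interior = np.linspace(start, end, m + 2)[1:-1]
    t = np.concatenate([np.full(order, start), interior, np.full(order, end)])
    grid = start + (np.arange(n_bins) + 0.5) * bin_s
    B = BSpline.design_matrix(grid, t, order - 1).toarray()
    return BSplineBasis(m=m, order=order, window_s=(start, end), bin_s=float(bin_s), grid=grid, B=B)


def resolution_ladder(
    knot_set,
    order: int = 4,
    window_s: tuple[float, float] = (-1.0, 1.0),
    bin_s: float = 0.01,
) -> list[BSplineBasis]:
    """One basis per knot count; resolutions M/(m+1) strictly decrease in m."""
    knots = list(knot_set)
    if not knots:
        raise ValueError("knot_set must not be empty")
    if len(set(knots)) != len(knots):
        raise ValueError("knot_set contains duplicates")
    if any(k < 0 for k in knots):
        raise ValueError("knot counts must be non-negative")
    if knots != sorted(knots):
        raise ValueError("knot_set must be strictly increasing")
    return [build_basis(m, order=order, window_s=window_s, bin_s=bin_s) for m in knots]


@dataclass
class FeatureMatrix:
    """Trials x (neurons x n_basis) features at a single temporal resolution.

    Layout is neuron-major: all basis coefficients of neuron n occupy
    the contiguous column block ``[n * n_basis, (n + 1) * n_basis)``.
    ``standardization`` holds per-column (mean, scale) when recorded
    from training folds; fitting code manages it and never leaks
    test-trial statistics.
    """

    X: np.ndarray
    m: int
    n_neurons: int
    n_basis: int
    standardization: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.X.shape[1] != self.n_neurons * self.n_basis:
            raise DimensionError("column count must equal n_neurons * n_basis")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    def column_index(self, neuron: int, j: int) -> int:
        if not (0 <= neuron < self.n_neurons and 0 <= j < self.n_basis):
            raise IndexError("neuron/basis index out of range")
        return neuron * self.n_basis + j

    def column_to_pair(self, col: int) -> tuple[int, int]:
        if not 0 <= col < self.X.shape[1]:
            raise IndexError("column out of range")
        return divmod(col, self.n_basis)

    def neuron_columns(self, neuron: int) -> np.ndarray:
        return np.arange(neuron * self.n_basis, (neuron + 1) * self.n_basis)


def featurize(tensor, basis: BSplineBasis) -> FeatureMatrix:
    """Project binned spikes onto a basis: feature(t, n, j) = sum_b spikes(t,n,b) B[b,j]."""
    data = np.asarray(tensor.data)
    if data.shape[2] != basis.B.shape[0]:
        raise DimensionError(
            f"tensor has {data.shape[2]} bins but basis grid has {basis.B.shape[0]}"
        )
    if abs(tensor.bin_s - basis.bin_s) > 1e-12 or (
        abs(tensor.window_s[0] - basis.window_s[0]) > 1e-9
        or abs(tensor.window_s[1] - basis.window_s[1]) > 1e-9
    ):
        raise DimensionError("tensor binning does not match basis grid")
    feats = np.tensordot(data.astype(float), basis.B, axes=([2], [0]))
    X = feats.reshape(data.shape[0], data.shape[1] * basis.n_basis)
    return FeatureMatrix(X=X, m=basis.m, n_neurons=data.shape[1], n_basis=basis.n_basis)
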