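"""Sparse classification functional matrices (SCFMs) and sparseness measures.

A trained stacked model can be rendered as a neurons x time map

    F'(n, tau) = sigmoid( w0' + sum_m sum_j b_j^m(tau) w(n, j) w'(m) )

that composes the base-learner coefficients ``w`` with the meta-learner
weights ``w'`` through the B-spline bases.  ``sigmoid(w0')`` is the
map's baseline: where no (basis x coefficient x meta-weight) product
survives the two L1 penalties, F' sits exactly at the baseline and a
spike there cannot move the decoded category's probability.  Regions
above the baseline mark spatio-temporal locations where a spike raises
that probability; regions below lower it.  Spatial sparseness is the
fraction of neurons whose entire row is baseline; temporal sparseness
is, per neuron, the fraction of the window at baseline.

Because the bagged replicas of one temporal resolution are copies of
the same learner on resampled trials, their coefficients are averaged
within each resolution and weighted by the summed meta weight of that
resolution by default; the per-replica sum is available via ``mode``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoder import EnsembleDecoder, TrainedStack, _sigmoid
from .exceptions import DimensionError
from .features import BSplineBasis

__all__ = [
    "SCFM",
    "compute_scfm",
    "mask_score",
    "spatial_sparseness",
    "temporal_sparseness",
    "scfm_to_frame",
]


@dataclass
class SCFM:
    """Neurons x time classification functional matrix of one category.

    ``values`` are in (0, 1); ``linear`` is the pre-sigmoid map whose
    magnitude against ``zero_tol`` defines the zero (baseline) regions.
    """

    values: np.ndarray
    linear: np.ndarray
    baseline: float
    zero_tol: float
    category_id: int
    tau_grid: np.ndarray

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def sign_map(self) -> np.ndarray:
        """+1 / -1 / 0 map relative to the baseline with the zero tolerance."""
        s = np.sign(self.linear).astype(int)
        s[np.abs(self.linear) <= self.zero_tol] = 0
        return s


def _stack_linear_map(
    stack: TrainedStack,
    bases: list[BSplineBasis],
    n_neurons: int,
    tau_grid: np.ndarray | None,
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    base_by_m = {b.m: b for b in bases}
    first = bases[0]
    if tau_grid is None:
        tau_grid = first.grid
    tau_grid = np.asarray(tau_grid, dtype=float)
    linear = np.zeros((n_neurons, len(tau_grid)))
    if mode == "replica_mean":
        by_m: dict[int, dict] = {}
        for L, wq in zip(stack.base_learners, stack.meta.weights):
            acc = by_m.setdefault(L.m, {"coefs": [], "w": 0.0})
            acc["coefs"].append(L.coef)
            acc["w"] += float(wq)
        for m, acc in by_m.items():
            if acc["w"] == 0.0:
                continue
            basis = base_by_m[m]
            B = _basis_at(basis, tau_grid)
            W = np.mean(acc["coefs"], axis=0).reshape(n_neurons, basis.n_basis)
            linear += acc["w"] * (W @ B.T)
    elif mode == "per_replica":
        for L, wq in zip(stack.base_learners, stack.meta.weights):
            if wq == 0.0:
                continue
            basis = base_by_m[L.m]
            B = _basis_at(basis, tau_grid)
            W = L.coef.reshape(n_neurons, basis.n_basis)
            linear += float(wq) * (W @ B.T)
    else:
        raise ValueError("mode must be 'replica_mean' or 'per_replica'")
    return linear, tau_grid


def _basis_at(basis: BSplineBasis, tau_grid: np.ndarray) -> np.ndarray:
    if tau_grid.shape == basis.grid.shape and np.allclose(tau_grid, basis.grid):
        return basis.B
    from scipy.interpolate import BSpline

    start, end = basis.window_s
    interior = np.linspace(start, end, basis.m + 2)[1:-1]
    t = np.concatenate([np.full(basis.order, start), interior, np.full(basis.order, end)])
    inside = np.clip(tau_grid, start, np.nextafter(end, start))
    return BSpline.design_matrix(inside, t, basis.order - 1).toarray()


def compute_scfm(
    decoder: EnsembleDecoder,
    category_id: int,
    stack: TrainedStack | None = None,
    tau_grid=None,
    mode: str = "replica_mean",
    zero_tol: float = 1e-6,
) -> SCFM:
    """SCFM of one category model.

    By default the model trained on all trials is used; pass a specific
    outer-fold ``stack`` to inspect a held-out-fold model instead.
    ``zero_tol`` is applied on the linear (pre-sigmoid) scale.
    """
    model = decoder.category_models[category_id]
    if model is None:
        raise RuntimeError(f"category {category_id} has no trained model")
    if stack is None:
        stack = model.full_model if model.full_model is not None else model.folds[0]
    linear, tau = _stack_linear_map(stack, decoder.bases, decoder.n_neurons, tau_grid, mode)
    w0 = stack.meta.intercept
    return SCFM(
        values=_sigmoid(w0 + linear),
        linear=linear,
        baseline=float(_sigmoid(w0)),
        zero_tol=zero_tol,
        category_id=category_id,
        tau_grid=tau,
    )


def mask_score(tensor, scfm: SCFM) -> np.ndarray:
    """Inner product of each trial's spike pattern with the baseline-centered SCFM.

    score(trial) = sum_{n,tau} spikes(trial, n, tau) * (F'(n, tau) - baseline).
    Subtracting the baseline makes zero regions exactly inert: a spike
    there contributes nothing to the score.
    """
    data = np.asarray(tensor.data)
    if data.shape[1] != scfm.n_neurons or data.shape[2] != len(scfm.tau_grid):
        raise DimensionError("tensor shape does not map onto the SCFM grid")
    mask = scfm.values - scfm.baseline
    mask[np.abs(scfm.linear) <= scfm.zero_tol] = 0.0
    return np.einsum("tnb,nb->t", data.astype(float), mask)


def spatial_sparseness(scfm: SCFM) -> float:
    """Fraction of neurons whose whole SCFM row sits at the baseline."""
    flat = (np.abs(scfm.linear) <= scfm.zero_tol).all(axis=1)
    return float(flat.mean())


def temporal_sparseness(scfm: SCFM, per_neuron: bool = False):
    """Per-neuron fraction of the window at baseline, with summaries.

    Returns a dict with the per-neuron fractions, their mean +/- SD over
    all neurons, and over contributing (non-flat) neurons only; with
    ``per_neuron=False`` only the summaries are returned.
    """
    zero = np.abs(scfm.linear) <= scfm.zero_tol
    frac = zero.mean(axis=1)
    contributing = ~zero.all(axis=1)
    out = {
        "mean_all": float(frac.mean()),
        "sd_all": float(frac.std()),
        "mean_contributing": float(frac[contributing].mean()) if contributing.any() else float("nan"),
        "sd_contributing": float(frac[contributing].std()) if contributing.any() else float("nan"),
        "n_contributing": int(contributing.sum()),
    }
    if per_neuron:
        out["per_neuron"] = frac
    return out


def plot_scfm(scfm: SCFM, ax=None, category_name: str | None = None):
    """Heatmap of an SCFM: neurons x time, diverging palette centered at the baseline.

    Requires matplotlib (the ``plot`` extra).  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    span = np.abs(scfm.values - scfm.baseline).max() or 1e-12
    im = ax.imshow(
        scfm.values,
        aspect="auto",
        origin="lower",
        extent=(scfm.tau_grid[0], scfm.tau_grid[-1], -0.5, scfm.n_neurons - 0.5),
        cmap="RdBu_r",
        vmin=scfm.baseline - span,
        vmax=scfm.baseline + span,
    )
    ax.set_xlabel("time from event (s)")
    ax.set_ylabel("neuron")
    if category_name:
        ax.set_title(f"SCFM — {category_name}")
    plt.colorbar(im, ax=ax, label="F'(n, τ)")
    return ax


def scfm_to_frame(scfm: SCFM):
    """SCFM as a tidy DataFrame (neuron, tau_s, value, linear, sign) for CSV export."""
    import pandas as pd

    n, t = scfm.values.shape
    neuron, tau = np.meshgrid(np.arange(n), scfm.tau_grid, indexing="ij")
    return pd.DataFrame(
        {
            "neuron": neuron.ravel(),
            "tau_s": tau.ravel(),
            "value": scfm.values.ravel(),
            "linear": scfm.linear.ravel(),
            "sign": scfm.sign_map.ravel(),
        }
    )
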