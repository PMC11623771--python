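"""Scoring primitives for binary category decoding.

Decoding performance is summarized with the Matthews correlation
coefficient (MCC), which stays informative under the 1-vs-4 class
imbalance of one-vs-rest category decoding: it is 1 for perfect
classification, -1 for perfectly inverted classification and 0 both at
chance and for degenerate single-class predictors.  Model loss is the
(optionally normalized) binary cross-entropy, and single-neuron coding
intervals are screened with a per-interval firing-rate contrast between
trials of the decoded category and all other trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DimensionError

__all__ = [
    "ConfusionMatrix",
    "mcc",
    "cross_entropy",
    "interval_rate_contrast",
]

_EPS = 1e-12


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a binary classifier's outcomes on a set of scored trials."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        if y_true.shape != y_pred.shape:
            raise DimensionError("y_true and y_pred must have identical shape")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient of a confusion matrix.

    Returns ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``.
    When any marginal factor of the denominator is zero (e.g. the
    classifier predicts a single class, or the labels are single-class)
    the coefficient is defined as 0: such predictors carry no
    information beyond chance.
    """
    if cm.total == 0:
        raise ValueError("cannot score an empty confusion matrix")
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    factors = (tp + fp, tp + fn, tn + fp, tn + fn)
    if any(f == 0 for f in factors):
        return 0.0
    num = tp * tn - fp * fn
    # python ints: no overflow in the product of marginals
    denom = float(factors[0] * factors[1] * factors[2] * factors[3])
    return float(num / np.sqrt(denom))


def label_entropy(y) -> float:
    """Entropy (nats) of the empirical label marginal of binary ``y``."""
    y = np.asarray(y, dtype=float)
    q = float(np.mean(y))
    if q <= 0.0 or q >= 1.0:
        raise ValueError("label entropy undefined for single-class labels")
    return float(-(q * np.log(q) + (1.0 - q) * np.log(1.0 - q)))


def cross_entropy(probabilities, labels, normalize: bool = False) -> float:
    """Mean binary cross-entropy of predicted probabilities.

    Probabilities are clipped to ``[1e-12, 1 - 1e-12]``.  With
    ``normalize=True`` the mean loss is divided by the entropy of the
    empirical label marginal, so a constant predictor at the class
    prevalence scores exactly 1.
    """
    p = np.asarray(probabilities, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if p.shape != y.shape:
        raise DimensionError("probabilities and labels must have equal length")
    if p.size == 0:
        raise ValueError("cannot compute cross-entropy of zero trials")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    ce = float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    if normalize:
        ce = ce / label_entropy(y)
    return ce


def _group_pvalue(a, b, method: str, n_permutations: int, rng) -> float:
    if method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.pvalue)
    if method == "permutation":
        observed = abs(a.mean() - b.mean())
        pooled = np.concatenate([a, b])
        na = len(a)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if abs(perm[:na].mean() - perm[na:].mean()) >= observed - 1e-15:
                hits += 1
        return float((hits + 1) / (n_permutations + 1))
    raise ValueError(f"unknown test method {method!r}")


def interval_rate_contrast(
    tensor,
    labels,
    neuron_id: int,
    category_id: int,
    interval_bins: int = 10,
    alpha: float = 0.05,
    method: str = "welch",
    n_permutations: int = 1000,
    baseline_tensor=None,
    correction: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-interval firing-rate contrast of decoded vs non-decoded trials.

    The decoding window is grouped into intervals of ``interval_bins``
    bins (default 100 ms at 10-ms bins).  For each interval the mean
    firing rate (Hz) of trials belonging to ``category_id`` is compared
    with that of all other trials using Welch's two-sample t-test (or a
    permutation test on the mean difference).  The returned frame has
    one row per interval with columns ``t_start_s, t_end_s,
    rate_decoded_hz, rate_other_hz, p_value, significant`` and carries
    the baseline firing rate in ``frame.attrs['baseline_rate_hz']``
    (taken from ``baseline_tensor`` — e.g. a pre-event window — when
    given, else from the whole decoding window).

    With ``correction='fdr'`` the per-interval p-values are
    Benjamini-Hochberg adjusted before thresholding at ``alpha``.
    """
    y = np.asarray(labels.labels)[:, category_id].astype(bool)
    counts = np.asarray(tensor.data)[:, neuron_id, :]  # trials x bins
    if y.sum() < 2 or (~y).sum() < 2:
        warnings.warn("fewer than 2 trials in a contrast group; p-values undefined")
    n_bins = counts.shape[1]
    edges = list(range(0, n_bins, interval_bins)) + [n_bins]
    rng = np.random.default_rng(seed)
    start, _ = tensor.window_s
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        dur = (hi - lo) * tensor.bin_s
        seg = counts[:, lo:hi].sum(axis=1)
        a = seg[y].astype(float)
        b = seg[~y].astype(float)
        if len(a) < 2 or len(b) < 2 or (a.std() == 0 and b.std() == 0 and a.mean() == b.mean()):
            # identical/degenerate groups: no evidence of difference
            p = 1.0 if (len(a) >= 2 and len(b) >= 2) else float("nan")
        else:
            p = _group_pvalue(a, b, method, n_permutations, rng)
        rows.append(
            {
                "t_start_s": start + lo * tensor.bin_s,
                "t_end_s": start + hi * tensor.bin_s,
                "rate_decoded_hz": a.mean() / dur if len(a) else float("nan"),
                "rate_other_hz": b.mean() / dur if len(b) else float("nan"),
                "p_value": p,
            }
        )
    frame = pd.DataFrame(rows)
    pvals = frame["p_value"].to_numpy()
    if correction == "fdr":
        valid = ~np.isnan(pvals)
        adj = np.full_like(pvals, np.nan)
        if valid.any():
            adj[valid] = stats.false_discovery_control(pvals[valid])
        frame["p_adjusted"] = adj
        frame["significant"] = adj < alpha
    elif correction is None:
        frame["significant"] = pvals < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    base = baseline_tensor if baseline_tensor is not None else tensor
    base_counts = np.asarray(base.data)[:, neuron_id, :]
    window_len = base.data.shape[2] * base.bin_s
    frame.attrs["baseline_rate_hz"] = float(base_counts.sum(axis=1).mean() / window_len)
    return frame
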