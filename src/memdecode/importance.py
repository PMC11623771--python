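"""Permutation feature importance (PFI) over feature groups.

The dependence of the trained decoder on a group of input features —
all features of one temporal resolution, of one hippocampal region, or
of one neuron — is measured by jointly permuting that group's columns
across held-out trials (one shared trial permutation per repeat, so
within-group structure is preserved) and recording the increase of the
normalized cross-entropy loss over the intact model.  Contributions are
averaged over permutation repeats, clipped at zero for reporting, and
normalized to sum to one across groups.

The CA3/CA1 decomposition runs three PFI passes (each region alone and
both together): redundancy is the shared contribution
R = C_CA3 + C_CA1 - C_both, and each region's unique contribution is
its individual contribution minus R, so unique_CA3 + unique_CA1 + R
equals C_both by construction.  Per-neuron contributions divide each
region's total by its neuron count to balance unequal ensemble sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoder import EnsembleDecoder, predict_stack
from .metrics import cross_entropy

__all__ = [
    "ImportanceReport",
    "RegionDecomposition",
    "pfi",
    "resolution_contributions",
    "region_decomposition",
    "groups_by_resolution",
    "groups_by_region",
    "groups_by_neuron",
]

GroupSpec = dict[str, dict[int, np.ndarray]]  # group name -> {m: feature columns}


def _n_basis(decoder: EnsembleDecoder, m: int) -> int:
    for b in decoder.bases:
        if b.m == m:
            return b.n_basis
    raise KeyError(f"resolution m={m} not in the decoder ladder")


def groups_by_resolution(decoder: EnsembleDecoder) -> GroupSpec:
    """One group per temporal resolution: every column of that basis."""
    out: GroupSpec = {}
    for b in decoder.bases:
        out[f"m={b.m}"] = {b.m: np.arange(decoder.n_neurons * b.n_basis)}
    return out


def _neuron_columns(decoder: EnsembleDecoder, neurons) -> dict[int, np.ndarray]:
    cols = {}
    for b in decoder.bases:
        nb = b.n_basis
        cols[b.m] = np.concatenate([np.arange(n * nb, (n + 1) * nb) for n in neurons])
    return cols


def groups_by_region(decoder: EnsembleDecoder, neuron_meta) -> GroupSpec:
    """CA3 and CA1 groups spanning all resolutions of the regions' neurons."""
    out: GroupSpec = {}
    for region in ("CA3", "CA1"):
        neurons = np.flatnonzero((neuron_meta["region"] == region).to_numpy())
        if len(neurons) == 0:
            raise ValueError(f"region {region} has zero neurons")
        out[region] = _neuron_columns(decoder, neurons)
    return out


def groups_by_neuron(decoder: EnsembleDecoder) -> GroupSpec:
    return {f"neuron={n}": _neuron_columns(decoder, [n]) for n in range(decoder.n_neurons)}


@dataclass
class ImportanceReport:
    """Per-(category, group) loss increases under feature permutation.

    ``frame`` columns: category, group, loss_base, loss_permuted,
    raw_contribution, clipped_contribution, normalized_contribution.
    """

    frame: pd.DataFrame
    n_permutations: int
    seed: int
    loss_normalized: bool

    def by_group(self, column: str = "normalized_contribution") -> pd.Series:
        """Mean of a contribution column over categories, indexed by group."""
        return self.frame.groupby("group", sort=False)[column].mean()


def _category_oof(decoder, model, features):
    n = next(iter(features.values())).shape[0]
    probs = np.full(n, np.nan)
    for stack in model.folds:
        rows = stack.test_idx
        probs[rows] = predict_stack(stack, {m: X[rows] for m, X in features.items()})
    return probs


def _permuted_oof(model, features, group, perms_by_fold):
    n = next(iter(features.values())).shape[0]
    probs = np.full(n, np.nan)
    for k, stack in enumerate(model.folds):
        rows = stack.test_idx
        perm = perms_by_fold[k]
        sub = {}
        for m, X in features.items():
            Xr = X[rows]
            if m in group and len(group[m]):
                Xr = Xr.copy()
                Xr[:, group[m]] = Xr[perm][:, group[m]]
            sub[m] = Xr
        probs[rows] = predict_stack(stack, sub)
    return probs


def pfi(
    decoder: EnsembleDecoder,
    tensor,
    labels,
    groups: GroupSpec,
    n_permutations: int = 50,
    seed: int = 0,
    normalize_loss: bool = True,
) -> ImportanceReport:
    """Grouped permutation feature importance on held-out predictions.

    For every category model and group, the group's feature columns are
    permuted jointly across the held-out trials of each outer fold
    (fresh permutation per repeat, shared across the group's columns)
    and the pooled held-out cross-entropy recomputed.  The contribution
    is the mean loss increase over repeats.
    """
    for name, group in groups.items():
        if not any(len(cols) for cols in group.values()):
            raise ValueError(f"group {name!r} is empty")
    features = decoder.featurize_tensor(tensor)
    rng = np.random.default_rng(seed)
    rows = []
    for c, model in enumerate(decoder.category_models):
        if model is None:
            continue
        y = labels.labels[:, c].astype(int)
        base_probs = _category_oof(decoder, model, features)
        loss_base = cross_entropy(base_probs, y, normalize=normalize_loss)
        # one set of fold permutations per repeat, shared by all groups:
        # the same exchangeable draw scores every group fairly
        perm_sets = [
            [rng.permutation(len(stack.test_idx)) for stack in model.folds]
            for _ in range(n_permutations)
        ]
        for name, group in groups.items():
            losses = np.empty(n_permutations)
            for i, perms in enumerate(perm_sets):
                p = _permuted_oof(model, features, group, perms)
                losses[i] = cross_entropy(p, y, normalize=normalize_loss)
            raw = float(losses.mean() - loss_base)
            rows.append(
                {
                    "category": c,
                    "group": name,
                    "loss_base": loss_base,
                    "loss_permuted": float(losses.mean()),
                    "raw_contribution": raw,
                    "clipped_contribution": max(raw, 0.0),
                }
            )
    frame = pd.DataFrame(rows)
    norm = np.full(len(frame), 0.0)
    for c in frame["category"].unique():
        sel = frame["category"] == c
        total = frame.loc[sel, "clipped_contribution"].sum()
        if total > 0:
            norm[sel.to_numpy()] = frame.loc[sel, "clipped_contribution"] / total
    frame["normalized_contribution"] = norm
    return ImportanceReport(
        frame=frame, n_permutations=n_permutations, seed=seed, loss_normalized=normalize_loss
    )


def resolution_contributions(
    decoder: EnsembleDecoder,
    tensor,
    labels,
    n_permutations: int = 50,
    seed: int = 0,
    normalize_loss: bool = True,
) -> pd.DataFrame:
    """Normalized contribution of each temporal resolution, per category and averaged.

    Returns a frame with columns category, m, resolution_s,
    raw_contribution, clipped_contribution, normalized_contribution;
    the rows with category == -1 hold the across-category average.
    """
    report = pfi(
        decoder, tensor, labels, groups_by_resolution(decoder),
        n_permutations=n_permutations, seed=seed, normalize_loss=normalize_loss,
    )
    frame = report.frame.copy()
    res_by_name = {f"m={b.m}": (b.m, b.resolution_s) for b in decoder.bases}
    frame["m"] = frame["group"].map(lambda g: res_by_name[g][0])
    frame["resolution_s"] = frame["group"].map(lambda g: res_by_name[g][1])
    mean = (
        frame.groupby(["group", "m", "resolution_s"], sort=False)[
            ["raw_contribution", "clipped_contribution", "normalized_contribution"]
        ]
        .mean()
        .reset_index()
    )
    mean["category"] = -1
    cols = ["category", "m", "resolution_s", "raw_contribution",
            "clipped_contribution", "normalized_contribution"]
    return pd.concat([frame[cols], mean[cols]], ignore_index=True)


@dataclass
class RegionDecomposition:
    """Unique / redundant contribution split between CA3 and CA1."""

    category_id: int
    c_ca3: float
    c_ca1: float
    c_both: float
    n_ca3: int
    n_ca1: int

    @property
    def redundancy(self) -> float:
        return self.c_ca3 + self.c_ca1 - self.c_both

    @property
    def unique_ca3(self) -> float:
        return self.c_ca3 - self.redundancy

    @property
    def unique_ca1(self) -> float:
        return self.c_ca1 - self.redundancy

    @property
    def per_neuron_ca3(self) -> float:
        return self.c_ca3 / self.n_ca3

    @property
    def per_neuron_ca1(self) -> float:
        return self.c_ca1 / self.n_ca1

    def fractions(self) -> dict[str, float]:
        """unique_CA3 / redundancy / unique_CA1 as fractions of the joint contribution."""
        if self.c_both == 0:
            return {"unique_ca3": float("nan"), "redundancy": float("nan"),
                    "unique_ca1": float("nan")}
        return {
            "unique_ca3": self.unique_ca3 / self.c_both,
            "redundancy": self.redundancy / self.c_both,
            "unique_ca1": self.unique_ca1 / self.c_both,
        }


def region_decomposition(
    decoder: EnsembleDecoder,
    tensor,
    labels,
    n_permutations: int = 50,
    seed: int = 0,
    normalize_loss: bool = True,
) -> list[RegionDecomposition]:
    """Three-pass PFI decomposition of regional contributions, one per category.

    Raw (unclipped) contributions enter the algebra so the identity
    unique_CA3 + unique_CA1 + R == C_both holds exactly.
    """
    meta = tensor.neuron_meta
    region_groups = groups_by_region(decoder, meta)
    both = {
        m: np.union1d(region_groups["CA3"][m], region_groups["CA1"][m])
        for m in region_groups["CA3"]
    }
    groups = {"CA3": region_groups["CA3"], "CA1": region_groups["CA1"], "both": both}
    report = pfi(decoder, tensor, labels, groups, n_permutations=n_permutations,
                 seed=seed, normalize_loss=normalize_loss)
    n_ca3 = int((meta["region"] == "CA3").sum())
    n_ca1 = int((meta["region"] == "CA1").sum())
    out = []
    for c, sub in report.frame.groupby("category"):
        vals = sub.set_index("group")["raw_contribution"]
        out.append(
            RegionDecomposition(
                category_id=int(c),
                c_ca3=float(vals["CA3"]),
                c_ca1=float(vals["CA1"]),
                c_both=float(vals["both"]),
                n_ca3=n_ca3,
                n_ca1=n_ca1,
            )
        )
    return out
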