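"""Data model and I/O for event-aligned spike patterns and category labels.

Spikes are interchanged as a flat event table (CSV) of event-relative
spike times — one row per spike — and binned on demand into a
``SpikeTensor`` (trials x neurons x bins) around a behavioral event
(sample response, match response or sample presentation of the
delayed match-to-sample task).  Category labels are a trials x 5 binary
matrix over the fixed category order Animal, Building, Plant, Tool,
Vehicle.  The two negative controls of the analysis are built here:
a time-shifted window that precedes the sample presentation (and hence
carries no category information) and a label matrix with rows shuffled
across trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, CoverageError, DimensionError, FormatError

__all__ = [
    "REGIONS",
    "CATEGORY_NAMES",
    "EVENT_TYPES",
    "SpikeEventStore",
    "SpikeTensor",
    "LabelMatrix",
    "read_spike_events",
    "write_spike_events",
    "extract_window",
    "make_time_shifted_control",
    "make_label_shuffled_control",
    "read_labels_json",
    "write_labels_json",
    "save_tensor",
    "load_tensor",
]

REGIONS = ("CA3", "CA1")
CATEGORY_NAMES = ("Animal", "Building", "Plant", "Tool", "Vehicle")
EVENT_TYPES = ("sample_response", "match_response", "sample_presentation")

_REQUIRED_COLUMNS = ["subject", "neuron", "region", "trial", "event_type", "spike_time_s"]


@dataclass
class SpikeEventStore:
    """Validated, indexed table of event-relative spike times.

    ``events`` has one row per spike with columns ``subject, neuron,
    region, trial, event_type, spike_time_s`` (plus optional
    ``electrode``).  ``span`` optionally records, per event type, the
    (start, end) time span over which spikes were observable; when
    absent, coverage checks fall back to the observed spike extrema.
    """

    events: pd.DataFrame
    span: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.events.columns]
        if missing:
            raise FormatError(f"spike-event table missing columns: {missing}")
        bad = set(self.events["region"].unique()) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region(s) {sorted(bad)}; expected one of {REGIONS}")
        # a neuron id must map to a single (subject, region)
        meta = self.events.drop_duplicates(["neuron"])[["neuron"]]
        per_neuron = self.events.groupby("neuron")[["subject", "region"]].nunique()
        if len(per_neuron) and (per_neuron > 1).any().any():
            raise FormatError("a neuron id maps to more than one subject/region")
        del meta

    @property
    def neuron_meta(self) -> pd.DataFrame:
        """Per-neuron metadata frame indexed 0..N-1 in neuron-id order."""
        cols = ["neuron", "subject", "region"]
        if "electrode" in self.events.columns:
            cols.append("electrode")
        meta = (
            self.events[cols]
            .drop_duplicates("neuron")
            .sort_values("neuron")
            .reset_index(drop=True)
        )
        if "electrode" not in meta.columns:
            meta["electrode"] = -1
        return meta.rename(
            columns={"neuron": "neuron_id", "subject": "subject_id", "electrode": "electrode_id"}
        )

    @property
    def trial_ids(self) -> np.ndarray:
        return np.sort(self.events["trial"].unique())

    @property
    def event_types(self) -> tuple[str, ...]:
        return tuple(sorted(self.events["event_type"].unique()))

    def coverage(self, event_type: str) -> tuple[float, float]:
        """Time span over which spikes of ``event_type`` are available."""
        if event_type in self.span:
            return self.span[event_type]
        sel = self.events.loc[self.events["event_type"] == event_type, "spike_time_s"]
        if sel.empty:
            raise CoverageError(f"store holds no spikes for event {event_type!r}")
        return float(sel.min()), float(sel.max())


@dataclass
class SpikeTensor:
    """Binned spike counts: trials x neurons x bins, plus window metadata."""

    data: np.ndarray
    window_s: tuple[float, float]
    bin_s: float
    event_type: str
    neuron_meta: pd.DataFrame
    trial_ids: np.ndarray

    def __post_init__(self) -> None:
        start, end = self.window_s
        expected = int(round((end - start) / self.bin_s))
        if self.data.ndim != 3:
            raise DimensionError("spike tensor must be trials x neurons x bins")
        if self.data.shape[2] != expected:
            raise DimensionError(
                f"tensor has {self.data.shape[2]} bins, window/bin imply {expected}"
            )
        if len(self.neuron_meta) != self.data.shape[1]:
            raise DimensionError("neuron_meta length must equal the neuron axis")
        if len(self.trial_ids) != self.data.shape[0]:
            raise DimensionError("trial_ids length must equal the trial axis")
        if (np.asarray(self.data) < 0).any():
            raise ValueError("spike counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.data.shape[1]

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]

    @property
    def bin_centers(self) -> np.ndarray:
        return self.window_s[0] + (np.arange(self.n_bins) + 0.5) * self.bin_s

    def region_indices(self, region: str) -> np.ndarray:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return np.flatnonzero((self.neuron_meta["region"] == region).to_numpy())


@dataclass
class LabelMatrix:
    """Trials x 5 binary one-vs-rest category labels."""

    labels: np.ndarray
    trial_ids: np.ndarray
    category_names: tuple[str, ...] = CATEGORY_NAMES

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.shape[1] != len(self.category_names):
            raise DimensionError("labels must be trials x n_categories")
        if not np.isin(lab, (0, 1)).all():
            raise ValueError("labels must be binary")
        if len(self.trial_ids) != lab.shape[0]:
            raise DimensionError("trial_ids length must equal the trial axis")
        self.labels = lab.astype(np.int8)

    @property
    def n_trials(self) -> int:
        return self.labels.shape[0]

    def column_decodable(self, category_id: int) -> bool:
        """True when the category column has both a 1 and a 0 (decoding defined)."""
        col = self.labels[:, category_id]
        return bool(col.any() and not col.all())

    def category_index(self) -> np.ndarray:
        """Per-trial category id for one-hot rows (used for stratification)."""
        if not (self.labels.sum(axis=1) == 1).all():
            raise ValueError("labels are not one-hot; no single category per trial")
        return self.labels.argmax(axis=1)


def read_spike_events(path) -> SpikeEventStore:
    """Read the spike-event CSV interchange format into a validated store."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"spike-event file {path} missing columns: {missing}")
    span = {}
    sidecar = Path(str(path) + ".span.json")
    if sidecar.exists():
        span = {k: tuple(v) for k, v in json.loads(sidecar.read_text()).items()}
    return SpikeEventStore(events=df, span=span)


def write_spike_events(store: SpikeEventStore, path) -> None:
    store.events.to_csv(path, index=False)
    if store.span:
        Path(str(path) + ".span.json").write_text(json.dumps(store.span))


def extract_window(
    store: SpikeEventStore,
    event_type: str,
    window_s: tuple[float, float] = (-1.0, 1.0),
    bin_s: float = 0.01,
    trial_ids=None,
) -> SpikeTensor:
    """Bin event-relative spike times into a trials x neurons x bins tensor.

    Bins are half-open ``[left, right)`` with 0-based indices; a spike at
    exactly the window start lands in bin 0 and a spike at the window end
    is excluded.  Trials without in-window spikes appear as all-zero rows
    (the trial set is the store's full trial list unless ``trial_ids`` is
    given).
    """
    start, end = float(window_s[0]), float(window_s[1])
    if not end - start > 0:
        raise ConfigurationError("window must have positive length")
    if bin_s <= 0:
        raise ConfigurationError("bin width must be positive")
    if event_type not in store.event_types:
        raise KeyError(f"event type {event_type!r} not present in store")
    n_bins = int(round((end - start) / bin_s))
    meta = store.neuron_meta
    neuron_pos = {nid: i for i, nid in enumerate(meta["neuron_id"])}
    trials = np.asarray(store.trial_ids if trial_ids is None else trial_ids)
    trial_pos = {tid: i for i, tid in enumerate(trials)}
    data = np.zeros((len(trials), len(meta), n_bins), dtype=np.int64)
    sel = store.events[store.events["event_type"] == event_type]
    t = sel["spike_time_s"].to_numpy(dtype=float)
    in_win = (t >= start) & (t < end)
    sel = sel.loc[in_win]
    t = t[in_win]
    bins = np.minimum(np.floor((t - start) / bin_s).astype(int), n_bins - 1)
    for trial, neuron, b in zip(sel["trial"].to_numpy(), sel["neuron"].to_numpy(), bins):
        ti = trial_pos.get(trial)
        if ti is not None:
            data[ti, neuron_pos[neuron], b] += 1
    return SpikeTensor(
        data=data,
        window_s=(start, end),
        bin_s=float(bin_s),
        event_type=event_type,
        neuron_meta=meta,
        trial_ids=trials,
    )


def make_time_shifted_control(
    store: SpikeEventStore,
    event_type: str = "sample_presentation",
    window_s: tuple[float, float] = (-3.0, -1.0),
    bin_s: float = 0.01,
    trial_ids=None,
) -> SpikeTensor:
    """Tensor for a window that fully precedes the alignment event.

    Shifting the decoding window to before the sample presentation
    yields spike patterns that cannot carry information about the
    upcoming image category; decoding them is the time-shifted null.
    """
    start, end = float(window_s[0]), float(window_s[1])
    if end > 0:
        raise CoverageError("time-shifted window must end at or before the event (end <= 0)")
    lo, hi = store.coverage(event_type)
    if start < lo - bin_s or end > hi + bin_s:
        raise CoverageError(
            f"requested window ({start}, {end}) not covered by available span ({lo:.3f}, {hi:.3f})"
        )
    return extract_window(store, event_type, (start, end), bin_s, trial_ids=trial_ids)


def make_label_shuffled_control(labels: LabelMatrix, seed: int) -> LabelMatrix:
    """Permute label rows uniformly across trials (one-hot rows preserved)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(labels.n_trials)
    return LabelMatrix(
        labels=labels.labels[perm],
        trial_ids=labels.trial_ids.copy(),
        category_names=labels.category_names,
    )


def write_labels_json(labels: LabelMatrix, path) -> None:
    obj = {int(t): [int(v) for v in row] for t, row in zip(labels.trial_ids, labels.labels)}
    Path(path).write_text(json.dumps({"category_names": list(labels.category_names), "labels": obj}))


def read_labels_json(path) -> LabelMatrix:
    obj = json.loads(Path(path).read_text())
    names = tuple(obj.get("category_names", CATEGORY_NAMES))
    items = sorted(((int(k), v) for k, v in obj["labels"].items()), key=lambda kv: kv[0])
    trial_ids = np.array([k for k, _ in items])
    lab = np.array([v for _, v in items], dtype=np.int8)
    return LabelMatrix(labels=lab, trial_ids=trial_ids, category_names=names)


def save_tensor(tensor: SpikeTensor, path) -> None:
    """Cache a tensor as .npz with a JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(path, data=tensor.data, trial_ids=tensor.trial_ids)
    meta = {
        "window_s": list(tensor.window_s),
        "bin_s": tensor.bin_s,
        "event_type": tensor.event_type,
        "neuron_meta": tensor.neuron_meta.to_dict(orient="list"),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_tensor(path) -> SpikeTensor:
    path = Path(path)
    arrays = np.load(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return SpikeTensor(
        data=arrays["data"],
        window_s=tuple(meta["window_s"]),
        bin_s=meta["bin_s"],
        event_type=meta["event_type"],
        neuron_meta=pd.DataFrame(meta["neuron_meta"]),
        trial_ids=arrays["trial_ids"],
    )
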