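"""Synthetic delayed match-to-sample spike ensembles with known ground truth.

Human hippocampal DMS recordings are not publicly available, so every
downstream stage is exercised on simulated ensembles with the structure
typical of such sessions: a few tens of CA3/CA1 neurons, ~150 trials
split evenly over five image categories, and a 2-second decoding window
binned at 10 ms.  Each coding neuron modulates its firing probability
for each category inside one contiguous active interval (excitation or
suppression of the baseline Bernoulli rate); non-coding neurons fire at
a flat baseline identical across categories.  Spikes are drawn
independently per bin (an inhomogeneous Poisson process thinned to the
bin grid), which is exactly the form the decoder consumes.

The generator's defaults are the conditions the tests assume: 75%
coding neurons and 75% temporal sparseness place the ensemble in the
regime where most neurons participate in encoding but only a minority
of the window carries signal — distributed spatial coding with sparse
temporal coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DimensionError
from .spikeio import CATEGORY_NAMES, LabelMatrix, SpikeEventStore, SpikeTensor

__all__ = [
    "SimConfig",
    "GroundTruthIntensity",
    "sample_intensities",
    "simulate_trials",
    "simulate_session",
    "ground_truth_scfm_proxy",
]

N_CATEGORIES = len(CATEGORY_NAMES)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic DMS session.

    ``temporal_sparseness_target`` is the fraction of the decoding
    window *outside* a coding neuron's active interval, so the interval
    length is ``(1 - target) * M``.  ``modulation_depth`` multiplies the
    baseline per-bin probability inside active intervals:
    ``p = clip(p0 * (1 + sign * depth), 0, 1)``.
    """

    n_neurons: int = 20
    fraction_ca3: float = 0.6
    n_trials: int = 150
    window_s: tuple[float, float] = (-1.0, 1.0)
    bin_s: float = 0.01
    fraction_coding_neurons: float = 0.75
    temporal_sparseness_target: float = 0.75
    baseline_rate_hz: float = 5.0
    modulation_depth: float = 1.25
    category_gain_profile: tuple[float, ...] = (-1.0, -1.0, -1.0, 2.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.category_gain_profile) != N_CATEGORIES:
            raise ConfigurationError("category_gain_profile needs one gain per category")
        for name in ("fraction_ca3", "fraction_coding_neurons",
                     "temporal_sparseness_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_neurons < 1:
            raise ConfigurationError("n_neurons must be >= 1")
        if self.n_trials < N_CATEGORIES:
            raise ConfigurationError("need at least one trial per category")
        start, end = self.window_s
        if not end - start > 0:
            raise ConfigurationError("window must have positive length")
        if self.bin_s <= 0:
            raise ConfigurationError("bin width must be positive")
        n_exact = (end - start) / self.bin_s
        if abs(n_exact - round(n_exact)) > 1.0:
            raise ConfigurationError("window length must divide into bins (within one bin)")
        if self.baseline_rate_hz <= 0:
            raise ConfigurationError("baseline rate must be positive")
        if self.modulation_depth < 0:
            raise ConfigurationError("modulation depth must be >= 0")
        if self.baseline_prob > 1.0:
            raise ConfigurationError("baseline rate implies per-bin probability > 1")

    @property
    def n_bins(self) -> int:
        start, end = self.window_s
        return int(round((end - start) / self.bin_s))

    @property
    def baseline_prob(self) -> float:
        """Per-bin baseline spike probability implied by the rate."""
        return self.baseline_rate_hz * self.bin_s

    @property
    def window_length_s(self) -> float:
        return self.window_s[1] - self.window_s[0]


@dataclass(frozen=True)
class GroundTruthIntensity:
    """Per-bin firing probability of one neuron under one category."""

    neuron_id: int
    category_id: int
    intensity: np.ndarray
    baseline_rate: float
    active_intervals: tuple[tuple[float, float], ...]
    modulation_sign: int

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity, dtype=float)
        if ((inten < 0) | (inten > 1)).any():
            raise ValueError("intensity values must lie in [0, 1]")
        object.__setattr__(self, "intensity", inten)

    @property
    def is_coding(self) -> bool:
        return len(self.active_intervals) > 0


def _streams(cfg: SimConfig) -> list[np.random.Generator]:
    """Named deterministic substreams: 0 intensities, 1 trials, 2 pre-event baseline."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(3)]


def sample_intensities(cfg: SimConfig) -> list[GroundTruthIntensity]:
    """Draw ground-truth intensity functions for every (neuron, category) pair.

    Exactly ``round(fraction_coding_neurons * n_neurons)`` neurons are
    coding; each coding neuron-category pair gets one contiguous active
    interval of length ``(1 - temporal_sparseness_target) * M`` with a
    uniformly random bin-aligned onset and a random modulation sign.
    """
    rng = _streams(cfg)[0]
    n_bins = cfg.n_bins
    p0 = cfg.baseline_prob
    n_coding = int(round(cfg.fraction_coding_neurons * cfg.n_neurons))
    coding = set(rng.choice(cfg.n_neurons, size=n_coding, replace=False).tolist())
    n_active_bins = int(round((1.0 - cfg.temporal_sparseness_target) * n_bins))
    start = cfg.window_s[0]
    out: list[GroundTruthIntensity] = []
    for neuron in range(cfg.n_neurons):
        is_coding = neuron in coding and n_active_bins > 0
        # one receptive interval per neuron, shared by all categories, so the
        # neuron's category information is confined to the target fraction of
        # the window; categories differ in their modulation gain inside it,
        # assigned as a random permutation of the gain profile so every
        # category's contrast against the others is bounded away from zero
        if is_coding:
            onset = int(rng.integers(0, n_bins - n_active_bins + 1))
            intervals = (
                (start + onset * cfg.bin_s, start + (onset + n_active_bins) * cfg.bin_s),
            )
            gains = rng.permutation(np.asarray(cfg.category_gain_profile))
        for cat in range(N_CATEGORIES):
            inten = np.full(n_bins, p0)
            sign = 0
            if is_coding:
                gain = float(gains[cat])
                sign = int(np.sign(gain)) or 1
                p_active = float(np.clip(p0 * (1.0 + gain * cfg.modulation_depth), 0.0, 1.0))
                inten[onset : onset + n_active_bins] = p_active
            out.append(
                GroundTruthIntensity(
                    neuron_id=neuron,
                    category_id=cat,
                    intensity=inten,
                    baseline_rate=cfg.baseline_rate_hz,
                    active_intervals=intervals if is_coding else (),
                    modulation_sign=sign,
                )
            )
    return out


def _intensity_cube(intensities, cfg: SimConfig) -> np.ndarray:
    """(categories, neurons, bins) cube from the flat intensity list."""
    cube = np.full((N_CATEGORIES, cfg.n_neurons, cfg.n_bins), np.nan)
    for gi in intensities:
        if gi.intensity.shape[0] != cfg.n_bins:
            raise DimensionError("intensity length does not match the config bin grid")
        cube[gi.category_id, gi.neuron_id] = gi.intensity
    if np.isnan(cube).any():
        raise DimensionError("intensity list does not cover every (neuron, category) pair")
    return cube


def _neuron_meta(cfg: SimConfig) -> pd.DataFrame:
    n_ca3 = int(round(cfg.fraction_ca3 * cfg.n_neurons))
    regions = ["CA3"] * n_ca3 + ["CA1"] * (cfg.n_neurons - n_ca3)
    # 10-contact probe layout: 6 CA3 then 4 CA1 contacts per probe
    electrode = [i % 6 for i in range(n_ca3)] + [6 + i % 4 for i in range(cfg.n_neurons - n_ca3)]
    return pd.DataFrame(
        {
            "neuron_id": np.arange(cfg.n_neurons),
            "subject_id": "S01",
            "region": regions,
            "electrode_id": electrode,
        }
    )


def simulate_trials(
    intensities, cfg: SimConfig, event_type: str = "sample_response"
) -> tuple[SpikeTensor, LabelMatrix]:
    """Realize Bernoulli-per-bin spike trials with balanced shuffled categories."""
    rng = _streams(cfg)[1]
    cube = _intensity_cube(intensities, cfg)
    cats = np.arange(cfg.n_trials) % N_CATEGORIES
    rng.shuffle(cats)
    probs = cube[cats]  # trials x neurons x bins
    data = (rng.random(probs.shape) < probs).astype(np.int8)
    labels = np.zeros((cfg.n_trials, N_CATEGORIES), dtype=np.int8)
    labels[np.arange(cfg.n_trials), cats] = 1
    trial_ids = np.arange(cfg.n_trials)
    tensor = SpikeTensor(
        data=data,
        window_s=cfg.window_s,
        bin_s=cfg.bin_s,
        event_type=event_type,
        neuron_meta=_neuron_meta(cfg),
        trial_ids=trial_ids,
    )
    return tensor, LabelMatrix(labels=labels, trial_ids=trial_ids)


def simulate_session(
    cfg: SimConfig, pre_event_span_s: tuple[float, float] = (-4.0, 0.0)
) -> tuple[SpikeEventStore, LabelMatrix, list[GroundTruthIntensity]]:
    """Full synthetic session as an event store.

    The store holds the category-modulated decoding window around the
    sample response plus flat-baseline spikes over ``pre_event_span_s``
    relative to the sample presentation, so the time-shifted control can
    be extracted from it.
    """
    intensities = sample_intensities(cfg)
    tensor, labels = simulate_trials(intensities, cfg)
    rng = _streams(cfg)[2]
    meta = tensor.neuron_meta

    def _event_frame(data, centers, event_type):
        t, n, b = np.nonzero(data)
        return pd.DataFrame(
            {
                "subject": meta["subject_id"].to_numpy()[n],
                "neuron": n,
                "region": meta["region"].to_numpy()[n],
                "trial": t,
                "event_type": event_type,
                "spike_time_s": centers[b],
                "electrode": meta["electrode_id"].to_numpy()[n],
            }
        )

    # flat-baseline spikes preceding the sample presentation
    lo, hi = pre_event_span_s
    n_pre = int(round((hi - lo) / cfg.bin_s))
    pre_centers = lo + (np.arange(n_pre) + 0.5) * cfg.bin_s
    pre = rng.random((cfg.n_trials, cfg.n_neurons, n_pre)) < cfg.baseline_prob
    events = pd.concat(
        [
            _event_frame(tensor.data, tensor.bin_centers, "sample_response"),
            _event_frame(pre, pre_centers, "sample_presentation"),
        ],
        ignore_index=True,
    )
    store = SpikeEventStore(
        events=events,
        span={"sample_response": cfg.window_s, "sample_presentation": (lo, hi)},
    )
    return store, labels, intensities


def ground_truth_scfm_proxy(intensities, category_id: int) -> np.ndarray:
    """Signed ground-truth contrast map: intensity(cat) - mean of the other categories.

    Zero exactly where a neuron is non-coding or outside every active
    interval; this is the oracle against which the sign pattern of a
    fitted classification functional matrix is validated.
    """
    if category_id not in range(N_CATEGORIES):
        raise KeyError(f"unknown category id {category_id}")
    by_pair = {}
    neurons = set()
    for gi in intensities:
        by_pair[(gi.neuron_id, gi.category_id)] = gi.intensity
        neurons.add(gi.neuron_id)
    n_neurons = max(neurons) + 1
    n_bins = next(iter(by_pair.values())).shape[0]
    contrast = np.zeros((n_neurons, n_bins))
    others = [c for c in range(N_CATEGORIES) if c != category_id]
    for n in range(n_neurons):
        target = by_pair[(n, category_id)]
        rest = np.mean([by_pair[(n, c)] for c in others], axis=0)
        contrast[n] = target - rest
    return contrast
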