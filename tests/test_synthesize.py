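import numpy as np
import pytest

from memdecode.exceptions import ConfigurationError
from memdecode.synthesize import (
    SimConfig,
    ground_truth_scfm_proxy,
    sample_intensities,
    simulate_trials,
)


class TestSampleIntensities:
    def test_no_coding_neurons_gives_flat_baseline(self):
        cfg = SimConfig(n_neurons=6, n_trials=20, fraction_coding_neurons=0.0, seed=1)
        for gi in sample_intensities(cfg):
            assert not gi.is_coding
            assert np.allclose(gi.intensity, cfg.baseline_prob)

    def test_coding_count_and_active_fraction_arithmetic(self):
        cfg = SimConfig(
            n_neurons=20, fraction_coding_neurons=0.75, temporal_sparseness_target=0.75, seed=2
        )
        intensities = sample_intensities(cfg)
        coding = {gi.neuron_id for gi in intensities if gi.is_coding}
        assert len(coding) == 15
        for gi in intensities:
            if gi.is_coding:
                (lo, hi), = gi.active_intervals
                n_active = round((hi - lo) / cfg.bin_s)
                assert n_active == round(0.25 * cfg.n_bins)

    def test_determinism_same_seed_bitwise_identical(self):
        cfg = SimConfig(seed=7)
        a = sample_intensities(cfg)
        b = sample_intensities(cfg)
        for ga, gb in zip(a, b):
            assert np.array_equal(ga.intensity, gb.intensity)
            assert ga.active_intervals == gb.active_intervals

    def test_non_coding_neuron_identical_across_categories(self):
        cfg = SimConfig(n_neurons=10, fraction_coding_neurons=0.5, seed=3)
        intensities = sample_intensities(cfg)
        by_neuron = {}
        for gi in intensities:
            by_neuron.setdefault(gi.neuron_id, []).append(gi)
        for group in by_neuron.values():
            if not group[0].is_coding:
                for gi in group[1:]:
                    assert np.array_equal(gi.intensity, group[0].intensity)

    def test_baseline_outside_active_intervals(self):
        cfg = SimConfig(seed=4)
        for gi in sample_intensities(cfg):
            mask = np.ones(cfg.n_bins, dtype=bool)
            for lo, hi in gi.active_intervals:
                b0 = round((lo - cfg.window_s[0]) / cfg.bin_s)
                b1 = round((hi - cfg.window_s[0]) / cfg.bin_s)
                mask[b0:b1] = False
            assert np.allclose(gi.intensity[mask], cfg.baseline_prob)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(fraction_coding_neurons=1.5)


class TestSimulateTrials:
    def test_all_zero_and_all_one_intensities(self):
        cfg = SimConfig(n_neurons=3, n_trials=10, seed=5)
        base = sample_intensities(SimConfig(n_neurons=3, n_trials=10,
                                            fraction_coding_neurons=0.0, seed=5))
        import dataclasses

        zeros = [dataclasses.replace(gi, intensity=np.zeros_like(gi.intensity)) for gi in base]
        tensor, _ = simulate_trials(zeros, cfg)
        assert not tensor.data.any()
        ones = [dataclasses.replace(gi, intensity=np.ones_like(gi.intensity)) for gi in base]
        tensor, _ = simulate_trials(ones, cfg)
        assert tensor.data.all()

    def test_balanced_one_hot_labels(self):
        cfg = SimConfig(seed=6)
        _, labels = simulate_trials(sample_intensities(cfg), cfg)
        assert (labels.labels.sum(axis=1) == 1).all()
        assert labels.labels.sum(axis=0).tolist() == [30] * 5

    def test_empirical_rate_matches_binomial_oracle(self):
        """5 Hz baseline, 10 ms bins: empirical per-bin rate within 3 SE of 0.05."""
        cfg = SimConfig(n_neurons=5, n_trials=40, fraction_coding_neurons=0.0, seed=7)
        tensor, _ = simulate_trials(sample_intensities(cfg), cfg)
        n = tensor.data.size  # 40 * 5 * 200 = 40000 neuron-bins
        p = 0.05
        se = np.sqrt(p * (1 - p) / n)
        assert abs(tensor.data.mean() - p) < 3 * se

    def test_determinism(self):
        cfg = SimConfig(n_neurons=6, n_trials=30, seed=8)
        inten = sample_intensities(cfg)
        t1, l1 = simulate_trials(inten, cfg)
        t2, l2 = simulate_trials(inten, cfg)
        assert np.array_equal(t1.data, t2.data)
        assert np.array_equal(l1.labels, l2.labels)

    def test_region_split_matches_fraction(self):
        cfg = SimConfig(n_neurons=20, fraction_ca3=0.6, seed=9)
        tensor, _ = simulate_trials(sample_intensities(cfg), cfg)
        assert (tensor.neuron_meta["region"] == "CA3").sum() == 12
        assert (tensor.neuron_meta["region"] == "CA1").sum() == 8

    def test_empirical_frequency_converges_to_intensity(self):
        """Per-bin spike frequency of each category is inside the binomial CI
        of the generating intensity (n_trials >= 200)."""
        cfg = SimConfig(n_neurons=8, n_trials=1000, seed=10)
        inten = sample_intensities(cfg)
        tensor, labels = simulate_trials(inten, cfg)
        cats = labels.category_index()
        cube = {}
        for gi in inten:
            cube[(gi.category_id, gi.neuron_id)] = gi.intensity
        worst = 0.0
        for c in range(5):
            sel = tensor.data[cats == c]
            n = sel.shape[0]
            for neuron in range(cfg.n_neurons):
                emp = sel[:, neuron, :].mean(axis=0)
                p = cube[(c, neuron)]
                se = np.sqrt(np.maximum(p * (1 - p), 1e-9) / n)
                z = np.abs(emp - p) / se
                worst = max(worst, z.max())
        # 8000 bin-level comparisons: max |z| beyond 5 would signal bias
        assert worst < 5.0


class TestGroundTruthProxy:
    def test_non_coding_neuron_row_is_zero(self):
        cfg = SimConfig(n_neurons=10, fraction_coding_neurons=0.5, seed=11)
        inten = sample_intensities(cfg)
        contrast = ground_truth_scfm_proxy(inten, 0)
        for gi in inten:
            if gi.category_id == 0 and not gi.is_coding:
                assert not contrast[gi.neuron_id].any()

    def test_zero_outside_active_intervals(self):
        cfg = SimConfig(seed=12)
        inten = sample_intensities(cfg)
        contrast = ground_truth_scfm_proxy(inten, 2)
        for gi in inten:
            if gi.category_id != 2 or not gi.is_coding:
                continue
            (lo, hi), = gi.active_intervals
            b0 = round((lo - cfg.window_s[0]) / cfg.bin_s)
            b1 = round((hi - cfg.window_s[0]) / cfg.bin_s)
            row = contrast[gi.neuron_id]
            assert not row[:b0].any() and not row[b1:].any()

    def test_suppressive_contrast_arithmetic(self):
        """Constructed intensities: category 0 suppressed by 0.02 inside the
        interval, others at baseline -> contrast is exactly -0.02 there."""
        import dataclasses

        cfg = SimConfig(n_neurons=1, n_trials=10, fraction_coding_neurons=1.0,
                        temporal_sparseness_target=0.75, seed=13)
        inten = sample_intensities(cfg)
        p0 = cfg.baseline_prob
        fixed = []
        for gi in inten:
            arr = np.full(cfg.n_bins, p0)
            if gi.category_id == 0:
                arr[40:90] = p0 - 0.02
            fixed.append(dataclasses.replace(gi, intensity=arr))
        contrast = ground_truth_scfm_proxy(fixed, 0)
        assert contrast[0, 40:90] == pytest.approx(-0.02)
        assert not contrast[0, :40].any() and not contrast[0, 90:].any()
        # excitatory interval seen from the same construction
        contrast1 = ground_truth_scfm_proxy(fixed, 1)
        assert (contrast1[0, 40:90] > 0).all()

    def test_unknown_category_rejected(self):
        cfg = SimConfig(n_neurons=2, n_trials=10, seed=14)
        with pytest.raises(KeyError):
            ground_truth_scfm_proxy(sample_intensities(cfg), 7)

    def test_shuffled_labels_destroy_association(self):
        """Per-category mean patterns of shuffled labels converge to the grand mean."""
        from memdecode.spikeio import make_label_shuffled_control

        cfg = SimConfig(n_neurons=6, n_trials=400, seed=15)
        inten = sample_intensities(cfg)
        tensor, labels = simulate_trials(inten, cfg)
        shuffled = make_label_shuffled_control(labels, seed=99)
        counts = tensor.data.sum(axis=2).astype(float)
        cats = shuffled.category_index()
        grand = counts.mean(axis=0)
        for c in range(5):
            sel = counts[cats == c]
            se = counts.std(axis=0, ddof=1) / np.sqrt(len(sel))
            z = (sel.mean(axis=0) - grand) / se
            assert np.abs(z).max() < 4.5
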