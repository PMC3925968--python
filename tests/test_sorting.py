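"""Photobleaching-step detection, trace classification, l and gamma."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringfret import sorting, synth
from ringfret.mixture import fret_efficiency


def step_trace(levels, lengths, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.concatenate([np.full(n, lv, dtype=float) for lv, n in zip(levels, lengths)])
    if noise_sd:
        y = y + rng.normal(0, noise_sd, y.size)
    return y


def single_pair_truth(e, donor_bleach, acceptor_bleach, molecule_id="m"):
    return synth.TraceTruth(
        molecule_id, "minusLPC", "closed", 5,
        np.array([0]), np.array([1]), np.array([[e]]),
        np.array([donor_bleach]), np.array([acceptor_bleach]),
        leakage=0.09, gamma=0.89, brightness=500.0,
    )


class TestStepDetection:
    def test_noiseless_single_step(self):
        fit = sorting.count_bleach_steps(step_trace([100, 0], [50, 50]))
        assert fit.n_steps == 1
        assert fit.change_points.tolist() == [50]
        assert fit.levels == pytest.approx([100.0, 0.0])

    def test_noiseless_double_step(self):
        fit = sorting.count_bleach_steps(step_trace([200, 100, 0], [40, 40, 40]))
        assert fit.n_steps == 2

    def test_constant_trace_has_no_steps(self):
        fit = sorting.count_bleach_steps(np.full(60, 7.0))
        assert fit.n_steps == 0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            sorting.count_bleach_steps(np.zeros(10))

    def test_deterministic(self):
        y = step_trace([100, 0], [60, 60], noise_sd=10, seed=3)
        a = sorting.count_bleach_steps(y)
        b = sorting.count_bleach_steps(y)
        assert np.array_equal(a.change_points, b.change_points)
        assert a.levels == pytest.approx(b.levels)

    @given(offset=st.floats(-1000, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_constant_offset(self, offset):
        y = step_trace([100, 0], [60, 60], noise_sd=10, seed=3)
        a = sorting.count_bleach_steps(y)
        b = sorting.count_bleach_steps(y + offset)
        assert np.array_equal(a.change_points, b.change_points)
        assert b.levels - a.levels == pytest.approx(np.full(a.levels.size, offset), abs=1e-9)

    def test_step_count_accuracy_at_ten_percent_noise(self):
        # 200 seeded traces, noise sd = 10% of the step size
        rng = np.random.default_rng(42)
        correct = 0
        for i in range(200):
            n_true = int(rng.integers(1, 3))
            cps = np.sort(rng.choice(np.arange(20, 180), size=n_true, replace=False))
            levels = list(100.0 * np.arange(n_true, -1, -1))
            lengths = np.diff([0, *cps, 200]).tolist()
            y = step_trace(levels, lengths, noise_sd=10.0, seed=1000 + i)
            correct += sorting.count_bleach_steps(y).n_steps == n_true
        assert correct / 200 >= 0.95


class TestClassification:
    def _fits(self, donor, acceptor):
        return (
            sorting.count_bleach_steps(donor),
            sorting.count_bleach_steps(acceptor),
        )

    def test_simultaneous_drop_is_donor_first(self):
        d, a = self._fits(
            step_trace([770, 0], [100, 100]), step_trace([230, 0], [100, 100])
        )
        cls = sorting.classify_trace(d, a)
        assert cls.keep and cls.bleach_order == "donor_first"

    def test_two_donor_steps_discarded(self):
        d, a = self._fits(
            step_trace([400, 200, 0], [60, 60, 60]), step_trace([230, 0], [120, 60])
        )
        assert not sorting.classify_trace(d, a).keep

    def test_acceptor_drop_with_donor_rise_is_acceptor_first(self):
        truth = single_pair_truth(0.5, donor_bleach=20.0, acceptor_bleach=10.0)
        tr = synth.simulate_trace(truth, n_frames=300, noise_sd=0.0)
        d, a = self._fits(tr.donor_channel, tr.acceptor_channel)
        cls = sorting.classify_trace(d, a)
        assert cls.keep and cls.bleach_order == "acceptor_first"

    def test_surviving_donor_discarded(self):
        # donor channel never goes dark: a second donor outlived the window
        d, a = self._fits(
            step_trace([700, 350], [100, 100]), step_trace([230, 0], [100, 100])
        )
        assert not sorting.classify_trace(d, a).keep

    def test_classification_accuracy_on_observable_molecules(self):
        # noise at 10% of brightness; molecules whose bleach geometry is
        # observable must be classified to >= 95% agreement with truth
        rng = np.random.default_rng(7)
        total = correct = 0
        for i in range(150):
            # E range keeps every level change above the detection floor
            # (a step buried in noise is undetectable for any algorithm)
            e = rng.uniform(0.4, 0.65)
            t_d, t_a = rng.exponential(10.0), rng.exponential(10.0)
            # observable: both bleaches well separated, inside the window
            if min(t_d, t_a) < 1.0 or abs(t_d - t_a) < 1.0 or max(t_d, t_a) > 25.0:
                continue
            truth = single_pair_truth(e, t_d, t_a, molecule_id=f"m{i}")
            tr = synth.simulate_trace(truth, n_frames=300, noise_sd=50.0, seed=i)
            cls = sorting.classify_trace(
                sorting.count_bleach_steps(tr.donor_channel),
                sorting.count_bleach_steps(tr.acceptor_channel),
            )
            expected = "donor_first" if t_d < t_a else "acceptor_first"
            total += 1
            correct += cls.keep and cls.bleach_order == expected
        assert total > 60
        assert correct / total >= 0.95

    def test_noiseless_sorting_never_keeps_observable_multi_dye(self):
        cfg = synth.DatasetConfig(
            n_molecules={"minusLPC": 400}, noise_sd=0.0, n_frames=600
        )
        traces, truths = synth.simulate_dataset(cfg, seed=5)
        tm = {t.molecule_id: t for t in truths}
        checked = 0
        for tr in traces:
            t = tm[tr.molecule_id]
            times = [*t.donor_bleach_times, *t.acceptor_bleach_times]
            # observable: every dye's bleach leaves a trace signature
            observable = (
                t.donor_count >= 1
                and max(times) < 59.0
                and (t.acceptor_count == 0 or t.acceptor_bleach_times.max() < t.donor_bleach_times.min())
            )
            if not observable:
                continue
            cls = sorting.classify_trace(
                sorting.count_bleach_steps(tr.donor_channel),
                sorting.count_bleach_steps(tr.acceptor_channel),
            )
            if cls.keep and cls.bleach_order == "donor_first":
                checked += 1
                assert t.donor_count == 1 and t.acceptor_count <= 1
        assert checked >= 12


class TestExtraction:
    def test_noiseless_donor_first_levels(self):
        donor = step_trace([770, 0], [150, 150])
        acceptor = step_trace([230, 0], [150, 150])
        d = sorting.count_bleach_steps(donor)
        a = sorting.count_bleach_steps(acceptor)
        cls = sorting.classify_trace(d, a)
        trace = synth.IntensityTrace(np.arange(300) * 0.1, donor, acceptor, "minusLPC", "m")
        pair = sorting.extract_pair_intensities(trace, d, a, cls)
        assert pair.i_d == pytest.approx(770.0)
        assert pair.i_a == pytest.approx(230.0)

    def test_round_trip_efficiency_to_machine_precision(self):
        truth = single_pair_truth(0.63, donor_bleach=12.0, acceptor_bleach=25.0)
        tr = synth.simulate_trace(truth, n_frames=300, noise_sd=0.0)
        d = sorting.count_bleach_steps(tr.donor_channel)
        a = sorting.count_bleach_steps(tr.acceptor_channel)
        pair = sorting.extract_pair_intensities(tr, d, a, sorting.classify_trace(d, a))
        e = fret_efficiency(pair.i_a, pair.i_d, truth.leakage, truth.gamma)
        assert e == pytest.approx(0.63, abs=1e-12)

    def test_discarded_trace_refused(self):
        donor = step_trace([400, 200, 0], [60, 60, 60])
        acceptor = step_trace([230, 0], [120, 60])
        d = sorting.count_bleach_steps(donor)
        a = sorting.count_bleach_steps(acceptor)
        cls = sorting.classify_trace(d, a)
        trace = synth.IntensityTrace(np.arange(180) * 0.1, donor, acceptor, "x", "m")
        with pytest.raises(ValueError, match="discarded"):
            sorting.extract_pair_intensities(trace, d, a, cls)

    def test_noisy_intensity_within_two_sd(self):
        rng = np.random.default_rng(11)
        checked = 0
        for i in range(20):
            e = rng.uniform(0.2, 0.7)
            truth = single_pair_truth(e, 15.0, 28.0)
            tr = synth.simulate_trace(truth, n_frames=300, noise_sd=25.0, seed=i)
            d = sorting.count_bleach_steps(tr.donor_channel)
            a = sorting.count_bleach_steps(tr.acceptor_channel)
            cls = sorting.classify_trace(d, a)
            if not cls.keep:  # occasional low-E acceptor step below threshold
                continue
            pair = sorting.extract_pair_intensities(tr, d, a, cls)
            checked += 1
            expected_i_d = 500.0 * (1 - e)
            assert abs(pair.i_d - expected_i_d) < 2 * 25.0  # well within noise
        assert checked >= 15


class TestCorrections:
    def _donor_only_pairs(self, leakage, n, noise_sd=0.0, seed0=0):
        pairs = []
        for i in range(n):
            truth = synth.TraceTruth(
                f"m{i}", "x", "closed", 5, np.array([0]), np.array([], int),
                np.zeros((1, 0)), np.array([12.0 + (i % 7)]), np.array([]),
                leakage=leakage, gamma=0.89, brightness=500.0,
            )
            tr = synth.simulate_trace(truth, 300, noise_sd, seed=seed0 + i)
            try:
                pairs.append(sorting.donor_only_pair(tr.donor_channel, tr.acceptor_channel))
            except ValueError:
                continue  # rare spurious extra step under noise
        return pairs

    def test_leakage_round_trip_exact(self):
        leak, _ = sorting.estimate_leakage(self._donor_only_pairs(0.09, 5))
        assert leak == pytest.approx(0.09, abs=1e-12)

    def test_zero_leakage(self):
        leak, _ = sorting.estimate_leakage(self._donor_only_pairs(0.0, 5))
        assert leak == pytest.approx(0.0, abs=1e-12)

    def test_leakage_recovery_within_ci(self):
        leak, se = sorting.estimate_leakage(
            self._donor_only_pairs(0.09, 300, noise_sd=25.0)
        )
        assert abs(leak - 0.09) < 1.96 * se + 1e-4

    def _acceptor_first_pairs(self, gamma, n, noise_sd=0.0, seed0=0):
        rng = np.random.default_rng(seed0)
        pairs = []
        for i in range(n):
            e = rng.uniform(0.2, 0.7)
            truth = synth.TraceTruth(
                f"m{i}", "x", "closed", 5, np.array([0]), np.array([1]),
                np.array([[e]]), np.array([22.0]), np.array([8.0 + (i % 5)]),
                leakage=0.09, gamma=gamma, brightness=500.0,
            )
            tr = synth.simulate_trace(truth, 300, noise_sd, seed=seed0 + i)
            d = sorting.count_bleach_steps(tr.donor_channel)
            a = sorting.count_bleach_steps(tr.acceptor_channel)
            cls = sorting.classify_trace(d, a)
            if cls.keep and cls.bleach_order == "acceptor_first":
                pairs.append(sorting.extract_pair_intensities(tr, d, a, cls))
        return pairs

    def test_gamma_round_trip_exact(self):
        gamma, _ = sorting.estimate_gamma(self._acceptor_first_pairs(0.89, 5))
        assert gamma == pytest.approx(0.89, abs=1e-12)

    def test_gamma_unity(self):
        gamma, _ = sorting.estimate_gamma(self._acceptor_first_pairs(1.0, 5))
        assert gamma == pytest.approx(1.0, abs=1e-12)

    def test_gamma_recovery_within_ci(self):
        gamma, se = sorting.estimate_gamma(
            self._acceptor_first_pairs(0.89, 300, noise_sd=25.0)
        )
        assert abs(gamma - 0.89) < 1.96 * se + 1e-3

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            sorting.estimate_leakage([])
        with pytest.raises(ValueError):
            sorting.estimate_gamma([])
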