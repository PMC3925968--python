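"""Synthetic-data generator: labelling statistics, trace model, spectra, IO."""

import itertools

import numpy as np
import pytest
from scipy.stats import kstest, norm

from ringfret import io, synth


def binomial_marginal_by_enumeration(n_sub, p_d, p_a):
    """Donor-count pmf by brute-force enumeration of per-subunit outcomes."""
    pmf = np.zeros(n_sub + 1)
    for outcome in itertools.product(("d", "a", "none"), repeat=n_sub):
        prob = 1.0
        for o in outcome:
            prob *= {"d": p_d, "a": p_a, "none": 1 - p_d - p_a}[o]
        pmf[sum(o == "d" for o in outcome)] += prob
    return pmf


class TestLabeling:
    def test_mean_stoichiometry(self):
        cfg = synth.LabelingConfig(5, 1.7, 1.3)
        draws = synth.draw_label_counts(cfg, 100_000, seed=0)
        donors = np.array([d for d, _, _, _ in draws])
        acceptors = np.array([a for _, a, _, _ in draws])
        assert abs(donors.mean() - 1.7) < 0.05
        assert abs(acceptors.mean() - 1.3) < 0.05

    def test_zero_labeling(self):
        draws = synth.draw_label_counts(synth.LabelingConfig(5, 0.0, 0.0), 50, seed=0)
        assert all(d == 0 and a == 0 for d, a, _, _ in draws)

    def test_marginal_matches_enumeration_oracle(self):
        cfg = synth.LabelingConfig(5, 1.7, 1.3)
        draws = synth.draw_label_counts(cfg, 100_000, seed=1)
        counts = np.bincount([d for d, _, _, _ in draws], minlength=6)
        empirical = counts / counts.sum()
        exact = binomial_marginal_by_enumeration(5, 1.7 / 5, 1.3 / 5)
        assert 0.5 * np.abs(empirical - exact).sum() < 0.01  # total variation

    def test_positions_distinct_and_disjoint(self):
        for d, a, dp, ap in synth.draw_label_counts(
            synth.LabelingConfig(5, 2.0, 2.0), 500, seed=2
        ):
            assert len(set(dp)) == d and len(set(ap)) == a
            assert not set(dp) & set(ap)

    def test_overfull_config_rejected(self):
        with pytest.raises(ValueError):
            synth.LabelingConfig(5, 3.0, 2.5)

    def test_reproducible(self):
        cfg = synth.LabelingConfig()
        a = synth.draw_label_counts(cfg, 100, seed=9)
        b = synth.draw_label_counts(cfg, 100, seed=9)
        assert all(
            x[0] == y[0] and np.array_equal(x[2], y[2]) for x, y in zip(a, b)
        )


class TestTraceModel:
    def test_donor_only_leakage_identity(self):
        truth = synth.TraceTruth(
            "m", "x", "closed", 5, np.array([0]), np.array([], int),
            np.zeros((1, 0)), np.array([5.0]), np.array([]),
            leakage=0.09, gamma=0.89, brightness=500.0,
        )
        tr = synth.simulate_trace(truth, n_frames=100, noise_sd=0.0)
        pre = tr.frame_times < 5.0
        assert tr.acceptor_channel[pre] == pytest.approx(0.09 * tr.donor_channel[pre])
        assert np.all(tr.donor_channel[~pre] == 0)
        assert np.all(tr.acceptor_channel[~pre] == 0)

    def test_acceptor_bleach_raises_donor_channel(self):
        truth = synth.TraceTruth(
            "m", "x", "open", 5, np.array([0]), np.array([1]),
            np.array([[0.4]]), np.array([20.0]), np.array([8.0]),
            leakage=0.09, gamma=0.89, brightness=500.0,
        )
        tr = synth.simulate_trace(truth, n_frames=250, noise_sd=0.0)
        before = tr.donor_channel[tr.frame_times < 8.0]
        after = tr.donor_channel[(tr.frame_times > 8.0) & (tr.frame_times < 20.0)]
        assert after.mean() > before.mean()
        assert tr.acceptor_channel[tr.frame_times < 8.0].mean() > tr.acceptor_channel[
            (tr.frame_times > 8.0) & (tr.frame_times < 20.0)
        ].mean()

    def test_mean_recovered_efficiency_over_noisy_traces(self):
        # 500 seeded traces at 5% noise: mean extracted E within 0.01 of truth
        from ringfret import sorting
        from ringfret.mixture import fret_efficiency

        e_true = 0.63
        errs = []
        for i in range(500):
            truth = synth.TraceTruth(
                f"m{i}", "x", "closed", 5, np.array([0]), np.array([1]),
                np.array([[e_true]]), np.array([10.0 + (i % 10)]), np.array([40.0]),
                leakage=0.09, gamma=0.89, brightness=500.0,
            )
            tr = synth.simulate_trace(truth, 300, noise_sd=25.0, seed=i)
            d = sorting.count_bleach_steps(tr.donor_channel)
            a = sorting.count_bleach_steps(tr.acceptor_channel)
            cls = sorting.classify_trace(d, a)
            if not cls.keep:
                continue
            pair = sorting.extract_pair_intensities(tr, d, a, cls)
            errs.append(fret_efficiency(pair.i_a, pair.i_d, 0.09, 0.89) - e_true)
        assert len(errs) > 450
        assert abs(np.mean(errs)) < 0.01

    def test_mixed_subunit_occupancy_rejected(self):
        with pytest.raises(ValueError, match="both a donor and an acceptor"):
            synth.TraceTruth(
                "m", "x", "closed", 5, np.array([0]), np.array([0]),
                np.array([[0.5]]), np.array([5.0]), np.array([5.0]),
                leakage=0.09, gamma=0.89, brightness=500.0,
            )


class TestDataset:
    def test_unimodal_when_fully_closed_single_near_pair(self):
        cfg = synth.DatasetConfig(
            n_molecules={"minusLPC": 200},
            closed_fraction={"minusLPC": 1.0},
            force_single_pair=True,
            force_sep=1,
            e_jitter_sd=0.02,
        )
        _, truths = synth.simulate_dataset(cfg, seed=0)
        es = np.array([t.true_e for t in truths])
        assert np.all(np.abs(es - 0.63) < 0.12)  # one population only

    def test_identical_seeds_give_identical_datasets(self, tmp_path):
        cfg = synth.DatasetConfig(n_molecules={"minusLPC": 20, "plusLPC": 20})
        tr1, _ = synth.simulate_dataset(cfg, seed=4)
        tr2, _ = synth.simulate_dataset(cfg, seed=4)
        for a, b in zip(tr1, tr2):
            assert np.array_equal(a.donor_channel, b.donor_channel)
            assert np.array_equal(a.acceptor_channel, b.acceptor_channel)
        # byte-identical on disk
        io.write_dataset(tr1, tmp_path / "a")
        io.write_dataset(tr2, tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_empty_condition_list_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_dataset(synth.DatasetConfig(n_molecules={}), seed=0)

    def test_true_efficiencies_converge_to_configured_mixture(self):
        cfg = synth.DatasetConfig(
            n_molecules={"x": 3000},
            closed_fraction={"x": 0.6},
            force_single_pair=True,
            noise_sd=0.0,
            n_frames=30,
        )
        _, truths = synth.simulate_dataset(cfg, seed=8)
        es = np.array([t.true_e for t in truths])
        comps = [  # (weight, mean, sd) implied by the default table
            (0.3, 0.63, cfg.e_jitter_sd),
            (0.3 + 0.2, 0.28, cfg.e_jitter_sd),
            (0.2, 0.10, cfg.e_jitter_sd),
        ]

        def cdf(x):
            return sum(w * norm.cdf(x, mu, sd) for w, mu, sd in comps)

        stat = kstest(es, cdf).statistic
        assert stat < 1.63 / np.sqrt(es.size) * 1.5  # ~ p > 0.01 with headroom

    def test_truth_table_round_trip(self):
        cfg = synth.DatasetConfig(n_molecules={"minusLPC": 30})
        _, truths = synth.simulate_dataset(cfg, seed=1)
        table = synth.truth_table(truths)
        assert len(table) == 30
        assert set(table["condition"]) == {"minusLPC"}
        assert (table["donor_count"] >= 0).all()


class TestSpectraAndIO:
    def test_zero_overlap_rectangles(self):
        from ringfret.photophysics import overlap_integral

        em = synth.rectangular_spectrum(480, 540, 490, 510, 1.0)
        ext = synth.rectangular_spectrum(560, 640, 580, 620, 9e4)
        with pytest.warns(UserWarning):
            assert overlap_integral(em.wavelengths, em.values, ext.wavelengths, ext.values) == 0.0

    def test_identical_spectra_return_standard_yield(self):
        from ringfret.photophysics import quantum_yield

        spectra = synth.simulate_spectra()
        area = np.trapezoid(spectra["standard_emission"].values,
                            spectra["standard_emission"].wavelengths)
        q = quantum_yield(0.05, 0.05, area, area, q_standard=0.925)
        assert q == pytest.approx(0.925)

    def test_nonmonotone_grid_rejected(self):
        with pytest.raises(ValueError):
            synth.SpectrumPair(np.array([500.0, 499.0, 501.0]), np.ones(3))

    def test_trace_tsv_round_trip(self, tmp_path):
        truth = synth.TraceTruth(
            "m0", "plusLPC", "open", 5, np.array([0]), np.array([1]),
            np.array([[0.3]]), np.array([5.0]), np.array([9.0]),
            leakage=0.09, gamma=0.89, brightness=500.0,
        )
        tr = synth.simulate_trace(truth, 100, noise_sd=10.0, seed=0)
        io.write_trace(tr, tmp_path / "m0.tsv")
        back = io.read_trace(tmp_path / "m0.tsv", condition="plusLPC")
        assert back.donor_channel == pytest.approx(tr.donor_channel, abs=1e-5)
        assert back.molecule_id == "m0"

    def test_spectrum_csv_round_trip(self, tmp_path):
        spec = synth.gaussian_spectrum(460, 650, 520, 18, 1.0)
        io.write_spectrum(spec, tmp_path / "em.csv")
        back = io.read_spectrum(tmp_path / "em.csv")
        assert back.values == pytest.approx(spec.values)

    def test_manifest_round_trip(self, tmp_path):
        cfg = synth.DatasetConfig(n_molecules={"minusLPC": 5, "plusLPC": 5})
        traces, _ = synth.simulate_dataset(cfg, seed=2)
        manifest = io.write_dataset(traces, tmp_path / "ds")
        back = io.read_dataset(manifest)
        assert len(back) == 10
        assert {t.condition for t in back} == {"minusLPC", "plusLPC"}
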