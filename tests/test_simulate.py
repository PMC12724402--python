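"""Synthetic ground truths, textures, observers, gaze streams and epochs."""

import numpy as np
import pytest

from perceptseg import eeg, gaze, inference, simulate
from perceptseg.maps import SegMap


class TestGroundTruth:
    def test_all_labels_present_and_compact(self):
        for seed in range(5):
            for K in (2, 3, 4, 5):
                gt = simulate.make_ground_truth_map(K, seed=seed)
                assert set(np.unique(gt.labels)) == set(range(1, K + 1))

    def test_seed_determinism(self):
        a = simulate.make_ground_truth_map(3, seed=7)
        b = simulate.make_ground_truth_map(3, seed=7)
        assert np.array_equal(a.labels, b.labels)

    def test_regions_more_compact_than_shuffled(self):
        """Within-region 4-neighbor agreement beats a spatially shuffled map."""
        def adjacency_agreement(labels):
            same = 0
            total = 0
            same += np.sum(labels[:, :-1] == labels[:, 1:])
            total += labels[:, :-1].size
            same += np.sum(labels[:-1, :] == labels[1:, :])
            total += labels[:-1, :].size
            return same / total

        rng = np.random.default_rng(0)
        for seed in range(5):
            gt = simulate.make_ground_truth_map(3, seed=seed)
            shuffled = rng.permutation(gt.labels.ravel()).reshape(15, 15)
            assert adjacency_agreement(gt.labels) > adjacency_agreement(shuffled)

    def test_tiny_grid_raises(self):
        with pytest.raises(ValueError):
            simulate.make_ground_truth_map(5, grid_h=2, grid_w=2)


class TestTexture:
    @staticmethod
    def _dominant_orientation(patch):
        win = np.hanning(patch.shape[0])[:, None] * np.hanning(patch.shape[1])[None, :]
        F = np.abs(np.fft.fft2(patch * win)) ** 2
        fy = np.fft.fftfreq(patch.shape[0])[:, None]
        fx = np.fft.fftfreq(patch.shape[1])[None, :]
        rho = np.hypot(fx, fy)
        m = (rho > 0.05) & (rho < 0.30)
        phi = np.arctan2(fy, fx)
        c = np.sum(F[m] * np.exp(2j * phi[m]))
        return np.rad2deg(np.angle(c) / 2) % 180

    @pytest.fixture()
    def split_partition(self):
        labels = np.ones((15, 15), dtype=int)
        labels[:, 8:] = 2
        return SegMap(labels, K=2)

    def test_orientations_match_specification(self, split_partition):
        """Fourier-peak oracle recovers each region's spectral orientation."""
        img = simulate.make_texture_stimulus(split_partition, [30.0, 120.0], seed=0)
        left = self._dominant_orientation(img[20:120, 10:110])
        right = self._dominant_orientation(img[20:120, 150:250])
        assert min(abs(left - 30.0), 180 - abs(left - 30.0)) < 5.0
        assert min(abs(right - 120.0), 180 - abs(right - 120.0)) < 5.0

    def test_identical_parameters_are_homogeneous(self, split_partition):
        """Equal band parameters leave no region-discriminating statistic."""
        from scipy.stats import ttest_ind

        img = simulate.make_texture_stimulus(split_partition, [45.0, 45.0], seed=1)
        # oriented local energy as the discriminating feature
        gy, gx = np.gradient(img)
        energy = gx**2 + gy**2
        left = energy[:, :120].ravel()
        right = energy[:, 136:].ravel()
        res = ttest_ind(left[::97], right[::97], equal_var=False)
        assert res.pvalue > 0.05

    def test_seed_determinism(self, split_partition):
        a = simulate.make_texture_stimulus(split_partition, [10.0, 100.0], seed=4)
        b = simulate.make_texture_stimulus(split_partition, [10.0, 100.0], seed=4)
        np.testing.assert_array_equal(a, b)

    def test_invalid_band_raises(self, split_partition):
        with pytest.raises(ValueError):
            simulate.make_texture_stimulus(split_partition, [0.0, 90.0],
                                           freqs_cpp=[0.7, 0.1])


class TestObserver:
    def test_deterministic_observer_matches_truth(self, gt2, stim2):
        obs = simulate.ObserverParams(ground_truth=gt2, certainty=1.0, lapse=0.0,
                                      seed=0)
        block = simulate.simulate_observer_block(obs, stim2, n_trials=225)
        _, rate = inference.classify_consistency(block, gt2)
        assert rate == 0.0

    def test_full_lapse_yields_coin_flip_marginal(self, gt2, stim2):
        obs = simulate.ObserverParams(ground_truth=gt2, certainty=0.9, lapse=1.0,
                                      seed=0)
        block = simulate.simulate_observer_block(obs, stim2, n_trials=900)
        frac = np.mean([t.response == "same" for t in block.trials])
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(900)

    def test_schedule_default_and_reproducibility(self, gt2, stim2):
        obs = simulate.ObserverParams(ground_truth=gt2, seed=5)
        b1 = simulate.simulate_observer_block(obs, stim2)
        b2 = simulate.simulate_observer_block(obs, stim2)
        assert len(b1.trials) == inference.trial_schedule(2)
        assert b1.trials == b2.trials

    def test_rt_follows_halving_curve(self, gt2, stim2):
        obs = simulate.ObserverParams(ground_truth=gt2, rt_alpha=1.0, rt_tau=20.0,
                                      rt_noise_sd=0.0, seed=0)
        block = simulate.simulate_observer_block(obs, stim2, n_trials=40)
        rts = np.array([t.rt for t in block.trials])
        np.testing.assert_allclose(
            rts, 2.0 ** (-np.arange(1, 41) / 20.0), rtol=1e-12
        )

    def test_parameter_validation(self, gt2):
        with pytest.raises(ValueError):
            simulate.ObserverParams(ground_truth=gt2, certainty=0.3)
        with pytest.raises(ValueError):
            simulate.ObserverParams(ground_truth=gt2, lapse=1.5)


class TestGazeSim:
    def test_point_fixation_single_cell(self):
        s = simulate.simulate_gaze(1.0, 0.0, 1, jitter_px=0.0, seed=0)
        assert gaze.coverage(s, 1.0) == pytest.approx(100.0 / 225)

    def test_seed_determinism(self):
        a = simulate.simulate_gaze(2.0, 40.0, 8, seed=3)
        b = simulate.simulate_gaze(2.0, 40.0, 8, seed=3)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.t, b.t)

    def test_samples_at_500hz_inside_image(self):
        s = simulate.simulate_gaze(2.0, 50.0, 8, seed=1)
        assert len(s) == 1000
        assert np.allclose(np.diff(s.t), 0.002)
        assert s.x.min() >= 0 and s.x.max() < 256

    def test_validators_accept_generated_stream(self):
        s = simulate.simulate_gaze(**simulate.gaze_preset("NT"), seed=2)
        cleaned, retention = gaze.clean_gaze(s)
        assert retention == 1.0


class TestEpochSim:
    def test_noiseless_component_peaks_at_latency(self):
        p = simulate.EEGSimParams(components=[(350.0, 5.0, 40.0)], noise_sd=0.0,
                                  n_epochs=2, seed=0)
        ep = simulate.simulate_epochs(p, [0.5, 0.6])
        erp = eeg.compute_erp(ep)
        ch, ti = np.unravel_index(np.argmax(erp.data), erp.data.shape)
        assert abs(ep.times_ms[ti] - 350.0) < 2.0
        # the peak channel carries the full component amplitude (up to the
        # half-sample offset between the latency and the time grid)
        assert erp.data[ch, ti] == pytest.approx(5.0, rel=1e-3)

    def test_amplitude_ratio_transfers_to_gfp_peak(self):
        """A x0.7 component amplitude yields a x0.7 grand-average GFP peak."""
        rts = np.full(40, 0.5)

        def grand_gfp(amp, base):
            erps = []
            for s in range(8):
                p = simulate.EEGSimParams(components=[(350.0, amp, 50.0)],
                                          n_epochs=40, seed=base + s)
                erps.append(eeg.compute_erp(simulate.simulate_epochs(p, rts)))
            return eeg.gfp(eeg.grand_average(erps).data)

        ga = grand_gfp(10.0, 100)
        gb = grand_gfp(7.0, 200)
        assert gb.max() / ga.max() == pytest.approx(0.7, rel=0.10)

    def test_seed_determinism(self):
        p = simulate.eeg_preset("NT", seed=9, n_epochs=3)
        a = simulate.simulate_epochs(p, [0.4, 0.5, 0.6])
        b = simulate.simulate_epochs(p, [0.4, 0.5, 0.6])
        np.testing.assert_array_equal(a.data, b.data)

    def test_latency_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            simulate.EEGSimParams(components=[(1500.0, 5.0, 40.0)])


class TestPresetContrasts:
    def test_qualitative_cohort_directions(self, stim2):
        """NT-like vs ASD-like bundles reproduce the study's contrast
        directions: faster NT medians, wider ASD coverage, and a detectable
        posterior GFP difference inside the image-presentation window."""
        rt_ok = cov_ok = 0
        n_seeds = 10
        for seed in range(n_seeds):
            gt = simulate.make_ground_truth_map(2, seed=seed)
            nt_block = simulate.simulate_observer_block(
                simulate.observer_preset("NT", gt, seed=seed), stim2, 225)
            asd_block = simulate.simulate_observer_block(
                simulate.observer_preset("ASD", gt, seed=seed + 999), stim2, 225)
            med_nt = np.median([t.rt for t in nt_block.trials])
            med_asd = np.median([t.rt for t in asd_block.trials])
            rt_ok += med_nt < med_asd

            nt_g = simulate.simulate_gaze(**simulate.gaze_preset("NT"), seed=seed)
            asd_g = simulate.simulate_gaze(**simulate.gaze_preset("ASD"),
                                           seed=seed + 999)
            cov_nt = gaze.coverage(gaze.clean_gaze(nt_g)[0], 9.0)
            cov_asd = gaze.coverage(gaze.clean_gaze(asd_g)[0], 10.5)
            cov_ok += cov_asd > cov_nt
        assert rt_ok >= 9
        assert cov_ok >= 8

    def test_unknown_cohort_rejected(self, gt2):
        with pytest.raises(ValueError):
            simulate.observer_preset("XX", gt2)
        with pytest.raises(ValueError):
            simulate.gaze_preset("XX")
        with pytest.raises(ValueError):
            simulate.eeg_preset("XX")


class TestMontage:
    def test_montage_names_and_geometry(self):
        names, pos = simulate.load_montage()
        assert len(names) == 64 and pos.shape == (64, 2)
        assert len(set(names)) == 64
        for c in eeg.OPO_CHANNELS:
            assert c in names
            assert pos[names.index(c), 1] < -0.4  # posterior channels sit low

    def test_fixture_matches_generator(self, tmp_path):
        simulate.write_montage_fixture(tmp_path / "m.csv")
        import csv

        with open(tmp_path / "m.csv") as fh:
            rows = list(csv.DictReader(fh))
        names, pos = simulate.load_montage()
        assert [r["name"] for r in rows] == names
        np.testing.assert_allclose(
            [[float(r["x"]), float(r["y"])] for r in rows], pos
        )
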