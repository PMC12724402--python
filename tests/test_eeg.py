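"""Epoch exclusion, referencing, ERPs, significance windows, GFP, clusters."""

import numpy as np
import pytest

from perceptseg import simulate
from perceptseg.eeg import (
    ERP,
    EpochSet,
    baseline_correct,
    channel_adjacency,
    cluster_permutation_test,
    compute_erp,
    exclude_by_rt,
    gfp,
    gfp_interval_tests,
    grand_average,
    pointwise_ttest_windows,
    rereference_average,
    topomap_frame,
)


def _times(n=768, sfreq=512.0):
    return -500.0 + np.arange(n) * 1000.0 / sfreq


def _epochs(data, rt, n_ch=None):
    data = np.asarray(data, float)
    n_ch = data.shape[0]
    names, pos = simulate.load_montage()
    return EpochSet(data, names[:n_ch], pos[:n_ch], _times(data.shape[1]),
                    np.asarray(rt, float))


class TestExcludeByRT:
    def test_even_grid_example(self):
        """20 epochs, RTs 0.1..2.0: the two slowest go, none exceed 2.5 s."""
        rt = np.linspace(0.1, 2.0, 20)
        ep = _epochs(np.zeros((2, 768, 20)), rt)
        out = exclude_by_rt(ep)
        assert out.n_epochs == 18
        assert out.rt.max() == pytest.approx(1.8)

    def test_equal_rts_ceil_rule(self):
        ep = _epochs(np.zeros((2, 768, 25)), np.full(25, 0.5))
        out = exclude_by_rt(ep)
        assert out.n_epochs == 25 - int(np.ceil(0.1 * 25))

    def test_cap_applies_after_slow_stage(self):
        rt = np.concatenate([np.full(18, 0.5), [3.0, 5.0]])
        ep = _epochs(np.zeros((2, 768, 20)), rt)
        out = exclude_by_rt(ep)
        assert np.all(out.rt <= 2.5)

    def test_all_excluded_raises(self):
        ep = _epochs(np.zeros((2, 768, 3)), np.full(3, 4.0))
        with pytest.raises(ValueError):
            exclude_by_rt(ep)


class TestReferenceAndBaseline:
    def test_common_signal_removed(self):
        sig = np.random.default_rng(0).standard_normal((1, 768, 4))
        data = np.repeat(sig, 8, axis=0)
        out = rereference_average(_epochs(data, np.full(4, 0.5)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_channel_mean_zero_everywhere(self):
        data = np.random.default_rng(1).standard_normal((8, 768, 3))
        out = rereference_average(_epochs(data, np.full(3, 0.5)))
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-9)

    def test_antisymmetric_pair_unchanged(self):
        a = np.random.default_rng(2).standard_normal((1, 768, 2))
        data = np.concatenate([a, -a], axis=0)
        out = rereference_average(_epochs(data, np.full(2, 0.5)))
        np.testing.assert_allclose(out.data, data, atol=1e-12)

    def test_baseline_zeroes_constant_signal(self):
        data = np.full((4, 768, 2), 3.3)
        out = baseline_correct(_epochs(data, np.full(2, 0.5)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_baseline_window_mean_is_zero(self):
        data = np.random.default_rng(3).standard_normal((4, 768, 2))
        out = baseline_correct(_epochs(data, np.full(2, 0.5)))
        sel = (out.times_ms >= -100) & (out.times_ms <= 0)
        np.testing.assert_allclose(out.data[:, sel, :].mean(axis=1), 0.0, atol=1e-12)

    def test_windows_differ_by_constant(self):
        data = np.random.default_rng(4).standard_normal((4, 768, 2))
        ep = _epochs(data, np.full(2, 0.5))
        a = baseline_correct(ep, (-100.0, 0.0)).data
        b = baseline_correct(ep, (-25.0, 0.0)).data
        diff = a - b
        assert np.abs(diff - diff[:, :1, :]).max() < 1e-12

    def test_empty_window_raises(self):
        ep = _epochs(np.zeros((4, 768, 2)), np.full(2, 0.5))
        with pytest.raises(ValueError):
            baseline_correct(ep, (1000.0, 1001.0))


class TestERP:
    def test_single_epoch_identity(self):
        data = np.random.default_rng(5).standard_normal((4, 768, 1))
        erp = compute_erp(_epochs(data, [0.5]))
        np.testing.assert_allclose(erp.data, data[:, :, 0])

    def test_opposite_epochs_cancel(self):
        a = np.random.default_rng(6).standard_normal((4, 768, 1))
        data = np.concatenate([a, -a], axis=2)
        erp = compute_erp(_epochs(data, [0.5, 0.5]))
        np.testing.assert_allclose(erp.data, 0.0, atol=1e-12)

    def test_named_subset_average(self):
        names, pos = simulate.load_montage()
        data = np.zeros((64, 768, 2))
        subset = ["O1", "Oz", "O2", "PO7", "PO3", "POz", "PO4", "PO8"]
        for c in subset:
            data[names.index(c)] = 8.0
        ep = EpochSet(data, names, pos, _times(), np.full(2, 0.5))
        erp = compute_erp(ep, channels=subset)
        assert erp.data.ndim == 1
        np.testing.assert_allclose(erp.data, 8.0)

    def test_empty_subset_raises(self):
        ep = _epochs(np.zeros((4, 768, 2)), np.full(2, 0.5))
        with pytest.raises(ValueError):
            compute_erp(ep, channels=[])

    def test_linearity_of_aggregation(self):
        rng = np.random.default_rng(7)
        d1 = rng.standard_normal((4, 100, 3))
        d2 = rng.standard_normal((4, 100, 3))
        e1 = ERP(d1.mean(axis=2), _times(100), 3)
        e2 = ERP(d2.mean(axis=2), _times(100), 3)
        ga = grand_average([e1, e2])
        np.testing.assert_allclose(ga.data, (e1.data + e2.data) / 2, atol=1e-12)


class TestPointwiseWindows:
    def test_identical_groups_no_windows(self):
        rng = np.random.default_rng(8)
        g = rng.standard_normal((6, 768))
        win = pointwise_ttest_windows(g, g.copy(), _times())
        assert win.windows == []

    def test_short_run_discarded(self):
        """A supra-threshold run of ~30 ms never survives the 50-ms rule."""
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1.0, (8, 768))
        b = rng.normal(0, 1.0, (8, 768))
        t = _times()
        run = (t >= 300) & (t < 330)  # 30 ms
        a[:, run] += 10.0
        win = pointwise_ttest_windows(a, b, t, min_duration_ms=50.0)
        assert all(not (lo <= 330 and hi >= 300) for lo, hi in win.windows)

    def test_injected_offset_detected_every_seed(self):
        """A +3 uV offset over 250-400 ms (n=8/8, sd 1 uV) is always found."""
        t = _times()
        band = (t >= 250) & (t <= 400)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1.0, (8, 768))
            b = rng.normal(0, 1.0, (8, 768))
            a[:, band] += 3.0
            win = pointwise_ttest_windows(a, b, t)
            hits += any(lo <= 400 and hi >= 250 for lo, hi in win.windows)
        assert hits == 20

    def test_ordering_invariance(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1.0, (8, 768))
        b = rng.normal(0, 1.0, (8, 768))
        a[:, 300:500] += 2.0
        w1 = pointwise_ttest_windows(a, b, _times()).windows
        perm = rng.permutation(8)
        w2 = pointwise_ttest_windows(a[perm], b[perm], _times()).windows
        assert w1 == w2


class TestGFP:
    def test_equal_channels_zero(self):
        assert gfp(np.full((8, 10), 3.0)).max() == 0.0

    def test_two_channel_printed_formula(self):
        assert gfp(np.array([[1.0], [-1.0]]))[0] == pytest.approx(1.0)

    def test_homogeneity(self):
        rng = np.random.default_rng(11)
        d = rng.standard_normal((8, 100))
        np.testing.assert_allclose(gfp(-2.5 * d), 2.5 * gfp(d), atol=1e-12)

    def test_invariant_to_average_reference(self):
        rng = np.random.default_rng(12)
        data = rng.standard_normal((8, 100, 3))
        ep = _epochs(data, np.full(3, 0.5))
        reref = rereference_average(ep)
        np.testing.assert_allclose(
            gfp(ep.data.mean(axis=2)), gfp(reref.data.mean(axis=2)), atol=1e-9
        )

    def test_interval_tests_flag_injected_band(self):
        """The injected band is flagged on every seed; outside the band the
        uncorrected tests fire at roughly their nominal false-positive rate."""
        t = _times()
        hits = 0
        out_flags = out_points = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = np.abs(rng.normal(1.0, 0.2, (8, 768)))
            b = np.abs(rng.normal(1.0, 0.2, (8, 768)))
            band = (t >= 250) & (t <= 400)
            a[:, band] += 2.0
            tt, p, flags = gfp_interval_tests(a, b, t)
            inside = flags & (tt >= 250) & (tt <= 400)
            outside_sel = (tt < 200) | (tt > 450)
            hits += bool(inside.any())
            out_flags += int((flags & outside_sel).sum())
            out_points += int(outside_sel.sum())
        assert hits == 20
        assert out_flags / out_points <= 0.12  # near the nominal 5% rate

    def test_constant_difference_flags_everywhere(self):
        t = _times()
        rng = np.random.default_rng(13)
        a = np.abs(rng.normal(2.0, 0.05, (8, 768)))
        b = np.abs(rng.normal(1.0, 0.05, (8, 768)))
        _, _, flags = gfp_interval_tests(a, b, t)
        assert flags.all()


class TestTopomap:
    def test_zero_erp_zero_frame(self):
        names, pos = simulate.load_montage()
        erp = ERP(np.zeros((64, 768)), _times(), 1)
        f = topomap_frame(erp, pos, 350.0)
        assert np.all(f["raw"] == 0) and np.all(f["display"] == 0)

    def test_clipping_keeps_raw(self):
        names, pos = simulate.load_montage()
        data = np.full((64, 768), 12.0)
        f = topomap_frame(ERP(data, _times(), 1), pos, 0.0)
        assert np.all(f["display"] == 10.0) and np.all(f["raw"] == 12.0)

    def test_out_of_epoch_raises(self):
        names, pos = simulate.load_montage()
        with pytest.raises(ValueError):
            topomap_frame(ERP(np.zeros((64, 768)), _times(), 1), pos, 2000.0)


@pytest.fixture(scope="module")
def adjacency():
    _, pos = simulate.load_montage()
    return channel_adjacency(pos)


class TestClusterPermutation:

    def test_null_calibration(self, adjacency):
        """Identical generating distributions rarely yield significant clusters."""
        sig = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal((8, 64, 60))
            b = rng.standard_normal((8, 64, 60))
            res = cluster_permutation_test(a, b, adjacency, n_perm=100, seed=seed)
            sig += bool(res.p_values.size and (res.p_values < 0.05).any())
        assert sig <= 1

    def test_posterior_effect_localized(self, adjacency):
        names, pos = simulate.load_montage()
        post = [names.index(c) for c in
                ("O1", "Oz", "O2", "PO7", "PO3", "POz", "PO4", "PO8")]
        rng = np.random.default_rng(1)
        a = rng.standard_normal((8, 64, 60))
        b = rng.standard_normal((8, 64, 60))
        a[:, np.asarray(post)[:, None], 20:40] += 3.0
        res = cluster_permutation_test(a, b, adjacency, n_perm=200, seed=0)
        best = int(np.argmin(res.p_values))
        assert res.p_values[best] < 0.05
        chans = set(np.unique(np.where(res.clusters[best])[0]))
        ring = set(post)
        for c in post:
            ring |= set(adjacency[c].indices)
        assert chans <= ring

    def test_single_permutation_boundary(self, adjacency):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((4, 64, 30)) + 2.0
        b = rng.standard_normal((4, 64, 30))
        res = cluster_permutation_test(a, b, adjacency, n_perm=1, seed=0)
        assert set(np.round(res.p_values, 6)) <= {0.5, 1.0}

    def test_too_few_units_raises(self, adjacency):
        with pytest.raises(ValueError):
            cluster_permutation_test(
                np.zeros((1, 64, 10)), np.zeros((4, 64, 10)), adjacency
            )


class TestEpochIO:
    def test_hdf5_roundtrip(self, tmp_path):
        p = simulate.eeg_preset("NT", seed=0, n_epochs=3)
        ep = simulate.simulate_epochs(p, [0.4, 0.5, 0.6], cohort="NT")
        ep.to_hdf5(tmp_path / "e.h5")
        back = EpochSet.from_hdf5(tmp_path / "e.h5")
        np.testing.assert_allclose(back.data, ep.data)
        assert back.ch_names == ep.ch_names and back.cohort == "NT"

    def test_long_table_adapter(self, tmp_path):
        import pandas as pd

        rows = []
        for e in range(2):
            for ch in ("A", "B"):
                for i, t in enumerate((-10.0, 0.0, 10.0)):
                    rows.append((e, ch, t, float(e * 10 + i + (ch == "B"))))
        pd.DataFrame(rows, columns=["epoch", "channel", "time_ms", "uv"]).to_csv(
            tmp_path / "long.tsv", sep="\t", index=False
        )
        ep = EpochSet.from_long_table(
            tmp_path / "long.tsv", np.array([[0.0, 0.0], [1.0, 1.0]]),
            rt=np.array([0.5, 0.6]),
        )
        assert ep.data.shape == (2, 3, 2)
        assert ep.data[0, 0, 0] == 0.0 and ep.data[1, 2, 1] == 13.0
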