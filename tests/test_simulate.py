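"""Synthetic sEMG generator: determinism, count laws, amplitude contracts."""

import numpy as np
import pytest
from dataclasses import replace

from emgvdi import (
    GESTURES,
    ActivationProfile,
    MUSCLES,
    SimConfig,
    default_activation_profile,
    gesture_by_id,
    gesture_by_name,
    rms,
    simulate_dataset,
    simulate_window,
)
from emgvdi.simulate import window_seed


class TestGestureLabels:
    def test_five_gestures_bijective(self):
        assert len(GESTURES) == 5
        for g in GESTURES:
            assert gesture_by_id(g.id) == g
            assert gesture_by_name(g.name) == g

    @pytest.mark.parametrize("bad_id", [0, 6, -1])
    def test_unknown_id_rejected(self, bad_id):
        with pytest.raises(ValueError, match="gesture id"):
            gesture_by_id(bad_id)


class TestActivationProfile:
    def test_default_profile_shape_and_determinism(self):
        p1 = default_activation_profile()
        p2 = default_activation_profile()
        assert p1.matrix.shape == (5, 4)
        assert p1.channels == MUSCLES
        np.testing.assert_array_equal(p1.matrix, p2.matrix)

    def test_default_rows_pairwise_distinct(self, profile):
        m = profile.matrix
        for a in range(5):
            for b in range(a + 1, 5):
                assert not np.array_equal(m[a], m[b])

    def test_muscle_involvement_encoded(self, profile):
        """Active muscles have higher activation than their tonic level."""
        epl = profile.channels.index("extensor_pollicis_longus")
        edm = profile.channels.index("extensor_digiti_minimi")
        thumbs, v, ok, fist, open_hand = profile.matrix
        # thumb extensor strongly active for thumbs_up, fist, open_hand
        for row in (thumbs, fist, open_hand):
            assert row[epl] > v[epl]
        # little-finger extensor active for ok_sign, fist, open_hand
        for row in (ok, fist, open_hand):
            assert row[edm] > thumbs[edm]

    def test_identical_rows_rejected(self):
        mat = np.ones((5, 4)) * 0.5
        with pytest.raises(ValueError, match="identical activation rows"):
            ActivationProfile(channels=MUSCLES, matrix=mat)

    def test_negative_activation_rejected(self, profile):
        mat = profile.matrix.copy()
        mat[0, 0] = -0.1
        with pytest.raises(ValueError, match="nonnegative"):
            ActivationProfile(channels=MUSCLES, matrix=mat)

    def test_subset_preserves_columns(self, profile):
        sub = profile.subset(("extensor_digiti_minimi", "extensor_carpi_ulnaris"))
        np.testing.assert_array_equal(sub.matrix[:, 0], profile.matrix[:, 3])
        np.testing.assert_array_equal(sub.matrix[:, 1], profile.matrix[:, 0])


class TestSimulateWindow:
    def test_seeded_determinism(self, profile, sim_cfg):
        w1 = simulate_window(GESTURES[3], profile, sim_cfg, seed=7)
        w2 = simulate_window(GESTURES[3], profile, sim_cfg, seed=7)
        np.testing.assert_array_equal(w1.data, w2.data)
        assert w1.data.shape == (200, 4)

    def test_different_seeds_differ(self, profile, sim_cfg):
        w1 = simulate_window(GESTURES[0], profile, sim_cfg, seed=1)
        w2 = simulate_window(GESTURES[0], profile, sim_cfg, seed=2)
        assert not np.array_equal(w1.data, w2.data)

    def test_zero_sources_give_zero_matrix(self, sim_cfg):
        mat = np.zeros((5, 4))
        mat[np.arange(5) % 5, 0] = [0, 0.1, 0.2, 0.3, 0.4]  # distinct rows
        profile = ActivationProfile(
            channels=MUSCLES, matrix=mat, baseline_sd=0.0, jitter_sigma=0.0
        )
        w = simulate_window(GESTURES[0], profile, sim_cfg, seed=3)
        np.testing.assert_array_equal(w.data, np.zeros((200, 4)))

    def test_variance_scales_with_activation_squared(self, sim_cfg):
        """Doubling the activation quadruples the sample variance exactly,
        because the same seeded carrier is scaled."""
        base = np.tile(np.linspace(0.1, 0.5, 5)[:, None], (1, 4))
        pa = ActivationProfile(MUSCLES, base, baseline_sd=0.0, jitter_sigma=0.0)
        pb = ActivationProfile(MUSCLES, 2 * base, baseline_sd=0.0, jitter_sigma=0.0)
        wa = simulate_window(GESTURES[2], pa, sim_cfg, seed=9)
        wb = simulate_window(GESTURES[2], pb, sim_cfg, seed=9)
        ratio = wb.data.var(axis=0) / wa.data.var(axis=0)
        np.testing.assert_allclose(ratio, 4.0, rtol=1e-9)

    def test_window_too_short_names_minimum(self, profile):
        cfg = SimConfig(window_len=20)
        with pytest.raises(ValueError, match=r"minimum is \d+ samples"):
            simulate_window(GESTURES[0], profile, cfg, seed=0)

    def test_non_gesture_rejected(self, profile, sim_cfg):
        with pytest.raises(TypeError, match="GestureLabel"):
            simulate_window(3, profile, sim_cfg, seed=0)

    def test_channel_subset_bit_identical(self, profile, sim_cfg):
        """A channel simulated within any montage equals the channel
        simulated alone — per-muscle seed streams are stable."""
        full = simulate_window(GESTURES[4], profile, sim_cfg, seed=21)
        sub_names = ("extensor_pollicis_longus", "extensor_digiti_minimi")
        sub = simulate_window(
            GESTURES[4], profile.subset(sub_names), sim_cfg, seed=21
        )
        np.testing.assert_array_equal(
            sub.data, full.select_channels(sub_names).data
        )


class TestSimulateDataset:
    @pytest.mark.parametrize("n_per, total", [(150, 750), (1, 5), (7, 35)])
    def test_count_law(self, profile, n_per, total):
        cfg = SimConfig(seed=5, n_windows_per_gesture=n_per)
        ds = simulate_dataset(profile, cfg)
        assert len(ds) == total
        labels = [g.id for _, g in ds]
        assert labels.count(1) == n_per

    def test_reproducibility(self, profile):
        cfg = SimConfig(seed=42, n_windows_per_gesture=2)
        d1 = simulate_dataset(profile, cfg)
        d2 = simulate_dataset(profile, cfg)
        for (w1, g1), (w2, g2) in zip(d1, d2):
            assert g1 == g2
            np.testing.assert_array_equal(w1.data, w2.data)

    def test_window_seed_order_independent(self):
        assert window_seed(3, 2, 10) == window_seed(3, 2, 10)
        assert window_seed(3, 2, 10) != window_seed(3, 2, 11)
        assert window_seed(3, 2, 10) != window_seed(3, 1, 10)
        assert 0 <= window_seed(3, 2, 10) < 2**31

    def test_rms_proportional_to_activation(self):
        """Statistical contract: with no baseline noise, mean per-channel
        RMS over many windows is proportional to the activation."""
        base = np.tile(np.array([[0.2, 0.4, 0.6, 0.8]]), (5, 1))
        base = base * np.linspace(0.5, 1.5, 5)[:, None]  # distinct rows
        profile = ActivationProfile(MUSCLES, base, baseline_sd=0.0)
        cfg = SimConfig(seed=8, n_windows_per_gesture=50)
        ds = [
            (w, g) for w, g in simulate_dataset(profile, cfg) if g.id == 3
        ]
        mean_rms = np.array(
            [np.mean([rms(w.data[:, c]) for w, _ in ds]) for c in range(4)]
        )
        expected = base[2]
        ratios = mean_rms / expected
        np.testing.assert_allclose(ratios, ratios[0], rtol=0.1)

    def test_default_profile_channels_separate_some_gestures(self, profile):
        """On every channel, at least one gesture pair differs in mean RMS
        by more than 3 pooled standard errors over 50 windows."""
        cfg = SimConfig(seed=17, n_windows_per_gesture=50)
        ds = simulate_dataset(profile, cfg)
        per_class = {
            g.id: np.array(
                [
                    [rms(w.data[:, c]) for c in range(4)]
                    for w, gg in ds
                    if gg.id == g.id
                ]
            )
            for _, g in [(None, g) for g in set(g for _, g in ds)]
        }
        n = cfg.n_windows_per_gesture
        for c in range(4):
            best = 0.0
            for a in range(1, 6):
                for b in range(a + 1, 6):
                    gap = abs(
                        per_class[a][:, c].mean() - per_class[b][:, c].mean()
                    )
                    se = np.sqrt(
                        per_class[a][:, c].var(ddof=1) / n
                        + per_class[b][:, c].var(ddof=1) / n
                    )
                    best = max(best, gap / se)
            assert best > 3.0
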