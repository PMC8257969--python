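"""Behavioral feature extraction: sessions, JID estimation, entropy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from touchtrace.features import (
    BIN_WIDTH,
    CELL_AREA,
    GRID_BINS,
    HourlyFeatureSeries,
    TouchEventLog,
    bin_centers,
    build_hourly_features,
    estimate_jid,
    jid_entropy,
    region_mass,
    sessionize,
)

MS_H = 3_600_000


def make_log(rows, category_map=None):
    df = pd.DataFrame(rows, columns=["timestamp_ms", "kind", "app_id"])
    return TouchEventLog(df, category_map or {})


def session_rows(start_ms, itis_ms, app="app.x"):
    """One screen_on, touches at cumulative ITIs, one screen_off."""
    rows = [(start_ms, "screen_on", "")]
    t = start_ms + 100
    rows.append((t, "touch", app))
    for iti in itis_ms:
        t += iti
        rows.append((t, "touch", app))
    rows.append((t + 100, "screen_off", ""))
    return rows


class TestSessionize:
    def test_no_screen_on_yields_no_sessions(self):
        log = make_log([(0, "touch", "a"), (10, "touch", "a"), (20, "screen_off", "")])
        assert sessionize(log) == []

    def test_touches_before_first_screen_on_are_discarded(self):
        rows = [(0, "touch", "a"), (50, "touch", "a")] + session_rows(100, [500, 500])
        sessions = sessionize(make_log(rows))
        assert len(sessions) == 1
        assert sessions[0].n_touches == 3
        assert all(t >= 100 for t in sessions[0].touch_timestamps)

    def test_pair_counts_for_5_and_3_touch_sessions(self):
        # n touches -> n-1 intervals -> n-2 consecutive pairs: 3 and 1
        rows = session_rows(0, [100, 200, 300, 400]) + session_rows(
            10_000, [150, 250]
        )
        log = make_log(rows)
        feats = build_hourly_features(log, hour_range=(0, 1))
        assert feats.n_pairs[0, 0] == 3 + 1

    def test_unmatched_screen_on_closes_at_last_event(self):
        rows = [(0, "screen_on", ""), (10, "touch", "a"), (30, "touch", "a")]
        sessions = sessionize(make_log(rows))
        assert len(sessions) == 1
        assert sessions[0].end == 30

    def test_screen_on_while_open_closes_previous_session(self):
        rows = [
            (0, "screen_on", ""),
            (10, "touch", "a"),
            (100, "screen_on", ""),
            (110, "touch", "b"),
            (200, "screen_off", ""),
        ]
        sessions = sessionize(make_log(rows))
        assert len(sessions) == 2
        assert sessions[0].end == 100 and sessions[1].start == 100


class TestEstimateJid:
    def test_concentrated_input_peaks_at_nearest_cell_to_3_3(self):
        pairs = np.full((100, 2), 1000.0)  # log10 = 3.0 on both axes
        grid = estimate_jid(pairs)
        assert abs(grid.values.sum() - 1.0) < 1e-9
        i, j = np.unravel_index(np.argmax(grid.values), grid.values.shape)
        c = bin_centers()
        assert i == np.argmin(np.abs(c - 3.0)) and j == i

    def test_transpose_symmetry_on_coordinate_swap(self):
        rng = np.random.default_rng(0)
        pairs = 10 ** rng.uniform(2, 4, size=(200, 2))
        g = estimate_jid(pairs)
        g_swapped = estimate_jid(pairs[:, ::-1])
        np.testing.assert_allclose(g_swapped.values, g.values.T, atol=1e-12)

    def test_matches_sklearn_kernel_density_oracle(self):
        from sklearn.neighbors import KernelDensity

        rng = np.random.default_rng(1)
        pairs = 10 ** rng.uniform(1.6, 4.8, size=(150, 2))
        grid = estimate_jid(pairs, bandwidth=0.1)
        kde = KernelDensity(bandwidth=0.1, kernel="gaussian").fit(np.log10(pairs))
        c = bin_centers()
        xx, yy = np.meshgrid(c, c, indexing="ij")
        dens = np.exp(kde.score_samples(np.column_stack([xx.ravel(), yy.ravel()])))
        dens = dens.reshape(GRID_BINS, GRID_BINS)
        dens /= dens.sum()
        np.testing.assert_allclose(grid.values, dens, atol=1e-9)

    def test_lowest_bin_center_is_1_535(self):
        c = bin_centers()
        assert c[0] == pytest.approx(1.535)
        assert c[-1] == pytest.approx(4.965)
        assert len(c) == GRID_BINS

    def test_doubling_itis_shifts_argmax_by_log10_2(self):
        pairs = np.full((50, 2), 500.0)
        c = bin_centers()
        i0 = np.unravel_index(np.argmax(estimate_jid(pairs).values), (50, 50))
        i1 = np.unravel_index(np.argmax(estimate_jid(2 * pairs).values), (50, 50))
        shift = c[i1[0]] - c[i0[0]]
        assert abs(shift - np.log10(2)) <= BIN_WIDTH
        assert i1[0] == i1[1]

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            estimate_jid(np.empty((0, 2)))

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=31, max_value=99_000),
                st.floats(min_value=31, max_value=99_000),
            ),
            min_size=1,
            max_size=40,
        ),
        st.randoms(use_true_random=False),
    )
    def test_grid_normalized_and_order_invariant(self, pair_list, rnd):
        pairs = np.array(pair_list)
        g1 = estimate_jid(pairs)
        assert abs(g1.values.sum() - 1.0) < 1e-9
        assert np.all(g1.values >= 0)
        perm = list(range(len(pairs)))
        rnd.shuffle(perm)
        g2 = estimate_jid(pairs[perm])
        np.testing.assert_allclose(g2.values, g1.values, atol=1e-12)


class TestHourlyFeatures:
    def test_hour_with_single_touch_is_absent(self):
        rows = [(0, "screen_on", ""), (100, "touch", "a"), (200, "screen_off", "")]
        feats = build_hourly_features(make_log(rows), hour_range=(0, 1))
        assert not feats.present[0, 0]
        assert feats.jid_all[0].sum() == 0

    def test_all_social_log_social_equals_all(self):
        rows = session_rows(1000, [400, 600, 800], app="com.facebook.katana")
        log = make_log(rows, {"com.facebook.katana": "Social"})
        feats = build_hourly_features(log, hour_range=(0, 1))
        assert feats.present[0, 1]
        np.testing.assert_allclose(feats.jid_social[0], feats.jid_all[0], atol=1e-12)

    def test_social_filter_equals_filtering_then_full_pipeline(self):
        soc = session_rows(1000, [300, 500, 200], app="soc.app")
        other = session_rows(2 * MS_H, [700, 900, 400], app="other.app")
        cmap = {"soc.app": "Social"}
        full = build_hourly_features(make_log(soc + other, cmap), hour_range=(0, 3))
        only_soc = build_hourly_features(make_log(soc, cmap), hour_range=(0, 3))
        np.testing.assert_allclose(full.jid_social, only_soc.jid_all, atol=1e-12)
        assert full.present[2, 0] and not full.present[2, 1]

    def test_pair_hour_assignment_follows_terminating_touch(self):
        # interval k ends just after the hour edge -> pair lands in hour 1
        start = MS_H - 2000
        rows = session_rows(start, [3000, 500])  # touches at ~H-1.9s, ~H+1.1s, ...
        feats = build_hourly_features(make_log(rows), hour_range=(0, 2))
        assert feats.n_pairs[1, 0] == 1 and feats.n_pairs[0, 0] == 0

    def test_social_mass_never_exceeds_all_pairs(self):
        rng = np.random.default_rng(7)
        rows = []
        cmap = {"s": "Social"}
        t = 0
        for k in range(20):
            app = "s" if rng.random() < 0.5 else "n"
            itis = list(10 ** rng.uniform(2, 3.5, size=rng.integers(2, 8)))
            rows += session_rows(t, itis, app=app)
            t += int(sum(itis)) + 120_000
        feats = build_hourly_features(make_log(rows, cmap))
        assert np.all(feats.n_pairs[:, 1] <= feats.n_pairs[:, 0])
        assert not np.any(feats.present[:, 1] & ~feats.present[:, 0])


class TestEntropy:
    def test_uniform_density_entropy_is_log2_of_support_area(self):
        uniform = np.full((GRID_BINS, GRID_BINS), 1.0 / GRID_BINS**2)
        assert jid_entropy(uniform) == pytest.approx(np.log2(12.25), abs=1e-9)

    def test_concentrated_grid_below_uniform_entropy(self):
        grid = estimate_jid(np.full((30, 2), 1000.0)).values
        assert jid_entropy(grid) < np.log2(12.25)

    def test_isotropic_gaussian_matches_closed_form(self):
        sigma = 0.3
        c = bin_centers()
        xx, yy = np.meshgrid(c, c, indexing="ij")
        dens = np.exp(-((xx - 3.25) ** 2 + (yy - 3.25) ** 2) / (2 * sigma**2))
        dens /= dens.sum()
        expected = np.log2(2 * np.pi * np.e * sigma**2)
        assert jid_entropy(dens) == pytest.approx(expected, abs=0.05)

    def test_all_zero_grid_is_undefined(self):
        assert np.isnan(jid_entropy(np.zeros((GRID_BINS, GRID_BINS))))


def test_region_mass_fast_corner():
    pairs = np.full((40, 2), 100.0)  # log10 = 2 -> inside the fast corner
    g = estimate_jid(pairs)
    assert region_mass(g.values) > 0.99
    slow = estimate_jid(np.full((40, 2), 10_000.0))
    assert region_mass(slow.values) < 0.01
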