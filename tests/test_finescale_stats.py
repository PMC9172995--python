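"""Cumulative profiles, per-bin significance, and zone metrics."""

import itertools

import numpy as np
import pytest
from scipy.special import betainc

from incubehave.core import Trajectory
from incubehave.finescale_stats import (
    CumulativeProfile,
    collapse_significance,
    cumulative_position_profile,
    cumulative_speed_profile,
    per_bin_significance,
    zone_metrics,
)


def _traj(arena, xs, ys=None, frame_rate=15.0, **kw):
    xs = np.asarray(xs, dtype=float)
    ys = np.full_like(xs, 100.0) if ys is None else np.asarray(ys, dtype=float)
    return Trajectory(
        kw.pop("subject_id", "s"), kw.pop("group", "A"), frame_rate,
        np.column_stack([xs, ys]), arena=arena,
    )


def _profiles_from_bins(bin_values, grid=(0.0, 1.0, 2.0)):
    """Wrap per-subject per-bin numbers as cumulative profiles for the scan."""
    out = []
    for i, vals in enumerate(bin_values):
        vals = np.sort(np.asarray(vals, dtype=float))  # monotone by construction
        out.append(
            CumulativeProfile(
                variable="position_along_axis",
                grid=np.asarray(grid, dtype=float)[: len(vals)],
                values=vals,
                subject_id=f"s{i}",
                total_time=float(vals[-1]),
                mode="time",
            )
        )
    return out


class TestPositionProfile:
    def test_everything_left_of_query_counts_full_record(self, arena):
        traj = _traj(arena, np.full(4500, -50.0))  # 300 s at 15 Hz in the light area
        prof = cumulative_position_profile(traj, np.array([-60.0, 0.0]), mode="time")
        assert prof.values[-1] == pytest.approx(300.0)

    def test_query_below_minimum_is_zero(self, arena):
        traj = _traj(arena, np.linspace(-50, 50, 100))
        prof = cumulative_position_profile(traj, np.array([-80.0, 60.0]))
        assert prof.values[0] == 0.0

    def test_uniform_positions_split_at_midpoint(self, arena):
        traj = _traj(arena, np.linspace(-100, 100, 4500))
        prof = cumulative_position_profile(traj, np.array([0.0, 100.0]), mode="time")
        assert abs(prof.values[0] - 150.0) <= 1.0 / 15.0  # within one frame

    def test_probability_mode_ends_at_one(self, arena):
        traj = _traj(arena, np.linspace(-100, 100, 50))
        prof = cumulative_position_profile(traj, np.array([0.0, 200.0]), mode="probability")
        assert prof.values[-1] == pytest.approx(1.0)

    def test_monotone_invariant(self, arena):
        rng = np.random.default_rng(2)
        traj = _traj(arena, rng.uniform(-150, 150, 500))
        grid = np.arange(-200.0, 201.0, 5.0)
        prof = cumulative_position_profile(traj, grid)
        assert (np.diff(prof.values) >= 0).all()


class TestSpeedProfile:
    def test_constant_speed_cdf_reaches_one_at_that_speed(self, arena):
        traj = _traj(arena, 2.0 * np.arange(50))  # 30 mm/s
        prof = cumulative_speed_profile(traj, np.array([29.0, 30.0]))
        assert prof.values[0] == 0.0
        assert prof.values[1] == pytest.approx(1.0)

    def test_quartet_of_speeds(self, arena):
        # steps of 10/15, 20/15, 30/15, 40/15 mm -> speeds 10, 20, 30, 40 mm/s
        xs = np.concatenate([[0.0], np.cumsum([10, 20, 30, 40]) / 15.0])
        traj = _traj(arena, xs)
        prof = cumulative_speed_profile(traj, np.array([25.0]))
        assert prof.values[0] == pytest.approx(0.5)

    def test_zone_filter_restricts_to_first_frame_membership(self, arena):
        # frames 0-9 in light (x<0), 10-19 in dark; distinct speeds per zone
        xs = np.concatenate([-100.0 + 0.5 * np.arange(10), 50.0 + 4.0 * np.arange(10)])
        traj = _traj(arena, xs)
        prof_dark = cumulative_speed_profile(traj, np.array([100.0]), zone_filter="dark")
        # dark-zone steps are 4 mm -> 60 mm/s, all <= 100
        assert prof_dark.values[0] == pytest.approx(1.0)
        # light zone: 9 slow pairs (7.5 mm/s) plus the light->dark jump pair,
        # which belongs to the light zone by first-frame membership
        prof_light = cumulative_speed_profile(traj, np.array([10.0]), zone_filter="light")
        assert prof_light.values[0] == pytest.approx(0.9)

    def test_no_qualifying_samples_rejected(self, arena):
        traj = _traj(arena, np.full(10, 50.0))  # never in the light zone
        with pytest.raises(ValueError):
            cumulative_speed_profile(traj, np.array([10.0]), zone_filter="light")


class TestPerBinSignificance:
    def test_identical_groups_give_zero_everywhere(self):
        profs = _profiles_from_bins([[1, 2, 3], [2, 3, 4], [1.5, 2.5, 3.5]])
        sig = per_bin_significance(profs, profs)
        np.testing.assert_allclose(sig.neg_log10_p, 0.0, atol=1e-12)

    def test_order_invariance_within_groups(self):
        a = _profiles_from_bins([[1, 2, 3], [2, 3, 4], [1.5, 2.5, 3.5]])
        b = _profiles_from_bins([[4, 5, 6], [5, 6, 7], [4.5, 5.5, 6.5]])
        sig1 = per_bin_significance(a, b)
        sig2 = per_bin_significance(a[::-1], b[::-1])
        np.testing.assert_allclose(sig1.neg_log10_p, sig2.neg_log10_p, rtol=1e-12)

    def test_matches_closed_form_t_oracle(self):
        # one-bin profiles; expected p from the hand-coded pooled-t formula
        # with the regularized incomplete beta as the t CDF
        a_vals = [0.1, 0.2, 0.3, 0.4]
        b_vals = [0.5, 0.6, 0.7, 0.8]
        a = _profiles_from_bins([[v] for v in a_vals], grid=(0.0,))
        b = _profiles_from_bins([[v] for v in b_vals], grid=(0.0,))
        sig = per_bin_significance(a, b)
        na = nb = 4
        ma, mb = np.mean(a_vals), np.mean(b_vals)
        sp2 = (
            (na - 1) * np.var(a_vals, ddof=1) + (nb - 1) * np.var(b_vals, ddof=1)
        ) / (na + nb - 2)
        t = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2  # 6 degrees of freedom
        p_oracle = betainc(df / 2.0, 0.5, df / (df + t * t))
        assert 10 ** (-sig.neg_log10_p[0]) == pytest.approx(p_oracle, abs=1e-10)

    def test_degenerate_bins_flagged(self):
        a = _profiles_from_bins([[1.0], [1.0], [1.0]], grid=(0.0,))
        b = _profiles_from_bins([[2.0], [2.0], [2.0]], grid=(0.0,))
        sig = per_bin_significance(a, b)
        assert sig.degenerate[0]
        assert sig.neg_log10_p[0] > 300  # machine-minimum p
        sig_same = per_bin_significance(a, a)
        assert sig_same.neg_log10_p[0] == 0.0

    def test_permutation_test_agrees_on_bin_ordering(self):
        # three bins with increasing effect size; exact permutation p over
        # all C(8,4) label splits must rank the bins identically
        rng = np.random.default_rng(3)
        base = rng.normal(size=(8, 3)) * 0.5
        base[4:, 0] += 0.3
        base[4:, 1] += 1.0
        base[4:, 2] += 3.0
        data = np.sort(np.abs(base), axis=1)  # monotone rows for profile validity
        a = _profiles_from_bins(data[:4])
        b = _profiles_from_bins(data[4:])
        sig = per_bin_significance(a, b)

        def perm_p(col):
            obs = abs(np.mean(col[4:]) - np.mean(col[:4]))
            count = 0
            splits = list(itertools.combinations(range(8), 4))
            for idx in splits:
                sel = np.zeros(8, dtype=bool)
                sel[list(idx)] = True
                if abs(col[sel].mean() - col[~sel].mean()) >= obs - 1e-12:
                    count += 1
            return count / len(splits)

        perm = np.array([perm_p(data[:, j]) for j in range(3)])
        assert list(np.argsort(perm)) == list(np.argsort(-sig.neg_log10_p))


class TestCollapse:
    def test_five_number_summaries(self):
        grid = np.arange(5.0)
        for values, expected in [
            (np.zeros(5), (0, 0, 0, 0, 0)),
            (np.array([2.3]), (2.3,) * 5),
            (np.array([0.0, 1, 2, 3, 4]), (0, 1, 2, 3, 4)),
        ]:
            from incubehave.finescale_stats import SignificanceProfile

            sig = SignificanceProfile(
                grid=grid[: len(values)], neg_log10_p=values, group_sizes=(3, 3)
            )
            assert collapse_significance(sig) == pytest.approx(expected)


class TestZoneMetrics:
    def test_never_leaving_dark_zone(self, arena):
        traj = _traj(arena, np.full(4500, 100.0))  # 300 s in the dark
        zm = zone_metrics(traj, zone_names=["light", "dark"])
        assert zm.time_in_zone["light"] == 0.0
        assert zm.transfer_count == 0
        assert zm.latency_first_transfer == pytest.approx(300.0)
        assert zm.latency_censored

    def test_single_crossing_latency(self, arena):
        xs = np.concatenate([np.full(150, -50.0), np.full(150, 50.0)])
        zm = zone_metrics(_traj(arena, xs), zone_names=["light", "dark"])
        assert zm.transfer_count == 1
        assert zm.latency_first_transfer == pytest.approx(10.0)
        assert not zm.latency_censored

    def test_scripted_crossings_match_brute_force_scan(self, arena):
        rng = np.random.default_rng(7)
        xs = rng.choice([-60.0, 60.0], size=200)
        traj = _traj(arena, xs)
        zm = zone_metrics(traj, zone_names=["light", "dark"])
        # independent frame-by-frame membership scan
        side = (xs > 0).astype(int)
        expected_transfers = int(np.sum(side[1:] != side[:-1]))
        expected_dark = float(np.sum(side) / 15.0)
        assert zm.transfer_count == expected_transfers
        assert zm.time_in_zone["dark"] == pytest.approx(expected_dark)

    def test_event_latency(self, arena):
        traj = _traj(arena, np.zeros(30) - 10.0)
        zm = zone_metrics(traj, zone_names=["light", "dark"], events=np.array([4.2, 9.9]))
        assert zm.latency_first_event == pytest.approx(4.2)
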