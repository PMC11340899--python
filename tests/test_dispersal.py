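"""Log-binned MSD/MIS profiles, segmented regression, classification."""

import numpy as np
import pytest

from pcimove.dispersal import (SegmentedFit, classify_diffusion,
                               displacement_table, log_time_bins, mis_profile,
                               msd_profile, segmented_fit,
                               start_finish_displacement)
from pcimove.io import Track


def test_log_bins_geometric_midpoints():
    edges, mid = log_time_bins(14, 1.6, 5400.0)
    assert len(edges) == 15 and len(mid) == 14
    np.testing.assert_allclose(mid, np.sqrt(edges[:-1] * edges[1:]))
    assert np.all(np.diff(mid) > 0)
    ratios = edges[1:] / edges[:-1]
    np.testing.assert_allclose(ratios, ratios[0])


def _straight_track(v=1.0, dt=1.6, n=3000):
    t = np.arange(n) * dt
    xy = np.column_stack([10.0 + v * t, np.full(n, 10.0)])
    return Track("s", "paper", t, xy)


def test_stationary_cohort_msd_zero_everywhere():
    tracks = [Track(f"a{i}", "paper", np.arange(3000) * 1.6,
                    np.full((3000, 2), 50.0 + i)) for i in range(3)]
    prof = msd_profile(tracks, {f"a{i}": 0.0 for i in range(3)})
    filled = prof.table["mean"].dropna()
    assert (filled == 0.0).all()


def test_constant_speed_mis_is_one_in_every_bin():
    tr = _straight_track(v=1.0)
    prof = mis_profile([tr], {"s": 0.0})
    filled = prof.table["mean"].dropna()
    np.testing.assert_allclose(filled, 1.0, rtol=1e-9)


def test_single_individual_profile_is_its_own_binned_values():
    tr = _straight_track(v=2.0)
    prof = msd_profile([tr], {"s": 0.0})
    tab = prof.table.dropna(subset=["mean"])
    # MSD of a straight line at speed v: (v*tau)^2 averaged within the bin
    edges = prof.edges
    tau = tr.times - tr.times[0]
    for _, row in tab.iterrows():
        b = np.searchsorted(prof.table["midpoint_s"].to_numpy(),
                            row["midpoint_s"])
        lo, hi = edges[b], edges[b + 1]
        sel = (tau > lo) & (tau <= hi) if b > 0 else (tau >= lo) & (tau <= hi)
        expected = np.mean((2.0 * tau[sel]) ** 2)
        assert row["mean"] == pytest.approx(expected, rel=1e-9)
        assert row["n_individuals"] == 1
        assert np.isnan(row["upper_ci"])  # no CI from a single individual


def test_msd_invariant_under_rotation_and_translation(brownian_cohort):
    tracks, pci_ends, _ = brownian_cohort
    sub = tracks[:5]
    prof = msd_profile(sub, pci_ends)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    moved = [Track(tr.individual_id, tr.treatment, tr.times,
                   tr.xy @ R.T + np.array([13.0, -4.0]))
             for tr in sub]
    prof2 = msd_profile(moved, pci_ends)
    np.testing.assert_allclose(prof.table["mean"], prof2.table["mean"],
                               rtol=1e-9, equal_nan=True)


def test_brownian_msd_matches_4dt_and_loglog_slope(brownian_cohort):
    tracks, pci_ends, D = brownian_cohort
    prof = msd_profile(tracks, pci_ends)
    x, y = prof.regression_points()
    slope = np.polyfit(np.log10(x), np.log10(y), 1)[0]
    assert 0.85 <= slope <= 1.15
    # per-bin across-individual CI covers the closed form
    # E[binned MSD] = 4*D*tbar with tbar the mean sample time in the bin
    tau = tracks[0].times - tracks[0].times[0]
    edges = prof.edges
    covered = n_checked = 0
    for b, row in prof.table.iterrows():
        if row["n_individuals"] < 20 or np.isnan(row["upper_ci"]):
            continue
        lo = edges[b] if b > 0 else edges[0] - 1e-9
        sel = (tau > lo) & (tau <= edges[b + 1])
        ref = 4.0 * D * np.mean(tau[sel])
        lower = 2.0 * row["mean"] - row["upper_ci"]  # symmetric t-interval
        n_checked += 1
        covered += lower <= ref <= row["upper_ci"]
    assert n_checked >= 10
    assert covered >= 0.9 * n_checked


def test_ramping_speed_gives_positive_mis_trend():
    t = np.arange(3000) * 1.6
    # speed grows linearly in time: x(t) = a*t^2/2
    xy = np.column_stack([1e-4 * t ** 2 / 2.0, np.zeros_like(t)])
    tr = Track("r", "paper", t, xy + 10.0)
    prof = mis_profile([tr], {"r": 0.0})
    tab = prof.table.dropna(subset=["mean"])
    x = np.log10(tab["midpoint_s"].to_numpy())
    slope = np.polyfit(x, tab["mean"].to_numpy(), 1)[0]
    assert slope > 0


class TestSegmentedFit:
    def test_exact_line_falls_back_to_simple(self):
        x = np.linspace(0.0, 6.0, 14)
        fit = segmented_fit(x, 2.0 * x + 1.0)
        assert not fit.is_segmented
        assert fit.breakpoint_p >= 0.05
        assert fit.slope1 == pytest.approx(2.0, abs=1e-9)

    def test_breakpoint_recovery_on_constructed_data(self):
        x = np.linspace(0.0, 6.0, 14)
        rng = np.random.default_rng(42)
        y = 1.0 + 0.5 * x + 1.5 * np.clip(x - 3.0, 0.0, None) \
            + rng.normal(0.0, 0.05, 14)
        fit = segmented_fit(x, y)
        assert fit.is_segmented
        assert 2.5 <= fit.psi <= 3.5
        assert fit.slope1_ci[0] <= 0.5 <= fit.slope1_ci[1]
        assert fit.slope2_ci[0] <= 2.0 <= fit.slope2_ci[1]
        assert fit.breakpoint_p < 0.05
        assert fit.r2_adj > 0.99

    def test_forced_psi_outside_range_reproduces_simple_fit(self):
        x = np.linspace(0.0, 6.0, 14)
        rng = np.random.default_rng(8)
        y = 0.3 * x + rng.normal(0.0, 0.2, 14)
        forced = segmented_fit(x, y, forced_psi=50.0)
        simple = np.polyfit(x, y, 1)
        assert not forced.is_segmented
        assert forced.slope1 == pytest.approx(simple[0], abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            segmented_fit(np.arange(5.0), np.arange(5.0))


@pytest.mark.parametrize("ci,expected", [
    ((1.2, 1.6), "super_diffusive"),
    ((0.9, 1.1), "diffusive"),
    ((0.3, 0.8), "sub_diffusive"),
])
def test_classification_from_designated_slope_ci(ci, expected):
    fit = SegmentedFit(is_segmented=False, slope1=np.mean(ci), slope1_ci=ci,
                       slope2=np.mean(ci), slope2_ci=ci, intercept=0.0,
                       psi=None, psi_ci=None, breakpoint_p=1.0, r2_adj=0.9,
                       n=14, n_left=14, n_right=0)
    assert classify_diffusion(fit) == expected


def test_classification_uses_segment_covering_most_bins():
    fit = SegmentedFit(is_segmented=True, slope1=1.5, slope1_ci=(1.3, 1.7),
                       slope2=0.5, slope2_ci=(0.3, 0.7), intercept=0.0,
                       psi=2.0, psi_ci=(1.5, 2.5), breakpoint_p=0.01,
                       r2_adj=0.9, n=14, n_left=4, n_right=10)
    assert classify_diffusion(fit) == "sub_diffusive"  # slope2 has 10 bins


class TestDisplacement:
    def test_start_equals_finish_gives_zero(self):
        assert start_finish_displacement(([5.0, 5.0], [5.0, 5.0])) == 0.0

    def test_centre_to_corner_is_half_diagonal(self):
        d = start_finish_displacement(([112.5, 112.5], [0.0, 0.0]))
        assert d == pytest.approx(np.sqrt(2) * 112.5, abs=1e-9)
        assert d == pytest.approx(159.1, abs=0.1)

    def test_table_flags_half_diagonal_ceiling(self):
        n = 5
        t = np.arange(n) * 1.6
        corner = Track("c", "paper", t, np.column_stack(
            [np.linspace(112.5, 0.0, n), np.linspace(112.5, 0.0, n)]))
        still = Track("s", "paper", t, np.full((n, 2), 112.5))
        tab = displacement_table([corner, still])
        assert tab.loc[tab["individual"] == "c", "at_ceiling"].item()
        assert not tab.loc[tab["individual"] == "s", "at_ceiling"].item()
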