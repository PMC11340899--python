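"""Synthetic cohort generator: laws, determinism, track rendering."""

import numpy as np
import pytest

from pcimove.bouts import extract_sequence, segment_bouts, wall_arrival_time
from pcimove.io import BoutSequence
from pcimove.preprocess import coarse_grain
from pcimove.synth import (ScenarioSpec, gen_bout_cohort, gen_cohort,
                           gen_track, sample_durations, scenario)


class TestSampleDurations:
    def test_exponential_mean_matches_closed_form(self):
        lam = 0.01
        x = sample_durations(("exponential", {"lam": lam}), 10_000, 1)
        se = (1.0 / lam) / np.sqrt(len(x))
        assert abs(x.mean() - 1.0 / lam) < 3 * se

    def test_powerlaw_ccdf_loglog_slope(self):
        x = sample_durations(("powerlaw", {"alpha": 2.5, "xmin": 1.0}),
                             20_000, 2)
        xs = np.sort(x)
        ccdf = 1.0 - np.arange(len(xs)) / len(xs)
        # regress on the well-populated part of the tail
        sel = (xs < np.quantile(xs, 0.999))
        slope = np.polyfit(np.log10(xs[sel]), np.log10(ccdf[sel]), 1)[0]
        assert slope == pytest.approx(-1.5, abs=0.1)

    def test_degenerate_lognormal_is_constant(self):
        x = sample_durations(("lognormal", {"mu": 0.0, "sigma": 0.0}), 50, 3)
        np.testing.assert_allclose(x, 1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sample_durations(("exponential", {"lam": -1.0}), 10, 0)
        with pytest.raises(ValueError):
            sample_durations(("powerlaw", {"alpha": 0.9, "xmin": 1.0}), 10, 0)


class TestBoutCohorts:
    def test_same_seed_gives_identical_cohorts(self):
        a = gen_bout_cohort(scenario("shallow", seed=9))
        b = gen_bout_cohort(scenario("shallow", seed=9))
        for s1, s2 in zip(a.sequences, b.sequences):
            np.testing.assert_array_equal(s1.immobility_durations,
                                          s2.immobility_durations)
            np.testing.assert_array_equal(s1.movement_durations,
                                          s2.movement_durations)

    def test_zero_variance_zero_slope_gives_constant_durations(self):
        spec = ScenarioSpec(name="flat", treatment="paper", n_individuals=3,
                            imm_slope=0.0, mov_slope=0.0, sd_intercept=0.0,
                            sd_slope=0.0, sd_resid=0.0, seed=4)
        cohort = gen_bout_cohort(spec)
        for s in cohort.sequences:
            assert np.ptp(s.immobility_durations) == pytest.approx(0.0)
            assert np.ptp(s.movement_durations) == pytest.approx(0.0)

    def test_generated_sequences_satisfy_invariants(self):
        # BoutSequence.__post_init__ enforces them; construction must succeed
        for name in ("paper", "shallow", "deep"):
            cohort = gen_bout_cohort(scenario(name, seed=21))
            for s in cohort.sequences:
                assert s.n_movement in (s.n_immobility - 1, s.n_immobility)
                total = (s.immobility_durations.sum()
                         + s.movement_durations.sum())
                assert total <= 5400.0 + 1e-9


class TestTracks:
    def test_zero_speed_track_is_single_immobility(self):
        seq = BoutSequence("z", "paper", [60.0, 30.0], [10.0])
        spec = ScenarioSpec(name="z", treatment="paper", n_individuals=1,
                            base_speed=0.0, jitter_sd=0.0, seed=0)
        tr = gen_track(seq, spec, 0)
        events = segment_bouts(coarse_grain(tr, 4), move_threshold=0.0)
        assert len(events) == 1 and events[0].kind == "immobility"

    def test_straight_movement_displacement_is_speed_times_time(self):
        seq = BoutSequence("d", "paper", [10.0], [60.0])
        # oversized arena so the straight path meets no wall
        spec = ScenarioSpec(name="d", treatment="paper", n_individuals=1,
                            base_speed=2.0, speed_trend=1.0, turn_sd=0.0,
                            jitter_sd=0.0, wall_margin=0.0, arena=2000.0,
                            drop=(1000.0, 1000.0), seed=3)
        tr = gen_track(seq, spec, 3)
        d = np.linalg.norm(tr.xy[-1] - tr.xy[0])
        assert d == pytest.approx(120.0, abs=1.0)

    def test_track_stops_at_wall_and_sequence_is_truncated(self):
        spec = scenario("paper", seed=5)
        cohort = gen_cohort(spec)
        walled = [s for s in cohort.sequences if s.reached_wall]
        assert len(walled) >= 18  # nearly all paper animals reach the wall
        for seq, tr in zip(cohort.sequences, cohort.tracks):
            if seq.reached_wall:
                edge_dist = np.minimum(tr.xy[-1], 225.0 - tr.xy[-1]).min()
                assert edge_dist <= spec.wall_margin + 1e-9

    def test_segmentation_inverts_generator_when_bouts_resolvable(self):
        """With jitter off and bouts >= 2 coarse frames, segmenting the
        rendered track recovers every bout within still_gap + one step."""
        tol = 3.2 + 1.6
        for name in ("paper", "shallow", "deep"):
            spec = scenario(name, seed=17, min_immobility=6.4,
                            min_movement=1.6, jitter_sd=0.0)
            cohort = gen_cohort(spec)
            for seq, tr in zip(cohort.sequences, cohort.tracks):
                wall_t = wall_arrival_time(tr, margin=spec.wall_margin)
                rec = extract_sequence(
                    segment_bouts(coarse_grain(tr, 4)),
                    seq.individual_id, seq.treatment, wall_time=wall_t)
                assert abs(rec.n_immobility - seq.n_immobility) <= (
                    1 if seq.reached_wall else 0)
                kI = min(rec.n_immobility, seq.n_immobility)
                kM = min(rec.n_movement, seq.n_movement)
                np.testing.assert_allclose(
                    rec.immobility_durations[:kI],
                    seq.immobility_durations[:kI], atol=tol)
                if kM:
                    np.testing.assert_allclose(
                        rec.movement_durations[:kM],
                        seq.movement_durations[:kM], atol=tol)

    def test_pci_recovered_under_default_jitter(self):
        tol = 3.2 + 1.6
        for name in ("paper", "deep"):
            spec = scenario(name, seed=5)
            cohort = gen_cohort(spec)
            for seq, tr in zip(cohort.sequences, cohort.tracks):
                rec = extract_sequence(
                    segment_bouts(coarse_grain(tr, 4)),
                    seq.individual_id, seq.treatment,
                    wall_time=wall_arrival_time(tr))
                assert abs(rec.pci - seq.pci) <= tol
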