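"""Event classification, bypass counting, recognition efficiency,
binomial fractions, and censored residence-time fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curtainkit import lesion_search, synthetic
from curtainkit.config import (
    DwellEvent,
    InsufficientDataError,
    InvalidConfigError,
    SimConfig,
    Trajectory,
)
from curtainkit.lesion_search import (
    ResidenceTimeFitter,
    classify_event,
    fit_residence_time,
    fraction_with_sd,
    recognition_efficiency,
)

LESION = (33.513, 33.630)
CENTER = 0.5 * (LESION[0] + LESION[1])


def _track(positions, dt=0.1, censored=False):
    positions = np.asarray(positions, dtype=float)
    return Trajectory("t", np.arange(positions.size) * dt, positions,
                      sigma_loc_kbp=0.0, censored_end=censored)


class TestClassifyEvent:
    def test_stationary_at_lesion_is_direct(self):
        ev = classify_event(_track(np.full(400, CENTER)), LESION)
        assert ev.mode == "direct"
        assert ev.bypass_count == 0

    def test_two_crossings_then_arrest_is_diffusion_bypass_two(self):
        # hand-crafted: far -> through window -> far -> through -> far -> arrest
        path = (
            [20.0] * 10 + [CENTER] * 3 + [45.0] * 10      # transit 1
            + [CENTER] * 3 + [20.0] * 10                  # transit 2
            + [CENTER] * 400                              # arrest
        )
        ev = classify_event(_track(path), LESION)
        assert ev.mode == "diffusion"
        assert ev.bypass_count == 2

    def test_never_arresting_track_is_none(self):
        rng = np.random.default_rng(0)
        ev = classify_event(_track(5.0 + rng.normal(0, 0.2, 300)), LESION)
        assert ev.mode == "none"
        assert ev.dwell_s == 0.0

    def test_lesion_outside_dna_rejected(self, stationary_track):
        with pytest.raises(InvalidConfigError):
            classify_event(stationary_track, (50.0, 60.0), dna_length_kbp=48.502)

    def test_censored_dwell_flagged(self):
        ev = classify_event(_track(np.full(400, CENTER), censored=True), LESION)
        assert ev.censored

    def test_ground_truth_recovery_on_explicit_simulation(self):
        # pooled over three seeds: >= 95% label agreement at default SNR
        agree = n = 0
        for seed in (0, 1, 2):
            cfg = SimConfig(rng_seed=seed, n_frames=3000, mean_dwell_s=900.0)
            for traj, truth in synthetic.simulate_search_experiment(
                cfg, 120, mode="explicit"
            ):
                pred = classify_event(traj, cfg.lesion_interval_kbp,
                                      cfg.dna_length_kbp)
                agree += pred.mode == truth.mode
                n += 1
        assert agree / n >= 0.95


class TestRecognitionEfficiency:
    @pytest.mark.parametrize(
        "bypasses,expected",
        [([0] * 5, 100.0), ([1] * 4, 50.0), ([0] * 8 + [1] + [2], 88.33333333333333)],
    )
    def test_weighted_sum(self, bypasses, expected):
        events = [DwellEvent(f"t{i}", "diffusion", b, 10.0, False)
                  for i, b in enumerate(bypasses)]
        res = recognition_efficiency(events)
        assert res.efficiency_percent == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_on_random_histogram(self):
        rng = np.random.default_rng(5)
        bypasses = rng.integers(0, 6, size=200)
        events = [DwellEvent(f"t{i}", "diffusion", int(b), 1.0, False)
                  for i, b in enumerate(bypasses)]
        brute = 100.0 * np.mean([1.0 / (b + 1) for b in bypasses])
        assert recognition_efficiency(events).efficiency_percent == pytest.approx(brute)

    def test_geometric_bypasses_match_closed_form(self):
        # E[1/(N+1)] for N ~ geometric(q) is -q ln q / (1-q)
        q = 0.885
        rng = np.random.default_rng(42)
        bypasses = rng.geometric(q, size=100_000) - 1
        events = [DwellEvent(f"t{i}", "diffusion", int(b), 1.0, False)
                  for i, b in enumerate(bypasses)]
        closed = -q * np.log(q) / (1.0 - q) * 100.0
        res = recognition_efficiency(events)
        assert res.efficiency_percent == pytest.approx(closed, rel=0.01)

    def test_none_events_excluded_and_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            recognition_efficiency([DwellEvent("a", "none", 3, 0.0, False)])


class TestFractionWithSd:
    def test_formula(self):
        res = fraction_with_sd(27, 144)
        assert res.p_hat == pytest.approx(0.1875)
        assert res.sd_binomial == pytest.approx(0.0325, abs=5e-4)

    @pytest.mark.parametrize("k", [0, 144])
    def test_degenerate_fractions_have_zero_sd(self, k):
        assert fraction_with_sd(k, 144).sd_binomial == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(InvalidConfigError):
            fraction_with_sd(1, 0)
        with pytest.raises(InvalidConfigError):
            fraction_with_sd(5, 4)

    @given(st.integers(0, 500), st.integers(1, 500))
    @settings(max_examples=50, derandomize=True)
    def test_sd_identity_property(self, k, n):
        if k > n:
            k = n
        res = fraction_with_sd(k, n)
        p = k / n
        assert res.sd_binomial == pytest.approx(np.sqrt(p * (1 - p) / n))


class TestResidenceTime:
    def test_censored_mle_closed_form(self):
        events = [
            DwellEvent("a", "diffusion", 0, 100.0, False),
            DwellEvent("b", "diffusion", 0, 200.0, False),
            DwellEvent("c", "diffusion", 0, 600.0, True),
            DwellEvent("d", "diffusion", 0, 50.0, False),
            DwellEvent("e", "diffusion", 0, 60.0, False),
        ]
        est = ResidenceTimeFitter(method="mle").fit(events)
        assert est.tau_s_ == pytest.approx((100 + 200 + 600 + 50 + 60) / 4)

    def test_uncensored_recovery_both_methods(self):
        rng = np.random.default_rng(3)
        dwells = rng.exponential(100.0, size=500)
        events = [DwellEvent(f"t{i}", "diffusion", 0, float(d), False)
                  for i, d in enumerate(dwells)]
        tau_mle, _ = fit_residence_time(events, 600.0, "mle")
        tau_naive, _ = fit_residence_time(events, 600.0, "naive")
        assert tau_mle == pytest.approx(100.0, rel=0.10)
        assert tau_naive == pytest.approx(100.0, rel=0.15)

    def test_naive_underestimates_when_tau_reaches_window(self):
        # tau = window = 600 s: the naive histogram fit is biased low,
        # the censored MLE is not
        cfg = SimConfig(rng_seed=9, mean_dwell_s=600.0)
        events = [e for _, e in synthetic.simulate_search_experiment(cfg, 1000)]
        tau_naive, _ = fit_residence_time(events, 600.0, "naive")
        tau_mle, _ = fit_residence_time(events, 600.0, "mle")
        assert tau_naive < 0.85 * 600.0
        assert tau_mle == pytest.approx(600.0, rel=0.10)

    def test_all_censored_reports_lower_bound(self):
        events = [DwellEvent(f"t{i}", "direct", 0, 600.0, True) for i in range(6)]
        est = ResidenceTimeFitter(method="mle").fit(events)
        assert est.lower_bound_only_
        assert est.tau_s_ >= 600.0

    def test_too_few_events_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_residence_time(
                [DwellEvent("a", "direct", 0, 10.0, False)] * 3, 600.0, "mle"
            )
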