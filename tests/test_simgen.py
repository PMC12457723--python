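"""Generator structure: branching, count model, determinism, calibration."""

import dataclasses
import math

import numpy as np
import pytest

from ascoalloc import simgen
from ascoalloc.core import SiteRecord


def test_no_branching_keeps_single_tip():
    rng = np.random.default_rng(0)
    b0, b1, history = simgen.simulate_tips(10, 0.0, rng)
    assert (b0, b1) == (1, 1)
    assert history == [1] * 11


def test_certain_branching_doubles_each_year():
    rng = np.random.default_rng(0)
    b0, b1, history = simgen.simulate_tips(3, 1.0, rng)
    assert (b0, b1) == (8, 4)
    assert history == [1, 2, 4, 8]


def test_tip_history_is_nondecreasing_and_b0_ge_b1():
    rng = np.random.default_rng(42)
    for _ in range(200):
        b0, b1, history = simgen.simulate_tips(8, 0.4, rng)
        assert b0 >= b1 >= 1
        assert all(a <= b for a, b in zip(history, history[1:]))


def test_mean_tip_ratio_matches_branching_probability():
    """E[b0 / b1] = 1 + p: each tip splits independently with prob p."""
    rng = np.random.default_rng(7)
    ratios = []
    for _ in range(10_000):
        b0, b1, _ = simgen.simulate_tips(10, 0.3, rng)
        ratios.append(b0 / b1)
    assert np.mean(ratios) == pytest.approx(1.3, abs=0.01)


def test_deterministic_limit_is_bit_identical():
    params = simgen.SimParams(
        nb_dispersion=math.inf, random_effect_sd=0.0, random_slope_sd=0.0,
        size_noise_sd=0.0, s1_mass_sd=0.0, branch_prob=0.0,
        first_reproductive_age=2, n_shoots=3, seed=99,
    )
    a = simgen.simulate_site(params)
    b = simgen.simulate_site(params)
    for sa, sb in zip(a.shoots, b.shoots):
        assert sa.vegetative_mass_V == sb.vegetative_mass_V
        assert sa.reproductive_mass_R == sb.reproductive_mass_R
        for ga, gb in zip(sa.segments, sb.segments):
            assert ga.segment_dry_mass == gb.segment_dry_mass
            assert ga.receptacle_count == gb.receptacle_count


def test_same_seed_reproduces_stochastic_site():
    params = simgen.SimParams(n_shoots=10, seed=123)
    a = simgen.simulate_site(params)
    b = simgen.simulate_site(params)
    assert [s.vegetative_mass_V for s in a.shoots] == [s.vegetative_mass_V for s in b.shoots]
    assert [s.reproductive_mass_R for s in a.shoots] == [s.reproductive_mass_R for s in b.shoots]


def test_pre_reproductive_segments_have_zero_counts():
    """Youngest and second-youngest segments carry no receptacles."""
    params = simgen.SimParams(first_reproductive_age=2, n_shoots=50, seed=5)
    ds = simgen.simulate_site(params)
    for shoot in ds.shoots:
        for seg in shoot.segments:
            if seg.age_years < 2:
                assert seg.receptacle_count == 0
    assert any(
        seg.receptacle_count > 0 for sh in ds.shoots for sh_seg in [sh.segments]
        for seg in sh_seg if seg.age_years >= 2
    )


def test_empirical_count_peak_matches_quadratic_argmax():
    """With beta=(1.5, 0.5, -0.06) the mean count peaks near -b1/(2 b2) = 4.17."""
    params = simgen.SimParams(
        count_beta=(1.5, 0.5, -0.06), first_reproductive_age=0,
        n_shoots=5000, seed=31,
    )
    ds = simgen.simulate_site(params)
    sums = np.zeros(params.max_age + 1)
    for sh in ds.shoots:
        for seg in sh.segments:
            sums[seg.age_years] += seg.receptacle_count
    assert int(np.argmax(sums)) in (4, 5)


def test_counts_are_overdispersed_at_finite_k():
    params = simgen.SimParams(
        count_beta=(2.0, 0.3, -0.05), nb_dispersion=0.8, random_effect_sd=0.0,
        first_reproductive_age=0, n_shoots=2000, seed=17,
    )
    ds = simgen.simulate_site(params)
    by_age: dict[int, list[int]] = {}
    for sh in ds.shoots:
        for seg in sh.segments:
            by_age.setdefault(seg.age_years, []).append(seg.receptacle_count)
    over = [np.var(v) > np.mean(v) for v in by_age.values() if np.mean(v) > 0.5]
    assert all(over)


def test_log_mean_counts_are_concave_in_age(profiles):
    """Concavity of the fitted quadratic holds empirically for every profile."""
    for name, base in profiles.items():
        params = dataclasses.replace(base, n_shoots=2000, seed=13)
        ds = simgen.simulate_site(params)
        sums: dict[int, float] = {}
        ns: dict[int, int] = {}
        for sh in ds.shoots:
            for seg in sh.segments:
                if seg.age_years >= params.first_reproductive_age:
                    sums[seg.age_years] = sums.get(seg.age_years, 0) + seg.receptacle_count
                    ns[seg.age_years] = ns.get(seg.age_years, 0) + 1
        ages = sorted(sums)
        logmeans = np.log([max(sums[a] / ns[a], 1e-9) for a in ages])
        # quadratic coefficient of an LS fit to the empirical log means
        coeffs = np.polyfit(ages, logmeans, 2)
        assert coeffs[0] < 0, name


def test_degenerate_parameters_are_rejected():
    with pytest.raises(ValueError, match="count_beta"):
        simgen.SimParams(count_beta=(1.0, 0.5, 0.01)).validate()
    with pytest.raises(ValueError, match="branch_prob"):
        simgen.SimParams(branch_prob=1.5).validate()
    with pytest.raises(ValueError, match="first_reproductive_age"):
        simgen.SimParams(first_reproductive_age=3).validate()
    with pytest.raises(ValueError):
        rng = np.random.default_rng(0)
        simgen.simulate_shoot(simgen.SimParams(count_beta=(1.0, 0.5, 0.0)), rng)


def test_profiles_span_observed_ranges(profiles):
    """At least four profiles covering RE 0.11-0.73 and turnover 0.22-0.67."""
    assert len(profiles) >= 4
    res = [simgen.PROFILE_ANCHORS[n]["target_re"] for n in profiles]
    tos = [simgen.PROFILE_ANCHORS[n]["target_turnover"] for n in profiles]
    assert min(res) <= 0.11 and max(res) >= 0.73
    assert min(tos) <= 0.22 and max(tos) >= 0.67
    assert simgen.PROFILE_ANCHORS["qeqertarsuaq-like"]["target_re"] == 0.14
    assert simgen.PROFILE_ANCHORS["hirsholmene-like"]["target_turnover"] == 0.67
    for params in profiles.values():
        params.validate()  # every calibrated profile is self-consistent


def test_calibration_hits_turnover_and_re_targets():
    """Moment matching reproduces arbitrary targets, not just the defaults."""
    base = simgen.SimParams(site=SiteRecord(site_id="t", latitude=60.0))
    cal = simgen.calibrate_profile(base, target_re=0.3, target_turnover=0.28)
    exp = simgen.expected_site_means(cal)
    assert exp["turnover"] == pytest.approx(0.28, abs=0.005)
    assert exp["RE"] == pytest.approx(0.3, abs=0.01)


@pytest.mark.parametrize("p", [0.0, 0.25, 0.7])
def test_expectation_estimator_matches_exact_moments(p):
    """The calibration's simulated E[V] agrees with the closed-form
    branching-process/lognormal moment recursion."""
    params = simgen.SimParams(s1_mass_mean=0.2, s1_mass_sd=0.06, max_age=8)
    exact = simgen._v_and_n_moments(params, p)
    mc = simgen._mc_ratio_moments(params, p)
    # MC relative error ~ CV/sqrt(nsim)
    tol = 3 * math.sqrt(max(exact["VarV"], 1e-12)) / math.sqrt(60_000)
    assert mc["EV"] == pytest.approx(exact["EV"], abs=max(tol, 1e-9))


def test_unreachable_turnover_target_raises():
    base = simgen.SimParams(max_age=12)
    with pytest.raises(ValueError, match="achievable range"):
        simgen.calibrate_profile(base, target_re=0.3, target_turnover=5.0)
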