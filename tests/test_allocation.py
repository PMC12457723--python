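"""Allocation arithmetic, identities and summaries."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ascoalloc import allocation as al
from ascoalloc import simgen
from ascoalloc.core import SiteRecord, SiteDataset


@pytest.mark.parametrize("b0, b1, expected", [(12, 8, 10), (1, 1, 1), (7, 4, 5.5)])
def test_tip_count_is_mean_of_bladder_counts(b0, b1, expected):
    assert al.tip_count(b0, b1) == expected


@pytest.mark.parametrize(
    "fn, args, expected",
    [
        (al.annual_vegetative_growth, (0.1, 10), 1.0),
        (al.annual_vegetative_growth, (0.05, 1), 0.05),
        (al.annual_vegetative_growth, (0.2, 5.5), 1.1),
        (al.turnover_rate, (1.0, 4.0), 0.25),
        (al.turnover_rate, (0.5, 0.5), 1.0),
        (al.reproductive_effort, (0, 5), 0.0),
        (al.reproductive_effort, (1, 4), 0.25),
        (al.reproductive_effort, (3.65, 5.0), 0.73),
        (al.annual_reproductive_allocation, (0, 1), 0.0),
        (al.annual_reproductive_allocation, (1, 1), 0.5),
        (al.annual_reproductive_allocation, (3, 1), 0.75),
        (al.to_carbon, (10, 0.30), 3.0),
        (al.to_carbon, (0, 0.4), 0.0),
        (al.carbon_allocation, (1, 1, 0.2, 0.3), 0.4),
    ],
)
def test_allocation_arithmetic(fn, args, expected):
    assert fn(*args) == pytest.approx(expected)


def test_carbon_conversion_of_areal_biomass():
    # standing biomass x RE x carbon fraction, independent arithmetic chain
    assert al.to_carbon(6522 * 0.14, 0.25) == pytest.approx(228.27)


@pytest.mark.parametrize(
    "fn, args",
    [
        (al.tip_count, (0, 3)),
        (al.annual_vegetative_growth, (0.0, 5)),
        (al.turnover_rate, (1.0, 0.0)),
        (al.reproductive_effort, (1.0, 0.0)),
        (al.annual_reproductive_allocation, (0.0, 0.0)),
        (al.to_carbon, (1.0, 1.5)),
        (al.carbon_allocation, (0.0, 0.0, 0.2, 0.3)),
    ],
)
def test_invalid_inputs_rejected(fn, args):
    with pytest.raises(ValueError):
        fn(*args)


def test_turnover_is_scale_invariant():
    for v in (0.5, 3.0, 120.0):
        assert al.turnover_rate(0.22 * v, v) == pytest.approx(0.22)


@given(
    r=st.floats(0.0, 50.0),
    annv=st.floats(1e-6, 50.0),
    v=st.floats(1e-3, 200.0),
)
@settings(derandomize=True, max_examples=300)
def test_annra_identity_links_re_and_turnover(r, annv, v):
    """annRA == RE / (RE + turnover) exactly, for any R, annV, V."""
    annra = al.annual_reproductive_allocation(r, annv)
    re = al.reproductive_effort(r, v)
    to = al.turnover_rate(annv, v)
    assert annra == pytest.approx(re / (re + to), rel=1e-12)
    assert 0.0 <= annra <= 1.0


@given(scale=st.floats(1e-3, 1e3))
@settings(derandomize=True, max_examples=100)
def test_annra_invariant_to_mass_rescaling(scale):
    base = al.annual_reproductive_allocation(2.0, 3.0)
    assert al.annual_reproductive_allocation(2.0 * scale, 3.0 * scale) == pytest.approx(base)


def test_annra_monotone_in_r_and_annv():
    assert al.annual_reproductive_allocation(2.0, 1.0) > al.annual_reproductive_allocation(1.0, 1.0)
    assert al.annual_reproductive_allocation(1.0, 2.0) < al.annual_reproductive_allocation(1.0, 1.0)


def test_carbon_allocation_below_mass_allocation_when_receptacles_carbon_poor():
    mass_based = al.annual_reproductive_allocation(1.5, 2.0)
    assert al.carbon_allocation(1.5, 2.0, 0.25, 0.40) < mass_based
    assert al.carbon_allocation(1.5, 2.0, 0.33, 0.33) == pytest.approx(mass_based)


def test_shoot_allocation_chains_the_components(simple_shoot):
    out = al.shoot_allocation(simple_shoot, mean_s1_mass=0.1, c_rep=0.25, c_veg=0.40)
    assert out.n_tips == 10
    assert out.annV == pytest.approx(1.0)
    assert out.turnover == pytest.approx(0.25)
    assert out.RE == pytest.approx(0.25)
    assert out.annRA == pytest.approx(0.5)
    assert out.annRA == pytest.approx(out.RE / (out.RE + out.turnover), rel=1e-12)
    assert out.annRA_C == pytest.approx((1.0 * 0.25) / (1.0 * 0.25 + 1.0 * 0.40))


def test_tip_count_brackets_annual_growth(simple_shoot):
    """annV with n=b1 <= annV with mean tips <= annV with n=b0."""
    lo = al.annual_vegetative_growth(0.1, simple_shoot.b1_count)
    mid = al.annual_vegetative_growth(0.1, al.tip_count(simple_shoot.b0_count, simple_shoot.b1_count))
    hi = al.annual_vegetative_growth(0.1, simple_shoot.b0_count)
    assert lo <= mid <= hi


def test_deterministic_generator_shoot_matches_hand_computation():
    params = simgen.SimParams(
        max_age=3, first_reproductive_age=2, count_beta=(1.0, 0.2, -0.1),
        nb_dispersion=math.inf, random_effect_sd=0.0, size_noise_sd=0.0,
        s1_mass_mean=0.1, s1_mass_sd=0.0, branch_prob=0.0,
        size_intercept_a=0.03, size_slope_b=-0.002, n_shoots=1, seed=1,
    )
    ds = simgen.simulate_site(params)
    shoot = ds.shoots[0]
    # masses: age profile (0.5, 1, 1, 1) x 0.1; single tip throughout
    assert shoot.vegetative_mass_V == pytest.approx(0.05 + 0.1 * 3)
    # counts: round(exp(1 + 0.2a - 0.1a^2)) at ages 2, 3
    c2, c3 = round(math.exp(1.0)), round(math.exp(0.7))
    assert [s.receptacle_count for s in shoot.segments] == [0, 0, c2, c3]
    expected_R = c2 * (0.03 - 0.004) + c3 * (0.03 - 0.006)
    assert shoot.reproductive_mass_R == pytest.approx(expected_R)
    out = al.shoot_allocation(shoot, mean_s1_mass=0.1)
    assert out.annV == pytest.approx(0.1)
    assert out.turnover == pytest.approx(0.1 / 0.35)
    assert out.RE == pytest.approx(expected_R / 0.35)


def test_site_summary_mean_and_se(demo_dataset):
    # shoots differ only in R: annRA values {1/2, 2/3}; RE {0.25, 0.5}
    summary = al.site_summary(demo_dataset, mean_s1_mass=0.1)
    assert summary.n_shoots == 2
    assert summary.RE.mean == pytest.approx(0.375)
    assert summary.RE.se == pytest.approx(np.std([0.25, 0.5], ddof=1) / math.sqrt(2))
    assert summary.turnover.se == pytest.approx(0.0)
    # two metric values {0.2, 0.4} -> mean 0.3, SE 0.1
    assert al._mean_se([0.2, 0.4]) == al.MetricSummary(
        mean=pytest.approx(0.3), se=pytest.approx(0.1), n=2
    )


def test_single_shoot_summary_has_undefined_se(demo_dataset):
    demo_dataset.shoots = demo_dataset.shoots[:1]
    summary = al.site_summary(demo_dataset, mean_s1_mass=0.1)
    assert summary.n_shoots == 1
    assert summary.RE.se is None


def test_broken_shoots_excluded_by_default(demo_dataset):
    demo_dataset.shoots[1].broken = True
    summary = al.site_summary(demo_dataset, mean_s1_mass=0.1)
    assert summary.n_shoots == 1
    both = al.site_summary(demo_dataset, mean_s1_mass=0.1, include_broken=True)
    assert both.n_shoots == 2


def test_areal_production_scales_linearly_with_biomass(demo_dataset):
    site = demo_dataset.site
    base = al.areal_production(site, demo_dataset, mean_s1_mass=0.1)
    doubled_site = dataclasses.replace(site, standing_biomass=2 * site.standing_biomass)
    doubled = al.areal_production(doubled_site, demo_dataset, mean_s1_mass=0.1)
    assert doubled.rep_C == pytest.approx(2 * base.rep_C)
    assert doubled.veg_C == pytest.approx(2 * base.veg_C)
    assert doubled.total_C == pytest.approx(2 * base.total_C)
    assert base.total_C == pytest.approx(base.rep_C + base.veg_C)
    # biomass 1000, mean RE 0.375, c_rep 0.25
    assert base.rep_C == pytest.approx(1000 * 0.375 * 0.25)


def test_areal_production_requires_biomass(demo_dataset):
    site = dataclasses.replace(demo_dataset.site, standing_biomass=None)
    with pytest.raises(ValueError, match="standing biomass"):
        al.areal_production(site, demo_dataset, mean_s1_mass=0.1)
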