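"""Shared fixtures: small hand-built shoots and the calibrated profiles."""

from __future__ import annotations

import zlib

import pytest

from ascoalloc.core import Segment, Shoot, SiteRecord, SiteDataset
from ascoalloc import simgen


def profile_seed(name: str) -> int:
    """Deterministic per-profile seed (stable hash of the profile name)."""
    return zlib.crc32(name.encode()) % (2**31)


@pytest.fixture(scope="session")
def profiles() -> dict[str, simgen.SimParams]:
    """The four calibrated site profiles (calibration is cached)."""
    return dict(simgen._cached_profiles())


@pytest.fixture
def simple_shoot() -> Shoot:
    """Five-segment shoot with easy arithmetic: V=4, R=1, b0=12, b1=8."""
    segments = [
        Segment(age_years=0, segment_dry_mass=0.05),
        Segment(age_years=1, segment_dry_mass=0.10),
        Segment(age_years=2, segment_dry_mass=0.10, receptacle_count=5,
                receptacle_masses=[0.02]),
        Segment(age_years=3, segment_dry_mass=0.10, receptacle_count=10,
                receptacle_masses=[0.03]),
        Segment(age_years=4, segment_dry_mass=0.10),
    ]
    return Shoot(
        shoot_id="s1", site_id="demo", segments=segments,
        b0_count=12, b1_count=8, vegetative_mass_V=4.0, reproductive_mass_R=1.0,
    )


@pytest.fixture
def demo_site() -> SiteRecord:
    return SiteRecord(
        site_id="demo", latitude=64.2, sst_mean=2.5,
        standing_biomass=1000.0, biomass_se=100.0,
        c_fraction_vegetative=0.40, c_fraction_reproductive=0.25,
    )


@pytest.fixture
def demo_dataset(simple_shoot, demo_site) -> SiteDataset:
    import copy

    other = copy.deepcopy(simple_shoot)
    other.shoot_id = "s2"
    other.reproductive_mass_R = 2.0
    return SiteDataset(site=demo_site, shoots=[simple_shoot, other])
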