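"""Per-shoot and per-site allocation statistics and carbon upscaling.

The core quantities for a perennial, apically growing shoot:

* annV = mean S1 dry mass x n, the annual vegetative growth, where n is
  the number of apical tips, taken as the average of the youngest (b0)
  and second-youngest (b1) bladder counts;
* turnover = annV / V, the annual fraction of standing vegetative
  biomass renewed;
* RE = R / V, reproductive effort (receptacle mass over vegetative
  shoot mass);
* annRA = R / (R + annV), the fraction of annual production invested
  in reproduction.

These obey the exact algebraic identity annRA = RE / (RE + turnover),
which the test suite enforces shoot by shoot.  Carbon-unit variants
weight R and annV by tissue-specific carbon fractions; areal fluxes
multiply standing biomass per m^2 by the per-shoot RE and turnover
fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Shoot, SiteDataset, SiteRecord

__all__ = [
    "ShootAllocation",
    "SiteSummary",
    "ArealProduction",
    "tip_count",
    "annual_vegetative_growth",
    "turnover_rate",
    "reproductive_effort",
    "annual_reproductive_allocation",
    "to_carbon",
    "carbon_allocation",
    "shoot_allocation",
    "site_summary",
    "areal_production",
]


@dataclass(frozen=True)
class ShootAllocation:
    shoot_id: str
    annV: float  # g DW yr^-1
    n_tips: float  # may be half-integer
    turnover: float  # yr^-1
    RE: float  # dimensionless
    annRA: float  # fraction in [0, 1]
    annRA_C: float | None = None  # carbon-unit fraction, if C fractions known
    broken: bool = False


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    se: float | None
    n: int


@dataclass(frozen=True)
class SiteSummary:
    site_id: str
    annV: MetricSummary
    turnover: MetricSummary
    RE: MetricSummary
    annRA: MetricSummary
    annRA_C: MetricSummary | None
    n_shoots: int


@dataclass(frozen=True)
class ArealProduction:
    site_id: str
    veg_C: float  # g C m^-2 yr^-1
    rep_C: float
    total_C: float
    veg_C_se: float | None
    rep_C_se: float | None
    total_C_se: float | None


def tip_count(b0: int, b1: int) -> float:
    """Average of the two bladder-based tip estimates; may be half-integer.

    b1 undercounts the tips formed during the last year (branches split
    after the bladder formed), b0 overcounts them, so their mean is the
    compromise estimate.
    """
    if b0 < 1 or b1 < 1:
        raise ValueError("bladder counts must be >= 1")
    return (b0 + b1) / 2


def annual_vegetative_growth(mean_s1_mass: float, n_tips: float) -> float:
    """annV = mean S1 dry mass (g) x number of tips (g DW yr^-1)."""
    if mean_s1_mass <= 0:
        raise ValueError("mean_s1_mass must be > 0")
    if n_tips < 1:
        raise ValueError("n_tips must be >= 1")
    return mean_s1_mass * n_tips


def turnover_rate(annV: float, V: float) -> float:
    """Annual fraction of standing vegetative biomass renewed (yr^-1)."""
    if annV <= 0:
        raise ValueError("annV must be > 0")
    if V <= 0:
        raise ValueError("V must be > 0")
    return annV / V


def reproductive_effort(R: float, V: float) -> float:
    """RE = R / V, receptacle mass relative to vegetative shoot mass."""
    if R < 0:
        raise ValueError("R must be >= 0")
    if V <= 0:
        raise ValueError("V must be > 0")
    return R / V


def annual_reproductive_allocation(R: float, annV: float) -> float:
    """annRA = R / (R + annV), in [0, 1]."""
    if R < 0 or annV < 0:
        raise ValueError("R and annV must be >= 0")
    if R == 0 and annV == 0:
        raise ValueError("annRA undefined when R = annV = 0")
    return R / (R + annV)


def to_carbon(mass: float, c_fraction: float) -> float:
    """Convert a dry mass (g DW) to carbon units (g C)."""
    if mass < 0:
        raise ValueError("mass must be >= 0")
    if not 0 <= c_fraction <= 1:
        raise ValueError("c_fraction must lie in [0, 1]")
    return mass * c_fraction


def carbon_allocation(R: float, annV: float, c_rep: float, c_veg: float) -> float:
    """annRA on a carbon basis: (R c_rep) / (R c_rep + annV c_veg).

    Receptacles hold less carbon per unit dry mass than vegetative
    tissue, so the carbon-based allocation sits below the mass-based
    one whenever c_rep < c_veg.
    """
    rc = to_carbon(R, c_rep)
    vc = to_carbon(annV, c_veg)
    if rc == 0 and vc == 0:
        raise ValueError("carbon allocation undefined when both terms are 0")
    return rc / (rc + vc)


def shoot_allocation(
    shoot: Shoot,
    mean_s1_mass: float,
    c_rep: float | None = None,
    c_veg: float | None = None,
) -> ShootAllocation:
    """All allocation statistics for one shoot.

    ``mean_s1_mass`` is normally the site-level mean over the sampled
    apical segments (the sampling design measures apical growth on a
    larger pool of individuals than full shoots); pass a per-shoot
    value to override.
    """
    n = tip_count(shoot.b0_count, shoot.b1_count)
    annV = annual_vegetative_growth(mean_s1_mass, n)
    to = turnover_rate(annV, shoot.vegetative_mass_V)
    re = reproductive_effort(shoot.reproductive_mass_R, shoot.vegetative_mass_V)
    ra = annual_reproductive_allocation(shoot.reproductive_mass_R, annV)
    ra_c = None
    if c_rep is not None and c_veg is not None:
        ra_c = carbon_allocation(shoot.reproductive_mass_R, annV, c_rep, c_veg)
    return ShootAllocation(
        shoot_id=shoot.shoot_id,
        annV=annV,
        n_tips=n,
        turnover=to,
        RE=re,
        annRA=ra,
        annRA_C=ra_c,
        broken=shoot.broken,
    )


def _mean_se(values: list[float]) -> MetricSummary:
    arr = np.asarray(values, dtype=float)
    n = arr.size
    se = float(arr.std(ddof=1) / math.sqrt(n)) if n >= 2 else None
    return MetricSummary(mean=float(arr.mean()), se=se, n=n)


def site_mean_s1_mass(dataset: SiteDataset) -> float:
    """Site-level mean S1 (age-1 segment) dry mass across shoots."""
    masses = [
        seg.segment_dry_mass
        for sh in dataset.shoots
        for seg in sh.segments
        if seg.age_years == 1
    ]
    if not masses:
        raise ValueError("no age-1 segments in dataset")
    return float(np.mean(masses))


def site_summary(
    dataset: SiteDataset,
    mean_s1_mass: float | None = None,
    include_broken: bool = False,
) -> SiteSummary:
    """Mean and standard error (sd / sqrt(n)) of each metric over shoots.

    Broken shoots lack reliable tip counts and are excluded from all
    metrics by default.  With a single shoot the SEs are ``None``.
    """
    shoots = [s for s in dataset.shoots if include_broken or not s.broken]
    if not shoots:
        raise ValueError("no usable shoots in dataset")
    m1 = mean_s1_mass if mean_s1_mass is not None else site_mean_s1_mass(dataset)
    c_rep = dataset.site.c_fraction_reproductive
    c_veg = dataset.site.c_fraction_vegetative
    allocs = [shoot_allocation(s, m1, c_rep, c_veg) for s in shoots]
    have_c = all(a.annRA_C is not None for a in allocs)
    return SiteSummary(
        site_id=dataset.site.site_id,
        annV=_mean_se([a.annV for a in allocs]),
        turnover=_mean_se([a.turnover for a in allocs]),
        RE=_mean_se([a.RE for a in allocs]),
        annRA=_mean_se([a.annRA for a in allocs]),
        annRA_C=_mean_se([a.annRA_C for a in allocs]) if have_c else None,
        n_shoots=len(allocs),
    )


def areal_production(
    site: SiteRecord, dataset: SiteDataset, mean_s1_mass: float | None = None
) -> ArealProduction:
    """Carbon fluxes per m^2: standing biomass x per-shoot fractions.

    rep_C = biomass x RE x c_rep (receptacles are shed after gamete
    release, so this flux is exported); veg_C = biomass x turnover x
    c_veg.  SEs are taken across shoots: each shoot's RE and turnover
    is converted to an areal flux with the site-mean biomass, and the
    mean/SE of those per-shoot fluxes is reported, mirroring the
    shoot-level replication of the sampling design.
    """
    if site.standing_biomass is None or site.standing_biomass <= 0:
        raise ValueError(f"standing biomass missing for site {site.site_id}")
    if site.c_fraction_reproductive is None or site.c_fraction_vegetative is None:
        raise ValueError(f"carbon fractions missing for site {site.site_id}")
    shoots = [s for s in dataset.shoots if not s.broken]
    m1 = mean_s1_mass if mean_s1_mass is not None else site_mean_s1_mass(dataset)
    allocs = [shoot_allocation(s, m1) for s in shoots]
    B = site.standing_biomass
    rep = [B * a.RE * site.c_fraction_reproductive for a in allocs]
    veg = [B * a.turnover * site.c_fraction_vegetative for a in allocs]
    tot = [r + v for r, v in zip(rep, veg)]
    rep_s, veg_s, tot_s = _mean_se(rep), _mean_se(veg), _mean_se(tot)
    return ArealProduction(
        site_id=site.site_id,
        veg_C=veg_s.mean,
        rep_C=rep_s.mean,
        total_C=tot_s.mean,
        veg_C_se=veg_s.se,
        rep_C_se=rep_s.se,
        total_C_se=tot_s.se,
    )
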