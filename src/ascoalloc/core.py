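"""Domain types for age-structured fucoid shoots and sampling sites.

*Ascophyllum nodosum* grows apically and lays down one air bladder per
year on each axis, so a primary shoot can be cut into annual segments of
known age.  Age is counted from the tip: age 0 is the current-season,
incompletely formed apical segment; age 1 ("S1") is the newest fully
formed segment.  Receptacles — lateral branches differentiated into
reproductive structures, shed after gamete release — are counted and
weighed per segment.

These containers are deliberately thin: validation reports rather than
raises, so partially broken field records can still be inspected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


@dataclass
class Segment:
    """One annual segment of a primary shoot.

    Parameters
    ----------
    age_years : int
        Years since formation (0 = incomplete apical segment, 1 = S1).
    segment_dry_mass : float
        Dry mass of the segment in g DW (> 0).
    receptacle_count : int
        Number of receptacles attached to the segment (>= 0).
    receptacle_masses : list of float
        Optional per-receptacle dry masses in g DW.  Field protocols
        usually pool receptacles by (site, segment age), so this list
        may be empty or shorter than ``receptacle_count``.
    """

    age_years: int
    segment_dry_mass: float
    receptacle_count: int = 0
    receptacle_masses: list[float] = field(default_factory=list)


@dataclass
class Shoot:
    """The longest unbroken primary shoot of one individual.

    ``b0_count`` and ``b1_count`` are the counts of the youngest and
    second-youngest bladders over the whole shoot (one per apical tip at
    the corresponding year); dichotomous branching makes b0 >= b1 for
    intact shoots.  ``vegetative_mass_V`` is the dry mass of the entire
    shoot without receptacles; ``reproductive_mass_R`` is the dry mass
    of all receptacles on the shoot.
    """

    shoot_id: str
    site_id: str
    segments: list[Segment]
    b0_count: int
    b1_count: int
    vegetative_mass_V: float
    reproductive_mass_R: float = 0.0
    broken: bool = False

    @property
    def max_age(self) -> int:
        return max((s.age_years for s in self.segments), default=-1)

    def segment_at(self, age: int) -> Segment | None:
        for s in self.segments:
            if s.age_years == age:
                return s
        return None


@dataclass
class SiteRecord:
    """Site-level covariates used for upscaling and meta-regression."""

    site_id: str
    latitude: float  # degrees N
    sst_mean: float | None = None  # deg C, long-term (2000-2020) mean
    standing_biomass: float | None = None  # g DW m^-2
    biomass_se: float | None = None
    c_fraction_vegetative: float | None = None  # fraction of DW
    c_fraction_reproductive: float | None = None


@dataclass
class SiteDataset:
    """A sampled shoot population together with its site covariates."""

    site: SiteRecord
    shoots: list[Shoot]


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_shoot`."""

    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule}"


def validate_shoot(shoot: Shoot) -> list[Violation]:
    """Check a shoot against the structural invariants; never raises.

    Returns an empty list iff the shoot is well formed.  Checks:
    contiguous segment ages 0..A with no duplicates, positive masses,
    non-negative counts, b0 >= b1 for unbroken shoots (dichotomous
    branching only adds tips), and that the whole-shoot vegetative mass
    is at least the summed primary-axis segment mass.
    """
    out: list[Violation] = []
    ages = [s.age_years for s in shoot.segments]
    if not ages:
        out.append(Violation("segments", "shoot has no segments"))
        return out
    if len(set(ages)) != len(ages):
        out.append(Violation("segments.age_years", "duplicate segment ages"))
    if sorted(ages) != list(range(min(ages), max(ages) + 1)) or min(ages) != 0:
        out.append(Violation("segments.age_years", "non-contiguous ages (expected 0..A)"))
    for s in shoot.segments:
        if s.age_years < 0:
            out.append(Violation("segments.age_years", f"negative age {s.age_years}"))
        if not s.segment_dry_mass > 0:
            out.append(
                Violation("segments.segment_dry_mass", f"non-positive mass at age {s.age_years}")
            )
        if s.receptacle_count < 0:
            out.append(
                Violation("segments.receptacle_count", f"negative count at age {s.age_years}")
            )
        if any(m <= 0 for m in s.receptacle_masses):
            out.append(
                Violation("segments.receptacle_masses", f"non-positive mass at age {s.age_years}")
            )
    if shoot.b0_count < 1:
        out.append(Violation("b0_count", "must be >= 1"))
    if shoot.b1_count < 1:
        out.append(Violation("b1_count", "must be >= 1"))
    if not shoot.broken and shoot.b0_count < shoot.b1_count:
        out.append(Violation("b0_count", "b0 < b1 on an unbroken shoot"))
    if not shoot.vegetative_mass_V > 0:
        out.append(Violation("vegetative_mass_V", "must be > 0"))
    if shoot.reproductive_mass_R < 0:
        out.append(Violation("reproductive_mass_R", "must be >= 0"))
    axis_mass = sum(s.segment_dry_mass for s in shoot.segments if s.segment_dry_mass > 0)
    # small tolerance: V and segment masses are measured independently
    if shoot.vegetative_mass_V < axis_mass * (1 - 1e-9):
        out.append(
            Violation("vegetative_mass_V", "less than summed primary-axis segment mass")
        )
    return out


def validate_site_record(site: SiteRecord) -> list[Violation]:
    """Range checks on site covariates (latitude, C fractions)."""
    out: list[Violation] = []
    if not -90 <= site.latitude <= 90:
        out.append(Violation("latitude", "outside [-90, 90]"))
    for name in ("c_fraction_vegetative", "c_fraction_reproductive"):
        v = getattr(site, name)
        if v is not None and not 0 <= v <= 1:
            out.append(Violation(name, "outside [0, 1]"))
    if site.standing_biomass is not None and site.standing_biomass < 0:
        out.append(Violation("standing_biomass", "must be >= 0"))
    return out


def validate_dataset(ds: SiteDataset) -> list[Violation]:
    """Validate the site record, every shoot, and cross-references."""
    out = validate_site_record(ds.site)
    for sh in ds.shoots:
        if sh.site_id != ds.site.site_id:
            out.append(Violation("shoots.site_id", f"{sh.shoot_id} references {sh.site_id}"))
        out.extend(validate_shoot(sh))
    return out
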