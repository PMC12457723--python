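"""CSV readers/writers for the field-data schemas.

All interchange is plain CSV (field records are tabular).  Column
names are frozen:

* ``sites.csv``: site_id, latitude_degN, sst_mean_C,
  standing_biomass_gDW_m2, biomass_se, c_frac_veg, c_frac_rep
* ``shoots.csv``: shoot_id, site_id, b0_count, b1_count, V_gDW, R_gDW,
  broken
* ``segments.csv``: shoot_id, age_years, segment_gDW,
  receptacle_count, receptacle_masses (semicolon-joined g DW, may be
  empty)
* ``receptacle_pools.csv``: site_id, age_years, mean_receptacle_gDW,
  n_pooled
* ``meta_records.csv``: region_id, latitude_degN, sst_mean_C, annRA,
  peak_month, peak_jd, source

Files open with UTF-8-BOM-tolerant decoding; lines starting with ``#``
are unit/provenance comments.  Masses are g DW unless a column name
says otherwise — confusing dry weight with carbon units is the main
user hazard, so every written file carries a unit comment header.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Segment, Shoot, SiteDataset, SiteRecord, validate_dataset

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_site_dataset",
    "write_site_dataset",
    "read_meta_records",
    "receptacle_pool_table",
]

SITE_COLUMNS = [
    "site_id", "latitude_degN", "sst_mean_C", "standing_biomass_gDW_m2",
    "biomass_se", "c_frac_veg", "c_frac_rep",
]
SHOOT_COLUMNS = ["shoot_id", "site_id", "b0_count", "b1_count", "V_gDW", "R_gDW", "broken"]
SEGMENT_COLUMNS = ["shoot_id", "age_years", "segment_gDW", "receptacle_count", "receptacle_masses"]
META_COLUMNS = ["region_id", "latitude_degN"]


class SchemaError(ValueError):
    """A CSV file does not conform to its frozen schema."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (used by the CLI)."""

    seed: int = 0
    profile: str | None = None
    n_shoots: int | None = None
    wrap_policy: str = "autumn-negative"
    fit_method: str = "pooled-nb"
    out_dir: Path = field(default_factory=lambda: Path("."))
    verbose: bool = False


def _read_csv(path: Path | str, required: list[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, comment="#", encoding="utf-8-sig", skip_blank_lines=True,
        float_precision="round_trip",
    )
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{name}: missing column {col!r}")
    return df


def _opt(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def read_site_dataset(
    sites_csv: Path | str,
    shoots_csv: Path | str,
    segments_csv: Path | str,
    site_id: str | None = None,
    validate: bool = True,
) -> SiteDataset:
    """Assemble a :class:`SiteDataset` from the three schema files.

    With several sites in ``sites.csv``, ``site_id`` selects one.
    Schema violations raise :class:`SchemaError` naming the column;
    shoot-invariant violations are raised as ``ValueError`` listing
    every offence (pass ``validate=False`` to inspect broken records).
    """
    sites = _read_csv(sites_csv, SITE_COLUMNS, "sites.csv")
    shoots = _read_csv(shoots_csv, SHOOT_COLUMNS, "shoots.csv")
    segments = _read_csv(segments_csv, SEGMENT_COLUMNS[:4], "segments.csv")

    if site_id is None:
        if len(sites) != 1:
            raise SchemaError("sites.csv holds several sites; pass site_id")
        row = sites.iloc[0]
    else:
        sel = sites[sites["site_id"] == site_id]
        if sel.empty:
            raise SchemaError(f"sites.csv: no row with site_id {site_id!r}")
        row = sel.iloc[0]
    site = SiteRecord(
        site_id=str(row["site_id"]),
        latitude=float(row["latitude_degN"]),
        sst_mean=_opt(row["sst_mean_C"]),
        standing_biomass=_opt(row["standing_biomass_gDW_m2"]),
        biomass_se=_opt(row["biomass_se"]),
        c_fraction_vegetative=_opt(row["c_frac_veg"]),
        c_fraction_reproductive=_opt(row["c_frac_rep"]),
    )

    seg_by_shoot: dict[str, list[Segment]] = {}
    for _, r in segments.iterrows():
        masses: list[float] = []
        if "receptacle_masses" in segments.columns:
            raw = r.get("receptacle_masses")
            if isinstance(raw, str):
                masses = [float(v) for v in raw.split(";") if v]
            elif raw is not None and not (isinstance(raw, float) and math.isnan(raw)):
                masses = [float(raw)]  # single pooled mass, parsed numeric
        seg_by_shoot.setdefault(str(r["shoot_id"]), []).append(
            Segment(
                age_years=int(r["age_years"]),
                segment_dry_mass=float(r["segment_gDW"]),
                receptacle_count=int(r["receptacle_count"]),
                receptacle_masses=masses,
            )
        )

    shoot_objs: list[Shoot] = []
    for _, r in shoots[shoots["site_id"] == site.site_id].iterrows():
        sid = str(r["shoot_id"])
        shoot_objs.append(
            Shoot(
                shoot_id=sid,
                site_id=site.site_id,
                segments=sorted(seg_by_shoot.get(sid, []), key=lambda s: s.age_years),
                b0_count=int(r["b0_count"]),
                b1_count=int(r["b1_count"]),
                vegetative_mass_V=float(r["V_gDW"]),
                reproductive_mass_R=float(r["R_gDW"]),
                broken=bool(r["broken"]),
            )
        )
    ds = SiteDataset(site=site, shoots=shoot_objs)
    if validate:
        violations = validate_dataset(ds)
        if violations:
            raise ValueError(
                "dataset violates invariants: " + "; ".join(map(str, violations))
            )
    return ds


_UNIT_HEADER = "# units: masses g DW, biomass g DW m^-2, latitude deg N, SST deg C\n"


def write_site_dataset(ds: SiteDataset, out_dir: Path | str) -> dict[str, Path]:
    """Write sites/shoots/segments (+ receptacle pools) CSVs; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = ds.site
    sites = pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "latitude_degN": s.latitude,
                "sst_mean_C": s.sst_mean,
                "standing_biomass_gDW_m2": s.standing_biomass,
                "biomass_se": s.biomass_se,
                "c_frac_veg": s.c_fraction_vegetative,
                "c_frac_rep": s.c_fraction_reproductive,
            }
        ]
    )
    shoots = pd.DataFrame(
        [
            {
                "shoot_id": sh.shoot_id,
                "site_id": sh.site_id,
                "b0_count": sh.b0_count,
                "b1_count": sh.b1_count,
                "V_gDW": sh.vegetative_mass_V,
                "R_gDW": sh.reproductive_mass_R,
                "broken": sh.broken,
            }
            for sh in ds.shoots
        ]
    )
    segments = pd.DataFrame(
        [
            {
                "shoot_id": sh.shoot_id,
                "age_years": seg.age_years,
                "segment_gDW": seg.segment_dry_mass,
                "receptacle_count": seg.receptacle_count,
                "receptacle_masses": ";".join(repr(m) for m in seg.receptacle_masses),
            }
            for sh in ds.shoots
            for seg in sh.segments
        ]
    )
    paths = {}
    for name, frame in [("sites", sites), ("shoots", shoots), ("segments", segments),
                        ("receptacle_pools", receptacle_pool_table(ds))]:
        p = out / f"{name}.csv"
        with open(p, "w", newline="") as fh:
            fh.write(_UNIT_HEADER)
            # %.17g keeps doubles exact through a write/read cycle
            frame.to_csv(fh, index=False, float_format="%.17g")
        paths[name] = p
    return paths


def receptacle_pool_table(ds: SiteDataset) -> pd.DataFrame:
    """Pooled mean receptacle dry mass per segment age across shoots.

    Receptacles are pooled by (site, segment age) before weighing, so
    the pool table — not per-receptacle masses — is the canonical
    granularity for the size-age analysis.
    """
    rows: dict[int, list[float]] = {}
    counts: dict[int, int] = {}
    for sh in ds.shoots:
        for seg in sh.segments:
            if seg.receptacle_count > 0 and seg.receptacle_masses:
                rows.setdefault(seg.age_years, []).extend(seg.receptacle_masses)
                counts[seg.age_years] = counts.get(seg.age_years, 0) + seg.receptacle_count
    return pd.DataFrame(
        [
            {
                "site_id": ds.site.site_id,
                "age_years": age,
                "mean_receptacle_gDW": float(np.mean(m)),
                "n_pooled": counts[age],
            }
            for age, m in sorted(rows.items())
        ]
    )


def read_meta_records(path: Path | str) -> pd.DataFrame:
    """Read a meta-records CSV (literature survey rows)."""
    return _read_csv(path, META_COLUMNS, "meta_records.csv")
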