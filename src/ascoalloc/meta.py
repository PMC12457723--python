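"""Cross-study meta-dataset assembly and latitudinal regressions.

Published estimates of annual reproductive allocation (annRA) and
reproduction-peak timing are compiled to one data point per region:
sub-populations sampled within a region are averaged into a regional
mean, and sources that only report reproductive effort (RE = R/V,
which is not convertible to annRA without annV) are excluded from the
annRA analysis.  Four headline ordinary-least-squares regressions then
relate annRA and peak Julian day to latitude and mean sea surface
temperature; latitude and SST are too collinear across the North
Atlantic (Pearson r near -0.8) for a joint model, so the predictors
are tested separately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .phenology import month_to_julian_day

__all__ = [
    "MetaRecord",
    "RegressionFit",
    "assemble_meta_table",
    "ols_fit",
    "collinearity",
    "run_headline_regressions",
    "load_reference_table",
    "RE_ONLY_TAG",
]

log = logging.getLogger(__name__)

#: Source tag marking studies that report only RE, excluded from annRA.
RE_ONLY_TAG = "re-only"


@dataclass(frozen=True)
class MetaRecord:
    region_id: str
    latitude: float  # degrees N
    sst_mean: float | None = None  # deg C
    annRA: float | None = None  # fraction
    peak_jd: int | None = None  # approximate Julian day
    source: str = ""

    def __post_init__(self) -> None:
        if self.annRA is None and self.peak_jd is None:
            raise ValueError(f"region {self.region_id}: no response present")


@dataclass(frozen=True)
class RegressionFit:
    """Simple linear regression summary (response ~ predictor)."""

    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    p_value: float  # two-sided t-test on the slope
    slope_se: float
    n: int
    residual_normality_p: float | None  # Shapiro-Wilk on residuals


def _opt(v) -> float | None:
    return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)


def assemble_meta_table(
    records: pd.DataFrame, wrap_policy: str = "autumn-negative"
) -> list[MetaRecord]:
    """Collapse raw literature records to one point per region.

    ``records`` columns: ``region_id``, ``latitude_degN``, optional
    ``sst_mean_C``, ``annRA``, ``peak_month``, ``peak_jd``, ``source``.
    Rows sharing a ``region_id`` are sub-population replicates and are
    averaged into the regional mean.  A region fed by more than one
    distinct source is ambiguous and rejected.  Rows whose source
    carries the ``re-only`` tag have their annRA dropped (with a logged
    reason).  ``peak_month`` is converted to an approximate Julian day;
    an explicit ``peak_jd`` passes through.
    """
    req = {"region_id", "latitude_degN"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out: list[MetaRecord] = []
    for region, grp in records.groupby("region_id", sort=False):
        sources = (
            sorted({s for s in grp["source"].dropna() if s}) if "source" in grp else []
        )
        base_sources = {s.replace(RE_ONLY_TAG, "").strip(" ;,") for s in sources}
        if len(base_sources) > 1:
            raise ValueError(f"region {region!r} has conflicting sources {sources}")
        re_only = any(RE_ONLY_TAG in s for s in sources)
        ann = None
        if "annRA" in grp and grp["annRA"].notna().any():
            if re_only:
                log.info(
                    "assemble_meta_table: %s reports RE only, excluded from annRA", region
                )
            else:
                ann = float(grp["annRA"].mean())
        jd = None
        if "peak_jd" in grp and grp["peak_jd"].notna().any():
            jd = int(round(grp["peak_jd"].mean()))
        elif "peak_month" in grp and grp["peak_month"].notna().any():
            months = grp["peak_month"].dropna().astype(int)
            jds = [month_to_julian_day(m, wrap_policy) for m in months]
            jd = int(round(float(np.mean(jds))))
        if ann is None and jd is None:
            log.info(
                "assemble_meta_table: %s has no usable response, dropped", region
            )
            continue
        out.append(
            MetaRecord(
                region_id=str(region),
                latitude=float(grp["latitude_degN"].mean()),
                sst_mean=_opt(grp["sst_mean_C"].mean()) if "sst_mean_C" in grp else None,
                annRA=ann,
                peak_jd=jd,
                source="; ".join(sources),
            )
        )
    n_ann = sum(r.annRA is not None for r in out)
    n_jd = sum(r.peak_jd is not None for r in out)
    log.info(
        "assemble_meta_table: %d regions (%d annRA, %d peak-timing points)",
        len(out), n_ann, n_jd,
    )
    return out


def ols_fit(x, y) -> RegressionFit:
    """Closed-form simple linear regression with slope t-test.

    Adjusted R^2 uses the single-predictor form
    1 - (1 - R^2)(n - 1)/(n - 2).  Residual normality is assessed with
    a Shapiro-Wilk test (reported, never enforced).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    resid = np.asarray(res.resid)
    shapiro_p = float(stats.shapiro(resid).pvalue) if x.size >= 3 else None
    r2 = float(res.rsquared)
    n = int(x.size)
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=r2,
        adj_r_squared=1 - (1 - r2) * (n - 1) / (n - 2),
        p_value=float(res.pvalues[1]),
        slope_se=float(res.bse[1]),
        n=n,
        residual_normality_p=shapiro_p,
    )


def collinearity(x1, x2) -> float:
    """Pearson product-moment correlation between two predictors."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size != x2.size or x1.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        raise ValueError("constant vector has undefined correlation")
    return float(stats.pearsonr(x1, x2).statistic)


def run_headline_regressions(
    table: list[MetaRecord],
) -> dict[str, RegressionFit | None]:
    """The four latitude/SST regressions on the assembled meta-table.

    Keys: ``annRA~latitude``, ``annRA~sst``, ``peak_jd~latitude``,
    ``peak_jd~sst``.  Rows missing the response or the predictor are
    dropped per regression; a regression with fewer than 3 usable
    points is reported as ``None`` (with a logged reason) rather than
    fitted.
    """
    out: dict[str, RegressionFit | None] = {}
    for resp in ("annRA", "peak_jd"):
        for pred in ("latitude", "sst"):
            attr = "latitude" if pred == "latitude" else "sst_mean"
            pairs = [
                (getattr(r, attr), getattr(r, resp))
                for r in table
                if getattr(r, attr) is not None and getattr(r, resp) is not None
            ]
            key = f"{resp}~{pred}"
            if len(pairs) < 3:
                log.info("run_headline_regressions: %s has %d usable points", key, len(pairs))
                out[key] = None
                continue
            x, y = zip(*pairs)
            out[key] = ols_fit(x, y)
    return out


def load_reference_table() -> pd.DataFrame:
    """The packaged literature table of regional annRA and peak months.

    One row per published region with the printed regional means;
    Nova Scotia appears as its single printed regional mean (the
    original nine sub-populations group into three regions, but those
    three means were not published — supply them as extra rows with
    region tags to reproduce the 11-point layout).
    """
    with resources.files("ascoalloc.data").joinpath("meta_records.csv").open() as fh:
        return pd.read_csv(fh, comment="#")
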