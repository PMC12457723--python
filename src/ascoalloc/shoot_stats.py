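"""Within-shoot receptacle-formation models.

Receptacle abundance along a shoot rises from the apical tip to a
maximum and falls towards the base, which a quadratic in segment age on
the log scale captures; counts are overdispersed (some shoots are
covered in receptacles, others nearly bare), hence a negative-binomial
error model with a shoot-level effect.  Mean receptacle dry mass
declines roughly linearly with segment age.  The 50%-cumulative age
summarizes how front-loaded reproduction is along the shoot.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

from .core import SiteDataset

__all__ = [
    "QuadraticCountFit",
    "SizeAgeFit",
    "counts_by_age",
    "fit_count_age",
    "fit_size_age",
    "cumulative_half_age",
    "MAX_SEGMENT_AGE",
]

log = logging.getLogger(__name__)

#: Shoots are rarely older than this; older segments are excluded from
#: the count-age analysis.
MAX_SEGMENT_AGE = 12


@dataclass(frozen=True)
class QuadraticCountFit:
    """NB regression of receptacle count on age + age^2 (log link)."""

    beta0: float
    beta1: float
    beta2: float
    dispersion_k: float | None  # NB size parameter (variance = mu + mu^2/k)
    shoot_intercept_var: float | None  # variance of shoot offsets, if fitted
    argmax_age: float | None  # -beta1 / (2 beta2) when beta2 < 0
    converged: bool
    n_obs: int
    method: str

    @property
    def concave(self) -> bool:
        return self.converged and self.beta2 < 0


@dataclass(frozen=True)
class SizeAgeFit:
    """OLS of mean receptacle dry mass on segment age."""

    intercept: float  # g DW
    slope: float  # g DW yr^-1
    r_squared: float
    p_value: float  # two-sided t-test on the slope
    slope_se: float
    n: int

    def slope_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        from scipy.stats import t

        q = t.ppf(1 - alpha / 2, self.n - 2)
        return self.slope - q * self.slope_se, self.slope + q * self.slope_se


def counts_by_age(dataset: SiteDataset, max_age: int = MAX_SEGMENT_AGE) -> pd.DataFrame:
    """Tidy (shoot_id, age_years, receptacle_count) table, ages <= max_age.

    Segments older than ``max_age`` are excluded (few shoots reach that
    age, so those cells would be dominated by one or two individuals);
    exclusions are logged.
    """
    rows = []
    n_excluded = 0
    for sh in dataset.shoots:
        for seg in sh.segments:
            if seg.age_years > max_age:
                n_excluded += 1
                continue
            rows.append((sh.shoot_id, seg.age_years, seg.receptacle_count))
    if n_excluded:
        log.info("counts_by_age: excluded %d segments older than %d", n_excluded, max_age)
    return pd.DataFrame(rows, columns=["shoot_id", "age_years", "receptacle_count"])


def _design(table: pd.DataFrame, method: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    age = table["age_years"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(age), age, age**2])
    names = ["const", "age", "age2"]
    if method == "shoot-offsets":
        dummies = pd.get_dummies(table["shoot_id"], drop_first=True, dtype=float)
        X = np.column_stack([X, dummies.to_numpy()])
        names += [f"shoot[{c}]" for c in dummies.columns]
    return X, table["receptacle_count"].to_numpy(dtype=float), names


def fit_count_age(table: pd.DataFrame, method: str = "pooled-nb") -> QuadraticCountFit:
    """Fit the quadratic negative-binomial count-age model.

    ``method`` is ``"pooled-nb"`` (all shoots share one intercept) or
    ``"shoot-offsets"`` (a fixed offset per shoot absorbs shoot-level
    heterogeneity; the variance of the estimated offsets is reported as
    a crude analogue of a random-intercept variance).  A full
    random-slope mixed model is deliberately avoided: it is fragile at
    the 10-14 shoots of a typical field sample, and shape recovery
    (sign of the quadratic term, location of the maximum) is the
    scientific target.

    Non-convergence or degenerate data (e.g., all-zero counts) is
    flagged on the returned fit rather than raised.
    """
    if method not in ("pooled-nb", "shoot-offsets"):
        raise ValueError(f"unknown method {method!r}")
    tab = table[table["age_years"] <= MAX_SEGMENT_AGE]
    n_obs = len(tab)
    if tab["age_years"].nunique() < 3 or tab["shoot_id"].nunique() < 2:
        raise ValueError("need >= 3 distinct ages and >= 2 shoots")
    bad = QuadraticCountFit(
        math.nan, math.nan, math.nan, None, None, None, False, n_obs, method
    )
    if (tab["receptacle_count"] == 0).all():
        log.warning("fit_count_age: all counts zero, degenerate fit")
        return bad
    X, y, names = _design(tab, method)
    try:
        model = NegativeBinomial(y, X, loglike_method="nb2")
        # Poisson start values stabilize the NB likelihood maximization;
        # the line search may probe boundary points, hence errstate
        with np.errstate(divide="ignore", invalid="ignore"):
            start = sm.GLM(y, X, family=sm.families.Poisson()).fit().params
            res = model.fit(
                start_params=np.append(start, 0.1), method="bfgs", maxiter=500, disp=0
            )
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception:
        log.warning("fit_count_age: NB likelihood maximization failed", exc_info=True)
        return bad
    params = res.params
    beta0, beta1, beta2 = params[0], params[1], params[2]
    alpha = params[-1]  # statsmodels NB2: Var = mu + alpha mu^2
    k = float(1 / alpha) if alpha > 0 else None
    offset_var = None
    if method == "shoot-offsets":
        offsets = np.concatenate([[0.0], params[3:-1]])
        offset_var = float(np.var(offsets, ddof=1)) if offsets.size > 1 else 0.0
    argmax = float(-beta1 / (2 * beta2)) if beta2 < 0 else None
    return QuadraticCountFit(
        beta0=float(beta0),
        beta1=float(beta1),
        beta2=float(beta2),
        dispersion_k=k,
        shoot_intercept_var=offset_var,
        argmax_age=argmax,
        converged=converged,
        n_obs=n_obs,
        method=method,
    )


def fit_size_age(mean_sizes: Sequence[tuple[float, float]] | pd.DataFrame) -> SizeAgeFit:
    """OLS of site-mean receptacle dry mass per age on segment age.

    Operates on pooled per-age means (receptacles are pooled by segment
    age when weighed), not per-receptacle data.
    """
    if isinstance(mean_sizes, pd.DataFrame):
        pairs = mean_sizes.iloc[:, :2].to_numpy(dtype=float)
    else:
        pairs = np.asarray(mean_sizes, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 3:
        raise ValueError("need >= 3 (age, mean mass) points")
    x, y = pairs[:, 0], pairs[:, 1]
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    r2 = float(res.rsquared)
    if np.ptp(y) == 0:  # constant response: define R^2 = 0, slope exactly 0
        r2 = 0.0
    return SizeAgeFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        r_squared=r2,
        p_value=float(res.pvalues[1]),
        slope_se=float(res.bse[1]),
        n=len(x),
    )


def cumulative_half_age(counts: Mapping[int, float] | Sequence[float]) -> int:
    """Smallest age, counting from the tip, holding >= half the receptacles.

    ``counts`` maps segment age to a (possibly mean) receptacle count,
    or is a sequence indexed by age starting at 0.  Ties resolve to the
    first age reaching the threshold (>=, not >), so the statistic is
    deterministic and scale-invariant.
    """
    if isinstance(counts, Mapping):
        ages = sorted(counts)
        values = [counts[a] for a in ages]
    else:
        values = list(counts)
        ages = list(range(len(values)))
    if any(v < 0 for v in values):
        raise ValueError("counts must be >= 0")
    total = sum(values)
    if total <= 0:
        raise ValueError("cumulative_half_age undefined for all-zero counts")
    acc = 0.0
    for a, v in zip(ages, values):
        acc += v
        if acc >= 0.5 * total:
            return a
    return ages[-1]  # pragma: no cover - unreachable (acc reaches total)
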