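"""Miscarriage-enrichment tests for carrier-couple mothers.

Two complementary models, both adjusting for the mother's year of birth
(miscarriage registration and recall vary strongly by cohort):

* ``history_logistic`` — logistic regression of ever-having-miscarried
  on carrier-couple status, reporting the carrier odds ratio with a
  two-sided Wald p-value.
* ``ratio_linear`` — ordinary least squares of the per-mother
  miscarriage ratio (miscarriages / pregnancies) on carrier-couple
  status, reporting the difference in mean ratio.

``couple_history_fraction`` is the simple descriptive statistic: of the
carrier-couple mothers with evaluable records, what fraction has any
miscarriage history.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .genealogy import CarrierCouple

logger = logging.getLogger(__name__)

# |log OR| beyond this is treated as separation (the MLE does not exist)
_SEPARATION_COEF = 15.0


@dataclass(frozen=True)
class MotherRecord:
    """One mother's reproductive history."""

    mother_id: str
    birth_year: int | None = None
    pregnancies: int | None = None
    miscarriages: int | None = None
    any_miscarriage: bool | None = None
    early_miscarriage_reported: bool | None = None
    carrier_couple: bool = False

    def __post_init__(self) -> None:
        if (
            self.pregnancies is not None
            and self.miscarriages is not None
            and self.miscarriages > self.pregnancies
        ):
            raise ValueError(f"{self.mother_id}: miscarriages > pregnancies")

    @property
    def has_history(self) -> bool | None:
        if self.any_miscarriage is not None:
            return self.any_miscarriage
        if self.miscarriages is not None:
            return self.miscarriages >= 1
        return None

    @property
    def ratio(self) -> float | None:
        if not self.pregnancies:
            return None
        return (self.miscarriages or 0) / self.pregnancies


@dataclass(frozen=True)
class LogisticResult:
    odds_ratio: float
    p_value: float
    coefficients: dict[str, float]
    conf_int: tuple[float, float]  # 95% CI for the odds ratio
    status: str  # "ok", "separation", or "unadjusted"


@dataclass(frozen=True)
class LinearResult:
    effect: float  # carrier - control difference in mean miscarriage ratio
    p_value: float
    conf_int: tuple[float, float]
    n_used: int


def _design(records: Sequence[MotherRecord]) -> tuple[np.ndarray, list[str], np.ndarray]:
    carrier = np.array([1.0 if r.carrier_couple else 0.0 for r in records])
    years = np.array(
        [float(r.birth_year) if r.birth_year is not None else np.nan for r in records]
    )
    if np.isnan(years).any():
        fill = np.nanmean(years) if not np.isnan(years).all() else 0.0
        years = np.where(np.isnan(years), fill, years)
    cols = [np.ones(len(records)), carrier]
    names = ["intercept", "carrier_couple"]
    if np.ptp(years) > 0:
        cols.append(years - years.mean())  # centered for numerical stability
        names.append("birth_year_centered")
    else:
        logger.info("birth_year constant; fitting unadjusted model")
    return np.column_stack(cols), names, carrier


def history_logistic(records: Sequence[MotherRecord]) -> LogisticResult:
    """Logistic regression of miscarriage history on carrier-couple status.

    Outcome is any_miscarriage; covariates are the carrier indicator and
    the mother's (centered) year of birth. Returns the exponentiated
    carrier coefficient as an odds ratio with a two-sided Wald p-value.
    Complete separation is reported with an inf/0 odds ratio and status
    "separation" rather than raised.
    """
    usable = [r for r in records if r.has_history is not None]
    if len(usable) < len(records):
        logger.info("dropped %d records without known history", len(records) - len(usable))
    y = np.array([1.0 if r.has_history else 0.0 for r in usable])
    if len(usable) == 0 or y.min() == y.max():
        raise ValueError("outcome takes a single value; logistic model unidentifiable")
    x, names, carrier = _design(usable)
    if carrier.min() == carrier.max():
        raise ValueError("carrier indicator takes a single value")
    status = "ok" if "birth_year_centered" in names else "unadjusted"
    try:
        fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        coef = dict(zip(names, fit.params))
        beta = coef["carrier_couple"]
        if abs(beta) > _SEPARATION_COEF:
            raise np.linalg.LinAlgError("diverging carrier coefficient")
        ci_lo, ci_hi = fit.conf_int()[1]
        return LogisticResult(
            odds_ratio=float(np.exp(beta)),
            p_value=float(fit.pvalues[1]),
            coefficients=coef,
            conf_int=(float(np.exp(ci_lo)), float(np.exp(ci_hi))),
            status=status,
        )
    except (np.linalg.LinAlgError, ValueError, PerfectSeparationError):
        # complete/quasi separation: report the direction, not a crash
        has = y[carrier == 1].mean()
        direction = np.inf if has >= y[carrier == 0].mean() else 0.0
        logger.warning("separation detected in history_logistic")
        return LogisticResult(
            odds_ratio=float(direction),
            p_value=float("nan"),
            coefficients={},
            conf_int=(float("nan"), float("nan")),
            status="separation",
        )


def history_logistic_lr_pvalue(records: Sequence[MotherRecord]) -> float:
    """Likelihood-ratio p-value for the carrier term (alternative to Wald)."""
    from scipy.stats import chi2

    usable = [r for r in records if r.has_history is not None]
    y = np.array([1.0 if r.has_history else 0.0 for r in usable])
    x, names, carrier = _design(usable)
    full = sm.Logit(y, x).fit(disp=0, maxiter=200)
    reduced = sm.Logit(y, np.delete(x, 1, axis=1)).fit(disp=0, maxiter=200)
    stat = 2.0 * (full.llf - reduced.llf)
    return float(chi2.sf(stat, df=1))


def ratio_linear(records: Sequence[MotherRecord]) -> LinearResult:
    """OLS of miscarriages/pregnancies on carrier status + centered birth year.

    Mothers with zero or unknown pregnancies are dropped (and logged);
    the carrier effect is the adjusted difference in mean ratio.
    """
    usable = [r for r in records if r.ratio is not None]
    dropped = len(records) - len(usable)
    if dropped:
        logger.info("ratio_linear: dropped %d mothers without pregnancy counts", dropped)
    if not usable:
        raise ValueError("no mothers with pregnancies >= 1")
    y = np.array([r.ratio for r in usable])
    x, names, carrier = _design(usable)
    fit = sm.OLS(y, x).fit()
    ci = fit.conf_int()[1]
    return LinearResult(
        effect=float(fit.params[1]),
        p_value=float(fit.pvalues[1]),
        conf_int=(float(ci[0]), float(ci[1])),
        n_used=len(usable),
    )


def percent_1dp(x: float) -> float:
    """Percent formatting helper: round half-up to one decimal (66.666->66.7)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class HistoryFraction:
    k: int  # mothers with a miscarriage history
    n: int  # evaluable mothers
    n_unavailable: int  # couples without a usable record
    percent: float | None

    def __str__(self) -> str:
        pct = "NA" if self.percent is None else f"{self.percent}%"
        return f"{self.k}/{self.n} ({pct})"


def couple_history_fraction(
    couples: Sequence[CarrierCouple],
    records: Mapping[str, MotherRecord] | Sequence[MotherRecord],
) -> HistoryFraction:
    """Fraction of carrier-couple mothers with any miscarriage history.

    Couples whose mother has no record (or an undetermined history) are
    tallied separately as unavailable, mirroring follow-up studies where
    records can be retrieved for only part of the couples.
    """
    if not isinstance(records, Mapping):
        records = {r.mother_id: r for r in records}
    k = n = unavailable = 0
    for c in couples:
        rec = records.get(c.mother_id)
        has = rec.has_history if rec is not None else None
        if has is None:
            unavailable += 1
            continue
        n += 1
        k += int(has)
    pct = percent_1dp(100.0 * k / n) if n else None
    return HistoryFraction(k=k, n=n, n_unavailable=unavailable, percent=pct)
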