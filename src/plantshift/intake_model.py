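"""Habitual-intake estimation, adjusted EAR, and prevalence of inadequacy.

Two 24-h recalls per person mix the between-person variation of interest
with day-to-day noise.  Two estimators of each person's habitual (long-run
average) intake are provided:

* ``two_day_mean`` — the mean of the available recall days; simple, but its
  population spread is inflated by within-person variance / n_days;
* ``shrinkage`` — a one-part lognormal variance-components model: daily
  intakes are log-transformed, between- and within-person variances are
  estimated by moments, each person's mean is shrunk toward the stratum mean
  by the best-linear factor between / (between + within / n_days), and the
  result is back-transformed.  With zero within-person variance it reduces
  to the two-day mean.

The protein EAR of 0.66 g of high-quality protein per kg body weight per day
ignores digestibility and amino-acid composition, so it is lowered by the
population-median relative loss between total and utilizable protein in the
unmodified diet before prevalence of inadequate intake is assessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from plantshift.errors import EstimationError, ValidationError

logger = logging.getLogger(__name__)

#: Protein EAR for adults, g high-quality protein per kg body weight per day.
STANDARD_EAR = 0.66

#: Offset added before log-transforming daily intakes (g or g/kg scale);
#: guards the occasional zero-intake day.
LOG_OFFSET = 0.01

DEFAULT_PERCENTILES = (25.0, 50.0, 75.0)


def weighted_percentile(
    values: Sequence[float] | np.ndarray,
    q: float | Sequence[float],
    weights: Sequence[float] | np.ndarray | None = None,
) -> float | np.ndarray:
    """Percentile(s) of `values` under survey weights.

    Inverse of the weighted empirical CDF with linear interpolation between
    adjacent order statistics: sorted value k sits at cumulative position
    (cumw_k - w_k) / (W - w_k), which with all-equal weights reduces exactly
    to the (k-1)/(n-1) positions of the default (linear) numpy percentile.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EstimationError("percentile of an empty set")
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != values.shape:
        raise ValidationError("weights and values must have the same length")
    if (weights < 0).any():
        raise ValidationError("negative survey weight")
    if weights.sum() == 0:
        raise EstimationError("all survey weights are zero")

    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w)
    total = cw[-1]
    denom = total - w
    with np.errstate(invalid="ignore", divide="ignore"):
        pos = np.where(denom > 0, (cw - w) / denom, 0.5)
    q_arr = np.atleast_1d(np.asarray(q, dtype=float)) / 100.0
    out = np.interp(q_arr, pos, v)
    return float(out[0]) if np.isscalar(q) else out


@dataclass
class HabitualDistribution:
    """Per-person habitual intake estimates for one stratum (sex x scenario)."""

    stratum: str
    method: str
    estimates: pd.DataFrame  # participant_id, habitual, survey_weight
    percentiles: dict[float, float]

    def percentile(self, q: float) -> float:
        return weighted_percentile(
            self.estimates["habitual"].to_numpy(),
            q,
            self.estimates["survey_weight"].to_numpy(),
        )


@dataclass
class EarResult:
    """Quality-adjusted estimated average requirement."""

    standard_ear: float
    median_relative_loss: float
    adjusted_ear: float
    prevalence_below: dict[str, float] = field(default_factory=dict)


def _person_day_table(daily: pd.DataFrame, value_col: str) -> pd.DataFrame:
    required = {"participant_id", value_col}
    missing = required - set(daily.columns)
    if missing:
        raise ValidationError(f"daily table missing column(s) {sorted(missing)}")
    return daily


def habitual_distribution(
    daily: pd.DataFrame,
    value_col: str,
    method: str = "shrinkage",
    stratum: str = "all",
    weight_col: str = "survey_weight",
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
) -> HabitualDistribution:
    """Estimate per-person habitual intakes and their weighted percentiles.

    `daily` holds one row per participant-day with the intake in `value_col`
    and the survey weight in `weight_col` (constant within participant).
    """
    if method not in ("two_day_mean", "shrinkage"):
        raise ValidationError(f"unknown habitual-intake method {method!r}")
    daily = _person_day_table(daily, value_col)
    if weight_col not in daily.columns:
        daily = daily.assign(**{weight_col: 1.0})

    grouped = daily.groupby("participant_id", sort=True)
    n_participants = grouped.ngroups
    if n_participants < 2:
        raise EstimationError(
            f"stratum {stratum!r} has {n_participants} participant(s); need >= 2"
        )

    per_person = grouped.agg(
        n_days=(value_col, "size"),
        raw_mean=(value_col, "mean"),
        survey_weight=(weight_col, "first"),
    )

    if method == "two_day_mean":
        habitual = per_person["raw_mean"].to_numpy()
    else:
        logs = np.log(daily[value_col].to_numpy(dtype=float) + LOG_OFFSET)
        ldf = pd.DataFrame(
            {"participant_id": daily["participant_id"].to_numpy(), "log": logs}
        )
        lg = ldf.groupby("participant_id", sort=True)["log"]
        m_i = lg.mean().to_numpy()
        n_i = lg.size().to_numpy()
        # pooled within-person variance from participants with repeat days
        sq = lg.var(ddof=1).to_numpy()
        repeat = (n_i > 1) & ~np.isnan(sq)
        if repeat.any():
            within = float(np.average(sq[repeat], weights=(n_i[repeat] - 1)))
        else:
            within = 0.0
        grand = float(np.average(m_i, weights=per_person["survey_weight"].to_numpy()))
        var_means = float(np.var(m_i, ddof=1))
        between = max(0.0, var_means - within * float(np.mean(1.0 / n_i)))
        if between + within == 0.0:
            lam = np.ones_like(m_i)
        else:
            lam = between / (between + within / n_i)
        habitual = np.exp(grand + lam * (m_i - grand)) - LOG_OFFSET
        habitual = np.clip(habitual, 0.0, None)

    estimates = pd.DataFrame(
        {
            "participant_id": per_person.index,
            "habitual": habitual,
            "survey_weight": per_person["survey_weight"].to_numpy(),
        }
    ).reset_index(drop=True)
    pct = {
        float(p): float(
            weighted_percentile(habitual, p, estimates["survey_weight"].to_numpy())
        )
        for p in percentiles
    }
    return HabitualDistribution(
        stratum=stratum, method=method, estimates=estimates, percentiles=pct
    )


def adjusted_ear(
    original_diet_daily: pd.DataFrame,
    method: str = "two_day_mean",
    weighted: bool = True,
    standard_ear: float = STANDARD_EAR,
) -> EarResult:
    """Derive the quality-adjusted EAR from the unmodified diet.

    Each participant's relative loss is 1 - utilizable/total habitual protein;
    the (survey-weighted) population median loss is subtracted multiplicatively
    from the 0.66 g/kg bw/day standard EAR and the result rounded to two
    decimals, matching how the requirement is quoted and used.
    """
    needed = {"participant_id", "total_protein_g", "utilizable_protein_g"}
    missing = needed - set(original_diet_daily.columns)
    if missing:
        raise ValidationError(f"daily table missing column(s) {sorted(missing)}")
    tot = habitual_distribution(
        original_diet_daily, "total_protein_g", method=method, stratum="ear"
    ).estimates.rename(columns={"habitual": "total"})
    uti = habitual_distribution(
        original_diet_daily, "utilizable_protein_g", method=method, stratum="ear"
    ).estimates.rename(columns={"habitual": "utilizable"})
    merged = tot.merge(uti[["participant_id", "utilizable"]], on="participant_id")

    zero = merged["total"] <= 0
    if zero.any():
        logger.warning(
            "excluding %d participant(s) with zero habitual total protein "
            "from the EAR loss computation", int(zero.sum()),
        )
        merged = merged[~zero]
    if merged.empty:
        raise EstimationError("no participants with positive habitual total protein")

    loss = 1.0 - merged["utilizable"].to_numpy() / merged["total"].to_numpy()
    w = merged["survey_weight"].to_numpy() if weighted else None
    median_loss = float(weighted_percentile(loss, 50.0, w))
    return EarResult(
        standard_ear=standard_ear,
        median_relative_loss=median_loss,
        adjusted_ear=round(standard_ear * (1.0 - median_loss), 2),
        prevalence_below={},
    )


def prevalence_below_ear(dist: HabitualDistribution, ear: float) -> float:
    """Survey-weighted fraction of habitual intakes strictly below `ear`."""
    est = dist.estimates
    if est.empty:
        raise EstimationError(f"stratum {dist.stratum!r} is empty")
    w = est["survey_weight"].to_numpy(dtype=float)
    if w.sum() == 0:
        raise EstimationError(f"stratum {dist.stratum!r} has zero total weight")
    below = (est["habitual"].to_numpy() < ear).astype(float)
    return float(np.average(below, weights=w))
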