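"""Correlating the vibrational mode amplitude with visual frame condition.

At each visual inspection the fractions of the central frame covered by
brood, honey and pollen are estimated on both sides (they agree closely, so
sides are averaged), and the nightly mode amplitude nearest the inspection
date is regressed on the three percentages:

    mode_amp ~ alpha*brood% + beta*pollen% + delta*honey% + intercept

an identity-link Gaussian linear model, fitted per colony or generically
over a pooled apiary.  Comb loads damp the measured vibration, so on data
where attenuation dominates all three coefficients come out negative, with
effect sizes ordered like the attenuation constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .distributions import ModeSeries

logger = logging.getLogger(__name__)

QUANTITIES = ("brood", "pollen", "honey")  # (alpha, beta, delta) order
#: Maximum distance between an inspection date and the night used for it.
MATCH_WINDOW_DAYS = 2


@dataclass
class LinearCombinationFit:
    """OLS fit of mode amplitude on frame-condition percentages."""

    colony_id: str  # "generic" for a pooled fit
    alpha: float  # m/s^2 per % brood
    beta: float  # m/s^2 per % pollen
    delta: float  # m/s^2 per % honey
    intercept: float
    r: float  # Pearson correlation of fitted vs observed (NaN if undefined)
    n: int
    dropped: list[str] = field(default_factory=list)

    @property
    def coefficients(self) -> dict[str, float]:
        return {"brood": self.alpha, "pollen": self.beta, "honey": self.delta}


def average_sides(records: pd.DataFrame) -> pd.DataFrame:
    """Side-averaged frame condition per colony and date.

    ``records`` has one row per (colony_id, date, side) with columns
    ``brood_pct``, ``pollen_pct``, ``honey_pct``.  When one side is missing
    the present side is used and the row is flagged (``one_sided``).
    """
    cols = [f"{q}_pct" for q in QUANTITIES]
    grouped = records.groupby(["colony_id", "date"], sort=True)
    out = grouped[cols].mean().reset_index()
    out["one_sided"] = (grouped.size() < 2).to_numpy()
    for _, row in out[out["one_sided"]].iterrows():
        logger.warning("only one side recorded for %s at %s", row["colony_id"], row["date"])
    return out


def match_inspections(
    series: ModeSeries,
    inspections: pd.DataFrame,
    window_days: int = MATCH_WINDOW_DAYS,
) -> pd.DataFrame:
    """Attach to each inspection the mode amplitude of the nearest night.

    The night histogram of the night closest to the inspection date (within
    +-``window_days``, NaN nights skipped) supplies ``mode_amp``;
    inspections with no usable night are dropped with a log message.
    """
    rows = []
    dates = np.array([d.toordinal() for d in series.dates])
    for _, rec in inspections.iterrows():
        d = rec["date"]
        target = d.toordinal() if isinstance(d, date) else pd.Timestamp(d).toordinal()
        dist = np.abs(dates - target)
        dist = np.where(np.isnan(series.mode_amps), np.inf, dist)
        j = int(np.argmin(dist))
        if dist[j] > window_days:
            logger.warning("no night within %d d of inspection %s; dropped", window_days, d)
            continue
        row = rec.to_dict()
        row["mode_amp"] = float(series.mode_amps[j])
        row["matched_night"] = series.dates[j]
        rows.append(row)
    return pd.DataFrame(rows)


def fit_linear_combination(
    matched: pd.DataFrame, mode: str = "per_colony"
) -> dict[str, LinearCombinationFit] | LinearCombinationFit:
    """Fit mode_amp on (brood%, pollen%, honey%) with an intercept.

    ``mode="per_colony"`` returns one fit per colony; ``mode="generic"``
    pools every matched point into a single coefficient set.  Constant
    (rank-deficient) predictor columns are dropped from the design, reported
    in ``fit.dropped``, and given a zero coefficient.
    """
    if mode == "per_colony":
        return {
            cid: _fit_one(g, cid)
            for cid, g in matched.groupby("colony_id", sort=True)
        }
    if mode == "generic":
        return _fit_one(matched, "generic")
    raise ValueError(f"mode must be 'per_colony' or 'generic', got {mode!r}")


def _fit_one(df: pd.DataFrame, colony_id: str) -> LinearCombinationFit:
    n = len(df)
    if n < 4:
        raise ValueError(
            f"{colony_id}: {n} matched points; at least 4 needed for a 3-coefficient fit"
        )
    y = df["mode_amp"].to_numpy(dtype=float)
    coefs = {q: 0.0 for q in QUANTITIES}
    dropped = [q for q in QUANTITIES if np.ptp(df[f"{q}_pct"].to_numpy(dtype=float)) == 0]
    kept = [q for q in QUANTITIES if q not in dropped]
    if dropped:
        logger.info("%s: dropped constant predictor(s) %s", colony_id, dropped)
    if np.ptp(y) == 0:
        # constant response: all coefficients zero, correlation undefined
        return LinearCombinationFit(
            colony_id=colony_id,
            alpha=0.0, beta=0.0, delta=0.0,
            intercept=float(y[0]), r=float("nan"), n=n, dropped=dropped,
        )
    X = sm.add_constant(df[[f"{q}_pct" for q in kept]].to_numpy(dtype=float))
    res = sm.OLS(y, X).fit()
    for q, c in zip(kept, res.params[1:]):
        coefs[q] = float(c)
    fitted = res.fittedvalues
    r = float(np.corrcoef(fitted, y)[0, 1]) if np.ptp(fitted) > 0 else float("nan")
    return LinearCombinationFit(
        colony_id=colony_id,
        alpha=coefs["brood"],
        beta=coefs["pollen"],
        delta=coefs["honey"],
        intercept=float(res.params[0]),
        r=r,
        n=n,
        dropped=dropped,
    )


def rank_contributions(
    fit: LinearCombinationFit, matched: pd.DataFrame
) -> list[tuple[str, float]]:
    """Rank brood/pollen/honey by |coefficient x observed range|, descending.

    The product of a coefficient with the range its predictor actually spans
    is the damping contribution of that comb content over the data at hand;
    ties are broken alphabetically for determinism.
    """
    effects = {}
    for q in QUANTITIES:
        rng = float(np.ptp(matched[f"{q}_pct"].to_numpy(dtype=float)))
        effects[q] = abs(fit.coefficients[q] * rng)
    return sorted(effects.items(), key=lambda kv: (-kv[1], kv[0]))
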