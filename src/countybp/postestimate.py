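"""Post-estimation: standardisation, pooling, and county summaries.

Cell-level posterior draws (age-group x race x county x year) become
race-county-year draws by a convex combination over age groups against a
fixed standard population, then county-year draws by weighting races with
county race-population shares. Both operations are per-draw convex
combinations, so they commute and preserve the (0, 1) range.

Uncertainty from both stages is combined by pooling posterior draws across
the imputed datasets (each imputation contributes its own stage-2 fit);
medians and equal-tailed 95% intervals are read off the pooled draws. A
moment-based multiple-imputation combination (within/between variance
decomposition on the probability scale) is provided as a cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class StandardPopulation:
    """Fixed age-group weights used for direct age standardisation."""

    weights: dict[str, float]

    def __post_init__(self):
        vals = np.asarray(list(self.weights.values()), float)
        if np.any(vals < 0):
            raise ValueError("standard-population weights must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"standard-population weights must sum to 1 (got {vals.sum():.12f})"
            )


def age_standardize(
    draws_by_age: dict[str, np.ndarray], std: StandardPopulation
) -> np.ndarray:
    """Weighted sum of age-group draw arrays against the standard population."""
    if set(draws_by_age) != set(std.weights):
        raise ValueError(
            f"age groups {sorted(draws_by_age)} do not match standard "
            f"population {sorted(std.weights)}"
        )
    keys = list(draws_by_age)
    out = np.zeros_like(np.asarray(draws_by_age[keys[0]], float))
    for k in keys:
        out = out + std.weights[k] * np.asarray(draws_by_age[k], float)
    return out


def race_weight(
    draws_by_race: dict[str, np.ndarray], shares: dict[str, float]
) -> np.ndarray:
    """Convex combination of race-specific draws with county race shares."""
    missing = set(draws_by_race) - set(shares)
    if missing:
        raise ValueError(f"missing race share(s): {sorted(missing)}")
    vals = np.asarray([shares[r] for r in draws_by_race], float)
    if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-6:
        raise ValueError("race shares must be nonnegative and sum to 1")
    keys = list(draws_by_race)
    out = np.zeros_like(np.asarray(draws_by_race[keys[0]], float))
    for r in keys:
        out = out + shares[r] * np.asarray(draws_by_race[r], float)
    return out


def pool_imputations(per_imputation_draws: list[np.ndarray]) -> np.ndarray:
    """Concatenate per-imputation posterior draw arrays along the draw axis.

    Draw pooling is the nested-imputation combination on the draw scale:
    the pooled empirical distribution carries both within-fit posterior
    spread and between-imputation spread.
    """
    if not per_imputation_draws:
        raise ValueError("need at least one imputation")
    shapes = {a.shape[1:] for a in per_imputation_draws}
    if len(shapes) != 1:
        raise ValueError(f"mismatched cell indexing across imputations: {shapes}")
    return np.concatenate([np.asarray(a, float) for a in per_imputation_draws], axis=0)


def rubin_pool(per_imputation_draws: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Moment-based combination: pooled mean and total variance per cell.

    Total variance = mean within-imputation variance + (1 + 1/M) x
    between-imputation variance of the means. Cross-check for the
    draw-pooling route, not the primary path.
    """
    M = len(per_imputation_draws)
    means = np.asarray([a.mean(axis=0) for a in per_imputation_draws])
    withins = np.asarray([a.var(axis=0, ddof=1) for a in per_imputation_draws])
    qbar = means.mean(axis=0)
    w = withins.mean(axis=0)
    b = means.var(axis=0, ddof=1) if M > 1 else np.zeros_like(qbar)
    return qbar, w + (1.0 + 1.0 / M) * b


def summarize_draws(
    draws: np.ndarray, meta: pd.DataFrame, outcome: str
) -> pd.DataFrame:
    """Median and equal-tailed 95% interval per column of a draw array.

    ``meta`` gives one row per draw column (county_id, year, sex, optional
    race); the result is the tidy county-estimate table.
    """
    if draws.shape[1] != len(meta):
        raise ValueError("draws and metadata disagree on the number of cells")
    q = np.percentile(draws, [2.5, 50.0, 97.5], axis=0)
    out = meta.copy().reset_index(drop=True)
    out["outcome"] = outcome
    out["point"] = q[1]
    out["lower"] = q[0]
    out["upper"] = q[2]
    return out


def summarize_counties(
    estimates: pd.DataFrame, by: list[str] = ("sex", "year")
) -> pd.DataFrame:
    """County-level median and min-max range per group, in percent (2 dp).

    Mirrors the layout of published county summary tables: one row per
    (outcome, group), columns median / range_low / range_high.
    """
    by = [c for c in by if c in estimates.columns]
    rows = []
    for keys, grp in estimates.groupby(["outcome", *by], observed=True):
        if grp.empty:
            logger.warning("empty group %s omitted from summary", keys)
            continue
        pts = grp["point"].to_numpy(float) * 100.0
        rec = dict(zip(["outcome", *by], keys if isinstance(keys, tuple) else (keys,)))
        rec.update(
            median=round(float(np.median(pts)), 2),
            range_low=round(float(pts.min()), 2),
            range_high=round(float(pts.max()), 2),
            n_counties=len(grp),
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def within_state_spread(
    estimates: pd.DataFrame, state_map: dict[int, int] | pd.Series
) -> pd.DataFrame:
    """Per-state max minus min of county point estimates, percentage points."""
    est = estimates.copy()
    state_map = dict(state_map) if not isinstance(state_map, dict) else state_map
    unmapped = set(est["county_id"]) - set(state_map)
    if unmapped:
        raise ValueError(f"counties without a state: {sorted(unmapped)[:5]}")
    est["state_id"] = est["county_id"].map(state_map)
    rows = []
    group_cols = [c for c in ("outcome", "sex", "year") if c in est.columns]
    for keys, grp in est.groupby(["state_id", *group_cols], observed=True):
        pts = grp["point"].to_numpy(float) * 100.0
        rec = dict(zip(["state_id", *group_cols], keys))
        rec["spread"] = round(float(pts.max() - pts.min()), 2)
        rec["single_county"] = len(grp) == 1
        rows.append(rec)
    return pd.DataFrame(rows)


# --- derived indicators from summary medians --------------------------------
# Arithmetic identities among published-style summary medians: the gap
# between bias-corrected total and self-reported prevalence, the share of
# the hypertensive population aware but untreated, and the share of treated
# individuals whose BP is controlled.


def selfreport_gap(total_prevalence: float, self_report: float) -> float:
    """Total-minus-self-reported prevalence, percentage points."""
    return round(total_prevalence - self_report, 2)


def aware_untreated_share(awareness: float, treatment: float) -> float:
    """Aware-but-untreated share of the hypertensive population (points)."""
    if treatment > awareness:
        raise ValueError("treatment cannot exceed awareness in nested outcomes")
    return round(awareness - treatment, 2)


def aware_untreated_decline(
    awareness_start: float, treatment_start: float,
    awareness_end: float, treatment_end: float,
) -> float:
    """Decline in the aware-but-untreated share between two years (points)."""
    return round(
        aware_untreated_share(awareness_start, treatment_start)
        - aware_untreated_share(awareness_end, treatment_end),
        2,
    )


def controlled_among_treated(control: float, treatment: float) -> float:
    """Share of treated individuals who are controlled, in percent."""
    if treatment <= 0:
        raise ValueError("treatment share must be positive")
    return round(100.0 * control / treatment, 1)
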