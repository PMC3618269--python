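"""Second-stage validation against a pooled direct gold standard.

Single-year county direct estimates are too noisy to judge a small-area
model against, so the reference is a multi-year pooled, design-weighted
direct estimate per county. Model predictions (and, as a baseline,
single-year direct estimates) are compared with this gold standard by root
mean squared error and Lin's concordance correlation coefficient, overall
and stratified by per-year county sample size — the stratification exposes
how the model behaves in sparsely sampled counties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DirectEstimate:
    county_id: int
    n: float
    proportion: float


@dataclass
class ValidationReport:
    bin_label: str
    n_counties: int
    model_ccc: float
    model_rmse: float
    direct_ccc: float
    direct_rmse: float
    flagged_small: bool = False


def weighted_proportion(values: np.ndarray, weights: np.ndarray) -> float:
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    if weights.sum() <= 0:
        raise ValueError("nonpositive total weight")
    return float(np.sum(values * weights) / np.sum(weights))


def pooled_gold_standard(
    records: pd.DataFrame,
    value_col: str,
    window: tuple[int, int],
    min_n: int = 50,
) -> pd.DataFrame:
    """Design-weighted county proportions pooled over a window of years.

    Counties whose pooled sample size falls below ``min_n`` are excluded
    (and logged); the returned table has county_id, n, proportion.
    """
    lo, hi = window
    if hi < lo:
        raise ValueError("empty pooling window")
    sub = records.loc[(records["year"] >= lo) & (records["year"] <= hi)]
    if sub.empty:
        raise ValueError("no records fall inside the pooling window")
    rows = []
    excluded = 0
    for cid, grp in sub.groupby("county_id", observed=True):
        n = len(grp)
        if n < min_n:
            excluded += 1
            continue
        w = grp["weight"].to_numpy(float) if "weight" in grp else np.ones(n)
        rows.append(
            {
                "county_id": cid,
                "n": n,
                "proportion": weighted_proportion(grp[value_col].to_numpy(float), w),
            }
        )
    if not rows:
        raise ValueError("no county reaches the min_n gold-standard threshold")
    if excluded:
        logger.info("gold standard excludes %d counties below min_n", excluded)
    return pd.DataFrame(rows)


def single_year_direct(
    records: pd.DataFrame, value_col: str, year: int
) -> pd.DataFrame:
    """Design-weighted single-year county proportions (the naive baseline)."""
    sub = records.loc[records["year"] == year]
    rows = []
    for cid, grp in sub.groupby("county_id", observed=True):
        w = grp["weight"].to_numpy(float) if "weight" in grp else np.ones(len(grp))
        rows.append(
            {
                "county_id": cid,
                "n": len(grp),
                "proportion": weighted_proportion(grp[value_col].to_numpy(float), w),
            }
        )
    return pd.DataFrame(rows)


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    """Root mean squared difference."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("rmse needs two equal-length nonempty vectors")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def concordance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments).

    ccc = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2), with 1/n moments;
    equals 1 only for perfect identity and penalises both dispersion and
    location shifts.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("ccc needs two equal-length vectors of length >= 2")
    sx = float(np.var(x))
    sy = float(np.var(y))
    loc = float((x.mean() - y.mean()) ** 2)
    denom = sx + sy + loc
    if denom == 0.0:
        raise ValueError("ccc undefined: both vectors constant and equal")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    return 2.0 * sxy / denom


def validate_by_sample_size(
    model: pd.DataFrame,
    gold: pd.DataFrame,
    direct: pd.DataFrame,
    bins: list[tuple[float, float]],
    per_year_n: pd.Series | dict | None = None,
) -> list[ValidationReport]:
    """CCC and RMSE by county-sample-size bin, model vs. direct baseline.

    ``model`` and ``direct`` carry county_id + proportion; ``gold`` is the
    pooled gold standard. ``per_year_n`` maps county to its per-year sample
    size for binning (defaults to the direct baseline's n). Bins are
    half-open intervals (lo, hi] and must not overlap.
    """
    edges = sorted(bins)
    for (a, b), (c, d) in zip(edges[:-1], edges[1:]):
        if b > c:
            raise ValueError(f"overlapping bins: ({a},{b}] and ({c},{d}]")
    merged = gold.merge(
        model.rename(columns={"proportion": "p_model"})[["county_id", "p_model"]],
        on="county_id",
    ).merge(
        direct.rename(columns={"proportion": "p_direct", "n": "n_direct"})[
            ["county_id", "p_direct", "n_direct"]
        ],
        on="county_id",
    )
    if per_year_n is None:
        merged["bin_n"] = merged["n_direct"]
    else:
        merged["bin_n"] = merged["county_id"].map(dict(per_year_n))

    reports = []
    for lo, hi in bins:
        sub = merged.loc[(merged["bin_n"] > lo) & (merged["bin_n"] <= hi)]
        label = f"({lo:g},{'inf' if np.isinf(hi) else f'{hi:g}'}]"
        if len(sub) < 2:
            logger.warning("bin %s has %d counties; skipped", label, len(sub))
            continue
        reports.append(
            ValidationReport(
                bin_label=label,
                n_counties=len(sub),
                model_ccc=concordance_correlation(sub["p_model"], sub["proportion"]),
                model_rmse=rmse(sub["p_model"], sub["proportion"]),
                direct_ccc=concordance_correlation(sub["p_direct"], sub["proportion"]),
                direct_rmse=rmse(sub["p_direct"], sub["proportion"]),
                flagged_small=len(sub) < 3,
            )
        )
    return reports


def reports_to_frame(reports: list[ValidationReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])


def summary_text(reports: list[ValidationReport], title: str = "validation") -> str:
    """Plain-text table: CCC (%) and RMSE (%) by sample-size bin,
    model against the pooled gold standard vs. the single-year baseline."""
    lines = [
        title,
        f"{'bin':>12} {'n':>5} {'model CCC%':>11} {'model RMSE%':>12} "
        f"{'direct CCC%':>12} {'direct RMSE%':>13}",
    ]
    for r in reports:
        flag = " *" if r.flagged_small else ""
        lines.append(
            f"{r.bin_label:>12} {r.n_counties:>5} {100 * r.model_ccc:>11.1f} "
            f"{100 * r.model_rmse:>12.2f} {100 * r.direct_ccc:>12.1f} "
            f"{100 * r.direct_rmse:>13.2f}{flag}"
        )
    if any(r.flagged_small for r in reports):
        lines.append("* bin holds fewer than 3 counties")
    return "\n".join(lines)
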