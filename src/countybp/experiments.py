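"""Repeatable simulation experiments probing the pipeline's key claims.

These are the package's benchmark runs: stage-1 coefficient recovery and
holdout accuracy, imputation calibration against the latent truth, and the
small-county shrinkage comparison of model predictions versus single-year
direct estimates. Tests and the reproduction script both call these
functions, so the numbers they report are always produced by the same code
path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bias import default_spec_set, fit_bias_models, holdout_accuracy, impute_uncontrolled
from .smallarea import SmallAreaSpec, fit_small_area, predict_cells
from .synthetic import WorldConfig, generate_world, sample_exam_survey, sample_phone_survey
from .validation import concordance_correlation, rmse


def _child_seeds(seed: int, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def _stratified_exam(world, n_per_stratum: int, seed: int) -> pd.DataFrame:
    """Examination sample with exactly n individuals per sex x diagnosis
    stratum (oversample, then truncate each stratum)."""
    # diagnosed strata are the rarest (~35%); oversample enough to fill them
    df = sample_exam_survey(world, int(n_per_stratum * 7), seed=seed)
    parts = []
    for sex in ("male", "female"):
        for diag in (0, 1):
            sub = df.loc[(df["sex"] == sex) & (df["diagnosed"] == diag)]
            if len(sub) < n_per_stratum:
                raise RuntimeError("oversampling factor too small")
            parts.append(sub.head(n_per_stratum))
    return pd.concat(parts, ignore_index=True)


def stage1_coverage(
    seed: int = 0, n_replicates: int = 150, n_per_stratum: int = 20_000
) -> dict:
    """95% CI coverage of every stage-1 truth coefficient over replicates.

    Each replicate draws a fresh examination sample with ``n_per_stratum``
    individuals in each sex x diagnosis stratum, refits the four models, and
    checks each Wald interval against the generating truth. Returns per-term
    coverage and the worst (minimum) coverage.
    """
    cfg = WorldConfig(n_counties=4, n_states=1, years=(2001,), seed=seed)
    world = generate_world(cfg)
    spec_set = default_spec_set(cfg.waves)
    hits: dict[tuple, int] = {}
    totals: dict[tuple, int] = {}
    for rep_seed in _child_seeds(seed, n_replicates):
        exam = _stratified_exam(world, n_per_stratum, seed=rep_seed)
        fits = fit_bias_models(exam, spec_set)
        for stratum, fit in fits.items():
            truth = cfg.truth_coefficients[stratum]
            se = np.sqrt(np.diag(fit.covariance))
            for i, term in enumerate(fit.spec.terms):
                key = (stratum, term)
                covered = abs(fit.coefficients[i] - truth.get(term, 0.0)) < 1.96 * se[i]
                hits[key] = hits.get(key, 0) + int(covered)
                totals[key] = totals.get(key, 0) + 1
    coverage = {k: hits[k] / totals[k] for k in hits}
    return {
        "coverage": coverage,
        "min_coverage": min(coverage.values()),
        "mean_coverage": float(np.mean(list(coverage.values()))),
        "n_replicates": n_replicates,
    }


def deterministic_rule_accuracy(seed: int = 0, n: int = 6000, k: int = 10) -> float:
    """Holdout accuracy when the outcome is a deterministic age threshold.

    The rule SBP >= 140 iff age >= 55 is separable in the age term. Ages are
    integer years (as surveys record them), so the decision boundary sits in
    a data-free gap and every replicate classifies the holdout perfectly
    (accuracy exactly 1).
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "age": rng.integers(30, 86, n).astype(float),
            "sex": rng.choice(["male", "female"], n),
            "race": rng.choice(["white", "black", "hispanic", "other"], n),
            "bmi": rng.normal(28, 5, n),
            "insured": rng.integers(0, 2, n),
            "diagnosed": rng.integers(0, 2, n),
            "weight": np.ones(n),
            "wave": rng.choice(["w1", "w2"], n),
        }
    )
    df["medicated"] = ((rng.random(n) < 0.6) & (df["diagnosed"] == 1)).astype(int)
    df["sbp"] = np.where(df["age"] >= 55.0, 150.0, 120.0)
    # The fitted model carries exactly the rule's terms (intercept + linear
    # age). Extra covariates would leave the separating direction non-unique
    # and let rare covariate patterns wobble the boundary, which would test
    # separation robustness rather than the holdout machinery.
    from .bias import BiasModelSpec

    spec_set = [
        BiasModelSpec((sex, diag), ["1", "age_c"], ("w1", "w2"))
        for sex in ("male", "female")
        for diag in (False, True)
    ]
    rep = holdout_accuracy(df, spec_set, k=k, seed=seed)
    return rep.overall


def imputation_calibration(
    seed: int = 0, n_exam: int = 20_000, n_per_county_year: int = 100, M: int = 10
) -> dict:
    """Imputed prevalence vs. latent truth, per stratum, in binomial SEs.

    Fits stage 1 on a fresh examination sample, imputes the telephone
    survey M times, and measures |mean imputed - latent truth| relative to
    the truth's binomial standard error within each sex x diagnosis stratum.
    """
    s_world, s_exam, s_phone, s_imp = _child_seeds(seed, 4)
    cfg = WorldConfig(n_counties=16, n_states=4, years=(2001, 2005, 2009), seed=s_world)
    world = generate_world(cfg)
    exam = sample_exam_survey(world, n_exam, seed=s_exam)
    fits = fit_bias_models(exam, default_spec_set(cfg.waves))
    sample = sample_phone_survey(world, n_per_county_year, seed=s_phone)
    sets = impute_uncontrolled(sample.records, fits, M=M, seed=s_imp)
    imputed = np.mean([d.records["uncontrolled"].to_numpy() for d in sets], axis=0)
    truth = sample.latent["uncontrolled"].to_numpy()
    out = {}
    for stratum in fits:
        sex, diag = stratum
        mask = (
            (sample.records["sex"] == sex)
            & (sample.records["diagnosed"] == int(diag))
        ).to_numpy()
        n = int(mask.sum())
        p = float(truth[mask].mean())
        se = float(np.sqrt(p * (1 - p) / n))
        out[stratum] = {
            "truth": p,
            "imputed": float(imputed[mask].mean()),
            "se_units": abs(float(imputed[mask].mean()) - p) / se,
        }
    return {
        "per_stratum": out,
        "max_se_units": max(v["se_units"] for v in out.values()),
        "M": M,
    }


@dataclass
class ShrinkageResult:
    seed: int
    model_ccc: float
    model_rmse: float
    direct_ccc: float
    direct_rmse: float

    @property
    def model_wins(self) -> bool:
        return (
            self.model_ccc > self.direct_ccc and self.model_rmse < self.direct_rmse
        )


def shrinkage_experiment(
    seed: int,
    n_counties: int = 100,
    years: tuple[int, ...] = (2001, 2005, 2009),
    n_per_county_year: int = 10,
    mcmc: dict | None = None,
) -> ShrinkageResult:
    """Model vs. single-year direct estimates in sparsely sampled counties.

    A world with spatially structured county effects is sampled at only
    ``n_per_county_year`` telephone interviews per county-year. The direct
    estimate is the raw county-year share of the latent uncontrolled
    indicator; the model estimate is the posterior mean from the hierarchical
    fit on county-year cells of the same indicator. Both are scored against
    the population truth (the expected latent share, evaluated on a large
    independent reference sample from the same world) by concordance
    correlation and RMSE over all county-years.
    """
    s_world, s_phone, s_ref, s_fit = _child_seeds(seed, 4)
    cfg = WorldConfig(n_counties=n_counties, n_states=5, years=years, seed=s_world)
    world = generate_world(cfg)

    sparse = sample_phone_survey(world, n_per_county_year, seed=s_phone)
    obs = sparse.latent
    direct = (
        obs.groupby(["county_id", "year"], observed=True)["uncontrolled"]
        .mean()
        .rename("direct")
    )

    ref = sample_phone_survey(world, 300, seed=s_ref)
    truth = (
        ref.latent.groupby(["county_id", "year"], observed=True)["p_true"]
        .mean()
        .rename("truth")
    )

    cells = (
        obs.groupby(["county_id", "year"], observed=True)
        .agg(trials=("uncontrolled", "size"), events=("uncontrolled", "sum"))
        .reset_index()
    )
    cells["sex"] = "all"
    cells["age_group"] = "30+"
    cells["race"] = "white"
    spec = SmallAreaSpec(
        county_covariates=(),
        include_spatial=True,
        include_iid=True,
        include_time=True,
        include_slopes=False,
        chains=2,
        warmup=350,
        draws=350,
        seed=s_fit,
        **(mcmc or {}),
    )
    fit = fit_small_area(cells, world.county_table, world.adjacency, spec)
    probs = predict_cells(fit, cells)
    model = pd.Series(
        probs.mean(axis=0), index=pd.MultiIndex.from_frame(cells[["county_id", "year"]])
    ).rename("model")

    joined = pd.concat([truth, direct, model], axis=1).dropna()
    return ShrinkageResult(
        seed=seed,
        model_ccc=concordance_correlation(joined["model"], joined["truth"]),
        model_rmse=rmse(joined["model"], joined["truth"]),
        direct_ccc=concordance_correlation(joined["direct"], joined["truth"]),
        direct_rmse=rmse(joined["direct"], joined["truth"]),
    )


def shrinkage_over_seeds(seed: int = 0, n_seeds: int = 10, **kwargs) -> dict:
    """Run the shrinkage comparison across seeds; count model wins."""
    results = [
        shrinkage_experiment(s, **kwargs) for s in _child_seeds(seed, n_seeds)
    ]
    return {
        "results": results,
        "wins": sum(r.model_wins for r in results),
        "n_seeds": n_seeds,
        "median_model_ccc": float(np.median([r.model_ccc for r in results])),
        "median_direct_ccc": float(np.median([r.direct_ccc for r in results])),
        "median_model_rmse": float(np.median([r.model_rmse for r in results])),
        "median_direct_rmse": float(np.median([r.direct_rmse for r in results])),
    }
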