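"""Stage-1 fits, holdout validation, and posterior-predictive imputation."""

import numpy as np
import pandas as pd
import pytest

import countybp as cb
from countybp.bias import (
    BiasModelSpec,
    EmptyStratumError,
    SeparationError,
    UnseenLevelError,
    stratum_mask,
)
from countybp.design import UnknownTermError, build_design

STRATA = [("male", False), ("male", True), ("female", False), ("female", True)]


def _flat_exam(n, rng, p=0.5):
    """Exam-like frame with outcome independent of covariates at rate p."""
    df = pd.DataFrame(
        {
            "age": rng.uniform(30, 85, n),
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
    df["sbp"] = np.where(rng.random(n) < p, 150.0, 120.0)
    return df


def test_spec_set_structure():
    specs = cb.default_spec_set(("w1", "w2", "w3"))
    assert len(specs) == 4
    assert {s.stratum for s in specs} == set(STRATA)
    for s in specs:
        has_med = any(t.startswith("medicated") for t in s.terms)
        assert has_med == s.stratum[1]
    # medication terms rejected in never-diagnosed strata
    with pytest.raises(ValueError, match="diagnosed"):
        BiasModelSpec(("male", False), ["1", "medicated"], ("w1",))


def test_unknown_design_term_rejected():
    with pytest.raises(UnknownTermError):
        build_design(pd.DataFrame({"age": [40.0]}), ["1", "bogus"])


def test_equal_weights_match_unweighted_fit(rng):
    """With all design weights equal the weighted fit is the plain MLE."""
    import statsmodels.api as sm

    df = _flat_exam(4000, rng)
    df["sbp"] = np.where(
        rng.random(4000) < 1 / (1 + np.exp(-(-0.5 + 0.05 * (df["age"] - 55)))),
        150.0,
        120.0,
    )
    specs = cb.default_spec_set(("w1", "w2"))
    fits = cb.fit_bias_models(df, specs)
    for spec in specs:
        sub = df.loc[stratum_mask(df, spec.stratum)]
        X = build_design(sub, spec.terms)
        y = (sub["sbp"] >= 140).astype(float)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            fits[spec.stratum].coefficients, ref.params, atol=1e-6
        )


def test_zero_effect_ci_covers_zero(small_world):
    """Truth with no BMI effect: 95% CI for the BMI coefficient covers 0."""
    coefs = {s: {"1": -0.5, "age_c": 0.4} for s in STRATA}
    cfg = cb.WorldConfig(n_counties=4, n_states=2, seed=17, truth_coefficients=coefs)
    exam = cb.sample_exam_survey(cb.generate_world(cfg), 20_000, seed=18)
    fits = cb.fit_bias_models(exam, cb.default_spec_set(cfg.waves))
    for fit in fits.values():
        i = fit.spec.terms.index("bmi_c")
        se = np.sqrt(fit.covariance[i, i])
        assert abs(fit.coefficients[i]) < 1.96 * se


def test_age_coefficient_recovery():
    """Truth age slope 0.04/yr recovered within ±0.01/yr at n=50k."""
    coefs = {s: {"1": -0.6, "age_c": 0.4} for s in STRATA}  # 0.4 per decade
    cfg = cb.WorldConfig(n_counties=4, n_states=2, seed=23, truth_coefficients=coefs)
    exam = cb.sample_exam_survey(cb.generate_world(cfg), 50_000, seed=24)
    fits = cb.fit_bias_models(exam, cb.default_spec_set(cfg.waves))
    for fit in fits.values():
        i = fit.spec.terms.index("age_c")
        per_year = fit.coefficients[i] / 10.0
        assert abs(per_year - 0.04) < 0.01


def test_fit_covariance_is_psd(stage1_fits):
    for fit in stage1_fits.values():
        cov = fit.covariance
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() > -1e-10
        assert len(fit.coefficients) == len(fit.spec.terms)


def test_empty_and_sparse_strata_rejected(rng):
    df = _flat_exam(2000, rng)
    women = df.loc[df["sex"] == "female"].copy()
    with pytest.raises(EmptyStratumError):
        cb.fit_bias_models(women, cb.default_spec_set(("w1", "w2")))
    few = df.copy()
    few.loc[few["sex"] == "male", "sbp"] = 120.0  # <10 events in male strata
    with pytest.raises(EmptyStratumError):
        cb.fit_bias_models(few, cb.default_spec_set(("w1", "w2")))


def test_separation_error_names_term(rng):
    df = _flat_exam(2000, rng)
    df["sbp"] = np.where(df["insured"] == 1, 150.0, 120.0)  # separable on insured
    with pytest.raises(SeparationError, match="insured"):
        cb.fit_bias_models(df, cb.default_spec_set(("w1", "w2")))


def test_holdout_perfect_rule_gives_accuracy_one():
    """A deterministic threshold rule is classified perfectly in every split."""
    from countybp.experiments import deterministic_rule_accuracy

    assert deterministic_rule_accuracy(seed=0, n=4000, k=3) == 1.0


def test_holdout_coinflip_outcome_near_half(rng):
    """Outcome independent of covariates at p=0.5: accuracy ~ 0.5."""
    df = _flat_exam(30_000, rng, p=0.5)
    rep = cb.holdout_accuracy(df, cb.default_spec_set(("w1", "w2")), k=3, seed=1)
    assert abs(rep.overall - 0.5) < 0.02


def test_holdout_returns_k_replicates(small_world, exam_20k):
    rep = cb.holdout_accuracy(
        exam_20k, cb.default_spec_set(small_world.config.waves), k=10, seed=2
    )
    assert len(rep.replicates) == 10
    assert rep.replicate_range == (min(rep.replicates), max(rep.replicates))
    for acc in rep.per_stratum.values():
        assert 0.0 <= acc <= 1.0


def test_impute_degenerate_probabilities(stage1_fits, phone_sample):
    phone = phone_sample.records.head(500)
    forced = {}
    for stratum, fit in stage1_fits.items():
        coefs = np.zeros_like(fit.coefficients)
        coefs[fit.spec.terms.index("1")] = 30.0  # p = 1 for everyone
        forced[stratum] = cb.BiasModelFit(
            fit.spec, coefs, np.zeros_like(fit.covariance), fit.n_used
        )
    ones = cb.impute_uncontrolled(phone, forced, M=3, seed=0)
    assert all((d.records["uncontrolled"] == 1).all() for d in ones)
    for stratum in forced:
        forced[stratum].coefficients[forced[stratum].spec.terms.index("1")] = -30.0
    zeros = cb.impute_uncontrolled(phone, forced, M=3, seed=0)
    assert all((d.records["uncontrolled"] == 0).all() for d in zeros)


def test_impute_interceptonly_rate(stage1_fits, phone_sample):
    """Intercept-only fit at p=0.4: grand mean of flags in (0.38, 0.42)."""
    phone = phone_sample.records.head(10_000)
    b0 = float(np.log(0.4 / 0.6))
    forced = {}
    for stratum, fit in stage1_fits.items():
        coefs = np.zeros_like(fit.coefficients)
        coefs[fit.spec.terms.index("1")] = b0
        forced[stratum] = cb.BiasModelFit(
            fit.spec, coefs, np.zeros_like(fit.covariance), fit.n_used
        )
    sets = cb.impute_uncontrolled(phone, forced, M=10, seed=3)
    grand = np.mean([d.records["uncontrolled"].mean() for d in sets])
    assert 0.38 < grand < 0.42


def test_impute_unseen_race_level_rejected(stage1_fits, phone_sample):
    phone = phone_sample.records.head(50).copy()
    phone.loc[phone.index[0], "race"] = "martian"
    with pytest.raises(UnseenLevelError, match="martian"):
        cb.impute_uncontrolled(phone, stage1_fits, M=1, seed=0)


def test_impute_records_audit_trail(stage1_fits, phone_sample):
    sets = cb.impute_uncontrolled(phone_sample.records.head(200), stage1_fits, M=2, seed=5)
    assert [d.m for d in sets] == [1, 2]
    for d in sets:
        assert set(d.coefficient_draws) == set(stage1_fits)
        assert d.records["uncontrolled"].isin([0, 1]).all()
    # different imputations use different coefficient draws
    a = sets[0].coefficient_draws[("male", False)]
    b = sets[1].coefficient_draws[("male", False)]
    assert not np.allclose(a, b)


def test_imputation_calibrated_to_latent_truth(small_world, stage1_fits, phone_sample):
    """Mean imputed prevalence tracks the latent truth within 3 binomial SEs,
    per sex x diagnosis stratum."""
    phone = phone_sample.records
    truth = phone_sample.latent["uncontrolled"].to_numpy()
    sets = cb.impute_uncontrolled(phone, stage1_fits, M=10, seed=7)
    imputed = np.mean([d.records["uncontrolled"].to_numpy() for d in sets], axis=0)
    for stratum in stage1_fits:
        mask = stratum_mask(phone, stratum)
        n = int(mask.sum())
        p = truth[mask].mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(imputed[mask].mean() - p) < 3 * se, stratum
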