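"""Cell building and the spatio-temporal hierarchical model."""

import numpy as np
import pandas as pd
import pytest

import countybp as cb
from countybp.design import expit
from countybp.smallarea import ModelDataError, SmallAreaSpec, age_group_label


def _person(county=0, year=2001, sex="male", age=45.0, race="white",
            diagnosed=0, medicated=0, uncontrolled=1):
    return {
        "county_id": county, "year": year, "sex": sex, "age": age,
        "race": race, "diagnosed": diagnosed, "medicated": medicated,
        "uncontrolled": uncontrolled,
    }


class TestBuildCells:
    def test_single_individual_single_cell(self):
        cells = cb.build_cells(pd.DataFrame([_person()]), "prevalence")
        assert len(cells) == 1
        assert cells.loc[0, "trials"] == 1
        assert cells.loc[0, "events"] == 1
        assert cells.loc[0, "age_group"] == "40-50"

    def test_trials_conserved_across_counties(self, rng):
        people = [
            _person(county=int(rng.integers(0, 2)), age=float(rng.uniform(30, 85)))
            for _ in range(100)
        ]
        cells = cb.build_cells(pd.DataFrame(people), "prevalence")
        assert cells["trials"].sum() == 100

    def test_nesting_conserved_per_cell(self, phone_sample, stage1_fits):
        imp = cb.impute_uncontrolled(phone_sample.records, stage1_fits, M=1, seed=0)[0]
        keys = ["county_id", "year", "sex", "age_group", "race"]
        tabs = {
            o: cb.build_cells(imp.records, o).set_index(keys)
            for o in ("prevalence", "awareness", "treatment", "control")
        }
        joined = tabs["prevalence"].join(
            [tabs[o][["events"]].add_suffix(f"_{o}") for o in
             ("awareness", "treatment", "control")],
            how="left",
        ).fillna(0)
        assert (joined["events_control"] <= joined["events_treatment"]).all()
        assert (joined["events_treatment"] <= joined["events_awareness"]).all()
        assert (joined["events_awareness"] <= joined["events"]).all()

    def test_denominators_match_outcome(self):
        people = pd.DataFrame([
            _person(uncontrolled=1),                      # in population, unaware
            _person(uncontrolled=0),                      # healthy
            _person(diagnosed=1, medicated=1, uncontrolled=0),  # controlled
        ])
        prev = cb.build_cells(people, "prevalence")
        assert prev["trials"].sum() == 3 and prev["events"].sum() == 2
        ctrl = cb.build_cells(people, "control")
        assert ctrl["trials"].sum() == 2 and ctrl["events"].sum() == 1

    def test_age_below_range_rejected(self):
        with pytest.raises(ModelDataError, match="age"):
            cb.build_cells(pd.DataFrame([_person(age=25.0)]), "prevalence")

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ModelDataError, match="outcome"):
            cb.build_cells(pd.DataFrame([_person()]), "incidence")


def test_age_group_labels_cover_range():
    labs = age_group_label(np.array([30.0, 39.9, 55.0, 80.0, 101.0]))
    assert list(labs) == ["30-40", "30-40", "50-60", "80+", "80+"]


def _intercept_spec(**kw):
    base = dict(
        county_covariates=(), include_spatial=False, include_iid=False,
        include_time=False, include_slopes=False,
        chains=2, warmup=300, draws=300, seed=4,
    )
    base.update(kw)
    return SmallAreaSpec(**base)


@pytest.fixture(scope="module")
def single_county_fit():
    cells = pd.DataFrame(
        {"county_id": [0], "year": [2001], "sex": ["male"],
         "age_group": ["30-40"], "race": ["white"], "trials": [500], "events": [200]}
    )
    ct = pd.DataFrame({"county_id": [0]})
    fit = cb.fit_small_area(cells, ct, [], _intercept_spec())
    return fit, cells


def test_single_county_matches_conjugate_oracle(single_county_fit):
    """Intercept-only binomial 200/500: posterior mean within ±0.02 of the
    Beta(200.5, 300.5) conjugate answer (~0.4)."""
    fit, cells = single_county_fit
    p = cb.predict_cells(fit, cells)
    assert abs(p.mean() - 0.4) < 0.02
    # spread also matches the conjugate posterior sd ~ 0.0219
    assert abs(p.std() - 0.0219) < 0.01


def test_prediction_identity_and_range(single_county_fit):
    fit, cells = single_county_fit
    a = cb.predict_cells(fit, cells)
    b = cb.predict_cells(fit, cells.copy())
    np.testing.assert_array_equal(a, b)  # deterministic given draws
    assert (a > 0).all() and (a < 1).all()


def test_unknown_county_and_year_rejected(single_county_fit):
    fit, cells = single_county_fit
    bad = cells.assign(county_id=99)
    with pytest.raises(ModelDataError, match="counties"):
        cb.predict_cells(fit, bad)
    with pytest.raises(ModelDataError, match="year"):
        cb.predict_cells(fit, cells.assign(year=1990))


def test_rhat_recorded_for_every_parameter(single_county_fit):
    fit, _ = single_county_fit
    assert fit.diagnostics["rhat_per_param"].shape[0] >= 1
    assert fit.diagnostics["max_rhat"] < 1.05
    assert fit.diagnostics["min_ess"] > 100


def _county_level_cells(eta, trials, rng, year=2001, sex="male"):
    events = rng.binomial(trials, expit(eta))
    return pd.DataFrame(
        {"county_id": np.arange(len(eta)), "year": year, "sex": sex,
         "age_group": "30-40", "race": "white",
         "trials": trials, "events": events}
    )


def test_county_covariate_recovery(rng):
    """beta=0.5 on a standardised covariate over 100 counties: posterior mean
    within ±0.15 and the 95% credible interval covers the truth."""
    C = 100
    z = rng.standard_normal(C)
    eta = -0.5 + 0.5 * z + 0.1 * rng.standard_normal(C)
    cells = _county_level_cells(eta, np.full(C, 200), rng)
    ct = pd.DataFrame({"county_id": np.arange(C), "cov": z})
    edges = cb.generate_world(cb.WorldConfig(n_counties=C, seed=0)).adjacency
    spec = SmallAreaSpec(
        county_covariates=("cov",), include_spatial=False, include_iid=True,
        include_time=False, include_slopes=False,
        chains=2, warmup=400, draws=400, seed=9,
    )
    fit = cb.fit_small_area(cells, ct, edges, spec)
    i = fit.fixed_names.index("county[cov]")
    draws = fit.draws["fixed"][:, i] / z.std()  # undo internal standardisation
    assert abs(draws.mean() - 0.5) < 0.15
    lo, hi = np.percentile(draws, [2.5, 97.5])
    assert lo < 0.5 < hi


def test_no_spatial_truth_shrinks_spatial_scale(rng):
    """Truth without spatial structure: posterior sigma_u concentrates low."""
    C = 49
    eta = -0.6 + 0.1 * rng.standard_normal(C)
    cells = _county_level_cells(eta, np.full(C, 150), rng)
    ct = pd.DataFrame({"county_id": np.arange(C)})
    edges = cb.generate_world(cb.WorldConfig(n_counties=C, seed=1)).adjacency
    spec = SmallAreaSpec(
        county_covariates=(), include_spatial=True, include_iid=True,
        include_time=False, include_slopes=False,
        chains=2, warmup=400, draws=400, seed=10,
    )
    fit = cb.fit_small_area(cells, ct, edges, spec)
    sigma_u = fit.draws["sigma"][:, 0]
    assert np.median(sigma_u) < 0.3


def test_monotone_age_truth_recovered(small_world):
    """With a truth that increases in age, fitted probabilities increase
    across age groups in every county (shared age effects + additive county
    effects preserve the ordering)."""
    sample = cb.sample_phone_survey(small_world, 200, seed=55)
    rec = sample.records.copy()
    rec["uncontrolled"] = sample.latent["uncontrolled"].to_numpy()
    cells = cb.build_cells(
        rec.loc[rec["sex"] == "male"], "prevalence", small_world.config.age_groups
    )
    spec = SmallAreaSpec(
        county_covariates=(), include_spatial=True, include_iid=True,
        include_time=False, include_slopes=False,
        chains=2, warmup=400, draws=400, seed=12,
    )
    fit = cb.fit_small_area(cells, small_world.county_table, small_world.adjacency, spec)
    labels = small_world.config.age_group_labels()
    grid = cb.complete_cell_grid(
        small_world.county_table["county_id"].to_numpy(),
        small_world.config.years, "male", labels, ("white",),
    )
    probs = cb.predict_cells(fit, grid).mean(axis=0)
    by_age = (
        grid.assign(p=probs)
        .groupby(["county_id", "age_group"], observed=True)["p"].mean()
        .unstack("age_group")[labels]
    )
    increasing = (by_age.diff(axis=1).iloc[:, 1:] > 0).all(axis=1)
    assert increasing.mean() >= 0.95


def test_label_permutation_equivariance(rng):
    """Relabelling counties (with adjacency relabelled) permutes estimates."""
    C = 16
    eta = -0.5 + 0.4 * rng.standard_normal(C)
    cells = _county_level_cells(eta, np.full(C, 120), rng)
    ct = pd.DataFrame({"county_id": np.arange(C)})
    edges = cb.generate_world(cb.WorldConfig(n_counties=C, seed=2)).adjacency
    spec = SmallAreaSpec(
        county_covariates=(), include_spatial=True, include_iid=True,
        include_time=False, include_slopes=False,
        chains=2, warmup=350, draws=350, seed=13,
    )
    fit = cb.fit_small_area(cells, ct, edges, spec)
    p1 = cb.predict_cells(fit, cells).mean(axis=0)

    perm = rng.permutation(C)
    cells2 = cells.assign(county_id=perm[cells["county_id"]])
    edges2 = [(int(perm[a]), int(perm[b])) for a, b in edges]
    fit2 = cb.fit_small_area(cells2, ct, edges2, spec)
    p2 = cb.predict_cells(fit2, cells2).mean(axis=0)
    np.testing.assert_allclose(p1, p2, atol=0.03)


def test_mixed_sex_cells_rejected():
    cells = pd.DataFrame(
        {"county_id": [0, 0], "year": [2001, 2001], "sex": ["male", "female"],
         "age_group": ["30-40"] * 2, "race": ["white"] * 2,
         "trials": [10, 10], "events": [5, 5]}
    )
    with pytest.raises(ModelDataError, match="one sex"):
        cb.fit_small_area(cells, pd.DataFrame({"county_id": [0]}), [], _intercept_spec())
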