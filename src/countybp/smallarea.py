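"""Stage 2: grouped-logistic spatio-temporal small-area model.

Imputed individuals are aggregated into county x year x sex x age-group x
race binomial cells. Per sex and per outcome the cell probabilities follow

    logit(p) = alpha + age dummies + race dummies + x_c' beta
               + u_c + v_c + delta_t + gamma_c * (t - t_bar)

with u_c a proper conditional-autoregressive (CAR) county effect on the
adjacency graph, v_c iid normal, delta_t a first-order random-walk shared
year effect, and gamma_c iid normal county-specific time slopes. All random
effects are sum-to-zero centred for identifiability and sampled in a
non-centred parameterisation; scale hyperparameters carry half-normal
priors. Posterior draws come from the package's Hamiltonian Monte Carlo
sampler with split-R-hat and effective-sample-size diagnostics.

Every structural block (CAR, iid, year walk, county slopes) is a config
switch, so the model collapses cleanly to simpler exchangeable or
non-spatial variants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hmc
from .design import expit
from .outcomes import classify_frame
from .synthetic import (
    DEFAULT_AGE_GROUPS,
    adjacency_matrix,
    car_covariance_chol,
    check_connected,
)

logger = logging.getLogger(__name__)

OUTCOMES = ("self_report", "prevalence", "awareness", "treatment", "control")

# Table-1 numerators/denominators: (event column, restrict to population?)
_OUTCOME_DEF = {
    "self_report": ("diagnosed", False),
    "prevalence": ("in_population", False),
    "awareness": ("aware", True),
    "treatment": ("treated", True),
    "control": ("controlled", True),
}


class ModelDataError(ValueError):
    """Cells, adjacency, or design inconsistent with the model."""


def age_group_label(age: np.ndarray, age_groups=DEFAULT_AGE_GROUPS) -> np.ndarray:
    """Assign each age to its configured group label; error outside range."""
    age = np.asarray(age, float)
    if np.any(age < age_groups[0][0]):
        raise ModelDataError("individual with age below the configured groups")
    labels = []
    for lo, hi in age_groups:
        labels.append(f"{lo:.0f}+" if np.isinf(hi) else f"{lo:.0f}-{hi:.0f}")
    edges = [g[0] for g in age_groups] + [np.inf]
    idx = np.searchsorted(edges, age, side="right") - 1
    return np.asarray(labels, object)[idx]


def build_cells(
    imputed: pd.DataFrame,
    outcome: str,
    age_groups=DEFAULT_AGE_GROUPS,
) -> pd.DataFrame:
    """Aggregate classified individuals into binomial cells for one outcome.

    ``imputed`` must carry diagnosed/medicated/uncontrolled plus county_id,
    year, sex, age, race. Denominators follow the outcome definitions:
    all adults for self-report and total prevalence, the hypertensive
    population for awareness, treatment, and control.
    """
    if outcome not in _OUTCOME_DEF:
        raise ModelDataError(f"unknown outcome {outcome!r}; one of {OUTCOMES}")
    event_col, restrict = _OUTCOME_DEF[outcome]
    df = classify_frame(imputed)
    df["age_group"] = age_group_label(df["age"].to_numpy(), age_groups)
    if restrict:
        df = df.loc[df["in_population"] == 1]
    grouped = (
        df.groupby(["county_id", "year", "sex", "age_group", "race"], observed=True)
        .agg(trials=(event_col, "size"), events=(event_col, "sum"))
        .reset_index()
    )
    return grouped


@dataclass
class SmallAreaSpec:
    """Model structure, priors, and MCMC settings for one outcome fit."""

    outcome: str = "prevalence"
    county_covariates: tuple[str, ...] = (
        "college_pct",
        "median_income",
        "poverty_pct",
        "restaurants_per_100k",
        "doctors_per_100k",
        "dentists_per_100k",
    )
    include_spatial: bool = True
    include_iid: bool = True
    include_time: bool = True
    include_slopes: bool = True
    car_rho: float = 0.95
    fixed_sd: float = 5.0
    sigma_scale: dict = field(
        default_factory=lambda: {"u": 1.0, "v": 1.0, "delta": 0.5, "gamma": 0.2}
    )
    chains: int = 2
    warmup: int = 500
    draws: int = 500
    max_leapfrog: int = 24
    target_accept: float = 0.8
    seed: int = 0


@dataclass
class SmallAreaFit:
    """Posterior draws and bookkeeping for one sex x outcome fit."""

    spec: SmallAreaSpec
    sex: str
    county_ids: np.ndarray
    years: np.ndarray
    age_labels: list[str]
    race_levels: list[str]
    fixed_names: list[str]
    covariate_stats: dict  # column -> (mean, sd) used for standardisation
    draws: dict  # name -> (n_total_draws, ...) arrays on natural scales
    diagnostics: dict

    @property
    def n_draws(self) -> int:
        return self.draws["fixed"].shape[0]

    def save(self, path) -> None:
        """Write full posterior draws (.npz) plus a JSON manifest beside it.

        The manifest records parameter names, seed, and convergence
        diagnostics; the draw file is a compressed columnar archive.
        """
        import json
        from pathlib import Path

        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), **self.draws)
        manifest = {
            "sex": self.sex,
            "outcome": self.spec.outcome,
            "seed": self.spec.seed,
            "fixed_names": list(self.fixed_names),
            "county_ids": self.county_ids.tolist(),
            "years": self.years.tolist(),
            "age_labels": list(self.age_labels),
            "race_levels": list(self.race_levels),
            "covariate_stats": self.covariate_stats,
            "diagnostics": {
                k: v for k, v in self.diagnostics.items()
                if not isinstance(v, np.ndarray)
            },
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean()


def _cell_design(
    cells: pd.DataFrame,
    county_table: pd.DataFrame,
    spec: SmallAreaSpec,
    age_labels: list[str],
    race_levels: list[str],
    stats: dict,
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(cells))]
    names = ["intercept"]
    for lab in age_labels[1:]:
        cols.append((cells["age_group"] == lab).to_numpy(float))
        names.append(f"age[{lab}]")
    for lev in race_levels[1:]:
        cols.append((cells["race"] == lev).to_numpy(float))
        names.append(f"race[{lev}]")
    ct = county_table.set_index("county_id")
    for cov in spec.county_covariates:
        mean, sd = stats[cov]
        vals = ct.loc[cells["county_id"], cov].to_numpy(float)
        cols.append((vals - mean) / sd)
        names.append(f"county[{cov}]")
    return np.column_stack(cols), names


def fit_small_area(
    cells: pd.DataFrame,
    county_table: pd.DataFrame,
    adjacency: list[tuple[int, int]],
    spec: SmallAreaSpec,
) -> SmallAreaFit:
    """Fit the hierarchical model to one sex's cells by HMC."""
    cells = cells.reset_index(drop=True)
    sexes = cells["sex"].unique()
    if len(sexes) != 1:
        raise ModelDataError("fit one sex at a time; got " + ", ".join(map(str, sexes)))
    sex = str(sexes[0])

    county_ids = np.sort(county_table["county_id"].unique())
    cid_index = {c: i for i, c in enumerate(county_ids)}
    missing = set(cells["county_id"]) - set(county_ids)
    if missing:
        raise ModelDataError(f"cells reference unknown counties: {sorted(missing)[:5]}")
    C = len(county_ids)
    years = np.sort(cells["year"].unique())
    T = len(years)
    yr_index = {y: i for i, y in enumerate(years)}
    age_labels = sorted(cells["age_group"].unique(), key=lambda s: float(s.split("-")[0].rstrip("+")))
    race_levels = sorted(cells["race"].unique())
    for lev in ("white",):
        if lev in race_levels:  # keep white as reference, matching stage 1
            race_levels.remove(lev)
            race_levels.insert(0, lev)

    stats = {
        cov: (
            float(county_table[cov].mean()),
            float(county_table[cov].std(ddof=0)) or 1.0,
        )
        for cov in spec.county_covariates
    }
    Xf, fixed_names = _cell_design(cells, county_table, spec, age_labels, race_levels, stats)
    nf = Xf.shape[1]
    if np.linalg.matrix_rank(Xf) < nf:
        raise ModelDataError("cell-level design matrix is rank deficient")

    y = cells["events"].to_numpy(float)
    n = cells["trials"].to_numpy(float)
    if np.any(y > n) or np.any(y < 0):
        raise ModelDataError("events must lie in [0, trials]")
    ci = cells["county_id"].map(cid_index).to_numpy()
    ti = cells["year"].map(yr_index).to_numpy()

    use_u = spec.include_spatial and C >= 2
    use_v = spec.include_iid and C >= 2
    use_t = spec.include_time and T >= 2
    use_g = spec.include_slopes and C >= 2 and T >= 2
    if use_u:
        edges = [(cid_index[a], cid_index[b]) for a, b in adjacency]
        check_connected(edges, C)
        A = adjacency_matrix(edges, C)
        Lcar = car_covariance_chol(A, spec.car_rho)
    else:
        Lcar = None
    ttil = (years - years.mean()).astype(float)
    if use_g and ttil.std() > 0:
        ttil = ttil / ttil.std()
    tt_cell = ttil[ti]

    tau = spec.sigma_scale
    s0sq = spec.fixed_sd**2

    # --- parameter packing -------------------------------------------------
    blocks = [("fixed", nf)]
    if use_u:
        blocks.append(("z_u", C))
    if use_v:
        blocks.append(("z_v", C))
    if use_t:
        blocks.append(("z_d", T))
    if use_g:
        blocks.append(("z_g", C))
    for name, flag in (("ls_u", use_u), ("ls_v", use_v), ("ls_d", use_t), ("ls_g", use_g)):
        if flag:
            blocks.append((name, 1))
    offsets = {}
    pos = 0
    for name, size in blocks:
        offsets[name] = (pos, pos + size)
        pos += size
    dim = pos

    def unpack(q):
        return {name: q[a:b] for name, (a, b) in offsets.items()}

    def transform(parts):
        out = {}
        if use_u:
            s = float(np.exp(parts["ls_u"][0]))
            out["u"] = s * _center(Lcar @ parts["z_u"])
        if use_v:
            s = float(np.exp(parts["ls_v"][0]))
            out["v"] = s * _center(parts["z_v"])
        if use_t:
            s = float(np.exp(parts["ls_d"][0]))
            out["delta"] = s * _center(np.cumsum(parts["z_d"]))
        if use_g:
            s = float(np.exp(parts["ls_g"][0]))
            out["gamma"] = s * _center(parts["z_g"])
        return out

    def logp_grad(q):
        parts = unpack(q)
        bf = parts["fixed"]
        eff = transform(parts)
        eta = Xf @ bf
        if use_u:
            eta = eta + eff["u"][ci]
        if use_v:
            eta = eta + eff["v"][ci]
        if use_t:
            eta = eta + eff["delta"][ti]
        if use_g:
            eta = eta + eff["gamma"][ci] * tt_cell

        ll = float(np.sum(y * eta - n * np.logaddexp(0.0, eta)))
        lp = ll - 0.5 * float(bf @ bf) / s0sq
        grad = np.empty(dim)
        g_eta = y - n * expit(eta)
        a, b = offsets["fixed"]
        grad[a:b] = Xf.T @ g_eta - bf / s0sq

        def hyper(name, scale, contrib):
            # d/d(log s) of likelihood + half-normal prior + Jacobian
            s = float(np.exp(parts[name][0]))
            a1, _ = offsets[name]
            grad[a1] = contrib + (-(s * s) / (scale * scale) + 1.0)
            return -0.5 * (s * s) / (scale * scale) + parts[name][0]

        if use_u:
            g_u = np.bincount(ci, weights=g_eta, minlength=C)
            z = parts["z_u"]
            s = float(np.exp(parts["ls_u"][0]))
            a1, b1 = offsets["z_u"]
            grad[a1:b1] = s * (Lcar.T @ (g_u - g_u.mean())) - z
            lp += -0.5 * float(z @ z) + hyper("ls_u", tau["u"], float(g_u @ eff["u"]))
        if use_v:
            g_v = np.bincount(ci, weights=g_eta, minlength=C)
            z = parts["z_v"]
            s = float(np.exp(parts["ls_v"][0]))
            a1, b1 = offsets["z_v"]
            grad[a1:b1] = s * (g_v - g_v.mean()) - z
            lp += -0.5 * float(z @ z) + hyper("ls_v", tau["v"], float(g_v @ eff["v"]))
        if use_t:
            g_t = np.bincount(ti, weights=g_eta, minlength=T)
            z = parts["z_d"]
            s = float(np.exp(parts["ls_d"][0]))
            a1, b1 = offsets["z_d"]
            gc = g_t - g_t.mean()
            grad[a1:b1] = s * np.cumsum(gc[::-1])[::-1] - z
            lp += -0.5 * float(z @ z) + hyper("ls_d", tau["delta"], float(g_t @ eff["delta"]))
        if use_g:
            g_g = np.bincount(ci, weights=g_eta * tt_cell, minlength=C)
            z = parts["z_g"]
            s = float(np.exp(parts["ls_g"][0]))
            a1, b1 = offsets["z_g"]
            grad[a1:b1] = s * (g_g - g_g.mean()) - z
            lp += -0.5 * float(z @ z) + hyper("ls_g", tau["gamma"], float(g_g @ eff["gamma"]))
        return lp, grad

    # --- sampling ----------------------------------------------------------
    root = np.random.SeedSequence(spec.seed)
    chain_seeds = root.spawn(spec.chains)
    p_bar = (y.sum() + 0.5) / (n.sum() + 1.0)
    chain_draws = []
    accept = []
    divergences = 0
    for ss in chain_seeds:
        rng = np.random.default_rng(ss)
        q0 = 0.1 * rng.standard_normal(dim)
        a, _ = offsets["fixed"]
        q0[a] = np.log(p_bar / (1 - p_bar))
        for name in ("ls_u", "ls_v", "ls_d", "ls_g"):
            if name in offsets:
                q0[offsets[name][0]] = np.log(0.3)
        res = hmc.sample_chain(
            logp_grad,
            q0,
            n_warmup=spec.warmup,
            n_draws=spec.draws,
            rng=rng,
            max_leapfrog=spec.max_leapfrog,
            target_accept=spec.target_accept,
        )
        chain_draws.append(res.draws)
        accept.append(res.accept_rate)
        divergences += res.divergences

    stacked = np.asarray(chain_draws)  # (chains, draws, dim)
    diagnostics = _diagnostics(stacked, offsets, accept, divergences)
    if diagnostics["max_rhat"] > 1.05:
        warnings.warn(
            f"MCMC quality warning: max split-R-hat = {diagnostics['max_rhat']:.3f} "
            "(> 1.05); increase warmup/draws before trusting intervals",
            stacklevel=2,
        )

    flat = stacked.reshape(-1, dim)
    out_draws: dict[str, np.ndarray] = {}
    a, b = offsets["fixed"]
    out_draws["fixed"] = flat[:, a:b]
    effs = {"u": np.zeros((len(flat), C)), "v": np.zeros((len(flat), C)),
            "delta": np.zeros((len(flat), T)), "gamma": np.zeros((len(flat), C))}
    sigmas = np.zeros((len(flat), 4))
    for i, q in enumerate(flat):
        parts = unpack(q)
        eff = transform(parts)
        for j, (nm, key) in enumerate(
            (("u", "ls_u"), ("v", "ls_v"), ("delta", "ls_d"), ("gamma", "ls_g"))
        ):
            if nm in eff:
                effs[nm][i] = eff[nm]
                sigmas[i, j] = np.exp(parts[key][0])
    out_draws.update(effs)
    out_draws["sigma"] = sigmas

    return SmallAreaFit(
        spec=spec,
        sex=sex,
        county_ids=county_ids,
        years=years,
        age_labels=age_labels,
        race_levels=race_levels,
        fixed_names=fixed_names,
        covariate_stats=stats,
        draws=out_draws,
        diagnostics=diagnostics,
    )


def _diagnostics(stacked: np.ndarray, offsets, accept, divergences) -> dict:
    import arviz as az

    posterior = {"theta": stacked}
    rhat = az.rhat(az.convert_to_dataset(posterior))["theta"].to_numpy()
    ess = az.ess(az.convert_to_dataset(posterior))["theta"].to_numpy()
    # split-R-hat needs >= 2 chains; a single chain reports NaN
    max_rhat = float(np.nanmax(rhat)) if not np.all(np.isnan(rhat)) else float("nan")
    return {
        "max_rhat": max_rhat,
        "min_ess": float(np.nanmin(ess)),
        "accept_rate": float(np.mean(accept)),
        "divergences": int(divergences),
        "rhat_per_param": rhat,
    }


def predict_cells(
    fit: SmallAreaFit, cells: pd.DataFrame, county_table: pd.DataFrame | None = None
) -> np.ndarray:
    """Posterior probability draws for arbitrary cells: (n_draws, n_cells).

    Cells may have trials = 0 (prediction-only). Counties and years must be
    known to the fit; predictions are a deterministic function of the stored
    draws. ``county_table`` is required when the fit used county covariates.
    """
    cells = cells.reset_index(drop=True)
    cid_index = {c: i for i, c in enumerate(fit.county_ids)}
    unknown = set(cells["county_id"]) - set(fit.county_ids)
    if unknown:
        raise ModelDataError(f"cells reference unknown counties: {sorted(unknown)[:5]}")
    unknown_y = set(cells["year"]) - set(fit.years)
    if unknown_y:
        raise ModelDataError(f"cells reference years outside the fit: {sorted(unknown_y)}")
    if fit.spec.county_covariates:
        if county_table is None:
            raise ModelDataError(
                "this fit includes county covariates; pass county_table"
            )
        Xf, _ = _cell_design(
            cells, county_table, fit.spec, fit.age_labels, fit.race_levels,
            fit.covariate_stats,
        )
    else:
        cols = [np.ones(len(cells))]
        for lab in fit.age_labels[1:]:
            cols.append((cells["age_group"] == lab).to_numpy(float))
        for lev in fit.race_levels[1:]:
            cols.append((cells["race"] == lev).to_numpy(float))
        Xf = np.column_stack(cols)
    return _eta_to_probs(fit, cells, Xf, cid_index)


def _eta_to_probs(fit, cells, Xf, cid_index) -> np.ndarray:
    yr_index = {y: i for i, y in enumerate(fit.years)}
    ci = cells["county_id"].map(cid_index).to_numpy()
    ti = cells["year"].map(yr_index).to_numpy()
    years = fit.years.astype(float)
    ttil = years - years.mean()
    if ttil.std() > 0 and fit.spec.include_slopes:
        ttil = ttil / ttil.std()
    eta = fit.draws["fixed"] @ Xf.T
    eta += fit.draws["u"][:, ci]
    eta += fit.draws["v"][:, ci]
    eta += fit.draws["delta"][:, ti]
    eta += fit.draws["gamma"][:, ci] * ttil[ti][None, :]
    return expit(eta)


def complete_cell_grid(
    county_ids, years, sex: str, age_labels, race_levels
) -> pd.DataFrame:
    """All county x year x age x race cells for one sex, trials = 0."""
    idx = pd.MultiIndex.from_product(
        [county_ids, years, age_labels, race_levels],
        names=["county_id", "year", "age_group", "race"],
    )
    grid = pd.DataFrame(index=idx).reset_index()
    grid["sex"] = sex
    grid["trials"] = 0
    grid["events"] = 0
    return grid
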