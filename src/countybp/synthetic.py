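"""Synthetic examination- and telephone-survey world generator.

Real analyses of this kind combine a national examination survey (measured
systolic blood pressure, no geography) with a large telephone survey
(county and year, self-report only). Both microdata sources are restricted,
so this module generates a synthetic "world" with the same joint structure:

* a latent logistic model for uncontrolled hypertension (SBP >= 140 mm Hg)
  given individual covariates, stratified by sex and previous diagnosis;
* county-level random effects on the logit scale, mixing a proper
  conditional-autoregressive (CAR) draw on a rook-adjacency county grid with
  iid noise;
* unequal design weights (log-normal, normalised to the sample size).

The examination sample carries measured SBP; the telephone sample carries
county and year but no SBP. Both share one covariate generator, so the
stage-1 transport assumption holds by construction. The telephone sample's
latent uncontrolled indicator is returned in a separate side table used only
by validation code and tests, never by the analysis pipeline itself.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.sparse import csgraph, csr_matrix

from .design import expit, linear_predictor

SEXES = ("male", "female")
DEFAULT_RACE_LEVELS = ("white", "black", "hispanic", "other")
DEFAULT_WAVES = ("1999-2000", "2001-2002", "2003-2004", "2005-2006", "2007-2008")
DEFAULT_AGE_GROUPS = (
    (30.0, 40.0),
    (40.0, 50.0),
    (50.0, 60.0),
    (60.0, 70.0),
    (70.0, 80.0),
    (80.0, float("inf")),
)

# National race marginal used when drawing individuals (white/black/hisp/other).
RACE_SHARES = (0.70, 0.11, 0.13, 0.06)
# Adult (30+) age-group shares used for county population tables.
AGE_POP_SHARES = (0.22, 0.21, 0.20, 0.17, 0.12, 0.08)


class InvalidConfigError(ValueError):
    """World configuration violating its invariants."""


class DisconnectedGraphError(ValueError):
    """Adjacency graph with more than one connected component."""

    def __init__(self, n_components: int):
        self.n_components = n_components
        super().__init__(
            f"adjacency graph is disconnected ({n_components} components); "
            "a proper CAR prior requires a connected graph"
        )


def default_truth_coefficients() -> dict[tuple[str, bool], dict[str, float]]:
    """Latent uncontrolled-hypertension logistic truth, per (sex, diagnosed).

    Signs follow the epidemiology the model family is built for: risk rises
    nonlinearly with age, is higher in black adults, increases with BMI among
    the never diagnosed, falls with insurance coverage, and medication lowers
    risk among the diagnosed with a wave-varying (improving) effect.
    """
    never_men = {
        "1": -1.9, "age_c": 0.80, "age_c2": -0.08,
        "race[black]": 0.35, "race[hispanic]": -0.15, "race[other]": 0.05,
        "bmi_c": 0.25, "insured": -0.20,
    }
    never_women = {
        "1": -2.2, "age_c": 0.90, "age_c2": -0.08,
        "race[black]": 0.40, "race[hispanic]": -0.20, "race[other]": 0.05,
        "bmi_c": 0.30, "insured": -0.25,
    }
    med_waves = {
        "medicated:wave[2001-2002]": -0.05,
        "medicated:wave[2003-2004]": -0.12,
        "medicated:wave[2005-2006]": -0.18,
        "medicated:wave[2007-2008]": -0.25,
    }
    diag_men = {
        "1": -0.2, "age_c": 0.45, "age_c2": -0.05,
        "race[black]": 0.30, "race[hispanic]": 0.15, "race[other]": 0.05,
        "bmi_c": 0.05, "insured": -0.15, "medicated": -0.55, **med_waves,
    }
    diag_women = {
        "1": -0.4, "age_c": 0.50, "age_c2": -0.05,
        "race[black]": 0.30, "race[hispanic]": -0.10, "race[other]": 0.05,
        "bmi_c": 0.05, "insured": -0.15, "medicated": -0.60, **med_waves,
    }
    return {
        ("male", False): never_men,
        ("female", False): never_women,
        ("male", True): diag_men,
        ("female", True): diag_women,
    }


def default_diagnosis_model() -> dict[str, float]:
    return {"1": -0.5, "age_c": 0.55, "bmi_c": 0.30, "race[black]": 0.30}


def default_medication_model() -> dict[str, float]:
    return {"1": 0.9, "age_c": 0.40}


@dataclass
class WorldConfig:
    """Parameters of the synthetic world.

    ``spatial_sd`` and ``iid_sd`` are logit-scale standard deviations of the
    two county random-effect components; ``spatial_mixing`` in [0, 1] is the
    linear weight on the spatial (CAR) component.
    """

    n_counties: int = 50
    n_states: int = 5
    years: tuple[int, ...] = tuple(range(2001, 2010))
    age_groups: tuple[tuple[float, float], ...] = DEFAULT_AGE_GROUPS
    race_levels: tuple[str, ...] = DEFAULT_RACE_LEVELS
    waves: tuple[str, ...] = DEFAULT_WAVES
    truth_coefficients: dict = field(default_factory=default_truth_coefficients)
    diagnosis_model: dict = field(default_factory=default_diagnosis_model)
    medication_model: dict = field(default_factory=default_medication_model)
    spatial_sd: float = 0.30
    iid_sd: float = 0.10
    spatial_mixing: float = 0.7
    car_rho: float = 0.95
    year_trend: float = -0.02  # logit per year, slow secular decline
    weight_cv: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_counties < 2:
            raise InvalidConfigError("n_counties must be at least 2")
        if self.n_states < 1 or self.n_states > self.n_counties:
            raise InvalidConfigError("n_states must be in [1, n_counties]")
        if len(self.race_levels) != 4:
            raise InvalidConfigError("race_levels must have exactly 4 entries")
        if self.spatial_sd < 0 or self.iid_sd < 0:
            raise InvalidConfigError("spatial_sd and iid_sd must be nonnegative")
        if not 0.0 <= self.spatial_mixing <= 1.0:
            raise InvalidConfigError("spatial_mixing must lie in [0, 1]")
        if not 0.0 <= self.car_rho < 1.0:
            raise InvalidConfigError("car_rho must lie in [0, 1)")
        lo = [g[0] for g in self.age_groups]
        hi = [g[1] for g in self.age_groups]
        if lo[0] != 30.0 or hi[-1] != float("inf"):
            raise InvalidConfigError("age_groups must cover [30, inf)")
        for a, b in zip(hi[:-1], lo[1:]):
            if a != b:
                raise InvalidConfigError("age_groups must tile [30, inf) without gaps")

    def age_group_labels(self) -> list[str]:
        out = []
        for lo, hi in self.age_groups:
            out.append(f"{lo:.0f}+" if np.isinf(hi) else f"{lo:.0f}-{hi:.0f}")
        return out


def grid_adjacency(n: int) -> list[tuple[int, int]]:
    """Rook adjacency of n counties laid row-major on a near-square grid."""
    ncols = int(np.ceil(np.sqrt(n)))
    edges = []
    for i in range(n):
        r, c = divmod(i, ncols)
        if c + 1 < ncols and i + 1 < n and (i + 1) // ncols == r:
            edges.append((i, i + 1))
        if i + ncols < n:
            edges.append((i, i + ncols))
    if not edges and n >= 2:  # degenerate 1-column layouts
        edges = [(i, i + 1) for i in range(n - 1)]
    return edges


def adjacency_matrix(edges: list[tuple[int, int]], n: int) -> np.ndarray:
    A = np.zeros((n, n))
    for a, b in edges:
        if a == b:
            raise InvalidConfigError("adjacency must be irreflexive")
        A[a, b] = A[b, a] = 1.0
    return A


def check_connected(edges: list[tuple[int, int]], n: int) -> None:
    """Raise DisconnectedGraphError if the county graph is not connected."""
    A = adjacency_matrix(edges, n)
    ncomp, _ = csgraph.connected_components(csr_matrix(A), directed=False)
    if ncomp != 1:
        raise DisconnectedGraphError(ncomp)


def car_covariance_chol(A: np.ndarray, rho: float) -> np.ndarray:
    """Cholesky factor of the standardised proper-CAR covariance.

    The precision is Q = D - rho * A (D the degree matrix). The covariance is
    rescaled so the mean marginal variance is 1, making ``spatial_sd`` the
    typical marginal standard deviation of the spatial component.
    """
    D = np.diag(A.sum(axis=1))
    Q = D - rho * A
    cov = sla.inv(Q)
    cov /= np.mean(np.diag(cov))
    return sla.cholesky(cov, lower=True)


@dataclass
class World:
    """A generated world: geography, county covariates, and truth parameters."""

    config: WorldConfig
    county_table: pd.DataFrame  # county_id, state_id, covariates, population
    race_age_population: pd.DataFrame  # county_id x race x age_group counts
    adjacency: list[tuple[int, int]]
    county_effects: np.ndarray  # logit-scale truth, one per county

    def race_shares(self) -> pd.DataFrame:
        """Per-county race population shares (rows sum to 1)."""
        pop = self.race_age_population.groupby(["county_id", "race"], observed=True)[
            "population"
        ].sum().unstack("race")
        return pop.div(pop.sum(axis=1), axis=0)

    def standard_population(self) -> dict[str, float]:
        """World-level age distribution, the generator's standard population."""
        pop = self.race_age_population.groupby("age_group", observed=True)[
            "population"
        ].sum()
        w = pop / pop.sum()
        return {k: float(v) for k, v in w.items()}

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.county_table.to_csv(outdir / "counties.csv", index=False)
        self.race_age_population.to_csv(
            outdir / "race_age_population.csv", index=False
        )
        pd.DataFrame(self.adjacency, columns=["county_a", "county_b"]).to_csv(
            outdir / "adjacency.csv", index=False
        )
        truth = dataclasses.asdict(self.config)
        truth["truth_coefficients"] = {
            f"{sex}|{'diagnosed' if d else 'never'}": coefs
            for (sex, d), coefs in self.config.truth_coefficients.items()
        }
        truth["county_effects"] = self.county_effects.tolist()
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2, default=str))


def generate_world(config: WorldConfig) -> World:
    """Build counties on a rook grid with CAR-plus-iid logit random effects."""
    rng = np.random.default_rng(config.seed)
    n = config.n_counties
    edges = grid_adjacency(n)
    check_connected(edges, n)
    A = adjacency_matrix(edges, n)

    if config.spatial_sd > 0 and config.spatial_mixing > 0:
        L = car_covariance_chol(A, config.car_rho)
        u = L @ rng.standard_normal(n)
    else:
        u = np.zeros(n)
    e = rng.standard_normal(n)
    effects = (
        config.spatial_mixing * config.spatial_sd * u
        + (1.0 - config.spatial_mixing) * config.iid_sd * e
    )

    # States as contiguous row-major blocks of the grid.
    state_id = (np.arange(n) * config.n_states // n).astype(int)

    county = pd.DataFrame(
        {
            "county_id": np.arange(n),
            "state_id": state_id,
            "college_pct": np.clip(rng.normal(28, 8, n), 5, 60),
            "median_income": np.round(rng.lognormal(np.log(48000), 0.25, n), 0),
            "poverty_pct": np.clip(rng.gamma(4.0, 3.2, n), 2, 45),
            "restaurants_per_100k": rng.gamma(6.0, 12.0, n),
            "doctors_per_100k": rng.gamma(5.0, 45.0, n),
            "dentists_per_100k": rng.gamma(5.0, 12.0, n),
            "population": np.round(rng.lognormal(np.log(3.0e4), 0.9, n), 0),
        }
    )

    rows = []
    age_labels = config.age_group_labels()
    race_alpha = np.array(RACE_SHARES) * 12.0
    for c in range(n):
        shares = rng.dirichlet(race_alpha)
        for race, rs in zip(config.race_levels, shares):
            for lab, ashare in zip(age_labels, AGE_POP_SHARES):
                rows.append(
                    {
                        "county_id": c,
                        "race": race,
                        "age_group": lab,
                        "population": float(
                            np.round(county.loc[c, "population"] * rs * ashare)
                        ),
                    }
                )
    race_age = pd.DataFrame(rows)

    return World(
        config=config,
        county_table=county,
        race_age_population=race_age,
        adjacency=edges,
        county_effects=effects,
    )


def _draw_covariates(config: WorldConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Shared covariate generator for both surveys (transport by design).

    Ages are drawn from the same age-group shares as the county population
    tables (uniform within group, 80+ spread over 80-90), so individual
    samples and the standard population describe one consistent world.
    """
    k = len(config.age_groups)
    shares = np.asarray(AGE_POP_SHARES[:k], float) if k <= len(AGE_POP_SHARES) else np.ones(k)
    shares = shares / shares.sum()
    gi = rng.choice(k, size=n, p=shares)
    lo = np.array([g[0] for g in config.age_groups])
    hi = np.array([g[1] if np.isfinite(g[1]) else g[0] + 10.0 for g in config.age_groups])
    age = lo[gi] + rng.random(n) * (hi[gi] - lo[gi])
    sex = rng.choice(SEXES, size=n)
    race = rng.choice(config.race_levels, size=n, p=RACE_SHARES)
    bmi = np.clip(rng.normal(28.5, 5.5, n), 16.0, 60.0)
    df = pd.DataFrame({"age": age, "sex": sex, "race": race, "bmi": bmi})
    p_ins = expit(0.8 + 0.3 * (age - 55.0) / 10.0)
    df["insured"] = (rng.random(n) < p_ins).astype(int)
    p_diag = expit(linear_predictor(df, config.diagnosis_model))
    df["diagnosed"] = (rng.random(n) < p_diag).astype(int)
    p_med = expit(linear_predictor(df, config.medication_model))
    df["medicated"] = ((rng.random(n) < p_med) & (df["diagnosed"] == 1)).astype(int)
    return df


def _design_weights(n: int, cv: float, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.zeros(0)
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    w = rng.lognormal(0.0, sigma, n)
    return w * (n / w.sum())


def _latent_uncontrolled_prob(
    df: pd.DataFrame, config: WorldConfig, extra_logit: np.ndarray | float = 0.0
) -> np.ndarray:
    """Truth P(SBP >= 140) per individual from the stratified logistic model."""
    p = np.empty(len(df))
    for (sex, diag), coefs in config.truth_coefficients.items():
        mask = (df["sex"] == sex).to_numpy() & (df["diagnosed"] == int(diag)).to_numpy()
        if not mask.any():
            continue
        eta = linear_predictor(df.loc[mask], coefs)
        extra = extra_logit[mask] if np.ndim(extra_logit) else extra_logit
        p[mask] = expit(eta + extra)
    return p


def sample_exam_survey(world: World, n: int, seed: int) -> pd.DataFrame:
    """Draw an examination-survey sample with measured systolic BP."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    config = world.config
    rng = np.random.default_rng(seed)
    df = _draw_covariates(config, n, rng)
    df["wave"] = rng.choice(config.waves, size=n)
    df["stratum_id"] = rng.integers(1, 16, size=n)
    df["weight"] = _design_weights(n, config.weight_cv, rng)

    p = _latent_uncontrolled_prob(df, config) if n else np.zeros(0)
    unc = rng.random(n) < p
    above = 140.0 + rng.gamma(2.0, 9.0, n)
    below = np.clip(139.5 - rng.gamma(2.0, 9.0, n), 85.0, None)
    df["sbp"] = np.where(unc, above, below)
    return df


def wave_for_year(year: int, waves: tuple[str, ...]) -> str:
    """Map a survey year to the nearest examination wave (clamped at the ends)."""
    mids = []
    for w in waves:
        ys = [int(tok) for tok in w.split("-")]
        mids.append(sum(ys) / len(ys))
    return waves[int(np.argmin([abs(year - m) for m in mids]))]


@dataclass
class PhoneSample:
    """Telephone-survey records plus the latent truth side table.

    ``latent`` is for validation and tests only; pipeline stages must never
    read it (the analysis sees self-report variables only).
    """

    records: pd.DataFrame
    latent: pd.DataFrame


def sample_phone_survey(world: World, n_per_county_year: int, seed: int) -> PhoneSample:
    """Draw a telephone-survey sample: county/year known, no measured SBP."""
    if n_per_county_year < 0:
        raise ValueError("n_per_county_year must be nonnegative")
    config = world.config
    rng = np.random.default_rng(seed)
    counties = world.county_table["county_id"].to_numpy()
    years = np.asarray(config.years)
    total = n_per_county_year * len(counties) * len(years)

    df = _draw_covariates(config, total, rng)
    df["county_id"] = np.repeat(counties, n_per_county_year * len(years))
    df["year"] = np.tile(np.repeat(years, n_per_county_year), len(counties))
    wave_map = {int(y): wave_for_year(int(y), config.waves) for y in years}
    df["wave"] = df["year"].map(wave_map)
    df["weight"] = _design_weights(total, config.weight_cv, rng)

    if total:
        extra = (
            world.county_effects[df["county_id"].to_numpy()]
            + config.year_trend * (df["year"].to_numpy() - years.mean())
        )
        p = _latent_uncontrolled_prob(df, config, extra)
    else:
        p = np.zeros(0)
    latent = pd.DataFrame(
        {
            "county_id": df["county_id"],
            "year": df["year"],
            "p_true": p,
            "uncontrolled": (rng.random(total) < p).astype(int),
        }
    )
    records = df.drop(columns=["wave"])
    return PhoneSample(records=records, latent=latent)
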