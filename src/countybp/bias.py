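"""Stage 1: self-report bias correction.

Uncontrolled hypertension (measured systolic BP >= 140 mm Hg) is observed in
the examination survey but not in the telephone survey. Four survey-weighted
logistic models — stratified by sex and previous diagnosis — relate the
uncontrolled indicator to individual covariates; among the previously
diagnosed, the medication effect is allowed to vary by survey wave.
Telephone records then receive imputed uncontrolled status by
posterior-predictive draws: one multivariate-normal coefficient draw per
imputed dataset and per stratum, then a Bernoulli draw per individual.

The coefficient posterior is approximated as MVN(beta_hat, sandwich
covariance), the standard asymptotic approximation for weighted
maximum-pseudo-likelihood fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import build_design, expit
from .synthetic import SEXES, wave_for_year

logger = logging.getLogger(__name__)

BASE_TERMS = [
    "1",
    "age_c",
    "age_c2",
    "race[black]",
    "race[hispanic]",
    "race[other]",
    "bmi_c",
    "insured",
]


class SeparationError(RuntimeError):
    """Quasi-complete separation detected in a stratum fit."""


class EmptyStratumError(ValueError):
    """A stratum with too few events or non-events to fit."""


class UnseenLevelError(ValueError):
    """A prediction-time covariate level absent from the training design."""


Stratum = tuple[str, bool]  # (sex, previously diagnosed)


@dataclass
class BiasModelSpec:
    """Term list for one (sex, diagnosed) stratum."""

    stratum: Stratum
    terms: list[str]
    wave_levels: tuple[str, ...]

    def __post_init__(self):
        has_med = any(t.startswith("medicated") for t in self.terms)
        if has_med and not self.stratum[1]:
            raise ValueError("medication terms are only valid in diagnosed strata")


def default_spec_set(
    wave_levels: tuple[str, ...],
    extra_terms: list[str] | None = None,
) -> list[BiasModelSpec]:
    """The four-model specification spanning sex x previous diagnosis.

    Diagnosed strata add a main medication effect plus medication x wave
    dummies (first wave as reference), the time-varying-treatment encoding.
    """
    med_terms = ["medicated"] + [f"medicated:wave[{w}]" for w in wave_levels[1:]]
    specs = []
    for sex in SEXES:
        for diagnosed in (False, True):
            terms = list(BASE_TERMS) + (extra_terms or [])
            if diagnosed:
                terms += med_terms
            specs.append(BiasModelSpec((sex, diagnosed), terms, tuple(wave_levels)))
    return specs


@dataclass
class BiasModelFit:
    spec: BiasModelSpec
    coefficients: np.ndarray
    covariance: np.ndarray
    n_used: int

    def __post_init__(self):
        p = len(self.coefficients)
        if self.covariance.shape != (p, p):
            raise ValueError("covariance shape does not match coefficient length")

    def predict_proba(self, df: pd.DataFrame, coefficients: np.ndarray | None = None) -> np.ndarray:
        _check_levels(df, self.spec)
        X = build_design(df, self.spec.terms)
        beta = self.coefficients if coefficients is None else coefficients
        return expit(X @ beta)

    def to_dict(self) -> dict:
        return {
            "sex": self.spec.stratum[0],
            "diagnosed": self.spec.stratum[1],
            "terms": list(self.spec.terms),
            "wave_levels": list(self.spec.wave_levels),
            "coefficients": self.coefficients.tolist(),
            "covariance": self.covariance.tolist(),
            "n_used": self.n_used,
        }


def _check_levels(df: pd.DataFrame, spec: BiasModelSpec) -> None:
    known_races = {"white"} | {
        t[5:-1] for t in spec.terms if t.startswith("race[")
    }
    unseen = set(df["race"].unique()) - known_races
    if unseen:
        raise UnseenLevelError(f"race level(s) not in training design: {sorted(unseen)}")
    if "wave" in df.columns and any(":wave[" in t for t in spec.terms):
        unseen_w = set(df["wave"].unique()) - set(spec.wave_levels)
        if unseen_w:
            raise UnseenLevelError(f"wave level(s) not in training design: {sorted(unseen_w)}")


def stratum_mask(df: pd.DataFrame, stratum: Stratum) -> np.ndarray:
    sex, diagnosed = stratum
    return ((df["sex"] == sex) & (df["diagnosed"] == int(diagnosed))).to_numpy()


def _drop_incomplete(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    complete = df.dropna(subset=[c for c in cols if c in df.columns])
    n_drop = len(df) - len(complete)
    if n_drop:
        logger.warning("dropping %d records with missing covariates", n_drop)
    return complete


def fit_bias_models(
    exam: pd.DataFrame,
    spec_set: list[BiasModelSpec],
    sbp_threshold: float = 140.0,
    check_separation: bool = True,
) -> dict[Stratum, BiasModelFit]:
    """Fit the four stratified survey-weighted logistic models.

    Weights are normalised within stratum to sum to the stratum sample size,
    so the pseudo-likelihood carries its nominal information content; the
    reported covariance is the robust (sandwich) estimate.

    ``check_separation=False`` skips the quasi-complete-separation guard,
    for callers that only need point predictions from a separable fit.
    """
    exam = _drop_incomplete(exam, ["age", "race", "bmi", "insured", "sbp", "weight"])
    y_all = (exam["sbp"].to_numpy(float) >= sbp_threshold).astype(float)
    fits: dict[Stratum, BiasModelFit] = {}
    for spec in spec_set:
        mask = stratum_mask(exam, spec.stratum)
        sub = exam.loc[mask]
        y = y_all[mask]
        n = len(sub)
        n_events = int(y.sum())
        if n == 0:
            raise EmptyStratumError(f"stratum {spec.stratum} is empty")
        if n_events < 10 or n - n_events < 10:
            raise EmptyStratumError(
                f"stratum {spec.stratum} has {n_events} events / {n - n_events} "
                "non-events; need at least 10 of each"
            )
        _check_levels(sub, spec)
        X = build_design(sub, spec.terms)
        w = sub["weight"].to_numpy(float)
        w = w * (n / w.sum())
        model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
        res = model.fit(cov_type="HC0", maxiter=200)
        beta = np.asarray(res.params)
        if not np.all(np.isfinite(beta)) or (
            check_separation and np.abs(beta).max() > 15.0
        ):
            worst = spec.terms[int(np.nanargmax(np.abs(beta)))]
            raise SeparationError(
                f"quasi-complete separation suspected in stratum {spec.stratum}; "
                f"term {worst!r} has coefficient {beta[np.argmax(np.abs(beta))]:.2f}"
            )
        cov = np.asarray(res.cov_params())
        cov = (cov + cov.T) / 2.0
        fits[spec.stratum] = BiasModelFit(spec, beta, cov, n)
    return fits


@dataclass
class AccuracyReport:
    """Holdout classification accuracy, per stratum and pooled."""

    per_stratum: dict[Stratum, float]
    overall: float
    replicates: list[float]
    replicate_range: tuple[float, float]
    excluded_replicates: int = 0


def _ridge_logistic(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, lam: float = 1e-6
) -> np.ndarray:
    """Weighted logistic fit with a vanishing ridge penalty.

    Used for holdout classification only. On regular data the penalty is
    numerically irrelevant; on separable data it keeps the solution finite
    and the decision boundary near the max-margin split, instead of the
    arbitrary direction a saturated unpenalised fit wanders into.
    """
    from scipy.optimize import minimize

    wn = w / w.sum()

    def nll_grad(beta):
        eta = X @ beta
        p = expit(eta)
        nll = -float(np.sum(wn * (y * eta - np.logaddexp(0.0, eta))))
        grad = -X.T @ (wn * (y - p)) + lam * beta
        return nll + 0.5 * lam * float(beta @ beta), grad

    res = minimize(nll_grad, np.zeros(X.shape[1]), jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    return res.x


def holdout_accuracy(
    exam: pd.DataFrame,
    spec_set: list[BiasModelSpec],
    k: int = 10,
    frac: float = 0.2,
    seed: int = 0,
    threshold: float = 0.5,
) -> AccuracyReport:
    """Repeated random-holdout prediction accuracy of the stage-1 models.

    For each of ``k`` splits a fraction ``frac`` of the examination sample is
    held out, models are refit on the remainder, and held-out individuals are
    classified as uncontrolled when the predicted probability reaches
    ``threshold``. Accuracy is the proportion correctly classified. Refits
    use the ridge-stabilised classifier (see ``_ridge_logistic``) so
    separable training splits still yield well-placed boundaries.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    y_all = (exam["sbp"].to_numpy(float) >= 140.0).astype(int)
    replicates: list[float] = []
    excluded = 0
    per_stratum_hits: dict[Stratum, list[int]] = {s.stratum: [0, 0] for s in spec_set}
    n = len(exam)
    for _ in range(k):
        holdout = rng.random(n) < frac
        train, test = exam.loc[~holdout], exam.loc[holdout]
        empty = [
            s.stratum for s in spec_set if not stratum_mask(train, s.stratum).any()
        ]
        if empty:
            logger.warning("holdout replicate excluded: empty strata %s", empty)
            excluded += 1
            continue
        correct = total = 0
        for spec in spec_set:
            tr = train.loc[stratum_mask(train, spec.stratum)]
            beta = _ridge_logistic(
                build_design(tr, spec.terms),
                (tr["sbp"].to_numpy(float) >= 140.0).astype(float),
                tr["weight"].to_numpy(float),
            )
            mask = stratum_mask(test, spec.stratum)
            if not mask.any():
                continue
            p = expit(build_design(test.loc[mask], spec.terms) @ beta)
            pred = (p >= threshold).astype(int)
            hits = int((pred == y_all[holdout][mask]).sum())
            per_stratum_hits[spec.stratum][0] += hits
            per_stratum_hits[spec.stratum][1] += int(mask.sum())
            correct += hits
            total += int(mask.sum())
        replicates.append(correct / total)
    if not replicates:
        raise EmptyStratumError("every holdout replicate was excluded")
    per_stratum = {
        s: (h / t if t else float("nan")) for s, (h, t) in per_stratum_hits.items()
    }
    pooled = sum(h for h, _ in per_stratum_hits.values()) / sum(
        t for _, t in per_stratum_hits.values()
    )
    return AccuracyReport(
        per_stratum=per_stratum,
        overall=pooled,
        replicates=replicates,
        replicate_range=(min(replicates), max(replicates)),
        excluded_replicates=excluded,
    )


@dataclass
class ImputedDataset:
    """One posterior-predictive completion of the telephone survey."""

    m: int
    records: pd.DataFrame  # phone records + 'uncontrolled' column
    coefficient_draws: dict[Stratum, np.ndarray] = field(repr=False, default=None)


def impute_uncontrolled(
    phone: pd.DataFrame,
    fits: dict[Stratum, BiasModelFit],
    M: int = 10,
    seed: int = 0,
) -> list[ImputedDataset]:
    """Posterior-predictive multiple imputation of uncontrolled status.

    Per imputed dataset and stratum one coefficient vector is drawn from
    MVN(beta_hat, Sigma_hat); each record's uncontrolled indicator is then a
    Bernoulli draw at its predicted probability. The drawn coefficients are
    kept on the dataset for audit.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    phone = phone.copy()
    if "wave" not in phone.columns:
        wave_levels = next(iter(fits.values())).spec.wave_levels
        wave_map = {
            int(y): wave_for_year(int(y), wave_levels)
            for y in phone["year"].unique()
        }
        phone["wave"] = phone["year"].map(wave_map)

    masks = {}
    covered = np.zeros(len(phone), dtype=bool)
    for stratum in fits:
        masks[stratum] = stratum_mask(phone, stratum)
        covered |= masks[stratum]
    if not covered.all():
        raise ValueError(
            f"{int((~covered).sum())} phone records map to no fitted stratum"
        )

    out = []
    for m in range(1, M + 1):
        flags = np.zeros(len(phone), dtype=int)
        draws: dict[Stratum, np.ndarray] = {}
        for stratum, fit in fits.items():
            beta = rng.multivariate_normal(
                fit.coefficients, fit.covariance, method="svd"
            )
            draws[stratum] = beta
            mask = masks[stratum]
            if not mask.any():
                continue
            p = fit.predict_proba(phone.loc[mask], coefficients=beta)
            flags[mask] = (rng.random(int(mask.sum())) < p).astype(int)
        rec = phone.drop(columns=["wave"]).copy()
        rec["uncontrolled"] = flags
        out.append(ImputedDataset(m=m, records=rec, coefficient_draws=draws))
    return out
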