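"""Explicit term-list design matrices shared by the generator and stage-1 fits.

The same term grammar drives both the synthetic truth model and the fitted
logistic models, so coefficient-recovery comparisons are exact by construction
(no hidden coding differences). Supported terms:

``"1"``
    intercept column of ones.
``"age_c"`` / ``"age_c2"``
    centred-and-scaled age, ``(age - 55) / 10``, and its square.
``"bmi_c"``
    centred-and-scaled body-mass index, ``(bmi - 28) / 5``.
``"insured"``
    0/1 health-insurance indicator.
``"medicated"``
    0/1 current antihypertensive-medication indicator.
``"race[level]"``
    dummy for ``race == level`` (reference level simply omitted).
``"medicated:wave[level]"``
    medication x survey-wave interaction dummy, the time-varying
    medication-effect encoding.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy.special import expit as _sp_expit

AGE_CENTER = 55.0
AGE_SCALE = 10.0
BMI_CENTER = 28.0
BMI_SCALE = 5.0

_RACE_RE = re.compile(r"^race\[(.+)\]$")
_MEDWAVE_RE = re.compile(r"^medicated:wave\[(.+)\]$")


class UnknownTermError(ValueError):
    """A term string that the design grammar does not recognise."""


def term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    """Return the design column for one term as a float array."""
    n = len(df)
    if term == "1":
        return np.ones(n)
    if term == "age_c":
        return (df["age"].to_numpy(float) - AGE_CENTER) / AGE_SCALE
    if term == "age_c2":
        a = (df["age"].to_numpy(float) - AGE_CENTER) / AGE_SCALE
        return a * a
    if term == "bmi_c":
        return (df["bmi"].to_numpy(float) - BMI_CENTER) / BMI_SCALE
    if term == "insured":
        return df["insured"].to_numpy(float)
    if term == "medicated":
        return df["medicated"].to_numpy(float)
    m = _RACE_RE.match(term)
    if m:
        return (df["race"].to_numpy() == m.group(1)).astype(float)
    m = _MEDWAVE_RE.match(term)
    if m:
        return df["medicated"].to_numpy(float) * (
            df["wave"].to_numpy() == m.group(1)
        ).astype(float)
    raise UnknownTermError(f"unrecognised design term: {term!r}")


def build_design(df: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Stack term columns into an (n, p) design matrix, in term order."""
    if not terms:
        raise ValueError("empty term list")
    return np.column_stack([term_column(df, t) for t in terms])


def linear_predictor(df: pd.DataFrame, coefficients: dict[str, float]) -> np.ndarray:
    """Logit-scale linear predictor for a term -> coefficient mapping."""
    eta = np.zeros(len(df))
    for term, beta in coefficients.items():
        eta += beta * term_column(df, term)
    return eta


def expit(eta: np.ndarray) -> np.ndarray:
    return _sp_expit(np.asarray(eta, float))
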