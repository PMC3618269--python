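"""Outcome taxonomy: hypertensive population, awareness, treatment, control.

An individual belongs to the hypertensive population when their (measured or
imputed) systolic BP is uncontrolled (>= 140 mm Hg) and/or they currently
take antihypertensive medication. Within that population the outcomes nest:

    controlled => treated => aware => in population

* aware: in population and previously diagnosed;
* treated: aware and currently medicated;
* controlled: treated and not uncontrolled (SBP < 140 on medication).

Self-reported hypertension — previous diagnosis regardless of measurement —
is carried alongside as its own indicator for comparison with the
bias-corrected total prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class OutcomeFlags:
    in_population: bool
    aware: bool
    treated: bool
    controlled: bool


def classify(diagnosed: bool, medicated: bool, uncontrolled: bool) -> OutcomeFlags:
    """Classify one individual into the nested outcome taxonomy."""
    if medicated and not diagnosed:
        raise ValueError("medicated without previous diagnosis: upstream data bug")
    in_pop = bool(uncontrolled or medicated)
    aware = in_pop and bool(diagnosed)
    treated = aware and bool(medicated)
    controlled = treated and not bool(uncontrolled)
    return OutcomeFlags(in_pop, aware, treated, controlled)


def classify_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised classification; returns df plus the four outcome columns.

    Requires integer/boolean columns diagnosed, medicated, uncontrolled.
    """
    diag = df["diagnosed"].to_numpy(bool)
    med = df["medicated"].to_numpy(bool)
    unc = df["uncontrolled"].to_numpy(bool)
    if np.any(med & ~diag):
        raise ValueError("medicated without previous diagnosis: upstream data bug")
    out = df.copy()
    out["in_population"] = (unc | med).astype(int)
    out["aware"] = ((unc | med) & diag).astype(int)
    out["treated"] = ((unc | med) & diag & med).astype(int)
    out["controlled"] = ((unc | med) & diag & med & ~unc).astype(int)
    return out
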