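"""Validation framework: pooled gold standard, CCC, and RMSE by bin.

Builds a pooled multi-year direct gold standard from phone-style records,
compares a deliberately noisy 'model' and the raw single-year baseline
against it, stratified by county sample size, and prints the plain-text
report.
"""

import numpy as np
import pandas as pd

from countybp import (
    concordance_correlation,
    pooled_gold_standard,
    single_year_direct,
    validate_by_sample_size,
)
from countybp.validation import summary_text

rng = np.random.default_rng(3)
rows = []
for county in range(40):
    p = rng.uniform(0.2, 0.5)
    n_per_year = int(rng.choice([8, 12, 60, 120]))
    for year in (2001, 2002, 2003):
        flags = rng.random(n_per_year) < p
        rows += [
            {"county_id": county, "year": year, "hit": float(f), "weight": 1.0}
            for f in flags
        ]
records = pd.DataFrame(rows)

gold = pooled_gold_standard(records, "hit", (2001, 2003), min_n=20)
direct = single_year_direct(records, "hit", 2002)
model = gold[["county_id"]].assign(
    proportion=gold["proportion"] + rng.normal(0, 0.015, len(gold))
)
reports = validate_by_sample_size(
    model, gold, direct, bins=[(0, 15), (15, np.inf)]
)
print(summary_text(reports, title="model vs single-year direct, by per-year county n"))
print()
print(f"worked CCC example: x=(0,1), y=(1,2) -> {concordance_correlation([0,1],[1,2]):.4f}")
# CCC penalises location shifts as well as scatter: the (0,1)/(1,2) pair is
# perfectly correlated but offset by 1, so its concordance is only 1/3.
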