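"""Stage 2: hierarchical shrinkage beats raw county estimates at n = 10.

Samples only 10 interviews per county-year from a 100-county world, fits
the spatio-temporal grouped-logistic model, and scores model and raw
single-year direct estimates against the population truth. The
hierarchical model borrows strength across neighbours and years, so its
error collapses where the direct estimate is hopeless.
"""

from countybp.experiments import shrinkage_experiment

result = shrinkage_experiment(seed=42)
print("county-year estimates vs population truth (100 counties, n=10/county-year)")
print(f"  model  CCC: {result.model_ccc:6.3f}   RMSE: {result.model_rmse:.3f}")
print(f"  direct CCC: {result.direct_ccc:6.3f}   RMSE: {result.direct_rmse:.3f}")
print(f"  model wins on both metrics: {result.model_wins}")
# RMSE of a direct estimate at n=10 is ~ sqrt(p(1-p)/10) ~ 0.12; the model's
# posterior means shrink toward the (spatially smoothed) mean and typically
# cut that error by a factor of 4-5 while correlating better with the truth.
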