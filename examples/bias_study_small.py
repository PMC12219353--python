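"""A reduced bias study: how estimated treatment effects on PIRA drift from
the truth as the treatment's effect on relapses grows.

Scaled down (150/arm, 10 replicates, three reduction levels) to run in
about a minute; the full study conditions are 800/arm with 200 replicates.
"""

from pirabias import scenario_a
from pirabias.study import report, run_study

results = run_study(
    {"A": scenario_a(n_per_arm=150, n_replicates=10, master_seed=99)},
    relapse_reductions=[0.0, 0.4, 0.8],
    definitions=("standard1", "non_raw", "ric"),
    n_boot=500,
)
hr = results[results.measure == "HR"]
print(hr[["definition", "relapse_reduction", "true_point", "estimated_point", "bias"]]
      .round(3).to_string(index=False))
paths = report(results, "scratch/bias_small")
print("\nwrote:", *[p.name for p in paths])
print(
    "\nAt 0% relapse reduction every definition is unbiased; by 80% the "
    "conservative standard1 rule discards so many control-arm PIRA events "
    "that the estimated hazard ratio drifts far above the truth."
)
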