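"""Build a hot-deck imputation pool on a simulated survey.

Simulates a small survey with one 4-level stratifier, indexes donor groups,
and fills the missing target cells 200 times.  The pool -- 200 completed
copies of the variable -- is the population from which replicate MI samples
are later drawn.
"""

import numpy as np

import miomega as mo

strat = mo.StratifierSpec("G", (1, 2, 3, 4), (0.25, 0.25, 0.25, 0.25))
target = mo.TargetSpec("Y", 1, 30, missing_fraction=0.1)
spec = mo.SyntheticSpec(400, (strat,), (target,), seed=11)
data = mo.generate_survey(spec)
print(f"survey: {data.n_records} records, {data.n_missing('Y')} missing Y cells")

index = mo.build_donor_groups(data, "Y", ["G"])
sizes = {k: len(v) for k, v in index.groups.items()}
print(f"donor groups by stratum: {sizes}")

pool = mo.hotdeck_impute_pool(data, "Y", index, M=200, seed=5)
rec = int(pool.missing_indices[0])
vals = pool.completed[rec]
print(f"pool: M={pool.M} completed copies of Y")
print(f"record {rec} (missing, stratum {data.data['G'][rec]}) was imputed with "
      f"{len(set(vals))} distinct donor values; mean {np.mean(vals):.2f}")
print("Observed cells are identical in every copy; only the imputed cells vary,")
print("and every imputed value is an observed value from the matching donor group.")
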