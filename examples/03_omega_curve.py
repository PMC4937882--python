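"""Measure the m-omega curve: how the accuracy of B improves with m.

For each m on a grid, draw n=10 replicate MI samples from a pool whose
per-imputation means are i.i.d. normal, compute the between-imputation
variance B of each, and summarise the spread: omega = SE of B over the
replicates.  Because B is a scaled chi-square with m-1 degrees of freedom,
omega should fall roughly like 1/sqrt(m-1).
"""

import numpy as np

import miomega as mo

rng = np.random.default_rng(0)
pool = mo.ImputationPool.from_columns(rng.standard_normal((4, 500)),
                                      variable_name="demo")
plan = mo.ReplicationPlan(m_grid=(2, 3, 5, 10, 20, 40, 80), n=10, seed=0)
curve = mo.build_omega_curve(pool, plan)

print(curve.to_frame().round(4).to_string(index=False))
print()
ratio = curve.omega[0] / curve.omega[-1]
print(f"omega shrinks {ratio:.0f}-fold from m=2 to m=80: a B estimated from")
print("2 imputations is extremely noisy, and the gain per extra imputation")
print("tapers off -- the shape both eta decision rules exploit.")
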