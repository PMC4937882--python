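"""The whole experiment end to end on a simulated workflow survey.

Simulate 2567 survey records (five targets, three donor-group stratifiers),
build an M=500 hot-deck pool per target, run the 13-point replication design
with n=10 samples per m, and decide eta by both rules.  Every artifact
(pools, curves, decision worksheets, summary) lands under scratch/pipeline/.
"""

import logging

import miomega as mo

logging.basicConfig(level=logging.INFO, format="%(message)s")

cfg = mo.RunConfig(seed=7, outdir="scratch/pipeline")
res = mo.run_pipeline(cfg)

print()
print("eta by variable and method:")
print(res["summary"].to_string())
print()
print("B magnitudes differ hugely across variables (the targets span 2-level")
print("codes to 0-99 counts) but each m-omega curve has the same falling,")
print("flattening shape, so both rules land in the tens of imputations --")
print("well above the classical 2-5 recommendation.")
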