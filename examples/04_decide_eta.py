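"""Decide eta on the bundled practice-size worksheet, both ways.

The bundled reference worksheet (13 m values, n=10 replicates per m, pool of
500 hot-deck imputations of a 5-category practice-size survey variable)
summarises a published replication experiment.  The moving-regression rule
asks when the omega curve flattens (|RS5| < 10, with an outlier-averaging
safeguard); the confidence-interval rule asks when the 95% CI for B_bar is
narrow relative to B_bar (P < 15).
"""

import miomega as mo

curve = mo.load_practice_size_worksheet()

mr = mo.decide_eta_moving_regression(curve, h=3, cutoff=10.0)
print("moving regression worksheet (S5 = omega drop per 5 imputations,")
print("RS5 = S5 as % of the window's mean omega):")
print(mr.worksheet.round(4).to_string(index=False))
for ev in mr.outlier_events:
    print(f"outlier omega at m={ev['o_m']}: averaged RS5 = {ev['average']:.2f} "
          f"-> {'accepted' if ev['accepted'] else 'rejected, keep scanning'}")
print(f"eta (moving regression, cutoff |RS5|=10): {mr.eta}")
print()

ci = mo.decide_eta_ci(curve, cutoff=15.0)
print("confidence interval worksheet (P = 100 * half CI width / B_bar):")
print(ci.worksheet.round(3).to_string(index=False))
print(f"eta (confidence interval, cutoff P=15): {ci.eta}")
print()
print("Same curve, two defensible answers (60 vs 40): the 'sufficient' m")
print("depends on the chosen criterion, not only on the data.")
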