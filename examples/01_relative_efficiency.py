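"""Rubin's relative efficiency: why 2-5 imputations looks like enough.

RE = (1 + gamma0/m)^(-1/2) measures, in standard-error units, how close an
m-imputation analysis gets to the infinite-imputation ideal.  Even with half
the information missing (gamma0 = 0.5), three imputations already give
RE ~ 0.93 -- the classical argument for small m that the omega-based
procedures in this package re-examine.
"""

import miomega as mo

for gamma0 in (0.2, 0.5):
    row = ", ".join(
        f"m={m}: {mo.relative_efficiency(gamma0, m):.4f}" for m in (2, 3, 5, 20, 100)
    )
    print(f"gamma0={gamma0}:  {row}")

print()
print("RE climbs toward 1 quickly in m: judged by RE alone, a handful of")
print("imputations suffices.  The point of the omega curve is that the")
print("*between-imputation variance* B is far less stable than RE suggests.")
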