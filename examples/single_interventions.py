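"""Minimum effective doses of the four single interventions.

A dose D scales a production ceiling by (1-D) or a removal rate by (1+D),
permanently from the start month.  Success means a final amyloid burden
A(27) <= 100 pg/mg — under 1/20 of the untreated level.
"""

from abkinetics import KineticParams, min_effective_dose

base = KineticParams()

print("minimum effective dose at t_start = 1 mo (threshold A(27) <= 100):")
for name in ("V1", "V1p", "k2", "k2p"):
    res = min_effective_dose(base, name, t_start=1.0)
    print(f"  {name:4s}: {res}")

print("\nstart-time dependence for the V1 intervention:")
for t0 in (1.0, 5.0, 10.0, 15.0):
    res = min_effective_dose(base, "V1", t_start=t0)
    print(f"  start {t0:4.0f} mo: min dose {res.min_dose:.2f}")

print("\nDampening either feedback ceiling (V1, V1') or boosting Aβ "
      "removal (k2) can succeed; boosting X removal (k2') cannot within "
      "its cap. Later starts need sharply higher doses — successful "
      "treatment must begin early and continue for life.")
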