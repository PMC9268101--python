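"""Activity arithmetic: conversions, potency classes, error factors, costs.

Reproduces the kind of bookkeeping used in antagonist-design tables:
pIC50 conversions, the four-class potency scale, signed experimental/
estimated error factors and pharmacophore cost-difference banding.
"""

from qsarligand.activity import (
    classify_activity,
    cost_summary,
    error_factor,
    ic50_from_pic50,
    pic50_from_ic50,
)

rows = [(0.43, 0.63), (0.7, 1.7), (20.7, 37.0), (684.0, 180.0)]
print("IC50_exp  IC50_est  pIC50_exp  class  error_factor")
for exp, est in rows:
    print(
        f"{exp:8.2f}  {est:8.2f}  {pic50_from_ic50(exp):9.3f}  "
        f"{classify_activity(exp):5s}  {error_factor(exp, est):+8.2f}"
    )

print(f"\npIC50 0.20 -> IC50 {ic50_from_pic50(0.20):.2f} uM")

cs = cost_summary(fixed=105.134, null=215.593, total=123.676)
print(
    f"cost difference = {cs.cost_difference:.3f} bits -> band {cs.band} "
    "(null-minus-total above 60 bits indicates a strongly correlated "
    "hypothesis)"
)
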