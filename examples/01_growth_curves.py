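"""Evaluate the four growth functions at a few ages.

Builds one parameter set per model for a large ray (asymptotic disc width
around 145 cm) and prints predicted disc width at selected ages.  All four
curves rise monotonically to the asymptote; the two-parameter von
Bertalanffy passes through the fixed size at birth (25 cm here).
"""

from raygrowth import GrowthParams, predict_size

curves = {
    "vbgf": GrowthParams("vbgf", w_inf=137, k=0.17, t0=0.68),
    "vbgf2": GrowthParams("vbgf2", w_inf=145, k=0.13, w0=25),
    "logistic": GrowthParams("logistic", w_inf=128, k=0.43, w0=25),
    "gompertz": GrowthParams("gompertz", w_inf=131, k=0.29, w0=25),
}

ages = [0, 1, 5, 10, 20, 40]
print("age(yr)  " + "  ".join(f"{m:>9}" for m in curves))
for age in ages:
    row = "  ".join(f"{predict_size(p, age):9.1f}" for p in curves.values())
    print(f"{age:7.0f}  {row}")
print("\nEach column is one model's predicted disc width (cm); every curve")
print("approaches its own asymptotic width as age grows.")
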