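"""Compare the multiplicative and logistic penetrance models.

Prints P(disease | k causative mutations) for the four parameterisations of
the study grid.  The multiplicative model leaves mutation-free individuals
unaffected and rises steeply; the logistic model has a non-zero baseline
risk and tolerates a few mutations before the risk takes off.
"""

from coalor.penetrance import PRESETS, disease_probability

ks = list(range(0, 11))
print("k   " + "".join("%22s" % name for name in PRESETS))
for k in ks:
    row = "".join(
        "%22.4f" % disease_probability(model, k) for model in PRESETS.values()
    )
    print("%-4d%s" % (k, row))

print(
    "\nUnder multiplicative penetrance P(0)=0, so every case carries a "
    "mutation; under logistic penetrance the baseline risk 1/(1+e^5)=0.0067 "
    "means cases exist even without mutations, diluting the case-control "
    "contrast of any single mutation."
)
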