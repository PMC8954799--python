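"""Bioindication verdicts from the published coefficient table.

Loading the printed coefficient columns with their significance stars and
running the verdict rules reproduces the study's conclusion: the plant can
bioindicate Cd and Cr (own dose term significant and positive, any
interference smaller than the own effect) but not Pb, Cu or Zn.
"""

from phytodoe import RSMFit, classify, summary_markdown
from phytodoe import reference as R

verdicts = []
for metal in R.RESPONSE_METALS:
    fit = RSMFit.from_published(metal, R.FACTOR_NAMES,
                                R.COEFFICIENTS[metal], R.STARS[metal])
    own = metal if metal in R.FACTOR_NAMES else None
    verdicts.append(classify(fit, own))

print(summary_markdown(verdicts))
print()
for v in verdicts:
    if v.evidence:
        lead = v.evidence[0]
        print(f"{v.metal}: decisive term {lead['term']} "
              f"(estimate {lead['estimate']:+g}{lead['stars']}, {lead['role']})")
# Cd and Cr carry the 'minor interference' label: one small foreign term is
# significant but stays below the own dose effect in magnitude.
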