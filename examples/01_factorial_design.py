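"""Build the replicated full-factorial dosing design.

Three metals (Cd, Pb, Cr) varied over three nutrient-solution levels give
3^3 = 27 growth experiments; three independent pots per run give 81 plant
samples. The coded scale maps each factor's low level to -1 and high to +1;
because the high level is twice the central one, the central level codes
slightly below 0 rather than exactly to it.
"""

from phytodoe import coded_central, full_factorial, replicate_design
from phytodoe import reference as R

design = full_factorial(list(R.FACTORS))
replicated = replicate_design(design, 3)

print(f"unique runs: {design['run_id'].nunique()}")
print(f"replicated rows (plant samples): {len(replicated)}")
print("coded central levels (the design's 'urban soil' points):")
for f in R.FACTORS:
    print(f"  {f.name}: {f.central} uM -> {coded_central(f):+.4f}"
          f"  (rounds to {round(coded_central(f), 2):+.2f})")
print()
print(replicated.head(6).to_string(index=False))
print("...")
# Each coded column spans -1..+1; *_uM columns carry the actual medium
# concentrations a technician would prepare.
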