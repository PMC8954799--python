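# phytodoe

Design-of-experiment modelling of plant trace-metal **bioindication**: can a
plant's shoot concentration of a metal be read as a proxy for the metal's
concentration in the growing medium, even when several metals are present at
once?

The package implements the full modelling chain used to answer that question
for *Polygonum aviculare* grown hydroponically with Cd, Pb and Cr dosed at
three soil-realistic levels each (countryside / urban / heavily polluted),
while Cu and Zn stayed at the nutrient-solution background:

- **`design`** — factors with natural (µM) and coded levels, replicated
  full-factorial designs (`L^F` runs; here 3³ = 27 runs × 3 pots = 81
  samples). Coding maps low → −1 and high → +1; the central levels land at
  −0.08, −0.07 and −0.18 because the high dose is twice the central one.
- **`rsm`** — the 10-term quadratic response-surface model per response
  metal, fitted by OLS on the coded design:

  `y = b₀ + Σᵢ bᵢxᵢ + Σᵢ<ⱼ bᵢⱼxᵢxⱼ + Σᵢ bᵢᵢxᵢ² + ε`

  with standard errors from `s²(XᵀX)⁻¹`, two-sided Student-t p-values and
  the conventional star labels.
- **`surfaces`** — predicted-response and 95% confidence-semiamplitude
  grids over two factors (third fixed), iso-response contours, and the
  mask of the region significantly different from zero.
- **`bioindication`** — verdict rules: a metal is a bioindicator when its
  own linear dose term is significant and positive and no foreign term
  rivals it in magnitude.
- **`aas`** — the analytical chain from AAS peak areas to mg/kg dry
  tissue: calibration lines, blank subtraction, LoD, dilution, the
  100 mg / 4 mL digest arithmetic, spike-recovery (90–110%) and control
  (95–105%) QC windows.
- **`simulate`** — a synthetic-data generator whose ground truth is the
  published coefficient table, used to exercise and validate every stage
  (the study's raw replicate table is not publicly deposited).
- **`pipeline` / `phytodoe` CLI** — the end-to-end driver.

## Worked example

```python
from phytodoe import simulate_study, fit_rsm, report_frame, classify

design, uptake = simulate_study(seed=7)   # 27 runs x 3 replicates, 5 metals
fit = fit_rsm(design, uptake["Cd"].to_numpy(), response="Cd")
print(report_frame(fit).head(4).to_string(index=False))
print(classify(fit, "Cd").status.value)
```

prints (abridged):

```
symbol      term  estimate      se       t         p stars
    b0 Intercept     3.189 0.08188   38.95 1.178e-49   ***
    b1        Cd    0.8579 0.03716   23.09  9.88e-35   ***
    b2        Pb    0.1247 0.03716   3.355  0.001278    **
    b3        Cr  0.001975 0.03708 0.05324    0.9577
bioindicator_minor_interference
```

The intercept (≈3.1 mg/kg) is the predicted shoot Cd at the coded origin;
the strongly significant, positive `b1` says shoot Cd tracks medium Cd, and
the verdict is positive because every significant foreign term stays smaller
than that own effect. The `examples/` directory walks through each
capability (design, fitting, surfaces, verdicts, AAS quantification) as a
short runnable script.

A full run of the published design on simulated data, with figures:

```sh
phytodoe reproduce-paper --seed 0 --out reproduction
```

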