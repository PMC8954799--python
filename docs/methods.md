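# Methods

## The experiment being modelled

A bioindicator plant is one whose shoot concentration of an element rises
(ideally linearly) with the element's concentration in the substrate, so
the plant can be read as a passive sampler of soil pollution. Whether that
holds in a *polymetallic* medium — where one metal's uptake may be enhanced
or suppressed by the others — is a question about interactions, and a full
factorial design is the canonical instrument for it.

The reference setting is hydroponic: *P. aviculare* grown in half-strength
Hoagland's solution with Cd, Pb and Cr dosed at three levels each, chosen
to represent countryside, urban and heavily polluted soil (Cd
0.0100/0.0700/0.140 µM; Pb 1.83/14.5/29.0 µM; Cr 6.92/23.1/46.2 µM). Cu
(0.5 µM) and Zn (2 µM) are nutrient-solution constants and appear only as
responses. 3³ = 27 level combinations × 3 independent pots = 81 plant
samples; the five shoot metal concentrations (mg/kg dry weight, by
graphite-furnace AAS) are the responses.

## Level coding

Each factor is coded affinely: low → −1, high → +1, i.e.
`x = (c − (lo+hi)/2) / ((hi−lo)/2)`. The high dose is twice the central
one, so the central level is *not* the midrange and codes to −0.0769, −0.0674
and −0.1762 for Cd, Pb, Cr (−0.08, −0.07, −0.18 at two decimals). Design
tables always store this true coded value at full precision; rounding is a
reporting concern, and snapping the central level to 0 (`with_central_at_zero`)
is a display convention used only to mimic the conventional figure layout
where the held factor sits "at level 0". Fitting on the true coded values
keeps the model faithful to the actual concentrations.

## The quadratic response-surface model

Per response, `y = b₀ + Σbᵢxᵢ + Σᵢ<ⱼbᵢⱼxᵢxⱼ + Σbᵢᵢxᵢ² + ε` with the fixed
column order `[1, x₁, x₂, x₃, x₁x₂, x₁x₃, x₂x₃, x₁², x₂², x₃²]` and symbols
`b0…b33` (factor 1 = Cd, 2 = Pb, 3 = Cr). Fitting is OLS via a stable
least-squares solve; rank deficiency raises an error naming the dependent
columns rather than silently pseudo-inverting (a 2-level design, for
example, cannot separate the intercept from the squared terms). The fit is
computed on all replicate observations by default (dof = 81 − 10 = 71), so
replication contributes pure-error information to the residual variance; a
`run_means=True` option averages replicates first. Inference is classical:
`se = s·sqrt(diag((XᵀX)⁻¹))`, two-sided Student-t p-values, stars at
0.05/0.01/0.001, no multiple-testing correction across the 10 terms × 5
models (matching field practice for DoE coefficient tables). Coefficients
are reported on the coded scale, where magnitudes are directly comparable
across factors; a natural-unit back-transformation exists as an
interpretation helper.

## Surfaces and the confidence semiamplitude

Surfaces evaluate the model on an `r × r` lattice (default 41 × 41,
node-centred on [−1, +1]) over two factors, with the remaining factor fixed
(default coded 0, per the display convention above; overridable). The
"semiamplitude" at a node is `t(1−α/2, dof) · se(ŷ)` with
`se(ŷ) = s·sqrt(x₀ᵀ(XᵀX)⁻¹x₀)` — the half-width of the confidence interval
of the *mean* response. A prediction-interval variant (adding the +1
replicate-variance term) is available but is not the default, since the
quantity of interest is the modelled mean uptake. The significance mask is
`|ŷ| > semiamplitude`, the region where the response differs from zero at
level α. The semiamplitude is minimal near the design centroid and grows
toward the corners, as prediction variance must.

## Verdict rules

The published verdicts are narrative; the classifier formalises them in
three ordered rules (own linear term significant and positive → candidate;
foreign significant terms compared in magnitude to the own effect at an
`interference_ratio` of 1.0; held-constant responses positive only if
nothing is significant). The ratio default of 1.0 encodes "interference
must not rival the dose effect": Cd passes (|−0.58| < 0.87) while Pb's
foreign terms (8.9, 5.8) dwarf its own non-significant 1.6. A candidate's
own squared term is dose-response curvature, not interference. The status
enum keeps "bioindicator" and "bioindicator with minor interference"
distinct — the reference narrative calls Cd both a "good bioindicator" and
one with a weak Cr interaction, and the distinction is worth preserving.

## AAS quantification

Peak area is the signal; blanks are subtracted before everything else, then
the calibration line (OLS through blank-corrected standard signals) maps
net area to solution concentration, the dilution factor multiplies back,
and the digest arithmetic (`c_solution × V_digest / m_sample`, default
4 mL / 100 mg) yields mg/kg dry tissue. LoD = 3·sd(blanks)/slope, falling
back to 3.3·(residual sd)/slope when fewer than three blank runs exist —
standard AAS practice; the only hard requirement enforced is LoD ≤ lowest
standard, which raises otherwise. QC windows (spike recovery 90–110%,
control solutions 95–105%) are closed intervals with a relative epsilon at
the boundaries so that an exactly-110% recovery passes despite floating
point. The 0.6 AU peak-height linearity guard is a validity flag on input
records, not signal processing; matrix modifiers are metadata. Instrument
replicates are averaged before quantification with the area sd propagated.

## Synthetic data

The generator's mean function is the quadratic surface itself (shared code
path with prediction), with the published coefficient columns as default
ground truth and additive i.i.d. Gaussian replicate noise. The reference
study reports no residual variance, so the default σ per metal is 10% of
the published intercept magnitude (Cd 0.31, Cr 0.014, Pb 0.59, Cu 0.32,
Zn 3.3 mg/kg) — small enough that the published significance pattern is
typically reproduced on refitting, which is the property the generator
exists to support. σ is a first-class knob. A lognormal option exists for
realism (concentrations are positive); zero-truncation is off by default
because it would bias the OLS-recovery tests that justify the pipeline.
One master seed drives per-response substreams derived deterministically,
so results are bit-reproducible and adding a response never perturbs the
others.

What the generator does *not* emulate: pot-to-pot biological covariance
across metals within a sample, heteroscedasticity with dose, growth
dilution, or any uptake kinetics. Passing tests therefore demonstrate that
the statistical machinery is correct under the model's own assumptions,
not that real *P. aviculare* data would satisfy them. Two consequences are
visible and deliberate: with the default small σ the whole Cd surface is
significantly non-zero (the published figure, with real replicate scatter,
shows significance only at high Cd — tests of that geometry use a larger
σ ≈ the response scale); and with σ = 10%·|b₀| some small true
coefficients that the reference table leaves unstarred come out
significant on refitting — the verdicts are robust to this because every
such term is small relative to the own effects.

The forward AAS model converts simulated tissue concentrations to digest
solutions, chooses the smallest integer dilution that keeps the reading
inside the standard range, and emits peak areas from a true line plus
noise, so the quantification chain can be validated as an exact
round-trip in the noise-free case.

## Numerical choices and problem sizes

- CSV readers use round-trip float parsing so pipeline reruns from disk are
  bit-identical to in-memory runs; the rerun-determinism contract of the
  report JSON depends on it.
- Grid coordinates come from `linspace` so that doubling the resolution
  leaves shared nodes bit-identical.
- Monte-Carlo suites (type-I error at 2000 replicates, bias/coverage at
  1000, verdict-pattern recovery at 40 seeds, bootstrap se checks at
  2000–3000) are vectorised over replicates, keeping the whole test suite
  a few seconds on one CPU; rates are asserted with seeded generators at
  the tolerances the statistics imply (e.g. a 5% rejection rate estimated
  from 2000 draws has a ±0.5% standard error).

## Known limitations

- The verdict rules are one formalisation of a narrative judgement; other
  defensible rule sets (e.g. judging interference on standardised rather
  than raw coefficients) could flip borderline cases.
- The reference text is internally inconsistent in one spot (its Pb
  narrative cites a squared-term p-value that conflicts with its own
  coefficient table); the package follows the table's star annotations.
- No lack-of-fit/pure-error decomposition is used for inference; it would
  be the natural next diagnostic for a replicated factorial.
- Natural-unit coefficients are provided for interpretation but all
  inference happens on the coded scale.
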