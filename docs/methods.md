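# Methods

## Scope and quantities

The package analyses Transwell-based absorption/metabolism assays and
connects them to clinical intestinal first-pass availability. Four
families of quantities are computed:

1. apparent permeability `Papp` (cm/s), efflux ratio, recovery and plate
   QC;
2. metabolite-formation rates (pmol/h/cm²) and derived activity
   comparisons;
3. the CES1/CES2 dominance pattern of a dual-ester prodrug;
4. clinical Fa·Fg via the well-stirred liver model, and its comparison
   with in vitro availability.

A mechanistic simulator supplies synthetic datasets with known ground
truth for all of them.

## Simulator model

Three well-mixed compartments — apical (donor or receiver), cell, basal —
exchange a parent drug and one metabolite. Amounts are pmol, volumes µL
(so amount/volume is µM directly), areas cm², permeabilities cm/s; the
unit bridge is 1 µM = 1 pmol/µL = 1000 pmol/cm³.

- **Passive diffusion.** Each membrane carries a flux
  `g · S · (C_adjacent − C_cell)` with conductance `g = 2 P`, where `P` is
  the *overall* transcellular permeability the user specifies. Two equal
  resistances in series halve the overall conductance, so assigning `2 P`
  per membrane makes the steady-state apical→basal throughput equal
  `P · S · ΔC` — the quantity a Papp assay estimates. Downstream
  `calc_papp_series` therefore recovers `passive_permeability` directly.
- **Efflux.** A saturable, unidirectional cell→apical pump
  `Jmax · S · C_cell / (Km(1 + I/Ki) + C_cell)` abstracts P-gp/BCRP.
- **Metabolism.** A saturable intracellular sink
  `Vmax · S · C_cell / (Km_m(1 + I/Ki_m) + C_cell)` produces the
  metabolite in the cell. The metabolite permeates both membranes with
  its own permeability; a separate apical-side value
  (`metabolite_apical_permeability`) can model basolateral-dominant
  export (e.g. MRP3-mediated glucuronide efflux). Inhibition of either
  process is competitive (Km scaled by `1 + I/Ki`) — adequate at a fixed
  inhibitor concentration even for mechanism-based inhibitors.
- **Sampling.** At every sample time an aliquot (`sample_volume` µL) is
  withdrawn from the receiver, by default replaced with blank buffer; the
  withdrawn amounts are carried in the mass balance and reported so that
  analysis-side corrections can be validated exactly.
- **Esterase cascade.** A second model covers a double prodrug hydrolysed
  along two branches: esterase 1 forms intermediate 1 from the parent and
  converts intermediate 2 to the active drug; esterase 2 does the
  mirror-image steps. Hydrolysis is first-order in intracellular amount
  (rates in s⁻¹), i.e. operates far below Km.

Integration uses LSODA with relative tolerance 1e-8 and absolute
tolerance 1e-10 of the dose, piecewise between sample times. States are
clipped at 0 after each segment; a negative excursion beyond 1e-9 of the
dose, or any non-finite state, raises an error naming the parameter set.
Every simulation conserves total moles to well below the 0.1% acceptance
band (observed ~1e-13 relative).

### Default geometries and conditions

| format | area (cm²) | apical (µL) | basal (µL) |
|---|---|---|---|
| EpiIntestinal-24 | 0.6 | 100 | 5000 |
| Caco2-24 | 0.33 | 200 | 800 |
| 96-well | 0.143 | 100 | 250 |

The 24-well and 96-well insert areas follow the standard polycarbonate
Transwell formats. The cell compartment volume is not directly
measurable; it defaults to 1 µL per cm² of insert area (epithelial
monolayer scale). Under sink conditions results are insensitive to it,
with one caveat: it sets the cell-loading lag
`τ ≈ V_cell / (4 P S · 1000)`, which reaches ~0.7 h at P = 1e-7 cm/s.
Low-permeability compounds are therefore sampled over 24 h (as in
practice), keeping the lag a small fraction of the regression window.

Scenario defaults mirror the assay conditions the package emulates:
10 µM donor concentration, 50 µL aliquots, triplicate wells, 10%
(permeability scenarios: 5%) lognormal measurement CV, LOQ of 0.5–1 pmol.
The noise multiplier is mean-one lognormal with
`σ² = ln(1 + CV²)`; amounts below the LOQ are flagged censored and
treated as zero in cumulative sums but excluded from regressions.

## Permeability estimation

`Papp = Q / (C0 · s · t)` with C0 converted to pmol/cm³ and t to seconds.
For time series the default estimator regresses the sampling-corrected
cumulative receiver amount on time through the origin, restricted to
quantifiable points with less than 10% of the dose transferred; when no
such window exists the fit uses all points and the result is flagged
out-of-linear-range. An `endpoint` mode applies the single-timepoint
formula at the last quantifiable point for parity with the classical
calculation. The sampling correction adds back the analyte removed in
prior withdrawals (`removed_j = amount_j · v_sample / V_receiver`), and is
exact for buffer-replaced sampling.

Residual estimator bias under the default windows is −4…−7% (donor
depletion, cell-loading lag, receiver backpressure), comfortably inside
the 10% recovery band verified in the tests. QC gates default to TEER ≥
200 Ω·cm², reference efflux ≥ 2, low-permeability marker ≤ 1e-6 cm/s and
recovery in [0.7, 1.2]; the criteria are standard, the cut-offs are a
package choice and fully configurable. A missing criterion fails closed.

## Enzyme activity

Formation rates are origin-constrained least-squares slopes of the basal
(supernatant) metabolite amount versus time, per insert area; fewer than
three quantifiable points yields a BLQ result. Intracellular metabolite
is reported as a separate percentage of total and never folded into the
rate, preserving comparability of supernatant-based rates across models.
The saturating working concentration is the lowest tested concentration
reaching 80% of the maximal observed rate (the plateau criterion is a
package choice); selecting the highest tested concentration triggers a
no-plateau warning. Cross-model comparisons report rate ratios; a BLQ
denominator yields a qualitative `> x-fold` bound instead of a number.
Michaelis–Menten Km/Vmax fitting is deliberately out of scope — the
concentration scan only selects a working concentration.

## CES classification

The three metabolites of the dual-ester prodrug are reduced to fractions
of total metabolite at the last common timepoint (AUC mode available).
The call is CES1-dominant / CES2-dominant / balanced according to whether
the CES1-path intermediate, the CES2-path intermediate or the active drug
is largest; a top-two relative gap under 10% or an all-zero profile is
indeterminate. The 10% tie margin reflects typical triplicate CVs of
such assays (tens of percent). Classification is invariant to uniform
scaling of the amounts.

For the bundled cascade scenario the balanced case uses esterase rates of
4e-3 s⁻¹ — matched to the metabolite escape rate from the cell
(metabolite permeability 1e-6 cm/s), so that roughly half of each
intermediate is converted onward before escaping. This reproduces the
qualitative patterns of interest: a 10:1 rate ratio accumulates the
corresponding intermediate (fraction ≈ 0.8 of basal metabolite), equal
rates push material through to the active drug (fraction ≈ 0.5).

## Clinical Fa·Fg chain

`CLb = CLp/RB`, `CLh = CLb(1 − fe)`, `Fh = 1 − CLh/QH` (well-stirred,
QH = 20.7 mL/min/kg, configurable), `Fa·Fg = F/Fh`. Values above 1 are
capped at 1 by default with the uncapped value retained; report
percentages are rounded to integer. Drugs whose hepatic clearance reaches
QH are flagged row-wise, not dropped. The chain assumes hepatic plus
renal elimination only and linear PK.

The packaged 12-drug clinical panel carries an `expected_match` flag:
for four drugs (midazolam, atorvastatin, rosuvastatin, irinotecan) the
published Fa·Fg percentages are not reproducible from the published
inputs via this chain (the chain gives ≈67, 28, 40 and 35 instead of 59,
61, 62 and 39); the flag makes reports surface the discrepancy rather
than assert false agreement. The in vitro counterpart is
`100 · receiver_amount(24 h) / dose`, values above 100% permitted, and
the concordance summary reports per-drug fold errors, the geometric mean
fold error and the fraction within 2-fold.

## Problem sizes and verification

The test suite exercises: mass conservation (<0.1%) for every bundled
scenario; bidirectional symmetry (<2%) without efflux; permeability
recovery at 1e-7/1e-6/1e-5 cm/s within 10% noiseless and 25% for noisy
triplicates; an efflux-inhibition titration (ratio > 2 uninhibited,
≤ 1.2 at I = 100·Ki, monotone over five inhibitor levels); CES
classification of 10:1 / 1:10 / 1:1 rate ratios in ≥90% of 20 noisy
replicates each; and exact reproduction of the concordant clinical Fa·Fg
percentages. Simulations use single wells or n ≤ 20 replicates — the
estimator variance at these sizes is already far inside the acceptance
bands, so larger designs add nothing.

## Known limitations

- No paracellular route, pH/ionization, unstirred water layer or flow;
  protein binding in the transport buffer is folded into the effective
  permeability.
- The cell is one well-mixed compartment; no apical/basolateral membrane
  asymmetry for the parent drug, no intracellular binding.
- Efflux and metabolism each collapse to a single lumped transporter /
  enzyme; inhibitors act on exactly one process.
- The media-replacement ("flow-mimicking") sampling mode is exposed via
  `replace_with_buffer` but claims no fidelity to any particular
  perfusion setup.
- Synthetic data share one noise/censoring model across analytes;
  real LC-MS/MS data have analyte-specific calibration ranges and
  heteroscedasticity beyond a constant CV. Passing the recovery tests
  therefore demonstrates estimator correctness under the stated model,
  not robustness to every bioanalytical pathology.
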