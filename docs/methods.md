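# Methods

This note documents the models, estimators and simulation design behind
`fretscreen`, the assumptions they make, and what the synthetic-data tests do
and do not demonstrate about real plate data.

## Signal model

Each well read is modelled as a linear superposition of fluorophore
contributions at the requested (excitation λx, emission λm) pair:

    I = blank
      + q_em · [ (D − E·[DA]) · exD(λx) · emD(λm) · b_D      (donor)
               +  A           · exA(λx) · emA(λm) · b_A      (direct excitation)
               +  E·[DA]      · exD(λx) · emA(λm) · b_A ]    (sensitized emission)
      + compound fluorescence(λx, λm)

where [DA] is the equilibrium donor–acceptor complex, E an apparent transfer
efficiency folding FRET efficiency and detection geometry into one number,
b_* molecular brightness (RFU/nM) and q_em a per-emission-channel compound
quench factor. Excited donors that transfer are removed from the donor
emission term and re-emitted with the acceptor's spectrum — the standard
linear picture; there is no inner-filter, photobleaching or maturation
modelling.

Default spectral templates (CFP-like donor: ex 410/430 → 1.0/0.8, em 477/527
→ 1.0/0.25; YFP-like acceptor: ex 410/430/477 → 0.05/0.08/1.0, em 527 → 1.0)
are hand-set, not fitted spectra. They reproduce two qualitative anchors of
CFP/YFP fusion pairs in this assay class: a bound pair shows roughly twice
the rFRET of its unbound control, and the three-channel unmixing removes
donor bleed-through (α = 0.25) and direct excitation (β = 0.08) exactly at
zero noise. Transfer efficiencies are 0.35 for the tight (ARC-type, K_d
35 nM, 100/200 nM) pair and 0.45 for the weaker (SAM-type, K_d 230 nM,
150/300 nM) pair; together with the noise defaults below these put the
680+680-control Z′ at 0.90 and 0.88 and keep Z′ ≥ 0.7 down to the 50/100 nM
level, matching the observed behaviour of such assays.

## Noise model

Three components, all configurable per `SimConfig`:

- **Per-well dispensing factor**, CV 2% (default). Dispensed volume scales
  every protein-derived read of a well identically, so this factor is shared
  across channels and excitations of a well and cancels exactly in
  ratiometric signals. It is the dominant term and sets the 2% CV seen by
  EmFRET titrations.
- **Per-read detection factor**, CV 0.5%. Independent per channel; the main
  noise floor of rFRET and of the dual-excitation comparison.
- **Additive floor**, SD = 0.5% of the negative control's (FRET-depleted)
  donor-channel intensity. Dominates at low signal.

The plate background (`blank_rfu`, 12 000 RFU default) is treated as a
property of the well (plate/buffer autofluorescence), not of the dispensed
volume, so it does not carry the per-well factor. This matters: a
volume-scaled background or a large fixed floor would make low-concentration
Z′ collapse, which contradicts how these ratiometric assays behave.

A deliberately simple alternative exists for statistical studies:
`simulate_titration_series` perturbs EmFRET values directly (2% CV per point
plus a floor of 0.5% of the plateau), bypassing the plate/calibration path.

## Binding model and K_d estimation

1:1 stoichiometry with ligand depletion: [DA] is the physical root of the
quadratic mass-action equation, evaluated in the cancellation-safe form
2DA/(S + sqrt(S² − 4DA)), S = D + A + K_d. The dilute approximation is not
used because donor/acceptor totals (50 nM–1.1 µM) are comparable to the K_d
values of interest.

The fit is EmFRET(A) = EmFRET_max·[DA]/D over pooled replicate points
(replicates are never averaged first — pooling preserves the error structure
for the interval). EmFRET_max is linear in the model, so it is solved
analytically at each candidate K_d (variable projection) and the 1-D profile
over log K_d is minimised to a 10⁻¹⁰ relative tolerance after coarse-grid
bracketing. Degenerate inputs: an all-zero EmFRET vector is a fit error; a
decreasing trend warns and flags the interval unreliable.

**Profile-likelihood CI.** Assuming iid Gaussian errors with the variance at
its maximum-likelihood value RSS_min/n, a log-likelihood drop of χ²₁(0.95)/2
(= 1.92) translates into the threshold RSS* = RSS_min·(1 + χ²₁/n). K_d is
profiled over a 201-point log grid spanning 100-fold either side of the
estimate; bounds are bisected between bracketing grid points to 10⁻³
relative. Unbracketed bounds are returned open and flagged (weak binders
with K_d far beyond the acceptor ladder get an open upper bound). At zero
residual the interval collapses onto the point estimate.

Monte-Carlo at K_d = 300 nM (250/500 nM totals, 23-point ladder, 4
replicates, the series-level noise model) gives 93–96% coverage over 500
repetitions — slightly under nominal because the noise is multiplicative
while the likelihood assumes homoscedasticity.

**Known limitation.** The full plate path estimates α and β from a finite
number of calibration wells; those estimates are shared by every titration
point of a plate, a per-plate systematic outside the iid error model, so
plate-path CIs undercover (the β error is amplified linearly up the acceptor
ladder). Two design mitigations are built into the generator because they are
simply correct assay design: acceptor-only calibration wells sit at the top
of the ladder, where the direct-excitation ratio is measured with the least
relative error, and eight calibration wells are used per plate. Residual
coverage on the plate path is ~80–90%, versus 93–96% at the series level.

## Quality control

Z′ and percent inhibition operate on rFRET (all reported signals in this
platform are ratiometric). Sample standard deviations (n−1) are used;
negative/positive control roles come from the plate map, and GdnHCl-treated
positive controls are ordinary wells flagged by role — the chemistry is not
modelled beyond binding being disabled. Controls are aggregated per plate,
matching plate-wise normalisation practice.

## Screen cascade

Stage thresholds follow strict inequalities ("more than 5 times", "above or
below 30%", "more than 10% difference"); the hit threshold (20%) is
inclusive. The two fluorescence criteria are one accounting stage (their
sub-flags are retained per compound). The pan-assay stage is evaluated only
on stage-1/2 survivors within each assay, using the partner assay's 410 nm
inhibition regardless of the partner's own exclusion status — which is what
makes per-assay pan counts differ. The pan "signal reduction" threshold is
set equal to the 20% hit threshold and is configurable; a compound absent
from the partner assay is marked not-evaluable and never pan-excluded.
Inhibition is reported from the 410 nm readout; 430 nm serves only the
discrepancy filter. Report percentages follow fixed conventions: exclusion
percentages to one decimal, hit rates to two, round-half-even.

## Seeded screening library

The default 1,120-compound library contains 1,072 inactives and seeded
classes chosen so every filter stage and both assays' hit calling are
exercised, with zero-noise margins of at least ~9% to each threshold:

| class | n | parameters | expected outcome |
|---|---|---|---|
| true_inhibitor_A | 10 | K_i 15 µM vs assay-A donor | hit in A (~56% inhibition at 100 µM) |
| true_inhibitor_B | 8 | K_i 40 µM vs assay-B donor | hit in B (~54%) |
| blue_fluor strong/moderate | 4+4 | +150k / +42k RFU at 477 nm | stage 1 (5× background / ±30%) |
| green_fluor strong/moderate | 3+3 | +150k / +30k RFU at 527 nm | stage 1 |
| excitation_shifted_fluor | 6 | +9k RFU (477 nm) at 410 nm ex, +30k at 430 nm ex | stage 2 (dual excitation) |
| dual_quencher gray | 5 | q = 0.5 both channels | stage 1 (±30%; rFRET itself unchanged) |
| dual_quencher chromatic | 5 | q477 = 1.0, q527 = 0.78 | stage 3 (pan-assay, both assays) |

True inhibitors are given moderate potency deliberately: a near-complete
inhibitor changes the donor-channel intensity by ~E/(1−E·f_bound) ≈ 30%+ and
would trip the ±30% deviation filter — a real failure mode of this filter
design for strong actives, worth knowing about.

Compound fluorescence and quenching scale linearly with tested concentration
(reference 100 µM), so a compound at zero dose is exactly the compound-free
well. Quenching multiplies only the protein terms, not the background.

## Dose–response and K_i

The 4-parameter logistic is fitted with lmfit; orientation (raw descending
signal vs ascending percent inhibition) is auto-detected and the anchor
controls placed two log-units beyond the tested range enter as ordinary
points. Fits with IC50 outside 100× the tested range, or flat responses, are
flagged unreliable.

The ternary equilibrium D+A⇌DA (K_d), D+I⇌DI (K_i) reduces to a single
monotone scalar equation in free donor and is solved with Brent's method;
mass balance of all three totals is asserted to 10⁻¹⁰ relative on every
call. `ic50_to_ki` returns the K_i at which the equilibrium predicts 50%
complex loss at inhibitor total = IC50 (bracketed search over [1 pM, 1 M]),
plus the Cheng–Prusoff value for comparison; at 50/100 nM probe and K_d
35 nM the two differ by a few percent, and they converge in the dilute-probe
limit.

The simulated dose–response readout is percent inhibition derived from
sensitized emission, which is linear in complex concentration — so the
logistic midpoint coincides with 50% complex loss and the round trip closes
within 1% noise-free. The generator's default dilution series brackets the
compound's expected IC50 by ±2 decades (17 points), as a real IC50
experiment is ranged; a library-wide fixed ladder leaves residual midpoint
bias up to ~1.5% because the depletion-regime competition curve is not
exactly logistic.

## Thermal shift

SYPRO-orange-type curves rise through unfolding and decline after a peak as
aggregates sequester dye; the decline breaks the Boltzmann form, so curves
are truncated at the global maximum and min–max normalised before fitting
(normalisation makes the fit invariant to affine rescaling of raw
fluorescence). Replicates are fitted independently; ΔT_m is the difference
of group means with replicate SDs propagated in quadrature (reported as
unavailable for single-replicate groups). The simulator places the
aggregation peak 12 °C past T_m with a linear decline; seeded shifts of
+0.87/+1.33/+2.94 °C emulate weak-binder and peptide-control effect sizes
and are recovered within 0.2 °C from four replicates at 1% noise.

## What the synthetic tests do not show

The generator's compound classes are clean archetypes with margins to the
filter thresholds; real libraries contain borderline interferers, so real
exclusion rates (≈12–14% at 100 µM in this assay class) are emergent
properties of the chemistry, not of the filter code, and the simulator
treats library composition as free configuration. Spatial plate artefacts
(edge effects, dispensing gradients), fluorophore maturation, inner-filter
effects and compound aggregation kinetics are not modelled; passing tests
demonstrate the correctness of the estimators and the cascade logic under
the stated noise model, not robustness to those artefacts.

## Problem sizes

Defaults used by the analysis scripts and checks: 23-point acceptor ladder ×
4 replicates per titration; 500 Monte-Carlo repetitions for CI coverage;
1,120-compound libraries on single 1536-well plates per assay and readout;
48 or 680 control wells per condition for Z′; 4 replicates per dose–response
and melt condition. These match the emulated study designs and keep every
script in the seconds-to-minutes range.
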