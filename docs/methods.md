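# Methods

## Model

A single mature duodenal enterocyte is described by 13 chemical species in
five compartments — lumen, cytoplasm and blood (3-D, sizes in litres) and
the apical and basal membranes (2-D, sizes in cm²) — connected by 19
reactions: four for DMT1 (iron import plus the endocytic cycle between the
apical membrane and a cytosolic vesicle pool), six for ferritin iron
sequestration and turnover, three for FPN export and its plasma-iron
("hepcidin") regulation, three for the IRPs arm (interconversion and
IRPs-repressed ferritin expression), and three auxiliary mass-action routes
(body sequestration of plasma iron, basal uptake, paracellular leak).

Assumptions inherited from the biology the model targets: protein synthesis
is a single lumped reaction; heme uptake, DCYTB and hephaestin are omitted
(the block occurs with ferrous iron alone); IRP1 and IRP2 are aggregated
into one two-state species; IRPs regulate only ferritin expression, not
DMT1 or FPN; hepcidin is not an explicit species — its effect is collapsed
into the FPN inactivation reaction driven by plasma iron.

### State, units and flux scaling

The ODE state is the vector of species amounts (mol). Rate laws are
evaluated on intensive values (mol/L for 3-D species, mol/cm² for the
membrane transporters) and converted to extensive fluxes (mol/s) by the
size of the compartment whose species leads the rate law: apical membrane
for the DMT1 reactions (including import), basal membrane for FPN
inactivation and export, cytoplasm for the ferritin/IRPs/fusion/activation
reactions, blood for sequestration and basal uptake, and the donor
compartment for each direction of the paracellular leak. This amount-based
formulation makes cross-compartment transport well-posed and keeps the
three transporter moieties (DMT1, FPN, IRPs totals) exactly conserved.

The di-ferric peroxo intermediate (DFP) carries two iron atoms; total iron
is computed with that weight and is conserved in any closed run. The
ferritin load `apc = amount(core)/amount(FT)` (0 when FT = 0) is clipped to
the 4300-atom cage capacity inside the mineralization saturation term, and
core release is implemented as `k_deg·core`, the algebraic simplification
of `k_deg·(core/FT)·FT`, which removes the FT → 0 singularity.

### Parameter provenance and calibration

Kinetic constants follow the published rate-law tables wherever the
printed value is dimensionally and dynamically coherent; the packaged
configuration (`src/ironblock/data/defaults.yaml`) lists them with units.
A small set of quantities could not be taken at face value — printed units
for a few constants are not self-consistent, and the compartment sizes and
initial state are not published in the main text. These were fixed by
requiring the model to reproduce the published steady-state table at the
three clamped luminal iron levels (12.5 nM / 0 M / 125 nM), which
over-determines them:

* conservation of the DMT1, FPN and IRPs totals across the table columns
  forces the membrane sizes to be numerically 1000× the cytosol volume;
  the defaults use a 1 pL cell with 100 µm² membranes;
* the steady-state identity *import flux = export flux* in both the basal
  and overload columns pins the DMT1 transport K_m to ~2.8×10⁻² M
  (printed mantissa retained: 2.835e-2);
* the DMT1 apical:cytosolic ratios of the two columns place the
  LIP-endocytosis K_m in the tens-of-µM range (default 2.805e-5, the
  printed mantissa); the steady-state table tolerates 1.2–6×10⁻⁵ M, and
  the default was chosen within that window for the best agreement with
  the published dose–depth proportionality of the block (see below);
* the FPN inactivation K_m is scaled to 122.1 nM (plasma iron never
  exceeds ~100 nM in this model, so a µM-scale threshold would make the
  hepcidin arm inert) and the FPN activation rate constant is calibrated
  to the overload column's active/inactive FPN split (1.011×10⁻⁷ s⁻¹);
* the blood volume (5.9 pL) follows from the export/body-sequestration
  balance at the printed plasma iron levels; the lumen volume (13 pL for
  the interval assay) is the one genuinely free scale — it sets how long a
  dose feeds the cell — and was chosen once to balance the published block
  phenomenology (minimum near 10 h, recovery past 95 % of control,
  approximately proportional dose–depth response).

With these choices every published steady-state quantity checked by the
test suite agrees within 5 %. The basal ferritin-core concentration is the
one clear discrepancy: the model yields 3.8 µM where the table prints
0.368 µM — but the table's own atoms-per-cage entry (1550) equals
core/FT only if core is ~3.7 µM, so the printed core value appears to be a
factor-of-10 typographical slip; the model agrees with the APC entry
within 4 %.

## Simulation engine

`solve_ivp` with LSODA (stiff/non-stiff switching), rtol 1e-8 and
per-species absolute tolerances of 1e-12 × the characteristic amount
scale. Doses are handled by stop–adjust–restart: integration halts at each
event time, the target amount jumps by the dose, and integration resumes —
no smoothing, so trajectories are continuous except exactly at events.
Clamped species ("fixed FT", clamped lumen) have their derivatives zeroed
while every flux that reads them stays active.

Steady states are computed by the nominal 5.5×10⁶ s integration followed
by continuation on doubling horizons until the scale-normalised residual
stops improving (the slowest modes — FPN and IRPs interconversion — relax
over ~10⁷ s), then a bounded Newton/least-squares polish on reduced
coordinates (one species per conserved moiety eliminated, which removes
the Jacobian null space). BDF is used for these long quasi-static runs:
LSODA's step-size control occasionally stalls near the fixed point. A
non-converged state raises rather than being returned.

`cross_integrator_check` compares the adaptive solution against a
fixed-step classical RK4 reference; the RK4 stability limit against the
~50 s⁻¹ DMT1 cycle requires h ≲ 0.02 s, so the check is run on short
segments with h = 0.01 s.

## Block assay and readout attribution

The five block characteristics are extracted from the uptake/transfer
curves over the inter-dose interval grid (argmin with first-occurrence tie
break; recovery = first grid interval at or after the uptake minimum with
uptake above 95 % of the no-loading control — the control defines
"initial value" on a curve that starts conditioned). The production grid
is 300 intervals over 0–72 h; tests and the acceptance script use 41–61
point grids, which change the value characteristics by well under 1 %.

The default readout attributes the 30-minute window increment to the test
dose by subtracting a counterfactual window without it, mirroring the
radiolabelled second dose of the in-vivo reference assay. The raw window
increment (`attribution="window"`) is also available; it folds continued
absorption of loading-dose remnants into the readout and buries the block
minimum at short intervals, which is why it is not the default.

The 72-h terminal analysis (loading dose at 0 h, test dose at 12 h) runs
with a 100 pL lumen — an in-vivo-scale reservoir that is not exhausted
within three days — while the interval assay uses the culture-scale 13 pL
lumen. This mirrors the per-experiment rescaling of the lumen
compartment that the calibration itself presumes; with the small lumen, 72-h cumulative
uptake saturates at 100 % of the dose and all parameter effects on it
vanish.

## Sensitivity analysis

Scaled coefficients `R = (ΔV/V)/(Δp/p)` with a one-sided +10 %
perturbation. Time characteristics are grid-quantised, so before
differencing each characteristic is made continuous: parabolic
interpolation of the minimum through its three neighbouring grid points,
linear interpolation of the 95 %-recovery crossing, and a locally 3×
refined interval grid around the baseline and perturbed optima. Entries
with |ΔV/V| < 0.005 are reported as negligible ("–"). The
"IRPs degradation" and "FT turnover" rows of the published table map to
the IRPs inactivation rate constant and the ferritin degradation constant
(no reactions carry those literal names); the FT-expression K_m row is
evaluated at the elevated expression rate 1.5 pM/s where its effect is
largest, following the published table's footnote.

## Synthetic calibration data and parameter recovery

The calibration observables emulate the structure of the published fitting
data — time courses of exported iron (blood + body), apical DMT1 fraction
and total cellular iron (LIP + 2·DFP + core) after a 20 µM apical dose —
sampled on a 25-point grid over 24 h with seeded Gaussian noise
(sd = 5 % of the value plus a floor of 1 % of the observable's dynamic
range). What the generator does **not** emulate: digitisation error,
inter-experiment offsets, non-Gaussian outliers and the population
heterogeneity of real cultured-cell or in-vivo measurements — so passing
recovery tests demonstrate optimiser and identifiability behaviour on this
model, not performance on real data.

Fitting is multi-start bounded weighted least squares (trust-region
reflective in log-parameter space, weights 1/sd²) on the numerical ODE
solutions; the published estimates are the packaged defaults, so
re-fitting is a recovery experiment, not re-calibration. Identifiability
is flagged from the objective's curvature along each parameter at the
optimum. The recovery checks fit two strongly identifiable constants
(DMT1 fusion and LIP-endocytosis rate constants) against three replicate
synthetic datasets with four optimiser starts — sizes chosen so the full
suite stays fast; errors at 5 % noise come out near 1 %.

## Known limitations

* With the printed DMT1 endocytosis constants (free 29.4 s⁻¹,
  LIP-modified 14.5 s⁻¹, fusion 50 s⁻¹) the apical DMT1 pool can be
  depleted by at most ~15 %, which caps the uptake-block depth at ~10 % of
  control. Published sensitivity magnitudes that imply a much deeper
  uptake block (loading dose −0.62 and DMT1 k_cat −0.37 on the minimum
  uptake value) are not reproducible under this reconstruction — the signs
  are, including the full loading-dose row.
* Iron transfer is export-capacity-limited (FPN saturates at µM LIP), so
  72-h cumulative transfer responds only weakly to DMT1 endocytosis, and
  the ferritin-expression effect on it reaches ~−18 % rather than the
  published −25 %.
* The interval-assay lumen volume trades off the published dose–depth fold
  (~3.5 at 11 pL) against the published recovery time (~24 h at 17 pL);
  the default 13 pL yields fold ≈ 3.1 and recovery ≈ 16 h.
* The hepcidin arm relaxes over ~10⁷ s; block-curve transfer dynamics are
  therefore dominated by ferritin buffering rather than FPN inactivation
  within a 72-h assay.
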