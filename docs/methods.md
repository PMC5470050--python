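# Methods

## Model

The package simulates ethanol oxidation by erythrocytes loaded with alcohol
dehydrogenase (ADH) and aldehyde dehydrogenase (ALD), with the cells' native
lactate dehydrogenase (LDH) regenerating NAD⁺ from NADH using pyruvate.  The
state couples six species — ethanol, acetaldehyde, acetate, pyruvate,
lactate, and the oxidized cofactor NAD⁺ — through three ordered bi-bi rate
laws and the pool conservation NAD + NADH = NAD₀.  NADH is always derived,
never integrated, so the cofactor balance holds to machine precision by
construction.

Assumptions inherited from the model family this implements:

- ADH and LDH are reversible ordered bi-bi; ALD is irreversible ordered
  bi-bi with dead-end NADH inhibition (K_iq).  H⁺ is omitted (the rate laws
  carry no pH term); the tabulated equilibrium constants enter only a
  reporting-grade Haldane diagnostic, never the dynamics.  The diagnostic
  reports the implied kinetic K_eq and its ratio to the tabulated value
  under both readings of the table's ambiguous "×10¹² M" scale, and the
  package never forces Haldane consistency on the constant set.
- All of glycolysis is replaced by a constant pyruvate source V_in
  (mmol/l_RBCs·h).  This is the model's defining simplification; its main
  consequence is discussed under *Known limitations*.
- One quirk of the published LDH denominator (an NADH·K_q/(K_iq·K_p) term
  where the textbook form has lactate in that position) is reproduced
  verbatim; it is numerically negligible at model concentrations but keeps
  the implementation checkable against the printed expressions.

### Compartments and units

The cofactor pool lives in cell water (µM, cell scale).  Ethanol, pyruvate,
acetaldehyde, lactate and acetate are treated as one rapidly equilibrating
pool at suspension scale: molar concentrations are taken equal across the
membrane, so the rate laws can be fed suspension-scale values directly.
Reaction fluxes are evaluated at cell scale and drain the suspension pool
multiplied by hematocrit; with hematocrit 0 the system collapses to a
single cell-free compartment.  Catalytic activities convert via
1 nkat/ml = 1 µM/s at the scale they are expressed in: an activity per ml
of *suspension* is concentrated into cell water by dividing by hematocrit
("suspension" convention, how enzymes are dosed into suspensions), whereas
loading-study activities quoted per ml of packed cells are used as cell-scale
Vmax directly ("packed_cells" convention).  This bookkeeping reproduces the
arithmetic that 30 mM of suspension ethanol oxidized in ~7 h at hematocrit
25% is ~17 mmol/l_RBCs·h.  Reverse maximal rates are tied to the forward
ones by the tabulated turnover ratio (V_r/V_f: 8.5 for ADH, 60/550 for
LDH), since only forward activities are measurable.

Externally everything is hours, mM (ethanol, acetate) and µM (the rest);
internally seconds and µM, with the conversions centralized in the model
module.

### Integration

The four chemical degrees of freedom (NAD⁺, ethanol, acetaldehyde,
pyruvate) are integrated with LSODA at rtol 1e-8 / atol 1e-10 µM, with
lactate and acetate carried as quadratures; output is evaluated on the
sampling grid (default ~36 s spacing).  The classical three-variable
closure through the conservation integrals is kept as
`integrate_reduced`, valid only without a pyruvate source, and is used as
an equivalence oracle in the tests (agreement to 1e-8 relative at
tightened tolerances).  Conservation residuals (NAD pool, alcohol mass,
and — when applicable — Pyr+Lac and the combined integral
C₀ = 2·Alc + Ald − Pyr − φ·NAD) are computed for every run and attached to
the result; under an influx the C₀ drift is checked against −∫V_in dt.
The pyruvate clamp is an algebraic hold (d(Pyr)/dt = 0 at the target),
emulating the micropump protocol without tuning a feedback controller.
Concentrations entering the rate laws are floored at zero within
integrator tolerance.

## Scenario presets

Each preset records its published conditions and, where reported, the
measured initial rate.  Where the source printed ranges (ADH 150–167
nkat/ml, hematocrit 25–27%), presets use midpoints and record the range;
where it printed nothing, the choice is documented on the preset:

- Initial ethanol for loaded-cell presets defaults to 20 mM (the plotted
  starting points; configurable).
- The intracellular pool of cells prepared without cofactor
  supplementation defaults to 9.5 µM — the value back-calculated for such
  cells — and 43 µM for NAD⁺-supplemented cells.
- The pyruvate condition of the NAD⁺-replenishment incubations is not
  printed.  Because the measured rates (2.5 and 7.3 mmol/l_RBCs·h) exceed
  the glycolysis-only ceiling of 1.8, exogenous pyruvate must have been
  present; the presets adopt the documented 100 µM maintained level of the
  micropump protocol.
- The saturating-cofactor scenario uses loading-study mid-range activities
  (ADH 925, ALD 20 mM/h per liter of cells), native LDH (33 IU/ml_RBCs),
  hematocrit 25%, NAD₀ = 1 mM, 100 µM clamped pyruvate.
- The co-loading (NAD⁺+NADH) presets have no published intracellular
  pools; they require the user to supply NAD₀ rather than guessing, and
  the 3.6-fold replenishment effect is computed from the two recorded
  experimental rates, not from simulation.

Metrics: the initial rate is the least-squares ethanol slope over the
first 30 simulated minutes (the floor of the experimental 30–60 min
sampling interval), divided by hematocrit.  "Complete" depletion is
operationalized at 99% of the starting ethanol — at or below the
practical detection floor of the perchlorate-extraction ethanol assay for
a 30 mM start — with depletion times linearly interpolated.  The
steady-state limit V_in/2 follows from quasi-steady acetaldehyde
(V_ADH = V_ALD) and the NAD balance (V_LDH = 2·V_ADH ≤ V_in).

## Inverse problems

`fit_scalar_rate` inverts the monotone map NAD₀ → initial rate by a
bracketed Brent solve after verifying monotonicity on a coarse scan of the
bracket; an observation ± is propagated through the locally linearized
inverse (sd_θ = sd_rate/|d rate/d θ|).  Rates outside the attainable range
raise an error reporting that range rather than returning a boundary
estimate.  `fit_timecourse` is bounded least squares on ethanol residuals
(the measured species; pyruvate optional) with a deterministic multi-start
(geometric midpoint plus seeded log-uniform draws, best objective wins,
lexicographic tie-break) and flags parameters whose near-optimal solutions
spread by more than 5% — the structural-confounding case of two enzymes
both far above limiting.

## Synthetic assays

`generate_timecourse` emulates the in vitro determinations: the latent
trajectory from the ODE model sampled every 30–60 min over ~5 h,
multiplicative Gaussian noise with CV 5% by default (a modeling choice
consistent in magnitude with the ± scatter reported on measured rates; no
explicit noise model was published), and a detection floor that keeps
measurements nonnegative.  Under a clamp regime the micropump's manual
regulation is mimicked by a seeded piecewise-constant ±20% jitter of the
target, one draw per sampling interval.  Every dataset records seed,
design, and latent truth, sufficient for bit-identical regeneration.

What the generator does *not* emulate: extraction/neutralization
chemistry, enzyme leakage and inactivation during storage, hemolysis, and
cell-to-cell heterogeneity of loading.  Passing recovery benchmarks on
this generator therefore demonstrates estimator correctness under the
stated noise model, not robustness to those real-world effects.

## Known limitations

- Replacing glycolysis by a constant pyruvate influx removes the
  glycolytic *demand* for NAD⁺ (glyceraldehyde-3-phosphate dehydrogenase
  competes with ADH/ALD for the same pool).  With saturating pyruvate this
  reduced model therefore over-predicts the absolute rates of the
  NAD⁺-replenishment experiments by roughly an order of magnitude, while
  reproducing their relative contrast (the simulated 43 µM / 9.5 µM rate
  ratio is 2.5–2.9 against a measured 2.9).  Consequently the back-fit of
  the intracellular pool from the measured 7.3 mmol/l_RBCs·h returns ~2 µM
  here rather than the ~44 µM obtained when the full erythrocyte
  metabolism is modeled.  Analyses that hinge on intracellular NAD⁺
  competition should treat this package's absolute rates for
  pyruvate-saturated, low-NAD₀ conditions as upper bounds.
- Kinetic constants are temperature- and pH-independent; isozyme
  differences and cofactor binding to hemoglobin are not represented.
- Acetaldehyde membrane partitioning is instantaneous; osmotic volume
  changes of loaded cells are ignored.

## Problem sizes

Default runs integrate 5–12 simulated hours on ~500–1200-point grids; the
recovery benchmark uses 8-sample courses with 50 noise replicates; the
full reproduction driver and the acceptance script each complete in
seconds on one CPU.
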