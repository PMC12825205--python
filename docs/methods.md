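# Methods

## The model

`prljag` models prolactin (PRL) signaling through JAK2/STAT3 in colorectal
cancer cells, ending in expression of the Notch ligand JAG1 on the cell
membrane. The network is a system of mass-action ODEs over 28 molecular
species and 34 labeled reaction steps (R1–R34), organized as:

* **Receptor module (R1–R6).** JAK2 binds the intracellular domain of the
  prolactin receptor to form the RJ complex (R1); PRL binds RJ (R2); two
  ligand-bound complexes pair into the signaling dimer (R3), which
  trans-activates (R4); cytosolic STAT3 docks on the active complex (R5)
  and is phosphorylated and released (R6). Phospho-STAT3 can re-bind the
  active receptor unproductively (R7, product sequestration).
* **Dimerization and nuclear transit.** Cytosolic phospho-STAT3 dimerizes
  (R8); the dimer enters the nucleus (R14), binds DNA (R24), and the
  DNA-bound dimer drives transcription.
* **Negative feedback.** Three regulatory modules return the system to
  rest: SHP2 binds and disassembles the active receptor (R9–R10); the
  cytosolic and nuclear phosphatases PPX/PPN dephosphorylate STAT3
  (R11–R12, R13, R15), which shuttles back to the cytosol (R16–R17); and
  STAT3-induced SOCS (R18–R24) binds and silences the receptor.
* **Expression cassette (R30–R34).** JAG1 mRNA is transcribed (R30),
  exported (R31), translated (R33) and the protein trafficked to the
  membrane (R34), the model's terminal readout. First-order decay steps
  for the transcript and protein pools (R26–R28, R32, and the R27
  membrane decay) are scaled by the dimensionless `deg_ratio`.

Kinetics are mass action except the two induction steps (SOCS induction,
JAG1 transcription), which saturate in the DNA-bound dimer with Michaelis
constants `k25_2`/`k30_2` — the model's only "denominator" parameters.
Exactly **49 parameters** (48 rate constants plus `deg_ratio`) are exposed
to the knockout analysis. Constant names follow the historical numbering
of this model lineage, which does not map one-to-one onto reaction labels:
`k25_1`/`k25_2` power the SOCS-induction step labeled R18, and `k30a` is
accepted as an alias of `k30_1`. R7, R26–R29 have no module assignment in
the schematic lineage; here they are, respectively, phospho-STAT3
receptor re-binding, cytosolic-JAG1 decay, membrane-JAG1 decay,
nuclear-mRNA decay and spontaneous receptor deactivation.

**Receptor dimerization stoichiometry.** An earlier encoding had one PRL
bridging two RJ complexes. That mechanism self-antagonizes at high ligand
(excess PRL singly occupies every RJ, starving dimer formation), which
produced a non-monotone dose-response, contradicting the monotone,
saturating behavior this pathway shows across gestational PRL levels. R3
therefore pairs two ligand-bound complexes (two PRL per dimer), which is
structurally monotone in dose and saturates through receptor-pool
depletion.

**Units and inputs.** Concentrations are nM, time is seconds. A PRL dose
in ng/mL is converted with the 23 kDa molar mass (1 ng/mL ≈ 0.0435 nM)
and added to the basal PRL pool at t = 0; no pre-equilibration phase is
run — the shipped initial conditions are the pre-stimulus state. Free
receptor and JAK2 pools default to zero with RJ pre-assembled (R1 inert
under the defaults), treating receptor assembly as complete before
stimulus.

**Baselines and the null-input property.** In-vitro readouts are
fold-changes over an untreated baseline, so the model's readouts are
normalized to their own t = 0 values and both baselines must be positive.
A positive basal pool that could reach DNA would, for some parameter
sets, transiently raise JAG1 without any PRL. The basal phospho-STAT3 is
therefore held as *nuclear monomer* (nuclear dimer dissociation is
irreversible, so monomers never re-form dimers), and basal JAG1 as
pre-made membrane protein with no basal mRNA. With zero PRL both readouts
are then non-increasing for **any** nonnegative parameter set — a
structural null-input guarantee, not a tuned one.

## Readouts

* `pSTAT3_total(t)`: phospho-STAT3 monomer equivalents summed over all
  phosphorylated species (dimers and the DNA-bound dimer count twice).
* `JAG1(t)`: the membrane JAG1 pool.

Both are reported as fold-change over t = 0.

## Numerical integration

The system mixes sub-minute phosphorylation with a 48-h expression arc
and is integrated with LSODA (adaptive, stiffness-switching) at rtol 1e-6
and atol 1e-9 nM, then sampled onto a uniform output grid — 60-s steps
over 0–48 h (2881 samples) by default. Sampling is interpolation only;
refining the grid does not change the solution. Negative solver
excursions are clamped to zero inside the rate laws and clipped in the
output after checking that the undershoot is within 10x the absolute
tolerance (relative to the state scale); larger undershoots raise a
simulation error carrying the offending parameter set. The per-reaction
rate loop is compiled with numba when available (a pure-Python fallback
is kept); a full 48-h simulation costs ~20 ms.

## Initial values

Default initial concentrations and rate constants are of the magnitudes
used in this model lineage (STAT pools ~1 µM, phosphatases tens of nM,
receptor ~12 nM; bimolecular constants 1e-3–1e-1 nM⁻¹s⁻¹). They were
chosen once, as the package's initial-guess tables, so that the unfitted
120 ng/mL response has the right shape (early peak near 5 min, delayed
JAG1 rise) with a modest overshoot of the in-vitro-scale fold-changes;
the Monte Carlo fit refines them. Both tables ship as editable JSON
fixtures (`data/initial_conditions.json`, `data/kinetic_parameters.json`)
and a flat CSV dialect round-trips with them.

## Two-stage Monte Carlo fitting

Candidates are drawn by `P_rand = |P_init − C_max · P_init · Z/3|` with
`Z ~ N(0,1)`, putting ±C_max at 3σ; the absolute value keeps draws
nonnegative. (The source description of the sampler is ambiguous between
a unit-interval and a standard normal draw; the standard normal is the
only reading consistent with the ±C_max-at-3σ construction and is used
here.) Twenty quantities are varied: the initial conditions RJ, PPX, S3c,
S3n and sixteen kinetic constants spanning receptor dynamics (k2f, k2r,
k4, k5f, k6), degradation (deg_ratio), phosphorylation (k8f), the
regulatory modules (k11f, k12, k23), transcription (k25_1, k30_1) and the
JAG1 expression cassette (k28, k31, k33, k34).

Each candidate is scored by simulating the 20/60/120 ng/mL doses and
computing one RMSE per readout against the observation grid — pSTAT3
fold-change at 5/15/30/60 min and JAG1 fold-change at 12/24/48 h,
against replicate means by default (12 and 9 residuals; a per-replicate
option exists, since the source procedure does not state which was used).
The winner minimizes the Euclidean distance of the RMSE pair from the
origin, ties broken toward the lower iteration index.

The search runs a coarse stage (10,000 iterations, C_max = 1.0) anchored
on the initial guesses, then a fine stage (30,000 iterations, C_max =
0.3) anchored on the coarse winner. **Each stage also scores its anchor
as a reference member** (iteration −1): the best-of-superset argument for
stage-wise improvement only holds if the incumbent competes, and it makes
the fit a true descent (a stage can never return something worse than its
starting point). Draws are keyed by (seed, iteration), so any execution
order — serial, resumed, or parallel — produces the identical ranked
list. `--budget-scale` scales both stage budgets for desk-scale runs; the
packaged fitted fixture (`data/fitted_parameters.json`) was produced by a
3,000 + 9,000-iteration run whose seed, budgets and final RMSE pair are
embedded in the file.

## Post-fit analyses

* **Knockout sensitivity.** Each of the 49 parameters in turn is set to 0
  (1e-6 for the two denominator constants, to keep the rational rate laws
  defined) at 120 ng/mL, and the perturbed normalized readouts are scored
  by RMSE against the fitted baseline over the full 60-s output grid
  (the comparison window and the normalized scale are recorded in the
  output metadata; the source does not state either). Integrator
  failures flag the row as infinite and the analysis continues.
* **Robustness ensembles.** The same sampler, centered on the fitted
  values, at C_max = 100%, 50%, 10% and 2% (all four listed levels are
  implemented), n = 10,000 by default; each member's pooled
  readout-RMSE to baseline, peak readouts and central-50% trajectory
  bands are summarized on a 10-min comparison grid.
* **Gestational scan.** Deterministic simulation of the 0 ng/mL control
  plus serum PRL at the recorded minimum (10), weeks 8–36 in 4-week
  steps (19, 27, 35, 47, 63, 84, 113, 123) and the recorded maximum
  (180 ng/mL); peak normalized readouts are regressed on gestational
  week over the eight week-labeled points by ordinary least squares.

## Assay statistics

* Normalized expression: `(F_protein − F_background) / (F_baseline −
  F_background)` on flow-cytometry MFIs; baselines may be pooled or
  per-replicate in the table dialect (pooled by default).
* EMT score: mean vimentin fold over mean E-cadherin fold (ratio of
  means; replicate-level ratios are deliberately not computed).
* TRAIL sensitization: `(%viable_control − %viable) / %viable_control`.
* Endpoint regressions: OLS with a two-sided slope test
  (scipy.stats.linregress).
* Cohort summaries: per-pregnancy-status tumor-size mean and *sample* SD
  (n−1) over non-missing sizes (missing sizes excluded, never imputed),
  intervention counts, and tumor-location distributions. Intervention
  counting tallies each listed procedure and each listed systemic agent
  once per patient; this reproduces the pregnant-group average (~2) but
  undercounts a non-pregnant average that includes repeated courses —
  flagged, not reconciled. Printed one-decimal values follow a
  *truncating* display convention (`printed_1dp`), which is the only
  convention consistent with all four printed group values (3.66 → 3.6).
* Outlier handling: a flag-only median-absolute-deviation screen is
  provided and off by default; no removal is ever performed.

## Synthetic data

The generator emulates the shapes of the in-vitro tables without any
external download:

* **Phenomenological mode** draws n = 3 replicates per cell around smooth
  templates: biphasic pSTAT3 (log-normal bump peaking at 5 min with a
  saturating Hill dose amplitude; +60% logistic secondary rise around
  12 h), delayed JAG1 rise at 12 h whose dose contrast (~2x for the
  pregnancy doses vs 20 ng/mL) equalizes by 24 h, vimentin drifting up
  and E-cadherin halving at the two pregnancy doses, a strong CD44 rise
  at 120 ng/mL, flat CD133, and a dose-independent NICD rise. Template
  constants are generator configuration, not biological claims.
* **Model-based mode** simulates the pathway model under supplied
  ground-truth parameters and emits the two modeled readouts — the route
  used for parameter-recovery tests.

Noise is multiplicative log-normal (`value · exp(ε)`, `ε ~ N(0, sd)`,
sd = 0.1 default; median-preserving). The viability table contains the
soluble-TRAIL dose-response arms (static/shear x ±PRL) and whole-blood
liposome arms; the PRL-pre-exposed dual-affinity-liposome arm is pinned
at 45% viability loss versus the untreated static control, the headline
liposome effect. The cohort fixture is the packaged 12-patient table
(5 pregnant, 7 non-pregnant, two missing tumor sizes in each group).

What passing on synthetic data does *not* show: the phenomenological
tables have independent log-normal replicate noise, no inter-passage or
batch structure, no flow-cytometry gating artifacts, and templates that
the model family can approximate; real in-vitro tables need none of
these to hold, so fit-quality numbers here do not transfer to other
datasets.

## Problem sizes used by the shipped checks

The test suite and the acceptance script scale the search budgets to
desk size as their own study conditions: recovery fits run 500 + 1,500
iterations, the demonstration fit in `scripts/acceptance.py` runs
200 + 600, robustness ensembles run 300–1,000 members per level, and the
sensitivity analysis is always the full 49 knockouts. The packaged
fitted fixture comes from a 3,000 + 9,000-iteration run. All stochastic
steps are seeded and reproducible.

## Known limitations

* The network stoichiometry is a reconstruction of this model lineage
  from its labeled module structure; individual rate constants are not
  literature-derived measurements.
* NOTCH1/NICD dynamics downstream of JAG1 are not modeled (measured in
  vitro but outside the model's scope), and there is no SBML layer, no
  spatial or stochastic simulation.
* The Monte Carlo search is a pure random search around an anchor; it
  characterizes the objective landscape the way the original procedure
  does but is not an efficient optimizer, and reported "fitted" values
  are the best sampled point, not a converged optimum.
* Whether the initial-condition table is nM or molecules/cell is
  immaterial to the fold-change readouts but matters for absolute
  concentrations; the fixtures declare nM.
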