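# prljag

Modeling how pregnancy-level prolactin drives JAK2/STAT3/JAG1 signaling
in colorectal cancer cells.

Serum prolactin (PRL) rises from ~20 ng/mL outside pregnancy to
120–180 ng/mL in late pregnancy. In PRL-receptor-positive colorectal
cancer cells this activates the JAK2/STAT3 pathway: STAT3 is
phosphorylated within minutes, dimerizes, enters the nucleus and drives
transcription of the Notch ligand JAG1, a route into
epithelial–mesenchymal transition and stem-like marker expression.
`prljag` packages the computational side of that story for systems
biologists and quantitative cancer researchers:

* a **mass-action ODE model** of the pathway (28 species, reactions
  R1–R34, 49 tunable kinetic parameters, SHP2/PPX–PPN/SOCS negative
  feedback, saturable transcription), integrated with a stiff adaptive
  solver and read out as pSTAT3 and membrane-JAG1 fold-changes;
* a **two-stage Monte Carlo fit** to normalized in-vitro time courses:
  candidates `P_rand = |P_init − C_max · P_init · Z/3|` (`Z ~ N(0,1)`,
  ±C_max at 3σ), scored by the RMSE pair
  `(RMSE_pSTAT3, RMSE_JAG1)` on a 5/15/30/60-min + 12/24/48-h grid at
  20/60/120 ng/mL, winner nearest the origin; 10,000 iterations at
  C_max = 1.0 then 30,000 at C_max = 0.3 around the coarse winner;
* **post-fit analyses**: 49 single-parameter knockouts scored by RMSE
  against the fitted baseline, perturbation-robustness ensembles at
  C_max = 100/50/10/2%, and a gestational dose scan (serum PRL from
  week 8 to week 36 plus recorded extremes) with a peak-vs-week
  regression;
* **assay statistics**: flow-cytometry fold-change normalization
  `(F_protein − F_bg)/(F_baseline − F_bg)`, the EMT score
  `mean(VIM)/mean(ECad)`, TRAIL sensitization
  `(%viable_ctrl − %viable)/%viable_ctrl`, endpoint regressions, and
  clinical cohort summaries;
* a **synthetic-data module** that generates in-vitro-shaped observation
  tables, viability tables and the 12-patient cohort fixture, so the
  whole pipeline runs without any external download.

## Worked example

Simulate late-pregnancy PRL with the packaged fitted parameters, scan
gestation, and summarize the cohort table:

```sh
$ prljag simulate --prl 120 --fitted --out out
wrote out/readouts_prl120.csv (2881 rows)

$ prljag analyze gestation --out out
peak pSTAT3 vs week: R^2 = 0.911; peak JAG1 vs week: R^2 = 0.939

$ prljag synth cohort --out out && prljag metrics cohort out/cohort.csv
pregnant: n=5, tumor size 5.1 cm ± 2.5 (n_sized=3), mean interventions 1.6, locations {'R': 3, 'CR': 1, 'CL': 1}
non_pregnant: n=7, tumor size 3.6 cm ± 2.4 (n_sized=5), mean interventions 3.9, locations {'CL': 6, 'R': 1}
```

The readout CSV holds both normalized readouts on a 60-s grid over
0–48 h. At 120 ng/mL the fitted model phosphorylates STAT3 rapidly —
fold-change 2.07 at 5 min, peaking at 2.32 around 8 min — then the
SHP2/SOCS/phosphatase feedback returns it toward baseline by 30 min
(0.97), while JAG1 stays flat for hours and then climbs to 1.87-fold at
12 h and 3.48-fold at 48 h: an early phosphorylation spike driving a
slow downstream expression wave. Across gestation the peak pSTAT3
fold-change grows monotonically with the week-specific PRL input and its
linear fit against gestational week gives R² = 0.911; a 0 ng/mL control
produces no activation at all. In the cohort table the pregnant patients
have larger resected tumors (5.1 ± 2.5 cm vs 3.6 ± 2.4 cm, mean ±
sample SD over recorded sizes) yet fewer interventions.

Fitting and the remaining analyses follow the same pattern:

```sh
prljag synth observations --seed 1 --out out     # Data-S1-shaped table
prljag fit out/observations.csv --seed 1 --budget-scale 0.05 --out out
prljag analyze sensitivity --out out             # 49 knockout rows
prljag analyze robustness --n 1000 --out out
```

Every command writes an append-only JSON-lines run manifest recording
its configuration and seeds; identical config + seed reproduces
identical outputs.

## Library surface

```python
import prljag as pj

net = pj.build_network()                      # validated reaction network
tc = pj.simulate(net, prl_dose=120.0)         # TimeCourse, 0-48 h
ps_fold, jag1_fold = pj.normalize_trajectory(tc)

obs = pj.ObservationSet.from_frame(
    pj.generate_observations(pj.SyntheticDesign(seed=1)))
ic = pj.load_default_initials()
anchor = {**pj.load_default_parameters(),
          **{k: ic[k] for k in ("RJ", "PPX", "S3c", "S3n")}}
s1, s2 = pj.default_stage_specs(anchor, seed=1, budget_scale=0.05)
result = pj.two_stage_fit(obs, net, s1, s2)   # winner + audit trail
```

See `docs/methods.md` for the model, the sampler, numerical choices and
known limitations.

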