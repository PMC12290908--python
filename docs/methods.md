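# Methods

## Model

`rrmcea` implements a decision-analytic Markov cohort model comparing two
management strategies for a healthy woman at elevated lifetime breast-cancer
(BC) risk, entering the model between ages 30 and 60:

* **RRM** — immediate bilateral risk-reducing mastectomy (100% uptake),
  which multiplies all subsequent annual BC incidence by a residual hazard
  ratio (default 0.09, i.e. ~91% risk reduction, sensitivity range
  0.02–0.38);
* **Screening + prevention** — NICE-tier risk-stratified screening
  (annual mammography 40–49 then triennial to 69 for 17–<32% lifetime risk;
  annual mammography 40–59 then triennial 60/63/66/69 for 32–<45%; annual
  MRI 30–49 plus annual mammography 50–69 at ≥45%; routine triennial
  mammography 50–68 below 17%), plus a 5-year course of chemoprevention with
  16.3% uptake (tamoxifen before the menopause age, anastrozole after;
  start at 30 for ≥30% risk, at 40 for 17–<30%).

Cycles are annual; the horizon is age 80; the cohort is a deterministic
occupancy vector (no microsimulation). Health states are: healthy;
diagnosed-BC tunnels indexed by stage (DCIS, stages 1–4) and years since
diagnosis (1–20); a pooled distant-recurrence state; long-term survivor
(alive, recurrence-free 20 years after diagnosis, facing general-population
mortality only); BC death; other-cause death. Stage transitions before
diagnosis are not modelled; the stage distribution at diagnosis carries the
stage-shift effect of screening (a screened-context distribution inside the
active screening window, the general-population distribution outside it, and
the general-population distribution for cancers arising after RRM).

### Lifetime risk and incidence scaling

Lifetime risk over ages 20–80 is the life-table cumulative probability of a
first diagnosis with all-cause mortality as the competing event:

    R = Σ_a inc(a) · Π_{b<a} (1 − inc(b))(1 − mort(b))

A target lifetime risk is imposed through a single lifetime-average hazard
ratio on the log-complement scale, HR = ln(1 − target)/ln(1 − baseline),
held constant over age and applied by *multiplying annual probabilities*
(clamped at 1), not hazards. Probability-scaling approximates
hazard-scaling; the package's round-trip tests bound the approximation at
5% relative error over targets 17–50% against the 10.79% UK baseline.
`calibrate_baseline` finds, by root-bracketing (Brent), the single
multiplier that makes a positive incidence shape reproduce a stated
lifetime risk to 1e−10.

### Within-cycle event conventions

Conventions the evidence base leaves open were fixed once and are tested:

* From the healthy state, diagnosis is drawn from the start-of-cycle mass
  (H·p) and other-cause death removes H·(1−p)·q. This makes cumulative
  cohort diagnoses equal the life-table risk formula exactly (to 1e−9),
  which is also how the calibration target is defined. The two events are
  treated as exclusive within a year; complements multiply for survivors.
* In a diagnosed tunnel the order is: other-cause death, then stage- and
  duration-specific BC death, then distant recurrence; survivors advance a
  tunnel year. Local recurrence is a costed event flow that neither moves
  mass nor resets the tunnel clock.
* Distant recurrence enters a single pooled state with a constant annual
  BC-death probability (fixture default: the general-population stage-4
  first-year value) rather than its own years-since-entry tunnel — the
  duration structure of recurrence survival is not recoverable from the
  main-text evidence, so the schema keeps it one explicit parameter.
* No half-cycle correction is applied. Life-years count start-of-cycle
  alive occupancy, one year each.
* Screens, false positives, and prevention drug use are computed on the
  start-of-cycle healthy mass; women already diagnosed leave the screening
  programme.
* A prevention plan whose nominal start age precedes cohort entry is
  shifted to start at entry; the treated window is the plan duration and
  the incidence effect persists through a carryover window (default 5
  years) after treatment ends. Prevention is assumed to act on all
  incidence, not ER-positive disease only; drug costs and the annual
  disutility are charged only to the uptake fraction actually treated.

Probability mass is checked every cycle; a leak beyond 1e−9 aborts the run
(it is an internal error, never a warning).

### Economics

Payer (NHS) perspective, 2021 GBP. Costs per cycle are event flows times
unit costs (screens by modality, false-positive recalls and biopsies,
surgery in its year, prevention drug-years) plus occupancy times annual
treatment costs (stage-specific first-year and subsequent-year costs,
recurrence-state annual cost, a terminal-care cost in the cycle of BC
death, a per-event local-recurrence cost). Utilities are age-adjusted
multiplicatively (population norm at the current age times the state
utility). Event disutilities are absolute decrements: 1/52 year per screen
attended, 5/52 year per false positive, a full-year decrement in the
surgery year, and an annual decrement per treated prevention year. A
negative per-cycle utility after decrements is clamped to zero with a
warning. Costs and effects are discounted at 3.5%/year by default,
independently configurable because the one-way analysis varies them
separately.

### Cost-effectiveness analysis

The ICER of RRM versus screening is Δcost/ΔQALY with dominance classified
before division. The threshold search walks the 17–50% lifetime-risk grid
in 1% steps (mirroring how the published results tables are organised) and
returns the smallest risk at which RRM is cost-effective at the given
willingness to pay (dominant, or ICER ≤ WTP with ΔQALY > 0); a finer grid
can be passed explicitly. Net monetary benefit ΔQALY·WTP − ΔCost drives
the probabilistic results.

### Sensitivity analysis

One-way analysis re-evaluates the ICER with one scalar at its low/high
range (defaults: costs ±30%, probabilities and utilities ±10%, stated
ranges where they exist, e.g. the surgical effect's 0.02–0.38), sorted by
spread. The PSA redraws all specified scalars jointly — gamma for costs
(shape (m/se)², scale se²/m), beta for probabilities (method of moments,
standard error shrunk if infeasible), lognormal for utilities (moment-
matched on the log scale, truncated at 1) — with a default standard error
of 10% of the mean when none is given, from one seeded
`numpy.random.Generator`, so results are bit-reproducible. Draws failing
bundle validation are redrawn; a redraw rate above 1% is a hard error.
Parameter correlation is not modelled.

## Synthetic parameter bundles

No machine-readable parameter tables accompany the evidence base, so the
package generates its own bundles (`rrmcea.fixtures`):

* **PAPER_LIKE** embeds every anchor printed in the main text — the
  10.79% baseline lifetime risk (the synthetic incidence shape is
  log-quadratic in age peaking in the mid-60s, qualitatively like UK
  registry incidence, calibrated to that figure under a Gompertz-like
  synthetic mortality schedule), 16.3% uptake, 3.5% discounting, residual
  surgical hazard ratio 0.09 (0.02–0.38), WTP pair £20k/£30k, horizon 80,
  20-year survivor rule, 1-week/5-week disutility durations, and the
  population-impact inputs (0.5% of women at 60% mean risk, 2.5% at 41.8%,
  11% population risk, 58 756 annual cases). Everything else — stage
  distributions, 20-year stage-specific survival (converted to constant
  annual death probabilities, one block per stage), recurrence rates, unit
  costs, utilities, false-positive rates — is a plausible stand-in chosen
  once at realistic UK magnitudes and documented in the source, not a
  reconstruction of the unavailable supplementary values.
* **RANDOM_VALID** draws seeded jitter around those values while
  preserving every invariant (distributions renormalised, probabilities
  clipped, per-cycle exit probabilities ≤ 1), for property tests.

Consequently the engine-level results on these bundles (absolute ICERs,
threshold risks, PSA probabilities) are fixture-dependent: the tests
assert the *structure* the method guarantees — conservation of mass,
equivalence with brute-force path enumeration on small models, calibration
recovery, dose-response monotonicity, the NMB/ICER identity, threshold
monotonicity in WTP, CEAC monotonicity, seed reproducibility, ICER
decreasing in risk, and screening costs stepping up at the 32%/45% tier
boundaries — not the published point estimates that depend on the
unavailable supplement. The desk-scale published numbers that *are*
derivable from the main text (the hazard-ratio transform values 2.52 and
6.07; the population-impact arithmetic 12.23%, 6538 with CI 4454–7041,
~11% of annual cases) are reproduced exactly.

What the synthetic bundles do not emulate: real age-specific registry
incidence and ONS mortality curves (only their qualitative shape), cost
inflation indexing, duration-structured recurrence survival, correlation
between PSA parameters, and screening sensitivity/sojourn-time natural
history (the stage-shift is carried entirely by the two stage
distributions).

## Numerical choices

* Calibration: Brent root-bracketing on [0, 1/max(shape)], xtol 1e−14;
  an unreachable target (risk saturates below it without clamping) raises.
* Tier boundaries are half-open with 0.45 inclusive to the top tier;
  triennial screens step by 3 years from the first eligible age while ≤69.
* Reported integers and currency round half away from zero (the
  population-impact case fraction is carried unrounded into the product —
  rounding it first would shift the prevented-case counts by one).
* Bundle serialization writes floats at 17 significant digits and reads
  them with round-trip parsing, so write→read is bit-identical.
* Problem sizes in the shipped tests: 100 random bundles for conservation,
  3-cycle models for oracle equivalence, 10 000 PSA draws at one scenario
  for the acceptability curve (a few tens of seconds on one CPU).

## Known limitations

Constant hazard ratio over age; no RRM mortality benefit beyond incidence
reduction; no screening nonattendance or partial RRM uptake; recurrence
pooled into one state; no half-cycle correction; probability- rather than
hazard-scaling of incidence; chemoprevention modelled on all incidence.
Each is either the stated behaviour of the method being reproduced or a
documented convention where the evidence base is silent.
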