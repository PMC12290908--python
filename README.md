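# rrmcea

Cost-effectiveness modelling of **risk-reducing mastectomy (RRM)** versus
**risk-stratified breast-cancer screening with medical prevention**, for
health economists and cancer-prevention researchers who want an open,
tested implementation of the lifetime-risk-threshold question: *at what
lifetime breast-cancer risk does offering surgery become cost-effective?*

## The model in brief

A deterministic annual-cycle Markov cohort follows healthy women from a
chosen entry age (30–60) to age 80 through diagnosis (DCIS, stages 1–4,
with 20-year years-since-diagnosis tunnels), distant recurrence, long-term
survivorship, and death (breast-cancer or other-cause). Lifetime risk over
ages 20–80 is the life-table quantity

```
R = Σ_a inc(a) · Π_{b<a} (1 − inc(b)) (1 − mort(b))
```

and an assumed risk is imposed by scaling age-specific incidence with the
constant lifetime-average hazard ratio
`HR = ln(1 − target) / ln(1 − baseline)` against the UK baseline of
10.79%. Strategies are compared by the incremental cost-effectiveness
ratio `ICER = ΔC/ΔQ` (costs in 2021 GBP discounted at 3.5%, effects as
QALYs with multiplicative age adjustment), with one-way (tornado) and
probabilistic sensitivity analysis (gamma/beta/lognormal redraws, CEAC),
a 1%-step lifetime-risk threshold search, and population-impact
arithmetic for the annual cases prevented nationally.

Because the original supplementary parameter tables are not publicly
deposited, the package ships a synthetic-bundle generator
(`rrmcea.fixtures`): a curated bundle embedding every value printed in
the main text of the evidence base, and seeded random bundles for
property testing. See `docs/methods.md` for what is anchored and what is
a documented stand-in.

## Worked example

```python
from rrmcea import (FixtureSpec, Realism, generate_fixture,
                    evaluate_scenario, threshold_sweep)

bundle = generate_fixture(FixtureSpec(realism=Realism.PAPER_LIKE))
sc = evaluate_scenario(bundle, age=30, lifetime_risk=0.34)
print(f"ICER {sc.comparison.icer:,.0f} GBP/QALY "
      f"(+{sc.comparison.delta_qaly:.3f} QALY, +{sc.comparison.delta_cost:,.0f} GBP)")

_, thresholds = threshold_sweep(bundle, ages=[30], wtps=[20_000.0, 30_000.0])
for th in thresholds:
    print(f"age {th.start_age}, WTP {th.wtp:,.0f}: threshold {th.threshold_risk:.0%}")
```

prints

```
ICER 17,365 GBP/QALY (+0.309 QALY, +5,363 GBP)
age 30, WTP 20,000: threshold 32%
age 30, WTP 30,000: threshold 26%
```

meaning that on the synthetic bundle, surgery for a 30-year-old at 34%
lifetime risk buys a QALY for about £17k; walking the risk grid, surgery
first becomes cost-effective at 32% lifetime risk under a £20 000/QALY
willingness to pay and at 26% under £30 000/QALY. (Absolute values are
properties of the synthetic bundle; the structure — ICER falling as risk
rises, threshold falling as willingness to pay rises — is what the model
guarantees.)

The `examples/` directory has one short narrative script per capability:
lifetime risk and hazard ratios, a single scenario, the threshold sweep,
sensitivity analysis, and population impact. The same pipeline is
scriptable from a shell:

```sh
rrmcea fixture --realism paper_like --out params/
rrmcea run --params params/ --age 30 --risk 0.34
rrmcea threshold --params params/ --out sweep.csv
rrmcea psa --params params/ --age 30 --risk 0.34 --n 10000 --seed 1 --out ceac.csv
rrmcea impact --params params/
```

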