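"""Lifetime-risk thresholds for cost-effective surgery, by age and WTP.

Sweeps the 17%-50% lifetime-risk grid (1% steps) for several surgery
ages and reports the smallest risk at which the ICER of mastectomy
versus screening falls below each willingness-to-pay threshold.
"""

from rrmcea import FixtureSpec, Realism, generate_fixture, threshold_sweep

bundle = generate_fixture(FixtureSpec(realism=Realism.PAPER_LIKE))

ages = [30, 40, 50, 60]
wtps = [20_000.0, 30_000.0]
cells, thresholds = threshold_sweep(bundle, ages, wtps)

for th in thresholds:
    risk = "none on grid" if th.threshold_risk is None else f"{th.threshold_risk:.0%}"
    print(f"age {th.start_age}, WTP {th.wtp:,.0f} GBP/QALY -> threshold {risk}")

# Each threshold is the lowest lifetime risk at which surgery buys QALYs
# at or below the stated price; it falls as willingness to pay rises and
# varies with surgery age through the remaining years at risk.
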