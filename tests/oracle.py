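"""Independent brute-force oracle for small cohort models.

Enumerates every individual path through the health-state space cycle by
cycle, multiplying branch probabilities, instead of propagating an
occupancy vector.  Feasible only for a handful of cycles; used to check
the Markov engine transition-for-transition.

The state encoding is deliberately independent of the package's arrays:
states are tuples ("H",), ("T", stage, year), ("R",), ("V",), ("DB",),
("DO",).  A single diagnosis context is supported (the toy models use
one context), with the stage distribution fixed per age.
"""

from collections import defaultdict


def enumerate_occupancy(
    n_cycles: int,
    incidence: list,
    mortality: list,
    stage_dist: list,
    bc_death: dict,
    distant_rec: dict,
    recurrence_death: float,
    survivor_cutoff: int = 20,
):
    """Occupancy dicts at each cycle start, 0..n_cycles.

    ``bc_death[(stage, year)]`` and ``distant_rec[(stage, year)]`` give
    the annual probabilities in tunnel year ``year`` (1-based); missing
    keys mean zero.
    """

    def transitions(state, t):
        p, q = incidence[t], mortality[t]
        if state == ("H",):
            out = [(p * w, ("T", s, 1)) for s, w in enumerate(stage_dist) if w]
            out.append(((1 - p) * q, ("DO",)))
            out.append(((1 - p) * (1 - q), ("H",)))
            return out
        if state[0] == "T":
            _, s, y = state
            d = bc_death.get((s, y), 0.0)
            rd = distant_rec.get((s, y), 0.0)
            nxt = ("V",) if y == survivor_cutoff else ("T", s, y + 1)
            return [
                (q, ("DO",)),
                ((1 - q) * d, ("DB",)),
                ((1 - q) * (1 - d) * rd, ("R",)),
                ((1 - q) * (1 - d) * (1 - rd), nxt),
            ]
        if state == ("R",):
            return [
                (q, ("DO",)),
                ((1 - q) * recurrence_death, ("DB",)),
                ((1 - q) * (1 - recurrence_death), ("R",)),
            ]
        if state == ("V",):
            return [(q, ("DO",)), (1 - q, ("V",))]
        return [(1.0, state)]  # absorbing

    occ = [defaultdict(float) for _ in range(n_cycles + 1)]

    def expand(state, prob, t):
        occ[t][state] += prob
        if t == n_cycles or prob == 0.0:
            return
        for w, nxt in transitions(state, t):
            expand(nxt, prob * w, t + 1)

    expand(("H",), 1.0, 0)
    return occ
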