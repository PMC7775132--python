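"""Shared independent oracle for SN P engine equivalence tests.

A deliberately naive re-derivation of the synchronous step semantics
for fire/forget systems, kept free of any engine code: applicability
from start-of-step counts, lowest rule index wins, emissions queued at
t+delay, arrivals lost at closed neurons, closed timers decrement at
step end.
"""

from spicseg.snp import Guard, Neuron, SNPRule, SNPSystem, relay_rule


def fire(guard, c=1, p=1, d=0):
    return SNPRule(kind="fire", guard=guard, consume=c, produce=p, delay=d)


def forget(s):
    return SNPRule(kind="forget", guard=Guard.exact(s), consume=s)


def make_system(neuron_rules, pulses, edges, seed=0):
    neurons = {
        i: Neuron(i, pulses=pulses[i], rules=tuple(rules))
        for i, rules in neuron_rules.items()
    }
    return SNPSystem(neurons=neurons, syn={e: 1.0 for e in edges},
                     input_labels=(), output_labels=(), rng_seed=seed)


def oracle_step(rules, pulses, closed, pending, syn, t):
    """One synchronous step; rules are (kind, guard_fn, consume, produce,
    delay) tuples with "all"/"consumed" sentinels as strings."""
    pulses = dict(pulses)
    closed = dict(closed)
    pending = list(pending)
    for lab in sorted(rules):
        if closed[lab] > 0:
            continue
        for rule in rules[lab]:
            kind, guard, c, p, d = rule
            need = pulses[lab] if c == "all" else c
            if not guard(pulses[lab]) or pulses[lab] < max(need, 1):
                continue
            got = pulses[lab] if c == "all" else c
            pulses[lab] -= got
            if kind == "fire":
                amount = got if p == "consumed" else p
                if d > 0:
                    closed[lab] = d
                if amount > 0:
                    for (i, j) in sorted(syn):
                        if i == lab:
                            pending.append((t + d, j, amount))
            break
    remaining = []
    for (arr, target, amount) in pending:
        if arr != t:
            remaining.append((arr, target, amount))
        elif closed[target] == 0:
            pulses[target] += amount
    for lab in closed:
        closed[lab] = max(0, closed[lab] - 1)
    return pulses, closed, remaining


def rule_catalog():
    """Finite catalog of (engine rule, oracle rule) pairs spanning the
    guard/consume/produce/delay space used by the equivalence checks."""
    cat = []
    for g, gf in [(Guard.exact(1), lambda n: n == 1), (Guard.exact(2), lambda n: n == 2),
                  (Guard.at_least(1), lambda n: n >= 1), (Guard.at_least(2), lambda n: n >= 2)]:
        for c in (1, 2):
            for p in (0, 1, 2):
                for d in (0, 1):
                    cat.append((fire(g, c=c, p=p, d=d), ("fire", gf, c, p, d)))
    cat.append((forget(1), ("forget", lambda n: n == 1, 1, 0, 0)))
    cat.append((forget(2), ("forget", lambda n: n == 2, 2, 0, 0)))
    cat.append((relay_rule(), ("fire", lambda n: n >= 1, "all", "consumed", 0)))
    return cat
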