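"""Spiking Neural P (SN P) system engine and the spiculation classifier.

An SN P system is a membrane-computing model: neurons σ_i hold counts of
identical pulses and are wired by weighted directed synapses.  Rules are
gated by a guard over the pulse count (a regular language over the unary
pulse alphabet):

* firing rules  E/a^c → a^p; d  consume c pulses and, after a delay of d
  steps during which the neuron is closed (it neither fires nor receives),
  deliver p pulses along every outgoing synapse;
* forgetting rules  a^s → λ  consume s pulses and emit nothing;
* synapse-plasticity rules  E/a^c → αk(i, Q)  consume c pulses and
  create (α = +), delete (α = −) or toggle over two steps (α = ±, ∓) up
  to k synapses toward a target label set Q.

Evolution is synchronous and, in this engine, deterministic: within a
neuron the lowest-index applicable rule fires, and the random selection
in plasticity rules is driven by the system's seeded generator.  A pulse
arriving over synapse (i, j) contributes round(p · w_ij) pulses; pulses
arriving at a closed neuron are lost.  The system halts when no rule is
applicable anywhere, no emission is pending and every neuron is open.

The spiculation classifier (:func:`build_network`) is a feed-forward
system fed by a 5×7 binary boundary grid: 35 input neurons (one per
cell, holding one pulse iff the cell is on) feed three Module 1 neurons,
then Module 2 (4 layers × 3 neurons), then Module 3 (4 layers × 5
neurons), densely layer to layer with all weights initially 1.  Every
computation neuron carries the single relay rule "while the neuron holds
pulses it is excited, until its count reaches 0" — it fires its whole
content each step — so any input drains through the network in at most
depth + total-pulses steps.  The last Module 3 layer is the output; the
classifier score is a weighted sum of the pulses those neurons received.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .imaging_io import Mask2D

__all__ = [
    "Guard",
    "SNPRule",
    "Neuron",
    "SNPSystem",
    "SystemState",
    "BoundaryGrid",
    "TrainedWeights",
    "boundary_pixels",
    "normalize_boundary",
    "build_network",
    "network_depth",
    "step",
    "run",
    "train",
    "classify",
    "relay_rule",
]

GRID_ROWS, GRID_COLS = 5, 7


# ------------------------------------------------------------------- guards

@dataclass(frozen=True)
class Guard:
    """Decidable predicate over a pulse count.

    Three primitives — exact count, at-least, and arithmetic-progression
    membership — are enough to express the regular languages over a
    unary alphabet that SN P guards range over.
    """

    kind: str  # "exact" | "at_least" | "progression"
    a: int
    d: int = 0

    @classmethod
    def exact(cls, n: int) -> "Guard":
        return cls("exact", n)

    @classmethod
    def at_least(cls, n: int) -> "Guard":
        return cls("at_least", n)

    @classmethod
    def progression(cls, start: int, step: int) -> "Guard":
        """Counts of the form start + k*step, k >= 0."""
        if step < 1:
            raise ValueError("progression step must be >= 1")
        return cls("progression", start, step)

    def matches(self, count: int) -> bool:
        if count < 0:
            raise ValueError("pulse count must be >= 0")
        if self.kind == "exact":
            return count == self.a
        if self.kind == "at_least":
            return count >= self.a
        if self.kind == "progression":
            return count >= self.a and (count - self.a) % self.d == 0
        raise ValueError(f"unknown guard kind {self.kind!r}")


# -------------------------------------------------------------------- rules

ALL = "all"  # consume the neuron's whole pulse content
CONSUMED = "consumed"  # produce as many pulses as were consumed


@dataclass(frozen=True)
class SNPRule:
    kind: str  # "fire" | "forget" | "syn_plastic"
    guard: Guard
    consume: int | str = 1
    produce: int | str = 0
    delay: int = 0
    alpha: str | None = None  # "+", "-", "+-", "-+"  (for syn_plastic)
    k_limit: int | None = None
    target_set: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fire", "forget", "syn_plastic"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.consume != ALL and (not isinstance(self.consume, int) or self.consume < 1):
            raise ValueError("consume must be an int >= 1 or 'all'")
        if self.kind == "forget":
            if self.produce not in (0,) or self.delay != 0:
                raise ValueError("forget rules produce nothing and have no delay")
        if self.kind == "fire":
            if self.produce != CONSUMED and (not isinstance(self.produce, int) or self.produce < 0):
                raise ValueError("produce must be an int >= 0 or 'consumed'")
            if self.delay < 0:
                raise ValueError("delay must be >= 0")
        if self.kind == "syn_plastic":
            if self.alpha not in ("+", "-", "+-", "-+"):
                raise ValueError("syn_plastic alpha must be one of '+', '-', '+-', '-+'")
            if self.k_limit is None or self.k_limit < 1:
                raise ValueError("syn_plastic requires k_limit >= 1")
            if self.target_set is None:
                raise ValueError("syn_plastic requires a target_set")

    def applicable(self, pulses: int) -> bool:
        if not self.guard.matches(pulses):
            return False
        need = 1 if self.consume == ALL else self.consume
        return pulses >= need


def relay_rule() -> SNPRule:
    """The threshold-free rule of the classifier network: a neuron with
    pulses is excited and fires its whole content until it reaches 0."""
    return SNPRule(kind="fire", guard=Guard.at_least(1), consume=ALL, produce=CONSUMED)


# ------------------------------------------------------------------ neurons

@dataclass
class Neuron:
    label: int
    pulses: int = 0
    rules: tuple[SNPRule, ...] = ()

    def __post_init__(self) -> None:
        if self.pulses < 0:
            raise ValueError("pulses must be >= 0")
        self.rules = tuple(self.rules)


@dataclass
class SNPSystem:
    """Neurons, weighted synapses, and input/output designations."""

    neurons: dict[int, Neuron]
    syn: dict[tuple[int, int], float]
    input_labels: tuple[int, ...] = ()
    output_labels: tuple[int, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for (i, j) in self.syn:
            if i == j:
                raise ValueError(f"self-loop synapse ({i}, {i}) not allowed")
            if i not in self.neurons or j not in self.neurons:
                raise ValueError(f"synapse ({i}, {j}) references a missing neuron")

    def successors(self, label: int) -> list[int]:
        return sorted(j for (i, j) in self.syn if i == label)

    def predecessors(self, label: int) -> list[int]:
        return sorted(i for (i, j) in self.syn if j == label)

    def total_pulses(self) -> int:
        return sum(n.pulses for n in self.neurons.values())


@dataclass
class SystemState:
    """Mutable run state: per-neuron counts/closed timers, pending
    deliveries, the step counter and bookkeeping audits."""

    pulses: dict[int, int]
    closed_for: dict[int, int]
    pending: list[tuple[int, int, int]]  # (arrival_step, target, amount)
    step: int = 0
    halted: bool = False
    rng: np.random.Generator | None = None
    pending_plastic: list[tuple[int, int, str]] = field(default_factory=list)
    delivered: dict[int, int] = field(default_factory=dict)
    weight_log: list[tuple[int, int, int, float]] = field(default_factory=list)
    audit: dict[str, int] = field(
        default_factory=lambda: {"consumed": 0, "emitted": 0, "delivered": 0, "lost": 0}
    )

    @classmethod
    def initial(cls, system: SNPSystem) -> "SystemState":
        state = cls(
            pulses={lab: n.pulses for lab, n in system.neurons.items()},
            closed_for={lab: 0 for lab in system.neurons},
            pending=[],
            rng=np.random.default_rng(system.rng_seed),
        )
        state.halted = _is_halted(system, state)
        return state


def _applicable_rule(neuron: Neuron, pulses: int) -> SNPRule | None:
    for rule in neuron.rules:  # lowest index wins (deterministic)
        if rule.applicable(pulses):
            return rule
    return None


def _is_halted(system: SNPSystem, state: SystemState) -> bool:
    if state.pending or state.pending_plastic:
        return False
    if any(t > 0 for t in state.closed_for.values()):
        return False
    return all(
        _applicable_rule(system.neurons[lab], state.pulses[lab]) is None
        for lab in system.neurons
    )


def _plastic_create(system, state, src: int, targets: Sequence[int], k: int) -> None:
    pool = sorted(set(targets) - {src} - set(system.successors(src)))
    if not pool:
        return
    if len(pool) > k:
        idx = state.rng.choice(len(pool), size=k, replace=False)
        pool = [pool[i] for i in sorted(idx)]
    for j in pool:
        system.syn[(src, j)] = 1.0
        state.weight_log.append((state.step, src, j, 1.0))


def _plastic_delete(system, state, src: int, targets: Sequence[int], k: int) -> None:
    pool = sorted(set(targets) & set(system.successors(src)))
    if not pool:
        return
    if len(pool) > k:
        idx = state.rng.choice(len(pool), size=k, replace=False)
        pool = [pool[i] for i in sorted(idx)]
    for j in pool:
        del system.syn[(src, j)]
        state.weight_log.append((state.step, src, j, float("nan")))


def step(system: SNPSystem, state: SystemState) -> SystemState:
    """Advance the system one synchronous step (mutates and returns state).

    Phase order: scheduled plasticity complements, rule application from
    start-of-step counts (synapses snapshotted for targeting), delivery
    of emissions arriving this step (lost if the target is closed), then
    closed-timer decrement and the halting check.
    """
    if state.halted:
        raise RuntimeError("cannot step a halted system")
    t = state.step
    syn_snapshot = dict(system.syn)

    # complements of +-/-+ plasticity rules applied one step earlier
    for (src, action, targets, k) in list(state.pending_plastic):
        if action == "+":
            _plastic_create(system, state, src, targets, k)
        else:
            _plastic_delete(system, state, src, targets, k)
    state.pending_plastic.clear()

    for lab in sorted(system.neurons):
        if state.closed_for[lab] > 0:
            continue
        neuron = system.neurons[lab]
        rule = _applicable_rule(neuron, state.pulses[lab])
        if rule is None:
            continue
        assert rule.applicable(state.pulses[lab])
        c = state.pulses[lab] if rule.consume == ALL else rule.consume
        state.pulses[lab] -= c
        state.audit["consumed"] += c
        if rule.kind == "forget":
            continue
        if rule.kind == "fire":
            p = c if rule.produce == CONSUMED else rule.produce
            if rule.delay > 0:
                state.closed_for[lab] = rule.delay
            if p > 0:
                for j in sorted(jj for (ii, jj) in syn_snapshot if ii == lab):
                    amount = int(round(p * syn_snapshot[(lab, j)]))
                    state.audit["emitted"] += p
                    if amount != 0:
                        state.pending.append((t + rule.delay, j, amount))
            continue
        # syn_plastic
        targets = sorted(rule.target_set)
        k = rule.k_limit
        if rule.alpha == "+":
            _plastic_create(system, state, lab, targets, k)
        elif rule.alpha == "-":
            _plastic_delete(system, state, lab, targets, k)
        elif rule.alpha == "+-":
            _plastic_create(system, state, lab, targets, k)
            state.pending_plastic.append((lab, "-", targets, k))
        else:  # "-+"
            _plastic_delete(system, state, lab, targets, k)
            state.pending_plastic.append((lab, "+", targets, k))

    # deliveries arriving at this step
    remaining: list[tuple[int, int, int]] = []
    for (arrival, target, amount) in state.pending:
        if arrival != t:
            remaining.append((arrival, target, amount))
            continue
        if state.closed_for[target] > 0:
            state.audit["lost"] += amount
            continue
        state.pulses[target] += amount
        state.audit["delivered"] += amount
        state.delivered[target] = state.delivered.get(target, 0) + amount
    state.pending = remaining

    for lab in state.closed_for:
        if state.closed_for[lab] > 0:
            state.closed_for[lab] -= 1

    state.step = t + 1
    state.halted = _is_halted(system, state)
    return state


def run(
    system: SNPSystem,
    grid: "BoundaryGrid | None" = None,
    max_steps: int | None = None,
) -> tuple[dict[int, int], bool, int]:
    """Run the system to halting (or ``max_steps``).

    If a grid is given, each input neuron is loaded with one pulse iff
    its cell is on.  Returns (output_counts, halted, steps) where
    ``output_counts[label]`` accumulates every pulse delivered to that
    output neuron over the whole run.
    """
    if grid is not None:
        cells = grid.cells.ravel()
        if len(system.input_labels) != cells.size:
            raise ValueError("grid size does not match the number of input neurons")
        for lab, val in zip(system.input_labels, cells):
            system.neurons[lab].pulses = int(val)
    if max_steps is None:
        max_steps = 10 * (len(system.neurons) + network_depth(system))
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    state = SystemState.initial(system)
    while not state.halted and state.step < max_steps:
        step(system, state)
    counts = {lab: state.delivered.get(lab, 0) for lab in system.output_labels}
    return counts, state.halted, state.step


# ---------------------------------------------------- boundary pulse coding

@dataclass(frozen=True)
class BoundaryGrid:
    """5×7 binary pulse encoding of a nodule boundary."""

    cells: np.ndarray

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells)
        if cells.shape != (GRID_ROWS, GRID_COLS):
            raise ValueError(f"BoundaryGrid must be {GRID_ROWS}x{GRID_COLS}, got {cells.shape}")
        vals = np.unique(cells)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("BoundaryGrid cells must be 0/1")
        object.__setattr__(self, "cells", cells.astype(np.uint8))

    def total_pulses(self) -> int:
        return int(self.cells.sum())


def boundary_pixels(mask: Mask2D) -> Mask2D:
    """Mark boundary pixels: mask pixels that are 4-adjacent to a 0 pixel
    or lie on the image border."""
    px = mask.pixels.astype(bool)
    padded = np.pad(px, 1, mode="constant", constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return Mask2D((px & ~interior).astype(np.uint8))


def normalize_boundary(boundary: Mask2D) -> BoundaryGrid:
    """Pool the tight bounding box of boundary pixels into a 5×7 grid;
    a cell is on iff it contains at least one boundary pixel."""
    rows, cols = np.nonzero(boundary.pixels)
    if rows.size == 0:
        raise ValueError("cannot normalize an empty boundary")
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    hb, wb = r1 - r0 + 1, c1 - c0 + 1
    cell_r = (rows - r0) * GRID_ROWS // hb
    cell_c = (cols - c0) * GRID_COLS // wb
    cells = np.zeros((GRID_ROWS, GRID_COLS), dtype=np.uint8)
    cells[cell_r, cell_c] = 1
    return BoundaryGrid(cells)


# ------------------------------------------------------- classifier network

_M1 = (100, 101, 102)
_M2_LAYERS = tuple(tuple(200 + 3 * l + j for j in range(3)) for l in range(4))
_M3_LAYERS = tuple(tuple(300 + 5 * l + j for j in range(5)) for l in range(4))
_INPUT_BLOCKS = (12, 12, 11)  # contiguous row-major cell blocks feeding Module 1


def _dense(edges: dict, src_layer, dst_layer) -> None:
    for i in src_layer:
        for j in dst_layer:
            edges[(i, j)] = 1.0


def trainable_edges() -> list[tuple[int, int]]:
    """Edges adjusted by learning: Module 2 → Module 3 and the edges into
    the output (last Module 3) layer."""
    edges = []
    for i in _M2_LAYERS[-1]:
        for j in _M3_LAYERS[0]:
            edges.append((i, j))
    for i in _M3_LAYERS[-2]:
        for j in _M3_LAYERS[-1]:
            edges.append((i, j))
    return edges


def build_network(
    grid: BoundaryGrid | None = None,
    weights: Mapping[tuple[int, int], float] | None = None,
    rng_seed: int = 0,
) -> SNPSystem:
    """Assemble the 3-module classification network.

    35 input neurons (one per grid cell) feed Module 1's three neurons in
    contiguous blocks of 12/12/11 cells; Modules 1→2→3 are densely wired
    layer to layer; every synapse weight is 1 unless a trained weight set
    is supplied.  All computation neurons carry the single relay rule.
    """
    neurons: dict[int, Neuron] = {}
    rule = relay_rule()
    cells = grid.cells.ravel() if grid is not None else np.zeros(35, dtype=np.uint8)
    for idx in range(35):
        neurons[idx] = Neuron(idx, pulses=int(cells[idx]), rules=(rule,))
    for lab in _M1 + sum(_M2_LAYERS, ()) + sum(_M3_LAYERS, ()):
        neurons[lab] = Neuron(lab, pulses=0, rules=(rule,))

    edges: dict[tuple[int, int], float] = {}
    start = 0
    for block, m1 in zip(_INPUT_BLOCKS, _M1):
        for idx in range(start, start + block):
            edges[(idx, m1)] = 1.0
        start += block
    _dense(edges, _M1, _M2_LAYERS[0])
    for l in range(3):
        _dense(edges, _M2_LAYERS[l], _M2_LAYERS[l + 1])
    _dense(edges, _M2_LAYERS[-1], _M3_LAYERS[0])
    for l in range(3):
        _dense(edges, _M3_LAYERS[l], _M3_LAYERS[l + 1])

    if weights is not None:
        for key, w in weights.items():
            key = tuple(key)
            if key not in edges:
                raise ValueError(f"weight for unknown synapse {key}")
            edges[key] = float(w)

    return SNPSystem(
        neurons=neurons,
        syn=edges,
        input_labels=tuple(range(35)),
        output_labels=_M3_LAYERS[-1],
        rng_seed=rng_seed,
    )


def network_depth(system: SNPSystem) -> int:
    """Longest directed path length (edges) by Bellman-Ford-style
    relaxation; returns the neuron count as a conservative bound when
    the synapse graph is cyclic."""
    order = sorted(system.neurons)
    depth = {lab: 0 for lab in order}
    changed = True
    rounds = 0
    while changed and rounds <= len(order):
        changed = False
        rounds += 1
        for (i, j), _w in system.syn.items():
            if depth[i] + 1 > depth[j]:
                depth[j] = depth[i] + 1
                changed = True
    if rounds > len(order):
        return len(order)  # cycle: conservative bound
    return max(depth.values(), default=0)


# ----------------------------------------------------- training and scoring

@dataclass(frozen=True)
class TrainedWeights:
    """Per-synapse weights for the trainable edges, the fitted decision
    threshold, and the per-epoch misclassification history."""

    weights: dict[tuple[int, int], float]
    threshold: float
    history: tuple[int, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": {f"{i}->{j}": w for (i, j), w in sorted(self.weights.items())},
                "threshold": self.threshold,
                "history": list(self.history),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainedWeights":
        doc = json.loads(text)
        weights = {}
        for key, w in doc["weights"].items():
            i, j = key.split("->")
            weights[(int(i), int(j))] = float(w)
        return cls(weights=weights, threshold=float(doc["threshold"]),
                   history=tuple(doc["history"]))


def network_score(
    grid: BoundaryGrid,
    weights: Mapping[tuple[int, int], float] | None = None,
    output_weights: Mapping[int, float] | None = None,
    max_steps: int | None = None,
) -> tuple[float, dict[int, int]]:
    """Run the classifier network on one grid and return (score, counts)."""
    system = build_network(grid, weights=weights)
    counts, halted, _steps = run(system, max_steps=max_steps)
    if not halted:
        raise RuntimeError("classifier network failed to halt")
    score = sum(
        (output_weights.get(lab, 1.0) if output_weights else 1.0) * cnt
        for lab, cnt in counts.items()
    )
    return float(score), counts


def _best_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, int]:
    """Threshold (label = score >= thr) minimizing training errors;
    midpoints between consecutive distinct scores are the candidates."""
    uniq = np.unique(scores)
    candidates = [uniq[0] - 1.0]
    candidates += list((uniq[:-1] + uniq[1:]) / 2.0)
    candidates.append(uniq[-1] + 1.0)
    best_thr, best_err = candidates[0], len(labels) + 1
    for thr in candidates:
        err = int(np.sum((scores >= thr).astype(int) != labels))
        if err < best_err:
            best_thr, best_err = thr, err
    return float(best_thr), best_err


W_MAX = 8.0


def train(
    grids: Sequence[BoundaryGrid],
    labels: Sequence[int],
    epochs: int = 50,
    learning_rate: float = 0.1,
    seed: int = 0,
) -> TrainedWeights:
    """Perceptron-style weight learning on the trainable synapses.

    Each epoch scores every training grid, refits the decision threshold,
    and on each misclassified example nudges the weights of trainable
    edges that carried pulses by ±learning_rate (up for a missed
    spiculated case, down for a false positive), clipped to [0, 8].
    Stops early once the epoch is error-free.
    """
    labels = np.asarray(labels, dtype=int)
    if len(grids) != len(labels) or len(grids) == 0:
        raise ValueError("grids and labels must be equally sized and non-empty")
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires examples from both classes")
    del seed  # deterministic path; kept for interface stability
    edges = trainable_edges()
    weights = {e: 1.0 for e in edges}
    history: list[int] = []
    best: tuple[int, dict, float] | None = None
    patience, stall = 5, 0
    for _epoch in range(epochs):
        scores = np.array([network_score(g, weights)[0] for g in grids])
        threshold, err = _best_threshold(scores, labels)
        history.append(err)
        if best is None or err < best[0]:
            best = (err, dict(weights), threshold)
            stall = 0
        else:
            stall += 1
        if err == 0 or stall >= patience:
            break
        preds = (scores >= threshold).astype(int)
        for g, y, yhat in zip(grids, labels, preds):
            if y == yhat or g.total_pulses() == 0:
                continue
            direction = 1.0 if y == 1 else -1.0
            for e in edges:
                weights[e] = float(np.clip(weights[e] + direction * learning_rate, 0.0, W_MAX))
    if best is not None:
        _err, weights, threshold = best
    else:  # epochs == 0: untouched unit weights, zero threshold
        threshold = 0.0
    return TrainedWeights(weights=weights, threshold=threshold, history=tuple(history))


def classify(
    output_counts: Mapping[int, int],
    threshold: float,
    output_weights: Mapping[int, float] | None = None,
) -> tuple[int, float]:
    """Weighted-sum decision: label = (score >= threshold)."""
    score = sum(
        (output_weights.get(lab, 1.0) if output_weights else 1.0) * cnt
        for lab, cnt in output_counts.items()
    )
    return int(score >= threshold), float(score)
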