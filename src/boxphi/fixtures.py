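"""Bundled demonstration systems and a seeded random-network generator.

Three systems ship with the package:

``xor_delay``
    Nine elements: three XOR gates coupled all-to-all through COPY elements
    that model one-step propagation delay.  Canonical macro view: three
    black boxes, each hiding its two input COPYs, at a time scale of two
    micro updates.

``nor_hierarchy``
    Fifty-five NOR elements in five groups of eleven.  Each group realises
    AND/OR logic at a time scale of two micro updates and MAJORITY of its
    three group inputs at a time scale of four.

``cell_cycle``
    The nine-element linear-threshold Boolean model of the fission-yeast
    cell cycle (Davidich & Bornholdt 2008), with its 9-state biological
    sequence.  The catalyst element SK receives no feedback and is treated
    as a background condition.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .blackbox import BlackBoxMapping
from .network import (MicroNetwork, NetworkSpecError, TruthTable,
                      parse_network, _gate_table)

__all__ = [
    "Fixture",
    "BiologicalSequence",
    "FIXTURE_NAMES",
    "make_fixture",
    "fixture_text",
    "random_network",
]

FIXTURE_NAMES = ("xor_delay", "nor_hierarchy", "cell_cycle")


@dataclass
class BiologicalSequence:
    """The ordered cell-division states t1..t9 of the cell-cycle model.

    ``excluded_states`` are sequence indices whose cause-effect structure is
    undefined within the 8-element network (t2 is caused by the external
    catalyst SK, not by the system itself).
    """

    states: list
    excluded_states: tuple = (1,)

    def analyzable(self):
        """(index, state) pairs with a defined cause-effect structure."""
        return [(i, s) for i, s in enumerate(self.states)
                if i not in self.excluded_states]


@dataclass
class Fixture:
    name: str
    network: MicroNetwork
    state: dict
    background: dict = field(default_factory=dict)
    mappings: dict = field(default_factory=dict)
    sequence: BiologicalSequence | None = None


def fixture_text(name: str) -> str:
    """Raw canonical spec text of a bundled system."""
    if name not in FIXTURE_NAMES:
        raise NetworkSpecError(
            f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    ref = importlib.resources.files("boxphi").joinpath(f"data/{name}.yaml")
    return ref.read_text()


def make_fixture(name: str) -> Fixture:
    """Load a bundled system with its canonical node order, analysed
    state(s), and standard black-box mappings."""
    text = fixture_text(name)
    net, state, background, mapping_block = parse_network(text)
    mappings = {}
    sequence = None
    if mapping_block:
        mappings["canonical"] = BlackBoxMapping(
            boxes={k: tuple(v) for k, v in mapping_block["boxes"].items()},
            outputs=dict(mapping_block["outputs"]),
            timescale=int(mapping_block["timescale"]),
            background=dict(background))
    if name == "nor_hierarchy":
        mappings.update(_nor_mappings(net))
    if name == "cell_cycle":
        order = net.metadata["node_order"]
        assert tuple(order) == net.node_labels
        seq = [tuple(s) for s in net.metadata["biological_sequence"]]
        sequence = BiologicalSequence(
            seq, tuple(net.metadata["excluded_states"]))
    return Fixture(name, net, state, background, mappings, sequence)


def _nor_mappings(net: MicroNetwork) -> dict:
    """The two canonical black-boxings of the 55-NOR hierarchy."""
    and_or = {}
    outputs_2 = {}
    majority = {}
    outputs_4 = {}
    for g in range(5):
        for a in range(3):
            box = f"g{g}A{a}"
            and_or[box] = (f"g{g}_and{a}_na", f"g{g}_and{a}_nb",
                           f"g{g}_and{a}_out")
            outputs_2[box] = f"g{g}_and{a}_out"
        and_or[f"g{g}O"] = (f"g{g}_or_n", f"g{g}_out")
        outputs_2[f"g{g}O"] = f"g{g}_out"
        majority[f"G{g}"] = tuple(
            l for l in net.node_labels if l.startswith(f"g{g}_"))
        outputs_4[f"G{g}"] = f"g{g}_out"
    return {
        "and_or": BlackBoxMapping(and_or, outputs_2, timescale=2),
        "majority": BlackBoxMapping(majority, outputs_4, timescale=4),
    }


def random_network(n: int, k: int, gate_family="NOR", seed: int = 0
                   ) -> MicroNetwork:
    """Reproducible random network: each node reads ``k`` distinct other
    nodes through a gate drawn from ``gate_family`` (a name or a sequence
    of names).  The same seed yields a byte-identical specification."""
    if n < 1 or k < 1:
        raise ValueError("n and k must be positive")
    if k >= n:
        raise ValueError("in-degree k must be smaller than n")
    if isinstance(gate_family, str):
        gate_family = (gate_family,)
    rng = np.random.default_rng(seed)
    labels = tuple(f"n{i}" for i in range(n))
    functions, wiring = {}, {}
    for i, lbl in enumerate(labels):
        others = [l for l in labels if l != lbl]
        ins = tuple(others[j] for j in sorted(
            rng.choice(len(others), size=k, replace=False)))
        gate = gate_family[int(rng.integers(len(gate_family)))]
        arity = 1 if gate in ("COPY", "NOT") else k
        wiring[lbl] = ins[:arity]
        functions[lbl] = TruthTable(_gate_table(gate, arity))
    return MicroNetwork(labels, functions, wiring,
                        metadata={"seed": int(seed), "k": int(k)})
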