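"""Discrete logic networks and their transition probability models.

A network is a set of binary elements, each with an ordered list of inputs
and an update rule (an explicit truth table or signed-weight threshold
logic).  All elements update synchronously at discrete time steps.  The
causal analysis in the rest of the package operates on the network's
transition probability model, obtained by perturbing the elements into all
possible states with a maximum-entropy distribution and recording the
distribution of each element's next state ("state-by-node" form).  Elements
outside the analysed system are clamped to fixed values ("background
conditions") while the model is built.

State indexing is little-endian throughout: element 0 of the declared node
order is the least-significant bit of a state index.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "NodeFunction",
    "TruthTable",
    "Threshold",
    "MicroNetwork",
    "TransitionModel",
    "NodeModel",
    "CandidateSystem",
    "NetworkSpecError",
    "ValidationError",
    "state_index",
    "state_from_index",
    "all_states",
    "build_transition_model",
    "simulate",
    "parse_network",
    "parse_network_file",
    "write_network",
    "GATES",
]

PROB_TOL = 1e-9


class NetworkSpecError(ValueError):
    """A network specification refers to unknown nodes or malformed blocks."""


class ValidationError(ValueError):
    """A structurally valid specification carries invalid values."""


# --------------------------------------------------------------------------
# State indexing (little-endian, node 0 = least-significant bit)
# --------------------------------------------------------------------------

def state_index(state) -> int:
    """Map a binary state tuple to its little-endian integer index."""
    idx = 0
    for k, v in enumerate(state):
        if v not in (0, 1):
            raise ValidationError(f"state values must be binary, got {v!r}")
        idx |= int(v) << k
    return idx


def state_from_index(idx: int, n: int) -> tuple:
    """Inverse of :func:`state_index` for an ``n``-element system."""
    if not 0 <= idx < (1 << n):
        raise ValidationError(f"state index {idx} out of range for {n} nodes")
    return tuple((idx >> k) & 1 for k in range(n))


def all_states(n: int):
    """Iterate over all 2**n states in index order."""
    for idx in range(1 << n):
        yield state_from_index(idx, n)


# --------------------------------------------------------------------------
# Node update rules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthTable:
    """Explicit update rule: probability of turning ON per input configuration.

    ``probs[i]`` is p(node = 1) for the input configuration with little-endian
    index ``i`` over the node's declared input order.
    """

    probs: tuple

    def __post_init__(self):
        k = len(self.probs).bit_length() - 1
        if len(self.probs) != 1 << k:
            raise ValidationError("truth table length must be a power of two")
        for p in self.probs:
            if not -PROB_TOL <= p <= 1 + PROB_TOL:
                raise ValidationError(f"probability {p} outside [0, 1]")

    @property
    def n_inputs(self) -> int:
        return len(self.probs).bit_length() - 1

    def is_deterministic(self) -> bool:
        return all(p in (0.0, 1.0) or abs(p) < 1e-12 or abs(p - 1) < 1e-12
                   for p in self.probs)


@dataclass(frozen=True)
class Threshold:
    """Signed-weight threshold logic.

    The next state is ON if the weighted input sum exceeds ``threshold``, OFF
    if it falls below, and decided by ``tie`` at equality: ``"hold"`` keeps
    the element's previous state (making the element implicitly self-dependent
    whenever the threshold is attainable), ``"off"``/``"on"`` force a value.
    """

    weights: tuple
    threshold: float = 0.0
    tie: str = "hold"

    def __post_init__(self):
        if self.tie not in ("hold", "off", "on"):
            raise ValidationError(f"unknown tie rule {self.tie!r}")

    @property
    def n_inputs(self) -> int:
        return len(self.weights)

    def tie_attainable(self) -> bool:
        """Whether some input configuration makes the sum equal the threshold."""
        sums = {0.0}
        for w in self.weights:
            sums = {s + w * v for s in sums for v in (0, 1)}
        return any(abs(s - self.threshold) < 1e-9 for s in sums)


NodeFunction = TruthTable | Threshold


def _gate_table(name: str, k: int) -> tuple:
    """Truth table (p(ON) per little-endian input config) for a named gate."""
    name = name.upper()
    out = []
    for idx in range(1 << k):
        bits = [(idx >> j) & 1 for j in range(k)]
        s = sum(bits)
        if name == "XOR":
            v = s % 2
        elif name == "NOR":
            v = 1 if s == 0 else 0
        elif name == "OR":
            v = 1 if s > 0 else 0
        elif name == "AND":
            v = 1 if s == k else 0
        elif name == "NAND":
            v = 0 if s == k else 1
        elif name in ("COPY", "BUFFER"):
            if k != 1:
                raise ValidationError("COPY takes exactly one input")
            v = bits[0]
        elif name == "NOT":
            if k != 1:
                raise ValidationError("NOT takes exactly one input")
            v = 1 - bits[0]
        elif name == "MAJORITY":
            v = 1 if 2 * s > k else 0
        else:
            raise NetworkSpecError(f"unknown gate {name!r}")
        out.append(float(v))
    return tuple(out)


GATES = ("XOR", "NOR", "OR", "AND", "NAND", "COPY", "NOT", "MAJORITY")


# --------------------------------------------------------------------------
# MicroNetwork
# --------------------------------------------------------------------------

@dataclass
class MicroNetwork:
    """A synchronously updated network of binary logic elements.

    ``node_labels`` fixes the global element order used for state indexing.
    ``wiring[label]`` is the ordered tuple of input labels consumed by the
    element's update rule (empty for input-free elements, which are then
    constant or externally driven).
    """

    node_labels: tuple
    functions: dict
    wiring: dict
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.node_labels = tuple(self.node_labels)
        labels = set(self.node_labels)
        if len(labels) != len(self.node_labels):
            raise NetworkSpecError("duplicate node labels")
        for lbl in self.node_labels:
            if lbl not in self.functions:
                raise NetworkSpecError(f"node {lbl!r} has no update function")
            ins = tuple(self.wiring.get(lbl, ()))
            self.wiring[lbl] = ins
            for src in ins:
                if src not in labels:
                    raise NetworkSpecError(
                        f"input {src!r} of node {lbl!r} is not a declared node")
            fn = self.functions[lbl]
            if fn.n_inputs != len(ins):
                raise NetworkSpecError(
                    f"node {lbl!r}: function consumes {fn.n_inputs} inputs "
                    f"but {len(ins)} are wired")

    @property
    def n(self) -> int:
        return len(self.node_labels)

    def index(self, label) -> int:
        try:
            return self.node_labels.index(label)
        except ValueError:
            raise NetworkSpecError(f"unknown node label {label!r}") from None

    def effective_rule(self, label):
        """Materialise the update rule of ``label`` as a truth table.

        Returns ``(input_labels, probs)`` where ``probs`` is a flat float
        array over the little-endian configurations of ``input_labels``.
        Threshold elements with an attainable tie under the ``hold`` rule gain
        their own previous state as an extra (implicit) input.
        """
        fn = self.functions[label]
        ins = list(self.wiring[label])
        if isinstance(fn, TruthTable):
            return tuple(ins), np.asarray(fn.probs, dtype=float)
        assert isinstance(fn, Threshold)
        self_dep = fn.tie == "hold" and fn.tie_attainable()
        ext = list(ins)
        if self_dep and label not in ext:
            ext.append(label)
        k = len(ext)
        probs = np.empty(1 << k)
        for idx in range(1 << k):
            cfg = {lbl: (idx >> j) & 1 for j, lbl in enumerate(ext)}
            s = sum(w * cfg[src] for w, src in zip(fn.weights, ins))
            if s > fn.threshold + 1e-9:
                v = 1.0
            elif s < fn.threshold - 1e-9:
                v = 0.0
            elif fn.tie == "on":
                v = 1.0
            elif fn.tie == "off":
                v = 0.0
            else:  # hold
                v = float(cfg[label]) if self_dep else 0.0
            probs[idx] = v
        return tuple(ext), probs

    def is_deterministic(self) -> bool:
        return all(
            fn.is_deterministic() if isinstance(fn, TruthTable) else True
            for fn in self.functions.values())

    def edges(self):
        """Directed (source, target) pairs, including implicit self-inputs."""
        out = []
        for lbl in self.node_labels:
            ins, _ = self.effective_rule(lbl)
            out.extend((src, lbl) for src in ins)
        return out


# --------------------------------------------------------------------------
# Transition model
# --------------------------------------------------------------------------

@dataclass
class NodeModel:
    """One analysis unit of a transition model.

    ``inputs`` are unit indices (sorted ascending); ``table`` is the tensor of
    p(unit = 1 | inputs) with shape ``(2,) * len(inputs)`` whose axis ``k``
    corresponds to ``inputs[k]`` (axis index 0 = OFF).
    """

    inputs: tuple
    table: np.ndarray

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (2,) * len(self.inputs):
            self.table = self.table.reshape((2,) * len(self.inputs), order="F")
        if np.any(self.table < -PROB_TOL) or np.any(self.table > 1 + PROB_TOL):
            raise ValidationError("node probability outside [0, 1]")

    def pruned(self) -> "NodeModel":
        """Drop inputs the table does not actually depend on."""
        keep, tbl = [], self.table
        for k in range(len(self.inputs) - 1, -1, -1):
            sl0 = np.take(tbl, 0, axis=k)
            sl1 = np.take(tbl, 1, axis=k)
            if np.max(np.abs(sl0 - sl1)) < 1e-12:
                tbl = sl0
            else:
                keep.append(k)
        keep = sorted(keep)
        return NodeModel(tuple(self.inputs[k] for k in keep), tbl)

    def marginalized(self, unit: int) -> "NodeModel":
        """Replace input ``unit`` by maximum-entropy noise (uniform average)."""
        if unit not in self.inputs:
            return self
        k = self.inputs.index(unit)
        tbl = self.table.mean(axis=k)
        ins = self.inputs[:k] + self.inputs[k + 1:]
        return NodeModel(ins, tbl)

    def prob_on(self, state) -> float:
        """p(unit = 1) given the full previous unit state tuple."""
        idx = tuple(state[i] for i in self.inputs)
        return float(self.table[idx])


@dataclass
class TransitionModel:
    """Conditional next-state model of a candidate system.

    Stores one :class:`NodeModel` per unit (state-by-node form; units are
    conditionally independent given the full previous state).  The dense
    state-by-state matrix is derived on demand.
    """

    labels: tuple
    nodes: list

    @property
    def n(self) -> int:
        return len(self.labels)

    def node_probabilities(self) -> np.ndarray:
        """(2**n, n) array of p(unit_j(t+1) = 1 | state at t)."""
        n = self.n
        out = np.empty((1 << n, n))
        for idx in range(1 << n):
            s = state_from_index(idx, n)
            for j, nm in enumerate(self.nodes):
                out[idx, j] = nm.prob_on(s)
        return out

    def state_by_state(self) -> np.ndarray:
        """Dense (2**n, 2**n) transition matrix; rows sum to one."""
        n = self.n
        probs = self.node_probabilities()
        out = np.ones((1 << n, 1 << n))
        for j in range(n):
            col = np.array([(idx >> j) & 1 for idx in range(1 << n)])
            p1 = probs[:, j][:, None]
            out *= np.where(col[None, :] == 1, p1, 1.0 - p1)
        return out

    def is_deterministic(self) -> bool:
        return all(
            np.all((np.abs(nm.table) < 1e-12) | (np.abs(nm.table - 1) < 1e-12))
            for nm in self.nodes)

    def pruned(self) -> "TransitionModel":
        return TransitionModel(self.labels, [nm.pruned() for nm in self.nodes])


def build_transition_model(network: MicroNetwork, background: dict | None = None
                           ) -> TransitionModel:
    """Transition model of the system nodes with background nodes clamped.

    ``background`` maps node labels to fixed binary values; the remaining
    nodes form the system.  Every system node's inputs must be system or
    background nodes (guaranteed here since the two sets cover the network).
    Deterministic networks yield tables with entries in {0, 1}.
    """
    background = dict(background or {})
    for lbl, v in background.items():
        if lbl not in network.node_labels:
            raise NetworkSpecError(f"unknown background node {lbl!r}")
        if v not in (0, 1):
            raise ValidationError(f"background value for {lbl!r} must be 0/1")
    sys_labels = tuple(l for l in network.node_labels if l not in background)
    if not sys_labels:
        raise ValidationError("candidate system is empty")
    sys_index = {l: i for i, l in enumerate(sys_labels)}
    nodes = []
    for lbl in sys_labels:
        ins, probs = network.effective_rule(lbl)
        tbl = probs.reshape((2,) * len(ins), order="F")
        # clamp background inputs, keep system inputs
        keep = []
        for k, src in enumerate(ins):
            if src in background:
                tbl = np.take(tbl, background[src], axis=len(keep))
            else:
                keep.append(src)
        order = np.argsort([sys_index[s] for s in keep])
        tbl = np.transpose(tbl, axes=tuple(order)) if keep else tbl
        nodes.append(NodeModel(tuple(sorted(sys_index[s] for s in keep)), tbl))
    return TransitionModel(sys_labels, nodes)


@dataclass
class CandidateSystem:
    """A subset of network nodes analysed in a state, with the complement
    clamped as background conditions."""

    network: MicroNetwork
    system_nodes: tuple
    background_state: dict
    current_state: tuple

    def __post_init__(self):
        self.system_nodes = tuple(self.system_nodes)
        if not self.system_nodes:
            raise ValidationError("system_nodes must be nonempty")
        comp = set(self.network.node_labels) - set(self.system_nodes)
        if set(self.background_state) != comp:
            raise ValidationError(
                "background_state must cover exactly the non-system nodes")
        if len(self.current_state) != len(self.system_nodes):
            raise ValidationError("current_state length mismatch")

    def transition_model(self) -> TransitionModel:
        return build_transition_model(self.network, self.background_state)


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

def simulate(network: MicroNetwork, start, steps: int):
    """Synchronous trajectory of a deterministic network.

    Returns ``steps + 1`` states including ``start``.  Stochastic update
    rules are refused (sampling them would need a seed and no bundled system
    requires it).
    """
    if not network.is_deterministic():
        raise ValidationError("simulate requires a deterministic network")
    rules = {lbl: network.effective_rule(lbl) for lbl in network.node_labels}
    for lbl, (_, probs) in rules.items():
        if not np.all((probs == 0) | (probs == 1)):
            raise ValidationError(f"node {lbl!r} has stochastic entries")
    state = tuple(int(v) for v in start)
    if len(state) != network.n:
        raise ValidationError("start state length mismatch")
    pos = {l: i for i, l in enumerate(network.node_labels)}
    traj = [state]
    for _ in range(steps):
        nxt = []
        for lbl in network.node_labels:
            ins, probs = rules[lbl]
            idx = 0
            for k, src in enumerate(ins):
                idx |= state[pos[src]] << k
            nxt.append(int(probs[idx]))
        state = tuple(nxt)
        traj.append(state)
    return traj


# --------------------------------------------------------------------------
# Network spec files (one canonical YAML dialect)
# --------------------------------------------------------------------------

_TOP_KEYS = {"nodes", "edges", "state", "background",
             "boxes", "outputs", "timescale", "metadata"}
_NODE_KEYS = {"label", "gate", "kind", "table", "threshold", "tie"}
_EDGE_KEYS = {"from", "to", "weight"}


def parse_network(text: str):
    """Parse the canonical network spec dialect.

    Returns ``(network, state, background, mapping_block)`` where ``state``
    and ``background`` are dicts (possibly empty) and ``mapping_block`` is the
    raw black-box mapping section (``boxes``/``outputs``/``timescale``) or
    ``None``.  Unknown keys are rejected.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise NetworkSpecError(f"malformed spec: {exc}") from exc
    if not isinstance(doc, dict):
        raise NetworkSpecError("spec must be a mapping at top level")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise NetworkSpecError(f"unknown top-level keys: {sorted(unknown)}")
    if "nodes" not in doc:
        raise NetworkSpecError("missing 'nodes' block")

    labels, kinds = [], {}
    for entry in doc["nodes"]:
        if not isinstance(entry, dict):
            raise NetworkSpecError(f"node entry must be a mapping: {entry!r}")
        unknown = set(entry) - _NODE_KEYS
        if unknown:
            raise NetworkSpecError(
                f"unknown node keys {sorted(unknown)} in {entry.get('label')!r}")
        if "label" not in entry:
            raise NetworkSpecError(f"node entry without label: {entry!r}")
        labels.append(entry["label"])
        kinds[entry["label"]] = entry

    wiring = {l: [] for l in labels}
    weights = {l: [] for l in labels}
    for entry in doc.get("edges") or []:
        unknown = set(entry) - _EDGE_KEYS
        if unknown:
            raise NetworkSpecError(f"unknown edge keys: {sorted(unknown)}")
        src, dst = entry.get("from"), entry.get("to")
        if src not in kinds or dst not in kinds:
            raise NetworkSpecError(f"edge {src!r} -> {dst!r} names unknown nodes")
        wiring[dst].append(src)
        weights[dst].append(entry.get("weight", 1))

    functions = {}
    for lbl in labels:
        entry = kinds[lbl]
        k = len(wiring[lbl])
        if "gate" in entry:
            functions[lbl] = TruthTable(_gate_table(entry["gate"], k))
        elif entry.get("kind") in ("threshold", "signed-threshold"):
            functions[lbl] = Threshold(
                weights=tuple(weights[lbl]),
                threshold=float(entry.get("threshold", 0.0)),
                tie=entry.get("tie", "hold"))
        elif entry.get("kind") in ("truth-table", None) and "table" in entry:
            functions[lbl] = TruthTable(tuple(float(p) for p in entry["table"]))
        else:
            raise NetworkSpecError(
                f"node {lbl!r} needs a 'gate', a 'table' or kind: threshold")

    net = MicroNetwork(tuple(labels), functions,
                       {l: tuple(w) for l, w in wiring.items()},
                       metadata=dict(doc.get("metadata") or {}))
    state = dict(doc.get("state") or {})
    background = dict(doc.get("background") or {})
    for d in (state, background):
        for lbl, v in d.items():
            if lbl not in kinds:
                raise NetworkSpecError(f"unknown node {lbl!r} in state block")
            if v not in (0, 1):
                raise ValidationError(f"state value for {lbl!r} must be 0/1")
    mapping = None
    if "boxes" in doc or "outputs" in doc or "timescale" in doc:
        mapping = {"boxes": doc.get("boxes"), "outputs": doc.get("outputs"),
                   "timescale": doc.get("timescale", 1)}
    return net, state, background, mapping


def parse_network_file(path):
    with open(path) as fh:
        return parse_network(fh.read())


def write_network(network: MicroNetwork, state: dict | None = None,
                  background: dict | None = None, mapping: dict | None = None
                  ) -> str:
    """Serialise a network (and optional state/mapping blocks) to the
    canonical dialect; ``parse_network(write_network(x))`` round-trips."""
    nodes, edges = [], []
    for lbl in network.node_labels:
        fn = network.functions[lbl]
        if isinstance(fn, TruthTable):
            nodes.append({"label": lbl, "kind": "truth-table",
                          "table": [float(p) for p in fn.probs]})
            for src in network.wiring[lbl]:
                edges.append({"from": src, "to": lbl})
        else:
            nodes.append({"label": lbl, "kind": "threshold",
                          "threshold": float(fn.threshold), "tie": fn.tie})
            for src, w in zip(network.wiring[lbl], fn.weights):
                edges.append({"from": src, "to": lbl, "weight": int(w)})
    doc = {"nodes": nodes, "edges": edges}
    if network.metadata:
        doc["metadata"] = dict(network.metadata)
    if state:
        doc["state"] = dict(state)
    if background:
        doc["background"] = dict(background)
    if mapping:
        doc.update({k: v for k, v in mapping.items() if v is not None})
    return yaml.safe_dump(doc, sort_keys=False)
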