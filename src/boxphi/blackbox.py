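"""Black-box macro elements: grouping, validation, and macro model derivation.

A black-box mapping groups disjoint subsets of micro elements into macro
elements ("boxes"), designates one *output* micro element per box, and fixes
a macro time scale of T micro updates per macro update.  The macro state of
a box is the state of its output element at the end of the macro update; the
remaining ("hidden") elements support the box's input-output function but
are concealed from the causal analysis.

The macro transition model is derived by perturbation: for every macro
state, each box's output element is clamped to its macro value at the start
of the macro update and all hidden elements are set to maximum entropy
(marginalised exactly, not sampled).  Cross-box connections transmit the
true source state only at the first micro update — inputs arrive at the
beginning of the macro time step — and are maximum-entropy noised at later
micro updates; connections leaving a box from non-output elements are always
noised; micro elements outside every box are background conditions, held
fixed.  Because all later-step cross-box influences are noised, each box's
macro table factorises and can be computed independently, which keeps large
substrates tractable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import (MicroNetwork, NodeModel, TransitionModel,
                      ValidationError)

__all__ = [
    "BlackBoxMapping",
    "MacroSystem",
    "Violation",
    "validate_mapping",
    "build_macro_system",
    "screened_off_check",
    "identity_mapping",
]

log = logging.getLogger("boxphi")


@dataclass(frozen=True)
class Violation:
    condition: str    # "i" | "iii" | "iv" | "structure"
    message: str


@dataclass
class BlackBoxMapping:
    """The map from micro onto macro: disjoint boxes, one output element per
    box, a time scale T >= 1, and fixed background states for micro elements
    outside every box."""

    boxes: dict              # box name -> tuple of micro labels
    outputs: dict            # box name -> designated output label
    timescale: int = 1
    background: dict = field(default_factory=dict)   # micro label -> 0/1

    def __post_init__(self):
        self.boxes = {name: tuple(members)
                      for name, members in self.boxes.items()}

    @property
    def box_names(self):
        return tuple(self.boxes)

    def constitution(self):
        """All micro elements inside boxes, in box order."""
        return tuple(l for name in self.boxes for l in self.boxes[name])

    def canonical(self):
        """Hashable normal form (box names are not identity)."""
        return (frozenset((frozenset(mem), self.outputs[name])
                          for name, mem in self.boxes.items()),
                self.timescale,
                frozenset(self.background.items()))


def identity_mapping(network: MicroNetwork, background=None) -> BlackBoxMapping:
    """Every non-background node its own box, T = 1, output = itself."""
    background = dict(background or {})
    boxes = {l: (l,) for l in network.node_labels if l not in background}
    outputs = {l: l for l in boxes}
    return BlackBoxMapping(boxes, outputs, 1, background)


# --------------------------------------------------------------------------
# Validation (black-box conditions)
# --------------------------------------------------------------------------

def validate_mapping(network: MicroNetwork, mapping: BlackBoxMapping):
    """Check the black-box conditions that are decidable structurally.

    Returns a list of :class:`Violation` (empty = ok).  Condition (iii) —
    every micro element causally contributes to its box's output — gets a
    structural pre-check (a directed path to the output realisable within T
    steps); its full force is enforced by Phi = 0 at evaluation.
    """
    v = []
    labels = set(network.node_labels)
    seen = {}
    for name, members in mapping.boxes.items():
        if not members:
            v.append(Violation("structure", f"box {name!r} is empty"))
            continue
        for l in members:
            if l not in labels:
                v.append(Violation("structure",
                                   f"box {name!r} member {l!r} unknown"))
            elif l in seen:
                v.append(Violation(
                    "iv", f"micro element {l!r} belongs to boxes "
                          f"{seen[l]!r} and {name!r} (overlap)"))
            seen.setdefault(l, name)
        out = mapping.outputs.get(name)
        if out is None:
            v.append(Violation("i", f"box {name!r} has no output element"))
        elif out not in members:
            v.append(Violation(
                "i", f"output {out!r} of box {name!r} is not a member"))
    if not isinstance(mapping.timescale, int) or mapping.timescale < 1:
        v.append(Violation("structure",
                           f"timescale must be an integer >= 1, "
                           f"got {mapping.timescale!r}"))
    boxed = set(seen)
    bg = set(mapping.background)
    for l in bg & boxed:
        v.append(Violation("structure",
                           f"background element {l!r} is inside a box"))
    for l, val in mapping.background.items():
        if l not in labels:
            v.append(Violation("structure", f"unknown background {l!r}"))
        elif val not in (0, 1):
            v.append(Violation("structure",
                               f"background {l!r} value must be 0/1"))
    uncovered = labels - boxed - bg
    if uncovered:
        v.append(Violation(
            "structure",
            f"elements {sorted(uncovered)} are neither boxed nor background"))
    if v:
        return v

    # condition (i): each box must receive input — from outside the box or
    # from its own output element (a macro-level self-connection)
    for name, members in mapping.boxes.items():
        mem = set(members)
        out = mapping.outputs[name]
        external = any(src not in mem or src == out
                       for l in members for src in network.wiring[l])
        if not external:
            v.append(Violation("i", f"box {name!r} receives no input"))

    # condition (iii) pre-check: hidden elements must be able to reach the
    # output through box-internal connections within T micro steps
    T = mapping.timescale
    for name, members in mapping.boxes.items():
        mem = set(members)
        g = nx.DiGraph()
        g.add_nodes_from(mem)
        for l in members:
            g.add_edges_from((src, l) for src in network.wiring[l]
                             if src in mem)
        out = mapping.outputs[name]
        dist = nx.single_source_shortest_path_length(g.reverse(copy=False),
                                                     out, cutoff=T)
        for l in members:
            if l == out:
                continue
            if l not in dist:
                v.append(Violation(
                    "iii", f"hidden element {l!r} of box {name!r} has no "
                           f"path to output {out!r} within {T} steps"))
    return v


# --------------------------------------------------------------------------
# Macro model derivation
# --------------------------------------------------------------------------

def _propagate(joint: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """One exact synchronous update of a joint distribution over k binary
    elements.  ``probs[x, j]`` is p(element j ON next | joint state x)."""
    nstates, k = probs.shape
    out = joint.ravel(order="F")[:, None]   # (states, partial-next)
    for j in range(k):
        pj = probs[:, j:j + 1]
        out = np.hstack([out * (1.0 - pj), out * pj])
    nxt = out.sum(axis=0)
    return nxt.reshape((2,) * k, order="F")


class MacroSystem:
    """A system of black-box macro elements over a micro network.

    Analysis units are the boxes; the micro substrate (for system cuts) is
    the union of all box members.  The macro transition model is rebuilt
    from the micro substrate for any set of severed micro connections, so
    system-level irreducibility is always assessed between micro elements.
    """

    def __init__(self, network: MicroNetwork, mapping: BlackBoxMapping,
                 macro_state=None):
        violations = validate_mapping(network, mapping)
        if violations:
            raise ValidationError(
                "invalid black-box mapping: "
                + "; ".join(f"({x.condition}) {x.message}" for x in violations))
        self.network = network
        self.mapping = mapping
        self.labels = mapping.box_names
        self.micro_labels = mapping.constitution()
        self._micro_index = {l: i for i, l in enumerate(self.micro_labels)}
        self._box_of = {l: name for name, mem in mapping.boxes.items()
                        for l in mem}
        self._unit_of_box = {name: u for u, name in enumerate(self.labels)}
        self._rules = {l: network.effective_rule(l)
                       for l in network.node_labels}
        self.state = None
        if macro_state is not None:
            self.state = tuple(int(x) for x in macro_state)
            if len(self.state) != len(self.labels):
                raise ValidationError("macro state length mismatch")
        self.macro_model = self.unit_models()
        # condition (i): every box must actually have two reachable states
        for u, nm in enumerate(self.macro_model.nodes):
            tbl = nm.table
            if np.all(tbl < 1e-12) or np.all(tbl > 1 - 1e-12):
                raise ValidationError(
                    f"box {self.labels[u]!r} violates condition (i): its "
                    "output cannot take both values")

    @classmethod
    def from_micro_state(cls, network, mapping, micro_state: dict):
        """Read the macro state off the output elements of a micro state."""
        macro = tuple(int(micro_state[mapping.outputs[name]])
                      for name in mapping.box_names)
        return cls(network, mapping, macro)

    def unit_members(self, unit: int):
        return self.mapping.boxes[self.labels[unit]]

    def micro_edges(self):
        """Wiring edges inside the substrate, as substrate-index pairs."""
        out = set()
        for l in self.micro_labels:
            j = self._micro_index[l]
            for src in self._rules[l][0]:
                if src in self._micro_index:
                    out.add((self._micro_index[src], j))
        return out

    # -- macro transition model -----------------------------------------

    def unit_models(self, severed=frozenset()) -> TransitionModel:
        """Per-box macro tables (boxes are conditionally independent because
        later-step cross-box influences are noised)."""
        nodes = [self._box_table(name, severed)
                 for name in self.mapping.box_names]
        return TransitionModel(self.labels, nodes)

    def _box_table(self, name: str, severed) -> NodeModel:
        mapping = self.mapping
        members = list(mapping.boxes[name])
        mem_pos = {l: k for k, l in enumerate(members)}
        out_label = mapping.outputs[name]
        T = mapping.timescale
        outputs_by_label = {mapping.outputs[b]: b for b in mapping.box_names}

        # candidate macro inputs: boxes whose output element feeds a member
        # through an unsevered connection (possibly this box itself)
        cand = set()
        for l in members:
            j = self._micro_index[l]
            for src in self._rules[l][0]:
                if src in outputs_by_label \
                        and (self._micro_index[src], j) not in severed:
                    cand.add(self._unit_of_box[outputs_by_label[src]])
        cand = sorted(cand)
        self_unit = self._unit_of_box[name]

        k = len(members)
        table = np.empty((2,) * len(cand))
        for cfg_idx in range(1 << len(cand)):
            cfg = {u: (cfg_idx >> c) & 1 for c, u in enumerate(cand)}
            # initial joint: output element clamped (if its value matters),
            # hidden elements at maximum entropy
            joint = np.ones((2,) * k) / (1 << k)
            if self_unit in cfg:
                v = cfg[self_unit]
                idx = [slice(None)] * k
                idx[mem_pos[out_label]] = 1 - v
                joint[tuple(idx)] = 0.0
                joint *= 2.0
            for step in range(1, T + 1):
                probs = self._step_probs(members, mem_pos, name, cfg,
                                         step, severed, k)
                joint = _propagate(joint, probs)
            p_on = joint.sum(axis=tuple(a for a in range(k)
                                        if a != mem_pos[out_label]))[1]
            table[tuple((cfg_idx >> c) & 1 for c in range(len(cand)))] = p_on
        return NodeModel(tuple(cand), table).pruned()

    def _step_probs(self, members, mem_pos, name, cfg, step, severed,
                    k) -> np.ndarray:
        """p(member ON next | joint member state) for one micro update."""
        mapping = self.mapping
        outputs_by_label = {mapping.outputs[b]: b for b in mapping.box_names}
        nstates = 1 << k
        probs = np.empty((nstates, k))
        for l in members:
            j_sub = mem_pos[l]
            j = self._micro_index[l]
            ins, flat = self._rules[l]
            tbl = flat.reshape((2,) * len(ins), order="F")
            kept_axes = []   # (axis-in-current-tbl, member position)
            pos = 0
            for src in ins:
                i = self._micro_index.get(src)
                if i is not None and (i, j) in severed:
                    tbl = tbl.mean(axis=pos)            # cut: always noised
                elif src in mem_pos:
                    kept_axes.append((pos, mem_pos[src]))
                    pos += 1
                    continue
                elif src in mapping.background:
                    tbl = np.take(tbl, mapping.background[src], axis=pos)
                elif src in outputs_by_label and step == 1:
                    u = self._unit_of_box[outputs_by_label[src]]
                    tbl = np.take(tbl, cfg[u], axis=pos)
                else:
                    # hidden element of another box, or a cross-box input
                    # after the first micro update: maximum-entropy noise
                    tbl = tbl.mean(axis=pos)
            # tbl now spans only internal member inputs (kept_axes order)
            if not kept_axes:
                probs[:, j_sub] = float(tbl)
                continue
            mem_axes = [mp for _, mp in kept_axes]
            if len(set(mem_axes)) == len(mem_axes):
                order = np.argsort(mem_axes)
                tbl = np.transpose(tbl, axes=tuple(order))
                sorted_axes = sorted(mem_axes)
                shape = [2 if a in sorted_axes else 1 for a in range(k)]
                full = np.broadcast_to(tbl.reshape(shape), (2,) * k)
                probs[:, j_sub] = full.ravel(order="F")
            else:       # duplicate internal wiring: evaluate state by state
                for x in range(nstates):
                    st = [(x >> a) & 1 for a in range(k)]
                    probs[x, j_sub] = tbl[tuple(st[mp] for mp in mem_axes)]
        return probs

    # -- symmetry support -------------------------------------------------

    def network_automorphisms(self):
        """Substrate permutations preserving the (background-conditioned)
        micro models, the box structure, outputs, and the macro state."""
        from .system import model_automorphisms

        micro_model = self._substrate_model()
        cand = model_automorphisms(micro_model, state=None,
                                   colors=self._micro_colors())
        boxes = {name: frozenset(self._micro_index[l] for l in mem)
                 for name, mem in self.mapping.boxes.items()}
        out_idx = {name: self._micro_index[self.mapping.outputs[name]]
                   for name in self.mapping.box_names}
        state_of = {name: (None if self.state is None
                           else self.state[self._unit_of_box[name]])
                    for name in self.mapping.box_names}
        perms = []
        for perm in cand:
            ok = True
            for name, mem in boxes.items():
                img = frozenset(perm[i] for i in mem)
                match = next((b for b, m2 in boxes.items() if m2 == img), None)
                if match is None or perm[out_idx[name]] != out_idx[match] \
                        or state_of[name] != state_of[match]:
                    ok = False
                    break
            if ok:
                perms.append(perm)
        return perms

    def _substrate_model(self) -> TransitionModel:
        """Micro node models over the substrate with background clamped."""
        nodes = []
        for l in self.micro_labels:
            ins, flat = self._rules[l]
            tbl = flat.reshape((2,) * len(ins), order="F")
            keep = []
            for src in ins:
                if src in self._micro_index:
                    keep.append(src)
                else:
                    tbl = np.take(tbl, self.mapping.background[src],
                                  axis=len(keep))
            order = np.argsort([self._micro_index[s] for s in keep])
            if keep:
                tbl = np.transpose(tbl, axes=tuple(order))
            nodes.append(NodeModel(
                tuple(sorted(self._micro_index[s] for s in keep)), tbl))
        return TransitionModel(self.micro_labels, nodes)

    def _micro_colors(self):
        """Per-substrate-element invariants for automorphism candidates."""
        cols = []
        for l in self.micro_labels:
            box = self._box_of[l]
            cols.append((len(self.mapping.boxes[box]),
                         self.mapping.outputs[box] == l))
        return cols


def build_macro_system(network: MicroNetwork, mapping: BlackBoxMapping,
                       micro_state: dict | None = None,
                       macro_state=None) -> MacroSystem:
    """Derive the macro transition model for a validated black-box mapping.

    The macro state, when wanted for cause-effect analysis, is either given
    directly or read off the output elements of a full micro state.
    """
    if micro_state is not None:
        if macro_state is not None:
            raise ValueError("give either micro_state or macro_state")
        return MacroSystem.from_micro_state(network, mapping, micro_state)
    return MacroSystem(network, mapping, macro_state)


def screened_off_check(macro: MacroSystem) -> dict:
    """Diagnostic: each box's macro transition distribution may depend only
    on boxes with a direct output -> member connection (influences mediated
    by a third box are screened off by the noising procedure)."""
    outputs_by_label = {macro.mapping.outputs[b]: b
                        for b in macro.mapping.box_names}
    report = {}
    for u, name in enumerate(macro.mapping.box_names):
        direct = set()
        for l in macro.mapping.boxes[name]:
            for src in macro._rules[l][0]:
                if src in outputs_by_label:
                    direct.add(macro._unit_of_box[outputs_by_label[src]])
        effective = set(macro.macro_model.nodes[u].pruned().inputs)
        report[name] = {
            "direct_inputs": tuple(macro.mapping.box_names[i]
                                   for i in sorted(direct)),
            "effective_inputs": tuple(macro.mapping.box_names[i]
                                      for i in sorted(effective)),
            "screened_off": effective <= direct,
        }
    report["ok"] = all(r["screened_off"] for r in report.values()
                       if isinstance(r, dict))
    return report
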