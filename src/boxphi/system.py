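"""System-level analysis: cause-effect structures, cuts, and Phi.

The cause-effect structure (CES) of a candidate system in a state is the
set of all its concepts (mechanisms with phi > 0 over the power set of
system elements).  Integrated information Phi measures how much the CES is
changed by the least disruptive unidirectional bipartition of the system's
*micro* substrate: connections from one part to the other are replaced by
maximum-entropy noise, the CES is recomputed, and the two structures are
compared with an extended earth-mover distance in which each concept's phi
is transported across concept space (ground metric: summed repertoire
distances after expansion over the full system purview; unmatched phi-mass
is transported to the null concept of the unconstrained system).

Phi = 0 means some part of the system is unconstrained by the rest: there
is no integrated system from the intrinsic perspective, however natural the
external description may be.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from .mechanism import (CAUSE, EFFECT, PHI_EPS, Concept, RepertoireCalculator,
                        hamming_emd)
from .network import (CandidateSystem, NodeModel, TransitionModel,
                      build_transition_model)

__all__ = [
    "CauseEffectStructure",
    "SystemCut",
    "PhiResult",
    "UndefinedCauseEffectStructure",
    "MicroAnalysisSystem",
    "compute_ces",
    "apply_system_cut",
    "ces_distance",
    "compute_big_phi",
]

log = logging.getLogger("boxphi")


class UndefinedCauseEffectStructure(ValueError):
    """The current state has no possible cause within the system."""


@dataclass
class SystemCut:
    """A unidirectional partition severing connections from ``from_part`` to
    ``to_part`` (micro element labels)."""

    from_part: tuple
    to_part: tuple

    def __post_init__(self):
        if not self.from_part or not self.to_part:
            raise ValueError("both cut parts must be nonempty")
        if set(self.from_part) & set(self.to_part):
            raise ValueError("cut parts must be disjoint")


@dataclass
class CauseEffectStructure:
    """All concepts of a candidate system in a state."""

    concepts: list
    labels: tuple
    state: tuple
    unconstrained_effect: np.ndarray = field(default=None, repr=False)

    def __len__(self):
        return len(self.concepts)

    def total_phi(self) -> float:
        return sum(c.phi for c in self.concepts)

    def mechanisms(self):
        return [c.mechanism for c in self.concepts]

    def to_dict(self) -> dict:
        """Structured report (little-endian flat repertoires)."""
        return {
            "labels": [str(l) for l in self.labels],
            "state": list(self.state),
            "concepts": [c.to_dict(self.labels) for c in self.concepts],
        }


@dataclass
class PhiResult:
    phi: float
    mip_cut: SystemCut | None
    intact_ces: CauseEffectStructure
    cut_ces: CauseEffectStructure | None
    cuts_evaluated: int = 0

    def summary(self) -> str:
        lines = [f"Phi = {self.phi:.3f}"]
        if self.mip_cut is not None:
            lines.append("MIP cut: {%s} -/-> {%s}" % (
                ",".join(map(str, self.mip_cut.from_part)),
                ",".join(map(str, self.mip_cut.to_part))))
        if self.intact_ces is None:
            lines.append("reducible by connectivity; "
                         "cause-effect structure not assembled")
            return "\n".join(lines)
        lines.append(f"concepts ({len(self.intact_ces)}):")
        for c in self.intact_ces.concepts:
            mech = ",".join(str(self.intact_ces.labels[i]) for i in c.mechanism)
            cp = ",".join(str(self.intact_ces.labels[i]) for i in c.cause.purview)
            ep = ",".join(str(self.intact_ces.labels[i]) for i in c.effect.purview)
            lines.append(f"  ({mech})  phi={c.phi:.4f}  "
                         f"cause=({cp})  effect=({ep})")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# Analysis systems: something with units, a state, and a micro substrate
# --------------------------------------------------------------------------

class MicroAnalysisSystem:
    """A candidate micro system: units are the system's own elements."""

    def __init__(self, system: CandidateSystem):
        self.system = system
        self.model = system.transition_model()
        self.labels = self.model.labels
        self.state = tuple(int(v) for v in system.current_state)
        self.micro_labels = self.labels

    def unit_models(self, severed=frozenset()) -> TransitionModel:
        """Transition model with the given micro connections (pairs of micro
        indices, source -> target) replaced by maximum-entropy noise."""
        if not severed:
            return self.model
        nodes = []
        for j, nm in enumerate(self.model.nodes):
            for i in list(nm.inputs):
                if (i, j) in severed:
                    nm = nm.marginalized(i)
            nodes.append(nm)
        return TransitionModel(self.labels, nodes)

    def micro_edges(self):
        """Effective micro connections as (source, target) index pairs."""
        out = set()
        for j, nm in enumerate(self.model.nodes):
            out.update((i, j) for i in nm.pruned().inputs)
        return out

    def network_automorphisms(self):
        return model_automorphisms(self.model, self.state)


def model_automorphisms(model: TransitionModel, state=None, colors=None):
    """Unit permutations that leave the transition model (and state) intact.

    Used to prune system-cut enumeration to orbit representatives: applying
    such a permutation to a cut yields a cut with the same constellation
    distance, so only one member per orbit needs evaluation.
    """
    n = model.n
    nodes = [nm.pruned() for nm in model.nodes]
    if state is None:
        state = (0,) * n
    node_color = {}
    for j, nm in enumerate(nodes):
        node_color[j] = (state[j], len(nm.inputs),
                         tuple(sorted(np.round(nm.table, 12).ravel())),
                         None if colors is None else colors[j])
    g = nx.DiGraph()
    for j in range(n):
        g.add_node(j, c=node_color[j])
    for j, nm in enumerate(nodes):
        g.add_edges_from((i, j) for i in nm.inputs)
    matcher = nx.algorithms.isomorphism.DiGraphMatcher(
        g, g, node_match=lambda a, b: a["c"] == b["c"])
    perms = []
    for iso in matcher.isomorphisms_iter():
        perm = tuple(iso[i] for i in range(n))
        if _perm_preserves_model(nodes, perm):
            perms.append(perm)
    return perms


def _perm_preserves_model(nodes, perm) -> bool:
    for j, nm in enumerate(nodes):
        jp = perm[j]
        target = nodes[jp]
        mapped = tuple(sorted(perm[i] for i in nm.inputs))
        if mapped != target.inputs:
            return False
        if nm.inputs:
            # axis a of nm.table (input i) must land on the axis of perm[i]
            tgt_axis = [target.inputs.index(perm[i]) for i in nm.inputs]
            axes = [tgt_axis.index(t) for t in range(len(tgt_axis))]
            if not np.allclose(np.transpose(nm.table, axes), target.table,
                               atol=1e-12):
                return False
        elif not np.allclose(nm.table, target.table, atol=1e-12):
            return False
    return True


def _as_analysis_system(system):
    """Accept a CandidateSystem, a MacroSystem, or an analysis system."""
    if isinstance(system, CandidateSystem):
        return MicroAnalysisSystem(system)
    if hasattr(system, "unit_models"):
        return system
    raise TypeError(f"cannot analyse {type(system).__name__}")


# --------------------------------------------------------------------------
# Cause-effect structure
# --------------------------------------------------------------------------

def _ces_from_calculator(calc: RepertoireCalculator) -> CauseEffectStructure:
    if not calc.state_reachable():
        raise UndefinedCauseEffectStructure(
            f"state {calc.state} has no cause within the system")
    concepts = []
    units = range(calc.n)
    for r in range(1, calc.n + 1):
        for mech in itertools.combinations(units, r):
            c = calc.concept(mech)
            if c is not None:
                concepts.append(c)
    return CauseEffectStructure(
        concepts, calc.labels, calc.state,
        unconstrained_effect=calc.unconstrained_effect_marginals())


def compute_ces(system) -> CauseEffectStructure:
    """All concepts of the candidate system in its current state.

    Raises :class:`UndefinedCauseEffectStructure` if the state has no
    possible cause within the system.
    """
    asys = _as_analysis_system(system)
    calc = RepertoireCalculator(asys.unit_models(), asys.state)
    return _ces_from_calculator(calc)


def apply_system_cut(system, cut: SystemCut):
    """Transition model of the system with the cut's connections noised.

    The cut partitions the *micro* substrate; for macro systems the macro
    transition model is re-derived after cutting the underlying network.
    """
    asys = _as_analysis_system(system)
    idx = {l: i for i, l in enumerate(asys.micro_labels)}
    a = {idx[l] for l in cut.from_part}
    b = {idx[l] for l in cut.to_part}
    severed = frozenset((i, j) for i in a for j in b)
    return asys.unit_models(severed)


# --------------------------------------------------------------------------
# Constellation distance
# --------------------------------------------------------------------------

def _expand_cause(concept: Concept, n: int) -> np.ndarray:
    """Cause repertoire expanded to the full system purview (absent elements
    maximum-entropy / uniform)."""
    pv = concept.cause.purview
    rep = concept.cause.repertoire.reshape((2,) * len(pv), order="F")
    view_shape = [2 if u in pv else 1 for u in range(n)]
    out = np.broadcast_to(rep.reshape(view_shape), (2,) * n)
    return (out / out.sum()).ravel(order="F")


def _expanded_effect_marginals(concept: Concept, uncon: np.ndarray) -> np.ndarray:
    """Per-unit ON-marginals of the effect repertoire expanded over the full
    system (absent elements unconstrained)."""
    n = len(uncon)
    out = uncon.copy()
    rep = concept.effect.repertoire
    for k, u in enumerate(concept.effect.purview):
        bits = np.array([(idx >> k) & 1 for idx in range(len(rep))])
        out[u] = float(rep[bits == 1].sum())
    return out


def _concept_ground_distance(c1, c2) -> float:
    """Sum of cause and effect repertoire distances between two (expanded)
    concepts.  The effect side is a product distribution on both sides, so
    its earth-mover distance is the sum of per-unit marginal differences."""
    return hamming_emd(c1["cause_x"], c2["cause_x"]) \
        + float(np.abs(c1["eff_x"] - c2["eff_x"]).sum())


def _concept_points(ces: CauseEffectStructure, n: int):
    uncon = ces.unconstrained_effect
    pts = []
    for c in ces.concepts:
        pts.append({
            "phi": c.phi,
            "cause_x": _expand_cause(c, n),
            "eff_x": _expanded_effect_marginals(c, uncon),
        })
    return pts


def _null_point(ces: CauseEffectStructure, n: int):
    return {
        "phi": 0.0,
        "cause_x": np.full(1 << n, 1.0 / (1 << n)),
        "eff_x": ces.unconstrained_effect.copy(),
    }


def ces_distance(intact: CauseEffectStructure, cut: CauseEffectStructure
                 ) -> float:
    """Extended earth-mover distance between two cause-effect structures.

    Concept phi-mass is transported in concept space; the ground distance
    between two concepts is the sum of the distances between their cause and
    effect repertoires expanded over the full system purview.  phi-mass
    without a partner is transported to the null concept (the unconstrained
    repertoires of the empty mechanism of the intact system).
    """
    if intact.labels != cut.labels:
        raise ValueError("structures must be over the same system")
    n = len(intact.labels)
    p1 = _concept_points(intact, n)
    p2 = _concept_points(cut, n)
    null = _null_point(intact, n)
    pts = p1 + p2 + [null]
    s1 = sum(p["phi"] for p in p1)
    s2 = sum(p["phi"] for p in p2)
    supply = np.array([p["phi"] for p in p1] + [0.0] * len(p2)
                      + [max(0.0, s2 - s1)])
    demand = np.array([0.0] * len(p1) + [p["phi"] for p in p2]
                      + [max(0.0, s1 - s2)])
    if supply.sum() < PHI_EPS:
        return 0.0
    m = len(pts)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = _concept_ground_distance(pts[i], pts[j])
    return _transport(supply, demand, D)


def _transport(supply, demand, D) -> float:
    """Transportation LP: move ``supply`` onto ``demand`` at cost ``D``."""
    m = len(supply)
    nz_s = [i for i in range(m) if supply[i] > 0]
    nz_d = [j for j in range(m) if demand[j] > 0]
    if not nz_s or not nz_d:
        return 0.0
    c = np.array([D[i, j] for i in nz_s for j in nz_d])
    a, b = len(nz_s), len(nz_d)
    A = np.zeros((a + b, a * b))
    for r in range(a):
        A[r, r * b:(r + 1) * b] = 1.0
    for s in range(b):
        A[a + s, s::b] = 1.0
    rhs = np.concatenate([supply[nz_s], demand[nz_d]])
    res = linprog(c, A_eq=A, b_eq=rhs, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"constellation EMD failed: {res.message}")
    return max(float(res.fun), 0.0)


# --------------------------------------------------------------------------
# Big Phi
# --------------------------------------------------------------------------

def _strong_connectivity_cut(asys):
    """A zero cut implied by the unit-level effective wiring, if any.

    If the directed graph of effective unit connections is not strongly
    connected, a sink component receives influence but sends none: severing
    its (nonexistent) outgoing connections changes nothing, so Phi = 0.
    """
    model = RepertoireCalculator(asys.unit_models(), asys.state)
    g = nx.DiGraph()
    g.add_nodes_from(range(model.n))
    for j, ins in enumerate(model.inputs):
        g.add_edges_from((i, j) for i in ins if i != j)
    if model.n == 1 or nx.is_strongly_connected(g):
        return None
    sink = next(c for c in nx.strongly_connected_components(g)
                if all(v in c for _, v in g.out_edges(c)))
    return sorted(sink)


def _micro_partitions(m: int):
    """All unidirectional bipartitions of m micro elements (2^m - 2 cuts),
    in stable little-endian mask order."""
    for mask in range(1, (1 << m) - 1):
        yield mask


def _orbit_representatives(m: int, perms):
    """Cut masks up to the symmetry group ``perms`` (index permutations)."""
    reps = []
    seen = set()
    for mask in _micro_partitions(m):
        if mask in seen:
            continue
        orbit = set()
        for perm in perms:
            pm = 0
            for i in range(m):
                if (mask >> i) & 1:
                    pm |= 1 << perm[i]
            orbit.add(pm)
        seen.update(orbit)
        reps.append((mask, len(orbit)))
    return reps


def compute_big_phi(system, symmetry: bool = False) -> PhiResult:
    """Integrated information of a candidate (micro or macro) system.

    Phi is the minimum, over all unidirectional bipartitions of the micro
    substrate, of the distance between the intact cause-effect structure and
    the one recomputed after noising the severed connections.  With
    ``symmetry=True`` only one cut per orbit of the network's
    state-preserving automorphism group is evaluated (the minimum is
    unchanged; needed for large substrates).
    """
    asys = _as_analysis_system(system)
    intact_calc = RepertoireCalculator(asys.unit_models(), asys.state)
    if not intact_calc.state_reachable():
        raise UndefinedCauseEffectStructure(
            f"state {intact_calc.state} has no cause within the system")

    micro = list(asys.micro_labels)
    m = len(micro)
    if m == 1:
        # no bipartition of a single micro element exists; with no effective
        # self-connection it is unconstrained, and in either case Phi = 0
        return PhiResult(0.0, None, _ces_from_calculator(intact_calc), None, 0)

    sc = _strong_connectivity_cut(asys)
    if sc is not None:
        # units in the sink component send nothing to the rest: severing
        # their (nonexistent) outgoing connections changes nothing, so the
        # expensive cause-effect structure need not be assembled at all
        units_a = sc
        a_labels = tuple(l for u in units_a
                         for l in _unit_micro_labels(asys, u))
        b_labels = tuple(l for l in micro if l not in a_labels)
        cut = SystemCut(a_labels, b_labels)
        log.debug("reducible by connectivity: cut %s", cut)
        return PhiResult(0.0, cut, None, None, 0)

    intact = _ces_from_calculator(intact_calc)

    if m > 24:
        raise ValueError(
            f"exhaustive cut enumeration over {m} micro elements is not "
            "tractable; use symmetry pruning on a smaller substrate")

    perms = None
    if symmetry:
        perms = asys.network_automorphisms()
        masks = _orbit_representatives(m, perms)
    else:
        masks = [(mask, 1) for mask in _micro_partitions(m)]

    edges = asys.micro_edges() if hasattr(asys, "micro_edges") else None
    best = (np.inf, None, None)
    evaluated = 0
    for mask, _orbit in masks:
        a = frozenset(i for i in range(m) if (mask >> i) & 1)
        b = frozenset(range(m)) - a
        severed = frozenset((i, j) for i in a for j in b)
        if edges is not None and not (severed & edges):
            cut = _cut_from_mask(micro, mask)
            return PhiResult(0.0, cut, intact, intact, evaluated)
        model = asys.unit_models(severed)
        calc = RepertoireCalculator(model, asys.state)
        try:
            cut_ces = _ces_from_calculator(calc)
        except UndefinedCauseEffectStructure:
            cut_ces = CauseEffectStructure(
                [], intact.labels, intact.state,
                unconstrained_effect=calc.unconstrained_effect_marginals())
        d = ces_distance(intact, cut_ces)
        evaluated += 1
        if d < best[0] - 1e-12:
            best = (d, mask, cut_ces)
            if d < PHI_EPS:
                break
    phi, mask, cut_ces = best
    cut = _cut_from_mask(micro, mask)
    return PhiResult(0.0 if phi < PHI_EPS else float(phi),
                     cut, intact, cut_ces, evaluated)


def _cut_from_mask(micro, mask):
    if mask is None:
        return None
    a = tuple(l for i, l in enumerate(micro) if (mask >> i) & 1)
    b = tuple(l for i, l in enumerate(micro) if not (mask >> i) & 1)
    return SystemCut(a, b)


def _unit_micro_labels(asys, unit):
    """Micro labels constituting one analysis unit."""
    if hasattr(asys, "unit_members"):
        return asys.unit_members(unit)
    return (asys.micro_labels[unit],)
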