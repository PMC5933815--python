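"""Search for local maxima of Phi across constitution, space, and time.

Candidate macro systems are generated by crossing every grouping of the
elements into black boxes (every set partition except the all-singleton
one, which is the micro system itself) with every choice of one output
element per box and every macro time scale.  Two candidate systems are
neighbours when they differ by exactly one unit of exactly one of three
distances: constitutional (micro elements added/removed), temporal
(difference in time scale), and spatial (the maximum matching distance
between their groupings — the number of micro elements that must be moved
from one grouping to the other).  A candidate is a local maximum if no
neighbour has strictly greater Phi.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .blackbox import BlackBoxMapping, MacroSystem, validate_mapping
from .network import CandidateSystem, MicroNetwork, ValidationError
from .system import (MicroAnalysisSystem, UndefinedCauseEffectStructure,
                     compute_big_phi, model_automorphisms)

__all__ = [
    "SystemDistance",
    "SearchRecord",
    "StabilityReport",
    "set_partitions",
    "enumerate_candidates",
    "count_candidates",
    "count_groupings",
    "partition_matching_distance",
    "system_distance",
    "find_local_maxima",
    "stability_across_states",
]

log = logging.getLogger("boxphi")


# --------------------------------------------------------------------------
# Enumeration
# --------------------------------------------------------------------------

def set_partitions(items):
    """All set partitions of ``items`` (restricted-growth-string order)."""
    items = list(items)
    n = len(items)
    if n == 0:
        yield []
        return
    rgs = [0] * n
    maxes = [0] * n

    def emit():
        blocks = [[] for _ in range(max(rgs) + 1)]
        for x, b in zip(items, rgs):
            blocks[b].append(x)
        return [tuple(b) for b in blocks]

    yield emit()
    while True:
        i = n - 1
        while i > 0 and rgs[i] == maxes[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        rgs[i] += 1
        maxes[i] = max(maxes[i], rgs[i])
        for j in range(i + 1, n):
            rgs[j] = 0
            maxes[j] = maxes[i]
        yield emit()


def count_groupings(n: int) -> int:
    """Number of set partitions of n elements (Bell number), computed by
    the triangle recurrence."""
    row = [1]
    for _ in range(n):
        nxt = [row[-1]]
        for v in row:
            nxt.append(nxt[-1] + v)
        row = nxt
    return row[0]


def _weighted_partition_sum(n: int) -> int:
    """Sum over all set partitions of the product of block sizes — i.e. the
    number of (grouping, one marked output per block) configurations."""
    f = [1] * (n + 1)
    for m in range(1, n + 1):
        total = 0
        for k in range(1, m + 1):
            total += math.comb(m - 1, k - 1) * k * f[m - k]
        f[m] = total
    return f[n]


def count_candidates(n: int, n_timescales: int) -> int:
    """Number of macro candidates: every grouping except the all-singleton
    one, crossed with output choices and time scales."""
    return n_timescales * (_weighted_partition_sum(n) - 1)


def enumerate_candidates(nodes, timescales, background=None):
    """Stream of candidate :class:`BlackBoxMapping`.

    Yields every set partition of ``nodes`` except the all-singleton one
    (that is the micro system), crossed with every choice of one output
    element per box and every time scale in ``timescales``.
    """
    nodes = list(nodes)
    background = dict(background or {})
    timescales = sorted(timescales)
    groupings = sorted(set_partitions(nodes), key=len)   # increasing box count
    for blocks in groupings:
        if len(blocks) == len(nodes):
            continue                    # all singletons: the micro system
        for outputs in itertools.product(*blocks):
            boxes = {f"B{i}": blk for i, blk in enumerate(blocks)}
            outs = {f"B{i}": o for i, o in enumerate(outputs)}
            for T in timescales:
                yield BlackBoxMapping(boxes, outs, T, dict(background))


# --------------------------------------------------------------------------
# Distances between systems
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SystemDistance:
    constitutional: int
    temporal: int
    spatial: int

    @property
    def total(self) -> int:
        return self.constitutional + self.temporal + self.spatial

    @property
    def neighbors(self) -> bool:
        return self.total == 1


def partition_matching_distance(p, q) -> int:
    """Maximum matching distance between two partitions of the same set:
    the number of elements that must be moved to turn one into the other
    (n minus the best one-to-one block-overlap matching)."""
    pb = [frozenset(b) for b in p]
    qb = [frozenset(b) for b in q]
    up, uq = frozenset().union(*pb) if pb else frozenset(), \
        frozenset().union(*qb) if qb else frozenset()
    if up != uq:
        raise ValueError("partitions must cover the same underlying set")
    if sum(len(b) for b in pb) != len(up) or sum(len(b) for b in qb) != len(uq):
        raise ValueError("blocks must be disjoint")
    m = max(len(pb), len(qb))
    overlap = np.zeros((m, m))
    for i, b1 in enumerate(pb):
        for j, b2 in enumerate(qb):
            overlap[i, j] = len(b1 & b2)
    rows, cols = linear_sum_assignment(-overlap)
    return int(len(up) - overlap[rows, cols].sum())


def _constitution(mapping: BlackBoxMapping) -> frozenset:
    return frozenset(mapping.constitution())


def system_distance(a: BlackBoxMapping, b: BlackBoxMapping) -> SystemDistance:
    """Constitutional, temporal, and spatial distance between two candidate
    systems over the same micro network.

    The spatial term compares the groupings restricted to the shared
    constitution (elements present in only one system are already charged
    to the constitutional term)."""
    ca, cb = _constitution(a), _constitution(b)
    shared = ca & cb
    constitutional = len(ca ^ cb)
    temporal = abs(a.timescale - b.timescale)
    pa = [tuple(x for x in blk if x in shared) for blk in a.boxes.values()]
    pb = [tuple(x for x in blk if x in shared) for blk in b.boxes.values()]
    pa = [blk for blk in pa if blk]
    pb = [blk for blk in pb if blk]
    spatial = partition_matching_distance(pa, pb) if shared else 0
    return SystemDistance(constitutional, temporal, spatial)


# --------------------------------------------------------------------------
# Evaluation and local maxima
# --------------------------------------------------------------------------

@dataclass
class SearchRecord:
    mapping: BlackBoxMapping
    state: tuple               # macro state of the candidate
    phi: float
    is_local_max: bool = False
    neighbors_evaluated: int = 0
    defined: bool = True

    def key(self):
        return self.mapping.canonical()


@dataclass
class StabilityReport:
    unique_maxima: list        # canonical mapping keys
    per_state_presence: dict   # key -> list of state indices where present
    stable_maxima: list        # keys present in every analysed state
    n_states: int


def _canonical_under_group(mapping: BlackBoxMapping, perms, labels):
    """Smallest canonical form of a mapping over its automorphism orbit."""
    idx = {l: i for i, l in enumerate(labels)}
    best = None
    for perm in perms:
        boxes = []
        for name, mem in mapping.boxes.items():
            mem_i = frozenset(perm[idx[l]] for l in mem)
            out_i = perm[idx[mapping.outputs[name]]]
            boxes.append((tuple(sorted(mem_i)), out_i))
        form = (tuple(sorted(boxes)), mapping.timescale,
                tuple(sorted((perm[idx[l]], v)
                             for l, v in mapping.background.items()
                             if l in idx)))
        if best is None or form < best:
            best = form
    return best


def _evaluate_candidate(network, mapping, micro_state, cache):
    key = json.dumps(_mapping_key(mapping), sort_keys=True)
    if key in cache:
        return cache[key]
    try:
        if len(mapping.boxes) == len(mapping.constitution()) \
                and mapping.timescale == 1:
            system = CandidateSystem(
                network, mapping.constitution(), dict(mapping.background),
                tuple(micro_state[l] for l in mapping.constitution()))
            res = compute_big_phi(system)
        else:
            macro = MacroSystem.from_micro_state(network, mapping, micro_state)
            res = compute_big_phi(macro)
        out = (float(res.phi), True)
    except (UndefinedCauseEffectStructure, ValidationError) as exc:
        log.debug("candidate skipped: %s", exc)
        out = (0.0, False)
    cache[key] = out
    return out


def _mapping_key(mapping: BlackBoxMapping):
    return {
        "boxes": sorted([sorted(mem), mapping.outputs[name]]
                        for name, mem in mapping.boxes.items()),
        "T": mapping.timescale,
        "bg": sorted(mapping.background.items()),
    }


def find_local_maxima(network: MicroNetwork, micro_state: dict,
                      timescales=(2, 3, 4), nodes=None,
                      include_micro: bool = True, dedup: bool = True,
                      cache: dict | None = None, candidates=None):
    """Evaluate candidate macro systems in one micro state and flag local
    maxima of Phi within the evaluated set.

    ``micro_state`` maps every network node to its observed value; elements
    outside a candidate's boxes are clamped to it as background.  The micro
    system (all-singleton grouping, T = 1) participates as a candidate and
    as a neighbour of T = 2 systems.  Candidates whose cause-effect
    structure is undefined are recorded with ``defined=False`` and do not
    compete.
    """
    nodes = list(nodes if nodes is not None else network.node_labels)
    cache = cache if cache is not None else {}
    records = []

    def bg_for(constitution):
        return {l: micro_state[l] for l in network.node_labels
                if l not in constitution}

    if candidates is None:
        candidates = list(enumerate_candidates(nodes, timescales))
        for c in candidates:
            c.background.update(bg_for(set(c.constitution())))
        if include_micro:
            micro_map = BlackBoxMapping(
                {l: (l,) for l in nodes}, {l: l for l in nodes}, 1,
                bg_for(set(nodes)))
            candidates = [micro_map] + candidates

    for mapping in candidates:
        phi, defined = _evaluate_candidate(network, mapping, micro_state,
                                           cache)
        macro_state = tuple(int(micro_state[mapping.outputs[n]])
                            for n in mapping.box_names)
        records.append(SearchRecord(mapping, macro_state, phi,
                                    defined=defined))

    # local-maximum flags within the evaluated set
    for rec in records:
        if not rec.defined or rec.phi <= 0:
            continue
        higher = False
        n_neigh = 0
        for other in records:
            if other is rec or not other.defined:
                continue
            if system_distance(rec.mapping, other.mapping).neighbors:
                n_neigh += 1
                if other.phi > rec.phi + 1e-9:
                    higher = True
                    break
        rec.neighbors_evaluated = n_neigh
        rec.is_local_max = not higher
    return records


def _dedup_keys(records, network, micro_state):
    """Canonical keys of local maxima, deduplicated under state-preserving
    network automorphisms."""
    labels = network.node_labels
    system = CandidateSystem(
        network, labels, {}, tuple(micro_state[l] for l in labels))
    asys = MicroAnalysisSystem(system)
    perms = model_automorphisms(asys.model, asys.state)
    keys = {}
    for rec in records:
        if rec.is_local_max and rec.phi > 0:
            keys[_canonical_under_group(rec.mapping, perms, labels)] = rec
    return keys


def stability_across_states(network: MicroNetwork, states, timescales=(2, 3, 4),
                            nodes=None, dedup: bool = True,
                            cache_dir: str | None = None):
    """Local maxima per state and their persistence across a state sequence.

    ``states`` is an ordered list of full micro states (dicts or tuples over
    the network's node order).  States with an undefined cause-effect
    structure contribute no maxima (the cell-cycle state t2 is excluded this
    way upstream).  Returns a :class:`StabilityReport`; maxima are
    deduplicated under network automorphisms and "stable" means present in
    every analysed state.
    """
    presence = {}
    any_defined = False
    n_states = 0
    for si, st in enumerate(states):
        micro_state = st if isinstance(st, dict) else \
            dict(zip(network.node_labels, st))
        cache = _load_cache(cache_dir, si)
        records = find_local_maxima(network, micro_state, timescales,
                                    nodes=nodes, cache=cache)
        _save_cache(cache_dir, si, cache)
        if any(r.defined for r in records):
            any_defined = True
        n_states += 1
        keys = _dedup_keys(records, network, micro_state) if dedup else {
            r.key(): r for r in records if r.is_local_max and r.phi > 0}
        for key in keys:
            presence.setdefault(key, []).append(si)
    if not any_defined:
        raise UndefinedCauseEffectStructure(
            "no analysed state has a defined cause-effect structure")
    unique = sorted(presence, key=lambda k: (-len(presence[k]), str(k)))
    stable = [k for k in unique if len(presence[k]) == n_states]
    return StabilityReport(unique, presence, stable, n_states)


def _load_cache(cache_dir, state_index):
    if cache_dir is None:
        return {}
    path = os.path.join(cache_dir, f"state_{state_index}.json")
    if os.path.exists(path):
        with open(path) as fh:
            return json.load(fh)
    return {}


def _save_cache(cache_dir, state_index, cache):
    if cache_dir is None:
        return
    os.makedirs(cache_dir, exist_ok=True)
    path = os.path.join(cache_dir, f"state_{state_index}.json")
    with open(path, "w") as fh:
        json.dump(cache, fh)
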