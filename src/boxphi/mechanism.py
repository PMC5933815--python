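"""Mechanism-level causal analysis: repertoires, irreducibility, concepts.

A *mechanism* is a subset of system elements in its current state.  Its
*cause repertoire* over a purview is the distribution of past purview states
obtained by Bayesian inversion of the transition model with a
maximum-entropy prior, factorised over mechanism elements (each element
conditions independently; the per-element likelihoods are multiplied and
renormalised).  Its *effect repertoire* is the product over purview elements
of each element's next-state distribution given the mechanism state, with
all other inputs marginalised uniformly.

Irreducibilityphi of a mechanism over a purview is the minimum, over all
non-trivial bipartitions of (mechanism, purview), of the earth-mover
distance between the whole repertoire and the product of the parts'
repertoires, with Hamming distance between purview states as the ground
metric.  A mechanism's *concept* pairs its maximally irreducible cause and
effect (purviews maximising phi) and carries phi = min(phi_cause,
phi_effect); the mechanism contributes a concept only if phi > 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .network import TransitionModel

__all__ = [
    "Repertoire",
    "Mice",
    "Concept",
    "RepertoireCalculator",
    "repertoire_distance",
    "hamming_emd",
    "cause_repertoire",
    "effect_repertoire",
    "compute_concept",
    "PHI_EPS",
]

PHI_EPS = 1e-10   # threshold below which phi counts as zero (float EMD noise)

CAUSE = "cause"
EFFECT = "effect"


# --------------------------------------------------------------------------
# Earth-mover distance with Hamming ground metric
# --------------------------------------------------------------------------

_INCIDENCE_CACHE: dict[int, sparse.csc_matrix] = {}


def _hypercube_incidence(n: int) -> sparse.csc_matrix:
    """Signed incidence matrix of the directed n-cube (both edge directions).

    Because Hamming distance is the shortest-path metric of the hypercube
    with unit edge costs, the earth-mover distance equals the optimal value
    of a min-cost flow on this graph, a linear program that is far smaller
    than the dense transportation formulation.
    """
    if n in _INCIDENCE_CACHE:
        return _INCIDENCE_CACHE[n]
    nv = 1 << n
    rows, cols, vals = [], [], []
    e = 0
    for u in range(nv):
        for b in range(n):
            v = u ^ (1 << b)
            rows.extend((u, v))
            cols.extend((e, e))
            vals.extend((1.0, -1.0))
            e += 1
    A = sparse.coo_matrix((vals, (rows, cols)), shape=(nv, e)).tocsc()
    _INCIDENCE_CACHE[n] = A
    return A


def hamming_emd(p, q) -> float:
    """Exact earth-mover distance between two distributions on binary
    purview states, with Hamming distance as the ground metric."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.shape != q.shape:
        raise ValueError("distributions must share a state space")
    diff = p - q
    if np.max(np.abs(diff)) < 1e-12:
        return 0.0
    n = len(p).bit_length() - 1
    if n == 0:
        return 0.0
    A = _hypercube_incidence(n)
    res = linprog(c=np.ones(A.shape[1]), A_eq=A, b_eq=diff,
                  bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - HiGHS is reliable on flows
        raise RuntimeError(f"EMD flow LP failed: {res.message}")
    return max(float(res.fun), 0.0)


# --------------------------------------------------------------------------
# Repertoires
# --------------------------------------------------------------------------

@dataclass
class Repertoire:
    """A probability distribution over the states of a purview.

    ``dist`` is flat and little-endian in the (ascending) purview order:
    the first purview element is the least-significant bit.
    """

    direction: str
    purview: tuple
    dist: np.ndarray

    def __post_init__(self):
        self.purview = tuple(self.purview)
        self.dist = np.asarray(self.dist, dtype=float).ravel()
        if len(self.dist) != 1 << len(self.purview):
            raise ValueError("distribution length does not match purview")
        if np.any(self.dist < -1e-9):
            raise ValueError("negative probability in repertoire")
        s = self.dist.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"repertoire does not normalise (sum={s})")


def repertoire_distance(a: Repertoire, b: Repertoire) -> float:
    """Earth-mover distance between two same-purview repertoires."""
    if a.purview != b.purview or a.direction != b.direction:
        raise ValueError("repertoires must share purview and direction")
    return hamming_emd(a.dist, b.dist)


@dataclass
class Mice:
    """A maximally irreducible cause or effect: the phi-maximising purview
    with its repertoire, phi value and minimum-information partition."""

    direction: str
    purview: tuple
    repertoire: np.ndarray
    phi: float
    partition: tuple | None


@dataclass
class Concept:
    """A mechanism with its maximally irreducible cause and effect."""

    mechanism: tuple
    state: tuple          # mechanism state, aligned with ``mechanism``
    cause: Mice
    effect: Mice

    @property
    def phi(self) -> float:
        return min(self.cause.phi, self.effect.phi)

    def to_dict(self, labels=None) -> dict:
        """Structured report; repertoires are flat little-endian arrays over
        the ascending purview order."""
        name = (lambda i: i) if labels is None else (lambda i: labels[i])
        return {
            "mechanism": [name(i) for i in self.mechanism],
            "state": list(self.state),
            "phi": self.phi,
            "cause": {"purview": [name(i) for i in self.cause.purview],
                      "phi": self.cause.phi,
                      "repertoire": [float(p) for p in self.cause.repertoire]},
            "effect": {"purview": [name(i) for i in self.effect.purview],
                       "phi": self.effect.phi,
                       "repertoire": [float(p)
                                      for p in self.effect.repertoire]},
        }


# --------------------------------------------------------------------------
# Calculator
# --------------------------------------------------------------------------

class RepertoireCalculator:
    """Repertoire and phi arithmetic for one transition model in one state.

    Caches per-element likelihoods so that the power-set sweeps of a full
    cause-effect structure reuse work.
    """

    def __init__(self, model: TransitionModel, state):
        self.model = model
        self.n = model.n
        self.labels = model.labels
        self.state = tuple(int(v) for v in state)
        if len(self.state) != self.n:
            raise ValueError("state length does not match model")
        self.nodes = [nm.pruned() for nm in model.nodes]
        self.inputs = [set(nm.inputs) for nm in self.nodes]
        self.outputs = [set() for _ in range(self.n)]
        for j, ins in enumerate(self.inputs):
            for i in ins:
                self.outputs[i].add(j)
        self._like_cache: dict = {}
        self._eff_cache: dict = {}

    # -- per-element building blocks ------------------------------------

    def _likelihood_tensor(self, i: int, purview: tuple) -> np.ndarray:
        """p(element i takes its current state | past purview state), as a
        tensor over the purview axes, other inputs marginalised uniformly."""
        nm = self.nodes[i]
        overlap = tuple(u for u in purview if u in self.inputs[i])
        key = (i, overlap)
        core = self._like_cache.get(key)
        if core is None:
            tbl = nm.table
            # average out inputs not in the purview (max-entropy past prior)
            for k in range(len(nm.inputs) - 1, -1, -1):
                if nm.inputs[k] not in overlap:
                    tbl = tbl.mean(axis=k)
            core = tbl if self.state[i] == 1 else 1.0 - tbl
            self._like_cache[key] = core
        # embed into the full purview shape (broadcast over absent axes)
        shape = [2 if u in overlap else 1 for u in purview]
        out = core.reshape(shape)
        return np.broadcast_to(out, (2,) * len(purview))

    def effect_marginal(self, j: int, mechanism: tuple, mstate: dict) -> float:
        """p(element j is ON next | mechanism clamped, other inputs uniform)."""
        nm = self.nodes[j]
        cond = tuple((u, mstate[u]) for u in nm.inputs if u in mstate)
        key = (j, cond)
        if key not in self._eff_cache:
            tbl = nm.table
            for k in range(len(nm.inputs) - 1, -1, -1):
                u = nm.inputs[k]
                if u in mstate:
                    tbl = np.take(tbl, mstate[u], axis=k)
                else:
                    tbl = tbl.mean(axis=k)
            self._eff_cache[key] = float(tbl)
        return self._eff_cache[key]

    # -- repertoires -----------------------------------------------------

    def cause_repertoire(self, mechanism, purview) -> Repertoire | None:
        """Distribution over past purview states; ``None`` when the mechanism
        state has zero probability under every past purview state (a state
        with no cause)."""
        purview = tuple(sorted(purview))
        mechanism = tuple(sorted(mechanism))
        k = len(purview)
        if not mechanism:
            return Repertoire(CAUSE, purview, np.full(1 << k, 1.0 / (1 << k)))
        like = np.ones((2,) * k)
        for i in mechanism:
            like = like * self._likelihood_tensor(i, purview)
        s = like.sum()
        if s <= 0.0:
            return None
        return Repertoire(CAUSE, purview, (like / s).ravel(order="F"))

    def effect_repertoire(self, mechanism, purview) -> Repertoire:
        """Product over purview elements of their next-state distributions
        given the mechanism state (empty mechanism: fully unconstrained)."""
        purview = tuple(sorted(purview))
        mechanism = tuple(sorted(mechanism))
        mstate = {u: self.state[u] for u in mechanism}
        dist = np.ones(1)
        for j in purview:
            q = self.effect_marginal(j, mechanism, mstate)
            dist = np.kron(np.array([1.0 - q, q]), dist)
        return Repertoire(EFFECT, purview, dist)

    def unconstrained_effect_marginals(self) -> np.ndarray:
        """p(element ON next) with every input at maximum entropy, per unit."""
        return np.array([self.effect_marginal(j, (), {}) for j in range(self.n)])

    def state_reachable(self) -> bool:
        """Whether the current full state has at least one possible cause."""
        like = np.ones((2,) * self.n)
        full = tuple(range(self.n))
        for i in range(self.n):
            like = like * self._likelihood_tensor(i, full)
        return bool(like.sum() > 0.0)

    # -- mechanism partitions and phi ------------------------------------

    @staticmethod
    def _mech_bipartitions(mechanism):
        """Unordered bipartitions (Ma, Mb) of the mechanism, one part possibly
        empty; each yielded once (orientation of the purview split supplies
        the ordering)."""
        m = list(mechanism)
        if not m:
            return
        rest = m[1:]
        for r in range(len(rest) + 1):
            for combo in itertools.combinations(rest, r):
                ma = tuple(sorted((m[0],) + combo))
                mb = tuple(sorted(set(m) - set(ma)))
                yield ma, mb
        yield (), tuple(m)

    def phi_cause(self, mechanism, purview):
        """(phi, MIP) of the mechanism over a cause purview."""
        mechanism = tuple(sorted(mechanism))
        purview = tuple(sorted(purview))
        k = len(purview)
        whole = self.cause_repertoire(mechanism, purview)
        if whole is None:
            return 0.0, None
        w = whole.dist
        mech = list(mechanism)
        nm = len(mech)
        tensors = [self._likelihood_tensor(i, purview) for i in mech]
        mask_of = {tuple(sorted(sub)): sum(1 << mech.index(i) for i in sub)
                   for r in range(nm + 1)
                   for sub in itertools.combinations(mech, r)}

        def subset_products(avgd, own_axes):
            """Products of the (individually averaged) likelihoods over
            every mechanism subset, by bitmask DP; each element of a part
            marginalises the absent purview axes on its own (the part
            repertoire factorises over mechanism elements).  The base (the
            empty subset) is the unnormalised uniform over ``own_axes``."""
            base = np.ones([2 if j in own_axes else 1 for j in range(k)])
            prods = [base]
            for mask in range(1, 1 << nm):
                low = (mask & -mask).bit_length() - 1
                prods.append(prods[mask ^ (1 << low)] * avgd[low])
            return prods

        best, best_part = np.inf, None
        axes = list(range(k))
        for bits in range(1 << k):
            pa = tuple(axes[j] for j in range(k) if (bits >> j) & 1)
            pb = tuple(axes[j] for j in range(k) if not (bits >> j) & 1)
            prods_a = subset_products(
                [t.mean(axis=pb, keepdims=True) if pb else t
                 for t in tensors], pa)
            prods_b = subset_products(
                [t.mean(axis=pa, keepdims=True) if pa else t
                 for t in tensors], pb)
            for ma, mb in self._mech_bipartitions(mechanism):
                if (not ma and not pa) or (not mb and not pb):
                    continue
                ta = prods_a[mask_of[ma]]
                tb = prods_b[mask_of[mb]]
                sa, sb = ta.sum(), tb.sum()
                if sa <= 0.0 or sb <= 0.0:
                    continue   # partition assigns no probability mass
                q = np.multiply(ta / sa, tb / sb)
                q = np.broadcast_to(q, (2,) * k).ravel(order="F")
                l1 = np.abs(w - q)
                if l1.max() < 1e-12:
                    part = ((ma, tuple(purview[j] for j in pa)),
                            (mb, tuple(purview[j] for j in pb)))
                    return 0.0, part
                if 0.5 * l1.sum() >= best:
                    continue   # EMD >= total variation: cannot beat current MIP
                d = hamming_emd(w, q)
                if d < best - 1e-15:
                    best = d
                    best_part = ((ma, tuple(purview[j] for j in pa)),
                                 (mb, tuple(purview[j] for j in pb)))
                    if best < PHI_EPS:
                        return 0.0, best_part
        if not np.isfinite(best):
            return 0.0, None
        return best, best_part

    def phi_effect(self, mechanism, purview):
        """(phi, MIP) of the mechanism over an effect purview.

        Effect repertoires (whole and partitioned) are products over purview
        elements, so the earth-mover distance reduces exactly to the sum of
        per-element marginal differences; the purview split is optimised
        element-wise for each mechanism bipartition.
        """
        mechanism = tuple(sorted(mechanism))
        purview = tuple(sorted(purview))
        mstate = {u: self.state[u] for u in mechanism}
        gw = {j: self.effect_marginal(j, mechanism, mstate) for j in purview}

        def g(j, ms):
            sub = {u: mstate[u] for u in ms}
            return self.effect_marginal(j, tuple(ms), sub)

        best, best_part = np.inf, None
        for ma, mb in self._mech_bipartitions(mechanism):
            ca = {j: abs(gw[j] - g(j, ma)) for j in purview}
            cb = {j: abs(gw[j] - g(j, mb)) for j in purview}
            side_a = [j for j in purview if ca[j] < cb[j] - 1e-15]
            cost = sum(min(ca[j], cb[j]) for j in purview)
            pa = tuple(side_a)
            pb = tuple(j for j in purview if j not in side_a)
            # validity: an empty mechanism part needs a nonempty purview part
            if not ma and not pa:
                move = min(purview, key=lambda j: ca[j] - cb[j])
                cost += ca[move] - cb[move]
                pa = (move,)
                pb = tuple(j for j in purview if j != move)
            if not mb and not pb:
                move = min(purview, key=lambda j: cb[j] - ca[j])
                cost += cb[move] - ca[move]
                pb = (move,)
                pa = tuple(j for j in purview if j != move)
            if cost < best - 1e-15:
                best = cost
                best_part = ((ma, pa), (mb, pb))
                if best < PHI_EPS:
                    return 0.0, best_part
        if not np.isfinite(best):
            return 0.0, None
        return best, best_part

    # -- purview search ---------------------------------------------------

    def _purview_candidates(self, mechanism, direction):
        """Purviews not excluded by connectivity.

        phi is provably zero unless every purview element interacts with the
        mechanism and every mechanism element interacts with the purview, so
        only subsets of the mechanism's inputs (cause) or outputs (effect)
        that touch every mechanism element need evaluation.
        """
        if direction == CAUSE:
            pools = [self.inputs[i] for i in mechanism]
        else:
            pools = [self.outputs[i] for i in mechanism]
        if any(not p for p in pools):
            return []
        union = sorted(set().union(*pools))
        out = []
        for r in range(1, len(union) + 1):
            for combo in itertools.combinations(union, r):
                cs = set(combo)
                if all(p & cs for p in pools):
                    out.append(tuple(combo))
        # prefer larger purviews, then lexicographically first, at phi ties
        out.sort(key=lambda P: (-len(P), P))
        return out

    def find_mice(self, mechanism, direction) -> Mice:
        """The maximally irreducible cause or effect of a mechanism."""
        mechanism = tuple(sorted(mechanism))
        best = Mice(direction, (), np.ones(1), 0.0, None)
        for P in self._purview_candidates(mechanism, direction):
            if direction == CAUSE:
                phi, part = self.phi_cause(mechanism, P)
            else:
                phi, part = self.phi_effect(mechanism, P)
            if phi > best.phi + PHI_EPS:
                rep = (self.cause_repertoire(mechanism, P) if direction == CAUSE
                       else self.effect_repertoire(mechanism, P))
                best = Mice(direction, P, rep.dist, phi, part)
        return best

    def concept(self, mechanism) -> Concept | None:
        """The concept of a mechanism, or ``None`` if it is reducible."""
        mechanism = tuple(sorted(mechanism))
        if not mechanism:
            raise ValueError("mechanism must be nonempty")
        effect = self.find_mice(mechanism, EFFECT)
        if effect.phi < PHI_EPS:
            return None
        cause = self.find_mice(mechanism, CAUSE)
        if cause.phi < PHI_EPS:
            return None
        return Concept(mechanism, tuple(self.state[i] for i in mechanism),
                       cause, effect)


# --------------------------------------------------------------------------
# Convenience wrappers (the operation-level interface)
# --------------------------------------------------------------------------

def cause_repertoire(model: TransitionModel, mechanism, state, purview):
    """Cause repertoire of ``mechanism`` (with the full system ``state``)
    over ``purview``; ``None`` if the state has no cause there."""
    return RepertoireCalculator(model, state).cause_repertoire(mechanism, purview)


def effect_repertoire(model: TransitionModel, mechanism, state, purview):
    return RepertoireCalculator(model, state).effect_repertoire(mechanism, purview)


def compute_concept(model: TransitionModel, mechanism, state):
    """Concept of a mechanism within the system, or ``None`` if reducible."""
    return RepertoireCalculator(model, state).concept(mechanism)
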