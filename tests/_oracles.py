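"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities from first principles with dense,
unpruned enumeration and a dense transportation linear program, sharing no
code path with the package implementation (which uses factorised
likelihoods, connectivity pruning, min-cost flow on the hypercube, and
product-distribution shortcuts).  Only tractable for tiny systems.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


# ---------------------------------------------------------------------------
# Dense transportation EMD
# ---------------------------------------------------------------------------

def hamming_matrix(n: int) -> np.ndarray:
    size = 1 << n
    D = np.zeros((size, size))
    for a in range(size):
        for b in range(size):
            D[a, b] = bin(a ^ b).count("1")
    return D


def transport_emd(p, q, D) -> float:
    """Earth-mover distance by the dense transportation LP over all pairs."""
    p = np.asarray(p, float).ravel()
    q = np.asarray(q, float).ravel()
    m = len(p)
    c = D.ravel()
    A = np.zeros((2 * m, m * m))
    for i in range(m):
        A[i, i * m:(i + 1) * m] = 1.0
        A[m + i, i::m] = 1.0
    res = linprog(c, A_eq=A, b_eq=np.concatenate([p, q]),
                  bounds=(0, None), method="highs")
    assert res.success, res.message
    return float(res.fun)


def hamming_emd_oracle(p, q) -> float:
    n = (len(np.ravel(p))).bit_length() - 1
    return transport_emd(p, q, hamming_matrix(n))


# ---------------------------------------------------------------------------
# Naive integrated-information engine over a state-by-state TPM
# ---------------------------------------------------------------------------

class NaivePhi:
    """Unpruned reference implementation over a dense state-by-state TPM.

    ``sbs[s, s']`` = p(next state s' | state s), little-endian state order.
    All repertoires, partitions, purviews, cuts, and distances are
    enumerated exhaustively; every distance is a dense transportation LP.
    """

    def __init__(self, sbs: np.ndarray, state):
        self.sbs = np.asarray(sbs, float)
        self.size = self.sbs.shape[0]
        self.n = self.size.bit_length() - 1
        self.state = tuple(state)
        self.units = tuple(range(self.n))

    # -- elementary conditionals ---------------------------------------

    def node_on(self, j: int) -> np.ndarray:
        """p(element j ON next | state), for every state."""
        cols = np.array([(s >> j) & 1 for s in range(self.size)])
        return self.sbs[:, cols == 1].sum(axis=1)

    def _consistent(self, subset, values) -> np.ndarray:
        """Boolean mask of full states agreeing with values on subset."""
        mask = np.ones(self.size, dtype=bool)
        for u, v in zip(subset, values):
            bits = np.array([(s >> u) & 1 for s in range(self.size)])
            mask &= bits == v
        return mask

    # -- repertoires -----------------------------------------------------

    def cause_rep(self, mech, purview):
        """Factorised cause repertoire; None if the mechanism state has no
        possible cause over this purview."""
        purview = tuple(sorted(purview))
        k = len(purview)
        rep = np.ones(1 << k)
        for i in sorted(mech):
            pi = self.node_on(i)
            like = pi if self.state[i] == 1 else 1.0 - pi
            r = np.empty(1 << k)
            for pidx in range(1 << k):
                vals = [(pidx >> a) & 1 for a in range(k)]
                r[pidx] = like[self._consistent(purview, vals)].mean()
            rep = rep * r
        if not mech:
            return np.full(1 << k, 1.0 / (1 << k))
        s = rep.sum()
        if s <= 0:
            return None
        return rep / s

    def effect_rep(self, mech, purview):
        purview = tuple(sorted(purview))
        mech = tuple(sorted(mech))
        mask = self._consistent(mech, [self.state[i] for i in mech])
        dist = np.ones(1)
        for j in purview:
            q = self.node_on(j)[mask].mean()
            dist = np.kron(np.array([1 - q, q]), dist)
        return dist

    def rep(self, direction, mech, purview):
        return (self.cause_rep(mech, purview) if direction == "cause"
                else self.effect_rep(mech, purview))

    # -- phi -------------------------------------------------------------

    @staticmethod
    def _bipartitions(items):
        items = list(items)
        if not items:
            yield (), ()
            return
        first, rest = items[0], items[1:]
        for r in range(len(rest) + 1):
            for combo in itertools.combinations(rest, r):
                a = tuple(sorted((first,) + combo))
                b = tuple(sorted(set(items) - set(a)))
                yield a, b
        yield (), tuple(items)

    def small_phi(self, direction, mech, purview):
        purview = tuple(sorted(purview))
        k = len(purview)
        whole = self.rep(direction, mech, purview)
        if whole is None:
            return 0.0
        D = hamming_matrix(k)
        best = np.inf
        for ma, mb in self._bipartitions(mech):
            for r in range(k + 1):
                for pa in itertools.combinations(purview, r):
                    pb = tuple(x for x in purview if x not in pa)
                    if (not ma and not pa) or (not mb and not pb):
                        continue
                    ra = self.rep(direction, ma, pa)
                    rb = self.rep(direction, mb, pb)
                    if ra is None or rb is None:
                        continue
                    q = np.zeros(1 << k)
                    for idx in range(1 << k):
                        va = sum(((idx >> purview.index(x)) & 1) << a
                                 for a, x in enumerate(pa))
                        vb = sum(((idx >> purview.index(x)) & 1) << b
                                 for b, x in enumerate(pb))
                        q[idx] = ra[va] * rb[vb]
                    best = min(best, transport_emd(whole, q, D))
        return 0.0 if not np.isfinite(best) else best

    def mice(self, direction, mech):
        best_phi, best_p = 0.0, ()
        purviews = []
        for r in range(1, self.n + 1):
            purviews.extend(itertools.combinations(self.units, r))
        purviews.sort(key=lambda P: (-len(P), P))
        for P in purviews:
            phi = self.small_phi(direction, mech, P)
            if phi > best_phi + 1e-10:
                best_phi, best_p = phi, P
        return best_phi, best_p

    def concept(self, mech):
        pe, Pe = self.mice("effect", mech)
        if pe < 1e-10:
            return None
        pc, Pc = self.mice("cause", mech)
        if pc < 1e-10:
            return None
        return {"mech": tuple(sorted(mech)), "phi": min(pc, pe),
                "cause": (Pc, self.cause_rep(mech, Pc)),
                "effect": (Pe, self.effect_rep(mech, Pe)),
                "sys": self}

    def ces(self):
        like = np.ones(self.size)
        for i in self.units:
            pi = self.node_on(i)
            like = like * (pi if self.state[i] == 1 else 1.0 - pi)
        if like.sum() <= 0:
            return None    # undefined cause-effect structure
        out = []
        for r in range(1, self.n + 1):
            for mech in itertools.combinations(self.units, r):
                c = self.concept(mech)
                if c is not None:
                    out.append(c)
        return out

    # -- cuts and big phi -------------------------------------------------

    def cut_tpm(self, part_a) -> np.ndarray:
        """Noise all connections from part_a: each element's conditional is
        averaged over the part_a coordinates of the previous state, except
        for elements of part_a themselves, which keep their own inputs...
        no — the cut is unidirectional: receivers *outside* part_a lose the
        part_a inputs; receivers inside keep everything."""
        size, n = self.size, self.n
        node_on = [self.node_on(j) for j in self.units]
        new_on = np.empty((size, n))
        for j in self.units:
            if j in part_a:
                new_on[:, j] = node_on[j]
            else:
                for s in range(size):
                    mask = self._consistent(
                        [u for u in self.units if u not in part_a],
                        [(s >> u) & 1 for u in self.units
                         if u not in part_a])
                    new_on[s, j] = node_on[j][mask].mean()
        sbs = np.ones((size, size))
        for j in self.units:
            col = np.array([(s >> j) & 1 for s in range(size)])
            pj = new_on[:, j][:, None]
            sbs *= np.where(col[None, :] == 1, pj, 1 - pj)
        return sbs

    def expand_concept(self, c):
        """(cause distribution, effect distribution) over the full system,
        filling absent units with the unconstrained repertoires of the
        system the concept was computed in."""
        n = self.n
        own = c.get("sys", self)
        Pc, rc = c["cause"]
        Pe, re = c["effect"]
        cause = np.ones(1 << n)
        for s in range(1 << n):
            idx = sum(((s >> u) & 1) << a for a, u in enumerate(sorted(Pc)))
            cause[s] = rc[idx] / (1 << (n - len(Pc)))
        eff_m = [own.effect_rep((), (j,))[1] for j in self.units]
        for a, u in enumerate(sorted(Pe)):
            bits = np.array([(idx >> a) & 1 for idx in range(len(re))])
            eff_m[u] = re[bits == 1].sum()
        effect = np.ones(1)
        for j in self.units:
            effect = np.kron(np.array([1 - eff_m[j], eff_m[j]]), effect)
        return cause, effect

    def ces_distance(self, ces1, ces2):
        n = self.n
        null_cause = np.full(1 << n, 1.0 / (1 << n))
        null_effect = self.effect_rep((), self.units)
        pts = [self.expand_concept(c) for c in ces1] \
            + [self.expand_concept(c) for c in ces2] \
            + [(null_cause, null_effect)]
        s1 = sum(c["phi"] for c in ces1)
        s2 = sum(c["phi"] for c in ces2)
        supply = np.array([c["phi"] for c in ces1] + [0.0] * len(ces2)
                          + [max(0.0, s2 - s1)])
        demand = np.array([0.0] * len(ces1) + [c["phi"] for c in ces2]
                          + [max(0.0, s1 - s2)])
        if supply.sum() < 1e-12:
            return 0.0
        D = hamming_matrix(n)
        m = len(pts)
        G = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                if i != j:
                    G[i, j] = transport_emd(pts[i][0], pts[j][0], D) \
                        + transport_emd(pts[i][1], pts[j][1], D)
        return transport_emd(supply, demand, G)

    def big_phi(self):
        intact = self.ces()
        if intact is None:
            return None
        best = np.inf
        for mask in range(1, self.size - 1 if self.size <= 2 else
                          (1 << self.n) - 1):
            part_a = tuple(u for u in self.units if (mask >> u) & 1)
            if not part_a or len(part_a) == self.n:
                continue
            cut = NaivePhi(self.cut_tpm(part_a), self.state)
            cut_ces = cut.ces()
            if cut_ces is None:
                cut_ces = []
            best = min(best, self.ces_distance(intact, cut_ces))
            if best < 1e-10:
                return 0.0
        return float(best) if np.isfinite(best) else 0.0
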