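# Methods

This note records the model conventions, algorithmic choices, and numerical
decisions behind `boxphi`, in the order the analysis runs.

## Networks and transition models

A network is a set of binary elements updated synchronously. Update rules
are explicit truth tables (probability of switching ON per input
configuration) or signed-weight threshold logic. Threshold elements turn ON
when the weighted input sum exceeds the threshold, OFF below it, and at
equality follow a tie rule; the default `hold` rule retains the previous
state, which makes the element implicitly self-dependent whenever the
threshold is attainable — the implicit self-input is materialised when the
rule is compiled to a table, so downstream machinery sees plain
conditional-probability tables throughout.

The transition probability model is built by maximum-entropy perturbation:
for every joint state, each element's next-state distribution is recorded.
Elements outside the candidate system are *background conditions*, clamped
to their observed values while the model is conditioned. The model is
stored in state-by-node form (one conditional table per element over its
effective inputs); elements are conditionally independent given the full
previous state, so the state-by-state matrix is a derived view. State
indexing is little-endian: element 0 of the declared order is the
least-significant bit. Probabilities are double-precision floats; all
bundled systems are deterministic, so no exact-rational mode is needed.
Simulation is defined only for deterministic networks (sampling stochastic
ones would need a seed and nothing here requires it).

## Mechanism analysis

Cause repertoires follow the factorised ("virtual element") convention:
each mechanism element conditions the past independently — its likelihood
over purview states is computed with all non-purview inputs marginalised
uniformly — and the per-element likelihoods are multiplied and
renormalised. Effect repertoires are products over purview elements of each
element's next-state distribution given the mechanism state, other inputs
uniform. An empty mechanism yields the uniform (cause) or fully
unconstrained (effect) repertoire. A mechanism state with zero likelihood
under every past purview state has no cause there; if the *full system*
state has no cause at all, the cause-effect structure is undefined and the
analysis reports that instead of a number.

φ of a mechanism over a purview is the minimum, over bipartitions of the
(mechanism, purview) pair, of the earth-mover distance between the whole
repertoire and the product of the parts' repertoires. The partition family
pairs every unordered mechanism bipartition (one side may be empty) with
every ordered purview bipartition, excluding assignments that leave a part
with neither mechanism nor purview elements; each part's repertoire again
marginalises its absent purview elements per mechanism element. A partition
whose parts jointly assign zero probability mass reproduces nothing and is
skipped. Purview maximisation breaks φ ties toward the larger purview,
then the lexicographically first one; the reproduced published values are
insensitive to this choice. φ below 1e-10 counts as zero (float noise from
the distance solver).

Two exact shortcuts keep the power-set sweeps tractable without changing
any value. First, connectivity pruning: φ is provably zero unless every
purview element interacts with the mechanism and every mechanism element
with the purview, so only such purviews are evaluated. Second, the
effect-side distance: effect repertoires (whole and partitioned) are
product distributions, for which the Hamming earth-mover distance equals
the sum of per-element marginal differences; the purview split of an
effect partition is therefore optimised element-wise. Both shortcuts are
cross-checked in the tests against a dense, unpruned reference
implementation.

## Earth-mover distances

The Hamming metric is the shortest-path metric of the hypercube, so the
earth-mover distance between repertoires is computed as a min-cost flow on
the hypercube graph (2^k nodes, k·2^k arcs per direction) with
`scipy.optimize.linprog` (HiGHS) — far smaller than the dense
transportation program over all state pairs, and exact. The test suite
validates it against an independently formulated dense transportation LP on
random distributions. Total variation is used as a lower bound to skip
hopeless partitions while minimising over a partition family.

## System analysis

The cause-effect structure collects the concepts of all 2^n − 1 candidate
mechanisms. Φ is minimised over *unidirectional* bipartitions of the micro
substrate (2^m − 2 cuts for m micro elements): connections from the cut's
source part to its target part are replaced by maximum-entropy noise, the
structure is recomputed, and the two structures are compared with an
extended earth-mover distance — concept φ-mass is transported with a ground
metric equal to the summed cause and effect repertoire distances after
expanding every repertoire over the full system purview (absent elements
filled with the repertoires of the empty mechanism of the concept's own
system), with unmatched mass sent to the null concept of the intact system.
Cut values are not normalised; ties take the first cut in the stable
little-endian enumeration order.

Two exact reductions apply. A system whose effective unit-level wiring is
not strongly connected is reducible outright: a sink component sends
nothing to the rest, so the corresponding cut severs no dependency and
Φ = 0 without assembling the structure (`PhiResult` then carries no
structures). Optionally, cut enumeration is restricted to one
representative per orbit of the network's state-preserving automorphism
group (graph automorphisms filtered by exact table, state, and — for macro
systems — box-structure preservation); orbit members have equal
constellation distance, so the minimum is unchanged, and equality with the
plain sweep is property-tested. The 9-element demonstration system has a
6-element group, reducing 510 cuts to 102 orbits.

## Black-boxing

A mapping groups disjoint micro elements into boxes with one designated
output element each, a common time scale T, and fixed background states for
unboxed elements. Validation enforces: disjointness (exclusion), output
membership, a macro input per box (an edge from outside the box or from the
box's own output element — a macro self-connection), coverage of all
elements, and a structural pre-check of micro integration: every hidden
element needs a box-internal directed path to the output within T steps.
The full integration condition is enforced downstream by Φ = 0, as it
cannot be decided structurally.

The macro transition model is derived by perturbation with exact
marginalisation (never sampling): each box's output element starts clamped
at its macro value, hidden elements start at maximum entropy, and the box
evolves for T synchronous micro updates during which cross-box connections
transmit the true source state only at the first update (inputs arrive at
the beginning of the macro step) and are noised afterwards; connections
leaving a box from non-output elements are always noised; background stays
fixed. Because every later-step cross-box influence is noised, the boxes
are conditionally independent and each box's table is computed separately
by propagating the exact joint distribution over its members (2^k states
for a k-element box) — this per-box factorisation is what makes the
55-element system tractable, avoiding any joint enumeration. The
intermediate-step noising convention is the one under which box functions
are well defined; it is confirmed by the derived logic tables of the
bundled systems (XOR over two steps; AND/OR at T = 2 and MAJORITY at T = 4
for the NOR groups) and by the macro Φ values. An identity mapping (every
element its own box, T = 1) provably reproduces the micro model, and the
noising construction is tested against brute-force enumeration of hidden
states and noise realisations. Macro-system cuts always partition the
*micro* substrate; the macro table is re-derived with the severed edges
noised at every step.

## Scale search

Candidates cross every grouping of the elements (all set partitions except
the all-singleton one, which is the micro system at T = 1 and participates
as a candidate and as a temporal neighbour of T = 2 systems) with every
choice of output element per box and every time scale (default T ∈
{2, 3, 4}). The candidate count is timescales × Σ over non-singleton
partitions of ∏(block sizes) — 124,176 for eight elements — verified
against brute-force enumeration for n ≤ 6. Neighbourhood combines three
distances: constitutional (symmetric difference of the constituting micro
sets), temporal (|ΔT|), and spatial (maximum matching distance between
groupings, solved as an assignment problem). For systems with different
constitutions the spatial term compares the groupings restricted to the
shared constitution; the difference is already charged to the
constitutional term. Local maxima are judged within the evaluated candidate
set; equivalent maxima are deduplicated under state-preserving network
automorphisms; stability across a state sequence means presence in every
analysed state. Per-state results are cached as JSON keyed by canonical
mapping so long sweeps are resumable; evaluation is serial — candidate
evaluations are independent, so external sharding is straightforward if
ever needed.

## Bundled systems

`xor_delay` (9 elements) and `nor_hierarchy` (55 elements) are constructed
demonstration circuits; `cell_cycle` is the Davidich–Bornholdt Boolean
model of the fission-yeast cell cycle (thresholds 0 except Cdc2/Cdc13 at
−½ and Cdc2/Cdc13* at +½; self-degradation loops on SK, Slp1, PP; tie
holds). The transcription reproduces the published 9-state biological
sequence exactly, which the tests assert state by state; the t2 state
indeed has no cause within the 8-element system (its cause is the external
catalyst SK) and is excluded from cause-effect analysis. The NOR
hierarchy's intra-group circuit is a reconstruction: three AND sub-circuits
(two 1-input NOR inverters feeding a 2-input NOR) and an OR sub-circuit (a
3-input NOR plus inverter, the inverter being the group output), with group
g receiving inputs from groups g+1..g+3 (mod 5), each input fanning out to
the two AND sub-circuits that consume it; the reconstruction is validated
by its derived macro logic tables and concept structure and is flagged as
such in the fixture metadata.

The random-network generator used by the property tests draws, per element,
k distinct inputs from the other elements and a gate from a named family,
under a single integer seed (identical seeds give byte-identical specs). It
emulates small, sparse, homogeneous logic networks — not degree
heterogeneity, self-loops, or stochastic rules — so passing property tests
demonstrates correctness of the machinery on such networks, not biological
realism of any particular system.

## Problem sizes and verification

The test suite and acceptance script run everything at the sizes the
analyses are defined on: the full 9-element micro system (Φ = 0.25; the
suite uses the automorphism-pruned cut sweep, 102 orbits in ~30 s, after
property-testing its equality with the plain sweep), the 3-element macro
XOR system over its 510 micro cuts (Φ = 1.875, ~5 s), and the 5-element
MAJORITY macro level of the 55-element hierarchy (30 of 31 mechanisms,
~40 s). Exhaustive oracle comparisons (dense LP, unpruned enumeration) run
on 3-node systems, where they are exact and fast. The full Φ values of the
55-element system at its micro and AND/OR levels, and the exhaustive
124,176-candidate cell-cycle sweep, are expressible with the same
machinery but are combinatorially long-running (power-set structures over
20+ units; 2^55 cuts barely reduced by the network's small automorphism
group); they are not part of the default verification runs. The library
enforces a hard bound (cut enumeration refuses substrates beyond 24
elements) rather than silently approximating.

## Known limitations

Binary elements and synchronous update only; one output element per box;
a single common time scale per system; no coarse-grained (average-based)
macro mappings; no heuristic search — enumeration is exhaustive within the
configured family. The implementation follows the earth-mover-distance
formulation of integrated information throughout; alternative divergences
from later theoretical variants are out of scope.
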