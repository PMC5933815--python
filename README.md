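# boxphi

Integrated information (φ, Φ) of discrete logic networks at the micro level
and at *black-boxed* macro spatiotemporal scales.

## The problem

Biological and engineered systems are routinely described at macro levels —
a neuron rather than its synapses, a protein module rather than individual
reactions — by treating the lower level as a black box: a unit characterised
only by its input–output function. `boxphi` asks whether such a macro
description can carry **more intrinsic cause–effect power** than the micro
description it supervenes on, and finds the spatiotemporal scales at which
cause–effect power peaks.

The measure is integrated information. For a system of binary elements with
a transition probability model (obtained by perturbing the elements into
all states with a maximum-entropy distribution):

- a **mechanism** is a subset of elements in its current state; its *cause*
  (*effect*) *repertoire* is the conditional distribution over past (future)
  states of a purview of elements;
- **φ** (small phi) measures a mechanism's irreducibility: the earth-mover
  distance (Hamming ground metric) between its repertoire and the closest
  factorisation across a bipartition of mechanism and purview, maximised
  over purviews, with a concept existing iff min(φ_cause, φ_effect) > 0;
- the **cause-effect structure** is the set of all concepts of the system;
- **Φ** (big Phi) measures the system's irreducibility: the minimum, over
  all unidirectional bipartitions of the *micro* substrate, of the extended
  earth-mover distance between the intact cause-effect structure and the one
  recomputed after the severed connections are replaced by noise.

A **black box** groups disjoint micro elements into a macro element whose
state is read from a single designated output element after T micro
updates; hidden elements and non-output connections are noised during the
perturbation analysis, and cross-box inputs arrive only at the beginning of
a macro update. Candidate macro systems across all groupings, output
choices, and time scales are compared through constitutional, temporal, and
spatial (partition-matching) distances; a **local maximum of Φ** is a
candidate none of whose neighbours does better.

## Worked example

Three XOR gates coupled through COPY elements that model one-step
propagation delay (9 micro elements, bundled as the `xor_delay` system):

```python
import boxphi as bp

fx = bp.make_fixture("xor_delay")

# micro level: 9 elements, all OFF
model = bp.build_transition_model(fx.network)
calc = bp.RepertoireCalculator(model, (0,) * 9)
print(calc.concept((0,)).phi)        # 0.5  — each XOR is a concept
print(calc.concept((1,)))            # None — a lone COPY has no effect

# macro level: three black boxes, each hiding its two input COPYs (T = 2)
macro = bp.MacroSystem.from_micro_state(fx.network,
                                        fx.mappings["canonical"], fx.state)
print(bp.compute_big_phi(macro).phi)   # 1.875
```

At the micro level the cause-effect structure holds three first-order
concepts (the XORs, φ = 0.5 each) and Φ = 0.25. Black-boxing conceals the
COPY delays and reveals three *second-order* concepts over pairs of macro
XOR elements — every mechanism now constrains the whole system — and the
same substrate supports Φ = 1.875: the macro level beats the micro level by
being more integrated, not by having more or stronger mechanisms.

The same pipeline from the command line:

```sh
boxphi fixtures xor_delay > xor.yaml
boxphi blackbox xor.yaml     # derived macro table: XOR over two time steps
boxphi phi xor.yaml --macro  # Phi = 1.875 + concept table
```

Also bundled: a 55-element NOR hierarchy whose groups implement AND/OR at
T = 2 and MAJORITY at T = 4 (`nor_hierarchy`), and the nine-element
linear-threshold Boolean model of the fission-yeast cell cycle with its
9-state biological sequence (`cell_cycle`), whose catalyst element SK is a
feedback-free background condition. `boxphi search` sweeps all black-box
candidates of a (small) network and flags local maxima of Φ.

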