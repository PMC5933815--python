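# A 55-element micro system in which every element implements NOR logic,
# arranged into five interconnected groups of 11.  Within a group, three
# 3-element sub-circuits (two single-input NOR inverters feeding a 2-input
# NOR) realise AND over two micro updates; their outputs feed a 3-input NOR
# whose single-input NOR inverter is the group's output element, realising
# OR over two further updates.  Black-boxed per sub-circuit (T=2) the group
# is three ANDs + one OR; boxed whole (T=4) it implements MAJORITY of its
# three group inputs.  Group g receives input from groups g+1, g+2, g+3
# (mod 5); each group input fans out to the two AND sub-circuits that
# consume it, so every input arrives at two different micro elements.  The
# intra-group circuit is a reconstruction satisfying these macro logic
# tables (see package docs); analysed state: all ON.
metadata:
  name: nor_hierarchy
  analyzed_state: all_on
  reconstruction: intra-group circuit rebuilt from the documented macro
    logic (AND/OR at T=2, MAJORITY at T=4); wiring between groups is the
    rotational scheme above.
nodes:
- {label: g0_and0_na, gate: NOR}
- {label: g0_and0_nb, gate: NOR}
- {label: g0_and0_out, gate: NOR}
- {label: g0_and1_na, gate: NOR}
- {label: g0_and1_nb, gate: NOR}
- {label: g0_and1_out, gate: NOR}
- {label: g0_and2_na, gate: NOR}
- {label: g0_and2_nb, gate: NOR}
- {label: g0_and2_out, gate: NOR}
- {label: g0_or_n, gate: NOR}
- {label: g0_out, gate: NOR}
- {label: g1_and0_na, gate: NOR}
- {label: g1_and0_nb, gate: NOR}
- {label: g1_and0_out, gate: NOR}
- {label: g1_and1_na, gate: NOR}
- {label: g1_and1_nb, gate: NOR}
- {label: g1_and1_out, gate: NOR}
- {label: g1_and2_na, gate: NOR}
- {label: g1_and2_nb, gate: NOR}
- {label: g1_and2_out, gate: NOR}
- {label: g1_or_n, gate: NOR}
- {label: g1_out, gate: NOR}
- {label: g2_and0_na, gate: NOR}
- {label: g2_and0_nb, gate: NOR}
- {label: g2_and0_out, gate: NOR}
- {label: g2_and1_na, gate: NOR}
- {label: g2_and1_nb, gate: NOR}
- {label: g2_and1_out, gate: NOR}
- {label: g2_and2_na, gate: NOR}
- {label: g2_and2_nb, gate: NOR}
- {label: g2_and2_out, gate: NOR}
- {label: g2_or_n, gate: NOR}
- {label: g2_out, gate: NOR}
- {label: g3_and0_na, gate: NOR}
- {label: g3_and0_nb, gate: NOR}
- {label: g3_and0_out, gate: NOR}
- {label: g3_and1_na, gate: NOR}
- {label: g3_and1_nb, gate: NOR}
- {label: g3_and1_out, gate: NOR}
- {label: g3_and2_na, gate: NOR}
- {label: g3_and2_nb, gate: NOR}
- {label: g3_and2_out, gate: NOR}
- {label: g3_or_n, gate: NOR}
- {label: g3_out, gate: NOR}
- {label: g4_and0_na, gate: NOR}
- {label: g4_and0_nb, gate: NOR}
- {label: g4_and0_out, gate: NOR}
- {label: g4_and1_na, gate: NOR}
- {label: g4_and1_nb, gate: NOR}
- {label: g4_and1_out, gate: NOR}
- {label: g4_and2_na, gate: NOR}
- {label: g4_and2_nb, gate: NOR}
- {label: g4_and2_out, gate: NOR}
- {label: g4_or_n, gate: NOR}
- {label: g4_out, gate: NOR}
edges:
- {from: g1_out, to: g0_and0_na}
- {from: g2_out, to: g0_and0_nb}
- {from: g0_and0_na, to: g0_and0_out}
- {from: g0_and0_nb, to: g0_and0_out}
- {from: g0_and0_out, to: g0_or_n}
- {from: g1_out, to: g0_and1_na}
- {from: g3_out, to: g0_and1_nb}
- {from: g0_and1_na, to: g0_and1_out}
- {from: g0_and1_nb, to: g0_and1_out}
- {from: g0_and1_out, to: g0_or_n}
- {from: g2_out, to: g0_and2_na}
- {from: g3_out, to: g0_and2_nb}
- {from: g0_and2_na, to: g0_and2_out}
- {from: g0_and2_nb, to: g0_and2_out}
- {from: g0_and2_out, to: g0_or_n}
- {from: g0_or_n, to: g0_out}
- {from: g2_out, to: g1_and0_na}
- {from: g3_out, to: g1_and0_nb}
- {from: g1_and0_na, to: g1_and0_out}
- {from: g1_and0_nb, to: g1_and0_out}
- {from: g1_and0_out, to: g1_or_n}
- {from: g2_out, to: g1_and1_na}
- {from: g4_out, to: g1_and1_nb}
- {from: g1_and1_na, to: g1_and1_out}
- {from: g1_and1_nb, to: g1_and1_out}
- {from: g1_and1_out, to: g1_or_n}
- {from: g3_out, to: g1_and2_na}
- {from: g4_out, to: g1_and2_nb}
- {from: g1_and2_na, to: g1_and2_out}
- {from: g1_and2_nb, to: g1_and2_out}
- {from: g1_and2_out, to: g1_or_n}
- {from: g1_or_n, to: g1_out}
- {from: g3_out, to: g2_and0_na}
- {from: g4_out, to: g2_and0_nb}
- {from: g2_and0_na, to: g2_and0_out}
- {from: g2_and0_nb, to: g2_and0_out}
- {from: g2_and0_out, to: g2_or_n}
- {from: g3_out, to: g2_and1_na}
- {from: g0_out, to: g2_and1_nb}
- {from: g2_and1_na, to: g2_and1_out}
- {from: g2_and1_nb, to: g2_and1_out}
- {from: g2_and1_out, to: g2_or_n}
- {from: g4_out, to: g2_and2_na}
- {from: g0_out, to: g2_and2_nb}
- {from: g2_and2_na, to: g2_and2_out}
- {from: g2_and2_nb, to: g2_and2_out}
- {from: g2_and2_out, to: g2_or_n}
- {from: g2_or_n, to: g2_out}
- {from: g4_out, to: g3_and0_na}
- {from: g0_out, to: g3_and0_nb}
- {from: g3_and0_na, to: g3_and0_out}
- {from: g3_and0_nb, to: g3_and0_out}
- {from: g3_and0_out, to: g3_or_n}
- {from: g4_out, to: g3_and1_na}
- {from: g1_out, to: g3_and1_nb}
- {from: g3_and1_na, to: g3_and1_out}
- {from: g3_and1_nb, to: g3_and1_out}
- {from: g3_and1_out, to: g3_or_n}
- {from: g0_out, to: g3_and2_na}
- {from: g1_out, to: g3_and2_nb}
- {from: g3_and2_na, to: g3_and2_out}
- {from: g3_and2_nb, to: g3_and2_out}
- {from: g3_and2_out, to: g3_or_n}
- {from: g3_or_n, to: g3_out}
- {from: g0_out, to: g4_and0_na}
- {from: g1_out, to: g4_and0_nb}
- {from: g4_and0_na, to: g4_and0_out}
- {from: g4_and0_nb, to: g4_and0_out}
- {from: g4_and0_out, to: g4_or_n}
- {from: g0_out, to: g4_and1_na}
- {from: g2_out, to: g4_and1_nb}
- {from: g4_and1_na, to: g4_and1_out}
- {from: g4_and1_nb, to: g4_and1_out}
- {from: g4_and1_out, to: g4_or_n}
- {from: g1_out, to: g4_and2_na}
- {from: g2_out, to: g4_and2_nb}
- {from: g4_and2_na, to: g4_and2_out}
- {from: g4_and2_nb, to: g4_and2_out}
- {from: g4_and2_out, to: g4_or_n}
- {from: g4_or_n, to: g4_out}
state:
  g0_and0_na: 1
  g0_and0_nb: 1
  g0_and0_out: 1
  g0_and1_na: 1
  g0_and1_nb: 1
  g0_and1_out: 1
  g0_and2_na: 1
  g0_and2_nb: 1
  g0_and2_out: 1
  g0_or_n: 1
  g0_out: 1
  g1_and0_na: 1
  g1_and0_nb: 1
  g1_and0_out: 1
  g1_and1_na: 1
  g1_and1_nb: 1
  g1_and1_out: 1
  g1_and2_na: 1
  g1_and2_nb: 1
  g1_and2_out: 1
  g1_or_n: 1
  g1_out: 1
  g2_and0_na: 1
  g2_and0_nb: 1
  g2_and0_out: 1
  g2_and1_na: 1
  g2_and1_nb: 1
  g2_and1_out: 1
  g2_and2_na: 1
  g2_and2_nb: 1
  g2_and2_out: 1
  g2_or_n: 1
  g2_out: 1
  g3_and0_na: 1
  g3_and0_nb: 1
  g3_and0_out: 1
  g3_and1_na: 1
  g3_and1_nb: 1
  g3_and1_out: 1
  g3_and2_na: 1
  g3_and2_nb: 1
  g3_and2_out: 1
  g3_or_n: 1
  g3_out: 1
  g4_and0_na: 1
  g4_and0_nb: 1
  g4_and0_out: 1
  g4_and1_na: 1
  g4_and1_nb: 1
  g4_and1_out: 1
  g4_and2_na: 1
  g4_and2_nb: 1
  g4_and2_out: 1
  g4_or_n: 1
  g4_out: 1
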