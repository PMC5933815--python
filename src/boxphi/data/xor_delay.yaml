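# Three XOR gates coupled all-to-all through explicit one-step propagation
# delays.  Each XOR's output is relayed by a dedicated COPY element to each
# of the other two XORs, so the micro system has 9 elements (3 XOR, 6 COPY).
# Cij is the COPY that relays Xj's output into Xi.  The bundled black-box
# mapping conceals each XOR's two input COPYs inside its box (output = the
# XOR, two micro updates per macro update), leaving three interconnected
# macro elements that implement XOR logic.  Analysed state: all OFF.
metadata:
  name: xor_delay
  analyzed_state: all_off
nodes:
- {label: X1, gate: XOR}
- {label: C12, gate: COPY}
- {label: C13, gate: COPY}
- {label: X2, gate: XOR}
- {label: C21, gate: COPY}
- {label: C23, gate: COPY}
- {label: X3, gate: XOR}
- {label: C31, gate: COPY}
- {label: C32, gate: COPY}
edges:
- {from: C12, to: X1}
- {from: C13, to: X1}
- {from: X2, to: C12}
- {from: X3, to: C13}
- {from: C21, to: X2}
- {from: C23, to: X2}
- {from: X1, to: C21}
- {from: X3, to: C23}
- {from: C31, to: X3}
- {from: C32, to: X3}
- {from: X1, to: C31}
- {from: X2, to: C32}
state: {X1: 0, C12: 0, C13: 0, X2: 0, C21: 0, C23: 0, X3: 0, C31: 0, C32: 0}
boxes:
  B1: [X1, C12, C13]
  B2: [X2, C21, C23]
  B3: [X3, C31, C32]
outputs: {B1: X1, B2: X2, B3: X3}
timescale: 2
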