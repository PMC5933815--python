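# Boolean network model of the fission-yeast cell cycle, transcribed from
# Davidich & Bornholdt (2008), PLoS ONE 3(2):e1672: nine linear-threshold
# elements with +1 (excitatory) / -1 (inhibitory) connections.  An element
# turns ON when its weighted input sum exceeds its threshold, OFF when the
# sum falls below it, and holds its previous state at equality.  Cdc2_Cdc13
# (threshold -1/2) is active by default; Cdc2_Cdc13_star (threshold +1/2)
# is the high-activity form requiring net activation.  SK, Slp1 and PP
# carry self-degradation loops.  SK receives no input from the rest of the
# network: it acts as an external catalyst that initiates division from the
# G1 attractor, so causal analyses treat it as a background condition.
# metadata.biological_sequence lists the 9 states t1..t9 of one division
# cycle (t9 = the G1 attractor again); t2 has no cause within the 8-element
# network (it is caused by SK) and is excluded from cause-effect analysis.
metadata:
  name: cell_cycle
  node_order: [SK, Cdc2_Cdc13, Ste9, Rum1, Slp1, Cdc2_Cdc13_star, Wee1_Mik1, Cdc25, PP]
  biological_sequence:
  - [1, 0, 1, 1, 0, 0, 1, 0, 0]
  - [0, 0, 0, 0, 0, 0, 1, 0, 0]
  - [0, 1, 0, 0, 0, 0, 1, 0, 0]
  - [0, 1, 0, 0, 0, 0, 0, 1, 0]
  - [0, 1, 0, 0, 0, 1, 0, 1, 0]
  - [0, 1, 0, 0, 1, 1, 0, 1, 0]
  - [0, 0, 0, 0, 1, 0, 0, 1, 1]
  - [0, 0, 1, 1, 0, 0, 1, 0, 1]
  - [0, 0, 1, 1, 0, 0, 1, 0, 0]
  excluded_states: [1]      # index into the sequence (the second state, t2)
nodes:
- {label: SK, kind: threshold, threshold: 0.0, tie: hold}
- {label: Cdc2_Cdc13, kind: threshold, threshold: -0.5, tie: hold}
- {label: Ste9, kind: threshold, threshold: 0.0, tie: hold}
- {label: Rum1, kind: threshold, threshold: 0.0, tie: hold}
- {label: Slp1, kind: threshold, threshold: 0.0, tie: hold}
- {label: Cdc2_Cdc13_star, kind: threshold, threshold: 0.5, tie: hold}
- {label: Wee1_Mik1, kind: threshold, threshold: 0.0, tie: hold}
- {label: Cdc25, kind: threshold, threshold: 0.0, tie: hold}
- {label: PP, kind: threshold, threshold: 0.0, tie: hold}
edges:
- {from: SK, to: SK, weight: -1}
- {from: Ste9, to: Cdc2_Cdc13, weight: -1}
- {from: Rum1, to: Cdc2_Cdc13, weight: -1}
- {from: Slp1, to: Cdc2_Cdc13, weight: -1}
- {from: SK, to: Ste9, weight: -1}
- {from: Cdc2_Cdc13, to: Ste9, weight: -1}
- {from: Cdc2_Cdc13_star, to: Ste9, weight: -1}
- {from: PP, to: Ste9, weight: 1}
- {from: SK, to: Rum1, weight: -1}
- {from: Cdc2_Cdc13, to: Rum1, weight: -1}
- {from: Cdc2_Cdc13_star, to: Rum1, weight: -1}
- {from: PP, to: Rum1, weight: 1}
- {from: Cdc2_Cdc13_star, to: Slp1, weight: 1}
- {from: Slp1, to: Slp1, weight: -1}
- {from: Cdc25, to: Cdc2_Cdc13_star, weight: 1}
- {from: Ste9, to: Cdc2_Cdc13_star, weight: -1}
- {from: Rum1, to: Cdc2_Cdc13_star, weight: -1}
- {from: Slp1, to: Cdc2_Cdc13_star, weight: -1}
- {from: Wee1_Mik1, to: Cdc2_Cdc13_star, weight: -1}
- {from: Cdc2_Cdc13, to: Wee1_Mik1, weight: -1}
- {from: PP, to: Wee1_Mik1, weight: 1}
- {from: Cdc2_Cdc13, to: Cdc25, weight: 1}
- {from: PP, to: Cdc25, weight: -1}
- {from: Slp1, to: PP, weight: 1}
- {from: PP, to: PP, weight: -1}
# default state: the G1 attractor (t9); analyses typically sweep the
# biological sequence instead
state: {SK: 0, Cdc2_Cdc13: 0, Ste9: 1, Rum1: 1, Slp1: 0, Cdc2_Cdc13_star: 0,
        Wee1_Mik1: 1, Cdc25: 0, PP: 0}
background: {SK: 0}
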