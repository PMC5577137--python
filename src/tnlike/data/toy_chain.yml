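# Minimal linear chain: uptake -> conversion -> sink (objective).
name: toy_chain
metabolites: [a, b]
objective: B_SINK
reactions:
  - id: A_UP
    stoich: {a: 1}
    ub: 1
  - id: A_B
    stoich: {a: -1, b: 1}
    gpr: "E1 or E2"
  - id: B_SINK
    stoich: {b: -1}
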