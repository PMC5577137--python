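# Toy Warburg network: lumped glycolysis, glutaminolysis, lactate export,
# a GPR-capped oxidative step, precursor synthesis and a biomass sink.
# Designed so that an oxidative cap forces pyruvate overflow to lactate.
name: toy_warburg
metabolites: [glc, gln, pyr, atp, prec]
objective: BIOMASS
reactions:
  - id: GLC_UP           # glucose uptake
    stoich: {glc: 1}
    ub: 10
    gpr: "SLC2A1"
  - id: GLN_UP           # glutamine uptake
    stoich: {gln: 1}
    ub: 10
    gpr: "SLC1A5"
  - id: GLYC             # lumped glycolysis: glc -> 2 pyr + 2 atp
    stoich: {glc: -1, pyr: 2, atp: 2}
    gpr: "HK1 and GAPDH and PKM"
  - id: GLNPYR           # glutaminolysis to pyruvate: gln -> pyr + atp
    stoich: {gln: -1, pyr: 1, atp: 1}
    gpr: "GLS and GLUD1"
  - id: PYR_OX           # lumped pyruvate oxidation (TCA + oxphos)
    stoich: {pyr: -1, atp: 10, prec: 1}
    gpr: "PDHA1 and SDHA and NDUFA1"
  - id: LDH_SEC          # lactate dehydrogenase + export
    stoich: {pyr: -1}
    gpr: "LDHA or LDHB"
  - id: PREC_SYN         # biosynthetic precursors from glucose
    stoich: {glc: -1, atp: -2, prec: 2}
    gpr: "G6PD"
  - id: ATPM             # non-growth ATP maintenance; its highly expressed
    stoich: {atp: -1}    # housekeeping GPR anchors the per-tumour maximum
    gpr: "ACTB"
  - id: BIOMASS          # growth objective
    stoich: {prec: -2, atp: -6}
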