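# Entner-Doudoroff glycolysis of Zymomonas mobilis, carbon atom transitions.
# Glucose uptake -> ED pathway -> pyruvate decarboxylase/alcohol dehydrogenase
# ethanol fermentation.  Positions are 1-based biochemical carbon numbers
# (glucose C1..C6).  Reduced-cofactor hydrides are pooled in a single
# well-mixed carrier species (REDH) that carries no carbon.
#
# An optional triose-phosphate isomerase dead-end (GAP <-> DHAP) can be
# enabled by uncommenting the DHAP metabolite and TPI reaction below.
element: C

metabolites:
  - {name: GLC.ext, formula: C6H12O6,  traced: [C1, C2, C3, C4, C5, C6], role: substrate_input}
  - {name: GLC,     formula: C6H12O6,  traced: [C1, C2, C3, C4, C5, C6]}
  - {name: G6P,     formula: C6H13O9P, traced: [C1, C2, C3, C4, C5, C6]}
  - {name: PGL6,    formula: C6H9O9P,  traced: [C1, C2, C3, C4, C5, C6]}
  - {name: P6G,     formula: C6H13O10P, traced: [C1, C2, C3, C4, C5, C6]}
  - {name: KDPG,    formula: C6H9O9P,  traced: [C1, C2, C3, C4, C5, C6]}
  - {name: GAP,     formula: C3H7O6P,  traced: [C1, C2, C3]}
  - {name: BPG,     formula: C3H8O10P2, traced: [C1, C2, C3]}
  - {name: PG3,     formula: C3H7O7P,  traced: [C1, C2, C3]}
  - {name: PG2,     formula: C3H7O7P,  traced: [C1, C2, C3]}
  - {name: PEP,     formula: C3H5O6P,  traced: [C1, C2, C3]}
  - {name: PYR,     formula: C3H4O3,   traced: [C1, C2, C3]}
  - {name: ACA,     formula: C2H4O,    traced: [C1, C2]}
  - {name: ETOH,    formula: C2H6O,    traced: [C1, C2]}
  - {name: ETOH.ext, formula: C2H6O,   traced: [C1, C2], role: sink_output}
  - {name: CO2,     formula: CO2,      traced: [C1], role: free_exchange}
  - {name: REDH,    formula: H,        traced: [], role: carrier_pool}
  # - {name: DHAP,  formula: C3H7O6P,  traced: [C1, C2, C3]}

reactions:
  - {id: GLCup, equation: "GLC.ext (abcdef) -> GLC (abcdef)"}
  - {id: GLK,   equation: "GLC (abcdef) -> G6P (abcdef)"}
  - {id: ZWF,   equation: "G6P (abcdef) -> PGL6 (abcdef) + REDH"}
  - {id: PGL,   equation: "PGL6 (abcdef) -> P6G (abcdef)"}
  - {id: EDD,   equation: "P6G (abcdef) -> KDPG (abcdef)"}
  - {id: EDA,   equation: "KDPG (abcdef) -> PYR (abc) + GAP (def)", reversible: true}
  - {id: GAPDH, equation: "GAP (abc) -> BPG (abc) + REDH", reversible: true}
  - {id: PGK,   equation: "BPG (abc) -> PG3 (abc)", reversible: true}
  - {id: PGM,   equation: "PG3 (abc) -> PG2 (abc)", reversible: true}
  - {id: ENO,   equation: "PG2 (abc) -> PEP (abc)", reversible: true}
  - {id: PYK,   equation: "PEP (abc) -> PYR (abc)"}
  - {id: PDC,   equation: "PYR (abc) -> ACA (bc) + CO2 (a)"}
  - {id: ADH,   equation: "ACA (ab) + REDH -> ETOH (ab)"}
  - {id: ETOHout, equation: "ETOH (ab) -> ETOH.ext (ab)"}
  # - {id: TPI, equation: "GAP (abc) -> DHAP (abc)", reversible: true}

inputs:
  - metabolite: GLC.ext
    labeled_fraction_free: true
    components:
      - {positions: [C1], fraction: 0.99}
      - {positions: [],   fraction: 0.01}

rates:
  - {reaction: GLCup,   value: 100.0, sd: 5.0}
  - {reaction: ETOHout, value: 200.0, sd: 10.0}

observations: [G6P, P6G, KDPG, GAP, PG3, PEP, PYR]

options:
  carriers_unlabeled: false
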