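# Entner-Doudoroff glycolysis of Zymomonas mobilis, hydrogen atom transitions.
# Same reactions, stoichiometry and rates as the carbon file; the traced
# element is the carbon-bound hydrogen at each biochemical position
# (H4 = the hydrogen riding glucose C4).  Key transitions:
#   ZWF transfers the G6P C1 hydride to the pooled NAD(P)H carrier (REDH);
#   EDD dehydration routes the C2/C3 hydrogens to solvent water;
#   EDA retains the KDPG C4-H on GAP C1;
#   GAPDH transfers the GAP C1 hydride to REDH, and the backward direction
#     redraws a hydride from the well-mixed pool;
#   ENO loses the C2-H to water forward and draws a (naturally labeled)
#     water hydrogen on the backward direction;
#   PYK's new methyl proton comes from solvent, and the PEP C3-H, which no
#     shipped tracer can label, is routed to the solvent sink.
# Water always enters with natural deuterium abundance.
element: H

metabolites:
  - {name: GLC.ext, formula: C6H12O6,  traced: [H1, H2, H3, H4, H5, H6], role: substrate_input}
  - {name: GLC,     formula: C6H12O6,  traced: [H1, H2, H3, H4, H5, H6]}
  - {name: G6P,     formula: C6H13O9P, traced: [H1, H2, H3, H4, H5, H6]}
  - {name: PGL6,    formula: C6H9O9P,  traced: [H2, H3, H4, H5, H6]}
  - {name: P6G,     formula: C6H13O10P, traced: [H2, H3, H4, H5, H6]}
  - {name: KDPG,    formula: C6H9O9P,  traced: [H4, H5, H6]}
  - {name: GAP,     formula: C3H7O6P,  traced: [H1, H2, H3]}
  - {name: BPG,     formula: C3H8O10P2, traced: [H2, H3]}
  - {name: PG3,     formula: C3H7O7P,  traced: [H2, H3]}
  - {name: PG2,     formula: C3H7O7P,  traced: [H2, H3]}
  - {name: PEP,     formula: C3H5O6P,  traced: [H3]}
  - {name: PYR,     formula: C3H4O3,   traced: []}
  - {name: ACA,     formula: C2H4O,    traced: []}
  - {name: ETOH,    formula: C2H6O,    traced: [H1]}
  - {name: ETOH.ext, formula: C2H6O,   traced: [H1], role: sink_output}
  - {name: CO2,     formula: CO2,      traced: [], role: free_exchange}
  - {name: WATER,   formula: H2O,      traced: [H1], role: free_exchange}
  - {name: REDH,    formula: H,        traced: [H1], role: carrier_pool}

reactions:
  - {id: GLCup, equation: "GLC.ext (abcdef) -> GLC (abcdef)"}
  - {id: GLK,   equation: "GLC (abcdef) -> G6P (abcdef)"}
  - {id: ZWF,   equation: "G6P (abcdef) -> PGL6 (bcdef) + REDH (a)"}
  - {id: PGL,   equation: "PGL6 (abcde) -> P6G (abcde)"}
  - {id: EDD,   equation: "P6G (abcde) -> KDPG (cde) + WATER (a) + WATER (b)"}
  - {id: EDA,   equation: "KDPG (abc) -> PYR + GAP (abc)", reversible: true}
  - {id: GAPDH, equation: "GAP (abc) -> BPG (bc) + REDH (a)", reversible: true}
  - {id: PGK,   equation: "BPG (ab) -> PG3 (ab)", reversible: true}
  - {id: PGM,   equation: "PG3 (ab) -> PG2 (ab)", reversible: true}
  - {id: ENO,   equation: "PG2 (ab) -> PEP (b) + WATER (a)", reversible: true}
  - {id: PYK,   equation: "PEP (a) -> PYR + WATER (a)"}
  - {id: PDC,   equation: "PYR -> ACA + CO2"}
  - {id: ADH,   equation: "ACA + REDH (a) -> ETOH (a)"}
  - {id: ETOHout, equation: "ETOH (a) -> ETOH.ext (a)"}

inputs:
  - metabolite: GLC.ext
    labeled_fraction_free: true
    components:
      - {positions: [H4], fraction: 0.99}
      - {positions: [],   fraction: 0.01}

rates:
  - {reaction: GLCup,   value: 100.0, sd: 5.0}
  - {reaction: ETOHout, value: 200.0, sd: 10.0}

observations: [G6P, KDPG, GAP, BPG, PG3, PG2, PEP]

options:
  carriers_unlabeled: false
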