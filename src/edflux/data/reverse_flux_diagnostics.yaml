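# Reverse-flux labeling diagnostics for ED glycolysis.
# Each entry designates the mass bins of a metabolite whose population,
# under the named glucose tracer, requires backward flux through the
# pathway (or is strongly enriched by it):
#   KDPG M+2 under [6-13C]: forward KDPG is at most M+1; M+2 needs
#     KDPG aldolase running backward, condensing a labeled pyruvate
#     (via pyruvate kinase) with labeled GAP.
#   3PG M+0 under [5-2H]: forward 3PG retains the C2 deuteron; losing
#     it requires backward enolase (which installs an unlabeled water
#     hydrogen) followed by backward phosphoglycerate mutase.
#   GAP M+0 under [4-2H]: forward GAP carries the C1 deuteron from
#     glucose C4; exchange through GAPDH replaces it with a hydride
#     drawn from the diluted NAD(P)H carrier pool.
# These encodings are provisional schematics and are shipped as data so
# they can be audited and replaced.
diagnostics:
  - {metabolite: KDPG, tracer: "6-13C", element: C, bins: [2]}
  - {metabolite: PG3,  tracer: "5-2H",  element: H, bins: [0]}
  - {metabolite: GAP,  tracer: "4-2H",  element: H, bins: [0]}
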