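# Default 13-scenario weighting grid for the motif ranking score.
# w1 weights the halved topological pair (degree + betweenness), w2 the
# disease-pathway count, w3 the gene-prioritization score, w4 the mean
# |log2FC|. Block structure: uniform; single-property emphasis; single
# property only; pairwise emphasis (adjacent weight pairs doubled).
scenarios:
  - {id: s01, w1: 1, w2: 1, w3: 1, w4: 1}
  - {id: s02, w1: 2, w2: 1, w3: 1, w4: 1}
  - {id: s03, w1: 1, w2: 2, w3: 1, w4: 1}
  - {id: s04, w1: 1, w2: 1, w3: 2, w4: 1}
  - {id: s05, w1: 1, w2: 1, w3: 1, w4: 2}
  - {id: s06, w1: 1, w2: 0, w3: 0, w4: 0}
  - {id: s07, w1: 0, w2: 1, w3: 0, w4: 0}
  - {id: s08, w1: 0, w2: 0, w3: 1, w4: 0}
  - {id: s09, w1: 0, w2: 0, w3: 0, w4: 1}
  - {id: s10, w1: 2, w2: 2, w3: 1, w4: 1}
  - {id: s11, w1: 1, w2: 2, w3: 2, w4: 1}
  - {id: s12, w1: 1, w2: 1, w3: 2, w4: 2}
  - {id: s13, w1: 2, w2: 1, w3: 1, w4: 2}
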