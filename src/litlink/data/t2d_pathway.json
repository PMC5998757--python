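{
  "entities": [
    {"id": "ADIPO", "type": "gene"},
    {"id": "GLUT4", "type": "gene"},
    {"id": "INS", "type": "gene"},
    {"id": "INSR", "type": "gene"},
    {"id": "IRS1", "type": "gene", "canonical": "IRS1/IRS"},
    {"id": "IRS", "type": "gene", "canonical": "IRS1/IRS"},
    {"id": "PI3K", "type": "gene"},
    {"id": "SOCS", "type": "gene"},
    {"id": "ERK", "type": "gene", "canonical": "ERK1/2"},
    {"id": "TNF-alpha", "type": "gene", "canonical": "TNFA"},
    {"id": "IKK", "type": "gene"},
    {"id": "JNK", "type": "gene"},
    {"id": "mTOR", "type": "gene"},
    {"id": "PRKCZ", "type": "gene", "canonical": "PKCZ"},
    {"id": "PKCD/E", "type": "gene"},
    {"id": "Obesity", "type": "disease"},
    {"id": "Transient hyperglycemia", "type": "disease"},
    {"id": "Type 2 diabetes mellitus", "type": "disease"},
    {"id": "FFA", "type": "molecular_function"}
  ],
  "edges": [
    {"source": "ADIPO", "target": "GLUT4", "interaction": "indirect", "directed": true, "participating_pathway": "Adipocytokine signaling pathway"},
    {"source": "INS", "target": "INSR", "interaction": "direct", "directed": true, "participating_pathway": null},
    {"source": "INSR", "target": "IRS1/IRS", "interaction": "direct", "directed": true, "participating_pathway": null},
    {"source": "IRS1/IRS", "target": "PI3K", "interaction": "direct", "directed": true, "participating_pathway": null},
    {"source": "INSR", "target": "SOCS", "interaction": "direct", "directed": true, "participating_pathway": null},
    {"source": "SOCS", "target": "IRS1/IRS", "interaction": "direct", "directed": true, "participating_pathway": null},
    {"source": "INSR", "target": "ERK1/2", "interaction": "indirect", "directed": true, "participating_pathway": "Insulin signaling pathway"},
    {"source": "ERK1/2", "target": "IRS1/IRS", "interaction": "indirect", "directed": true, "participating_pathway": "Insulin signaling pathway"},
    {"source": "PI3K", "target": "GLUT4", "interaction": "indirect", "directed": true, "participating_pathway": "Insulin signaling pathway"},
    {"source": "PI3K", "target": "mTOR", "interaction": "indirect", "directed": true, "participating_pathway": "Insulin signaling pathway"},
    {"source": "PI3K", "target": "PKCZ", "interaction": "indirect", "directed": true, "participating_pathway": "Insulin signaling pathway"},
    {"source": "TNFA", "target": "IKK", "interaction": "indirect", "directed": true, "participating_pathway": "Adipocytokine signaling pathway"},
    {"source": "TNFA", "target": "JNK", "interaction": "indirect", "directed": true, "participating_pathway": "Adipocytokine signaling pathway"},
    {"source": "TNFA", "target": "mTOR", "interaction": "indirect", "directed": true, "participating_pathway": "Adipocytokine signaling pathway"},
    {"source": "IKK", "target": "IRS1/IRS", "interaction": "direct", "directed": true, "participating_pathway": null},
    {"source": "JNK", "target": "IRS1/IRS", "interaction": "direct", "directed": true, "participating_pathway": null},
    {"source": "PKCZ", "target": "IRS1/IRS", "interaction": "direct", "directed": true, "participating_pathway": null},
    {"source": "PKCD/E", "target": "IRS1/IRS", "interaction": "direct", "directed": true, "participating_pathway": null}
  ],
  "expansions": [
    {"edge_ref": 0, "chain": ["ADIPO", "ADIPOR", "AMPKK", "AMPK", "GLUT4"], "undirected_steps": [1, 3]},
    {"edge_ref": 6, "chain": ["INSR", "SHC", "GRB2", "SOS", "Ras", "Raf", "MEK1/2", "ERK1/2"]},
    {"edge_ref": 7, "chain": ["IRS1/IRS", "GRB2", "SOS", "Ras", "Raf", "MEK1/2", "ERK1/2"]},
    {"edge_ref": 8, "chain": ["PI3K", "PDK1/2", "AKT", "GLUT4"]},
    {"edge_ref": 8, "chain": ["PI3K", "PDK1/2", "PKCZ", "GLUT4"]},
    {"edge_ref": 9, "chain": ["PI3K", "PDK1/2", "AKT", "mTOR"]},
    {"edge_ref": 10, "chain": ["PI3K", "PDK1/2", "PKCZ"]},
    {"edge_ref": 11, "chain": ["TNFA", "TNFR1", "TRADD", "TNFR2", "TRAF2", "IKK"], "undirected_steps": [4]},
    {"edge_ref": 11, "chain": ["TNFA", "TNFR2", "TRAF2", "IKK"], "undirected_steps": [2]},
    {"edge_ref": 12, "chain": ["TNFA", "TNFR1", "TRADD", "TNFR2", "TRAF2", "JNK"], "undirected_steps": [4]},
    {"edge_ref": 13, "chain": ["TNFA", "TNFR1", "TRADD", "TNFR2", "TRAF2", "mTOR"], "undirected_steps": [4]}
  ]
}
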