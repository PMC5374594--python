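{
  "name": "CRPC signaling network, combinational Boolean model",
  "inputs": ["EGF", "HBEGF", "IGF", "NRG1", "PTEN", "NKX3_1", "Androgens"],
  "outputs": ["SP1", "SRF_ELK1", "PSA", "TMPRSS2", "BCL2", "CDK2_CYCLINE"],
  "gates": [
    {"id": "EGFR", "kind": "BUF", "inputs": ["EGF"]},
    {"id": "HER2", "kind": "BUF", "inputs": ["HBEGF"]},
    {"id": "IGF1R", "kind": "BUF", "inputs": ["IGF"]},
    {"id": "HER3", "kind": "BUF", "inputs": ["NRG1"]},
    {"id": "GRB2_SOS", "kind": "OR", "inputs": ["EGFR", "HER2", "IGF1R", "HER3"]},
    {"id": "RAS", "kind": "BUF", "inputs": ["GRB2_SOS"]},
    {"id": "IRS1", "kind": "BUF", "inputs": ["IGF1R"]},
    {"id": "PI3K", "kind": "OR", "inputs": ["RAS", "IRS1"]},
    {"id": "RAF", "kind": "OR", "inputs": ["RAS", "PI3K"]},
    {"id": "MEK", "kind": "BUF", "inputs": ["RAF"]},
    {"id": "ERK", "kind": "BUF", "inputs": ["MEK"]},
    {"id": "PIP3", "kind": "NOT", "inputs": ["PTEN"]},
    {"id": "PDK1", "kind": "BUF", "inputs": ["PIP3"]},
    {"id": "AKT", "kind": "OR", "inputs": ["PDK1", "NKX3_1"], "inverted_inputs": [1]},
    {"id": "AR", "kind": "OR", "inputs": ["Androgens", "AKT"]},
    {"id": "TSC", "kind": "NOR", "inputs": ["AKT", "PI3K"]},
    {"id": "RHEB", "kind": "NOT", "inputs": ["TSC"]},
    {"id": "MTOR", "kind": "BUF", "inputs": ["RHEB"]},
    {"id": "S6K", "kind": "BUF", "inputs": ["MTOR"]},
    {"id": "FOUR_EBP1", "kind": "NOT", "inputs": ["MTOR"]},
    {"id": "EIF4E", "kind": "NOT", "inputs": ["FOUR_EBP1"]},
    {"id": "BAD", "kind": "NOT", "inputs": ["AKT"]},
    {"id": "SP1", "kind": "BUF", "inputs": ["ERK"]},
    {"id": "SRF_ELK1", "kind": "BUF", "inputs": ["ERK"]},
    {"id": "PSA", "kind": "BUF", "inputs": ["AR"]},
    {"id": "TMPRSS2", "kind": "BUF", "inputs": ["AR"]},
    {"id": "BCL2", "kind": "NOT", "inputs": ["BAD"]},
    {"id": "CDK2_CYCLINE", "kind": "OR", "inputs": ["S6K", "EIF4E", "PI3K"]}
  ],
  "fault_sites": [
    {"label": 1, "line": "EGFR", "stuck": 1, "position": "pre_drug"},
    {"label": 2, "line": "HER2", "stuck": 1, "position": "pre_drug"},
    {"label": 3, "line": "IGF1R", "stuck": 1, "position": "pre_drug"},
    {"label": 4, "line": "HER3", "stuck": 1, "position": "pre_drug"},
    {"label": 5, "line": "GRB2_SOS", "stuck": 1, "position": "pre_drug"},
    {"label": 6, "line": "RAS", "stuck": 1, "position": "pre_drug"},
    {"label": 7, "line": "PTEN", "stuck": 0, "position": "pre_drug"},
    {"label": 8, "line": "PI3K", "stuck": 1, "position": "pre_drug"},
    {"label": 9, "line": "IRS1", "stuck": 1, "position": "pre_drug"},
    {"label": 10, "line": "PIP3", "stuck": 1, "position": "pre_drug"},
    {"label": 11, "line": "PDK1", "stuck": 1, "position": "pre_drug"},
    {"label": 12, "line": "NKX3_1", "stuck": 0, "position": "pre_drug"},
    {"label": 13, "line": "AKT", "stuck": 1, "position": "pre_drug"},
    {"label": 14, "line": "Androgens", "stuck": 1, "position": "pre_drug"},
    {"label": 15, "line": "AR", "stuck": 1, "position": "pre_drug"},
    {"label": 16, "line": "RAF", "stuck": 1, "position": "pre_drug"},
    {"label": 17, "line": "MEK", "stuck": 1, "position": "pre_drug"},
    {"label": 18, "line": "MEK", "stuck": 1, "position": "post_drug"},
    {"label": 19, "line": "TSC", "stuck": 0, "position": "pre_drug"},
    {"label": 20, "line": "RHEB", "stuck": 1, "position": "pre_drug"},
    {"label": 21, "line": "MTOR", "stuck": 1, "position": "pre_drug"},
    {"label": 22, "line": "S6K", "stuck": 1, "position": "pre_drug"},
    {"label": 23, "line": "FOUR_EBP1", "stuck": 0, "position": "pre_drug"},
    {"label": 24, "line": "BAD", "stuck": 0, "position": "pre_drug"}
  ],
  "drugs": [
    {"index": 0, "name": "Lapatinib", "target": "EGFR"},
    {"index": 0, "name": "Lapatinib", "target": "HER2"},
    {"index": 0, "name": "Lapatinib", "target": "HER3"},
    {"index": 1, "name": "Cixutumumab", "target": "IGF1R"},
    {"index": 2, "name": "AZD6244", "target": "MEK"},
    {"index": 3, "name": "BKM120", "target": "PI3K"},
    {"index": 4, "name": "AZD5363", "target": "AKT"},
    {"index": 5, "name": "Temsirolimus", "target": "MTOR"},
    {"index": 6, "name": "Enzalutamide", "target": "AR"}
  ]
}
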