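{
  "nets": [
    {
      "id": "EGF",
      "label": "EGF",
      "kind": "input"
    },
    {
      "id": "TGA",
      "label": "TGA",
      "kind": "input"
    },
    {
      "id": "EML4-ALK",
      "label": "EML4-ALK",
      "kind": "input"
    },
    {
      "id": "p16",
      "label": "p16",
      "kind": "input"
    },
    {
      "id": "PTEN",
      "label": "PTEN",
      "kind": "input"
    },
    {
      "id": "CCND1",
      "label": "CCND1",
      "kind": "output"
    },
    {
      "id": "E2F",
      "label": "E2F",
      "kind": "output"
    },
    {
      "id": "MST1",
      "label": "MST1",
      "kind": "output"
    },
    {
      "id": "STAT3/5",
      "label": "STAT3/5",
      "kind": "output"
    },
    {
      "id": "BAD",
      "label": "BAD",
      "kind": "output"
    },
    {
      "id": "CASP9",
      "label": "CASP9",
      "kind": "output"
    },
    {
      "id": "FORKHEAD",
      "label": "FORKHEAD",
      "kind": "output"
    },
    {
      "id": "EGFR",
      "label": "EGFR",
      "kind": "internal"
    },
    {
      "id": "ERBB2",
      "label": "ERBB2",
      "kind": "internal"
    },
    {
      "id": "GRB2",
      "label": "GRB2",
      "kind": "internal"
    },
    {
      "id": "SOS",
      "label": "SOS",
      "kind": "internal"
    },
    {
      "id": "KRAS",
      "label": "KRAS",
      "kind": "internal"
    },
    {
      "id": "RASSF1",
      "label": "RASSF1",
      "kind": "internal"
    },
    {
      "id": "PLCG",
      "label": "PLCG",
      "kind": "internal"
    },
    {
      "id": "PKC",
      "label": "PKC",
      "kind": "internal"
    },
    {
      "id": "JAK3",
      "label": "JAK3",
      "kind": "internal"
    },
    {
      "id": "PI3K",
      "label": "PI3K",
      "kind": "internal"
    },
    {
      "id": "BRAF",
      "label": "BRAF",
      "kind": "internal"
    },
    {
      "id": "MEK",
      "label": "MEK",
      "kind": "internal"
    },
    {
      "id": "ERK",
      "label": "ERK",
      "kind": "internal"
    },
    {
      "id": "PTEN~not",
      "label": "PTEN~not",
      "kind": "internal"
    },
    {
      "id": "AKT",
      "label": "AKT",
      "kind": "internal"
    },
    {
      "id": "CDK4/6",
      "label": "CDK4/6",
      "kind": "internal"
    }
  ],
  "gates": [
    {
      "op": "OR",
      "inputs": [
        "EGF",
        "TGA"
      ],
      "output": "EGFR"
    },
    {
      "op": "OR",
      "inputs": [
        "EGF",
        "TGA"
      ],
      "output": "ERBB2"
    },
    {
      "op": "BUF",
      "inputs": [
        "EGFR"
      ],
      "output": "GRB2"
    },
    {
      "op": "BUF",
      "inputs": [
        "GRB2"
      ],
      "output": "SOS"
    },
    {
      "op": "OR",
      "inputs": [
        "SOS",
        "EML4-ALK"
      ],
      "output": "KRAS"
    },
    {
      "op": "BUF",
      "inputs": [
        "KRAS"
      ],
      "output": "RASSF1"
    },
    {
      "op": "BUF",
      "inputs": [
        "RASSF1"
      ],
      "output": "MST1"
    },
    {
      "op": "BUF",
      "inputs": [
        "EGFR"
      ],
      "output": "PLCG"
    },
    {
      "op": "BUF",
      "inputs": [
        "PLCG"
      ],
      "output": "PKC"
    },
    {
      "op": "BUF",
      "inputs": [
        "EML4-ALK"
      ],
      "output": "JAK3"
    },
    {
      "op": "BUF",
      "inputs": [
        "JAK3"
      ],
      "output": "STAT3/5"
    },
    {
      "op": "OR",
      "inputs": [
        "ERBB2",
        "EML4-ALK",
        "KRAS"
      ],
      "output": "PI3K"
    },
    {
      "op": "OR",
      "inputs": [
        "KRAS",
        "ERBB2",
        "PI3K"
      ],
      "output": "BRAF"
    },
    {
      "op": "BUF",
      "inputs": [
        "BRAF"
      ],
      "output": "MEK"
    },
    {
      "op": "BUF",
      "inputs": [
        "MEK"
      ],
      "output": "ERK"
    },
    {
      "op": "BUF",
      "inputs": [
        "ERK"
      ],
      "output": "CCND1"
    },
    {
      "op": "NOT",
      "inputs": [
        "PTEN"
      ],
      "output": "PTEN~not"
    },
    {
      "op": "OR",
      "inputs": [
        "PI3K",
        "PTEN~not"
      ],
      "output": "AKT"
    },
    {
      "op": "NOT",
      "inputs": [
        "AKT"
      ],
      "output": "BAD"
    },
    {
      "op": "NOT",
      "inputs": [
        "AKT"
      ],
      "output": "CASP9"
    },
    {
      "op": "NOT",
      "inputs": [
        "AKT"
      ],
      "output": "FORKHEAD"
    },
    {
      "op": "NOT",
      "inputs": [
        "p16"
      ],
      "output": "CDK4/6"
    },
    {
      "op": "AND",
      "inputs": [
        "CCND1",
        "CDK4/6"
      ],
      "output": "E2F"
    }
  ],
  "input_order": [
    "EGF",
    "TGA",
    "EML4-ALK",
    "p16",
    "PTEN"
  ],
  "output_order": [
    "CCND1",
    "E2F",
    "MST1",
    "STAT3/5",
    "BAD",
    "CASP9",
    "FORKHEAD"
  ],
  "constants": {},
  "roles": {
    "EGF": "growth_factor",
    "TGA": "growth_factor",
    "EML4-ALK": "growth_factor",
    "p16": "tumor_suppressor",
    "PTEN": "tumor_suppressor",
    "CCND1": "proliferative_output",
    "E2F": "proliferative_output",
    "MST1": "proliferative_output",
    "STAT3/5": "proliferative_output",
    "BAD": "pro_apoptotic_output",
    "CASP9": "pro_apoptotic_output",
    "FORKHEAD": "pro_apoptotic_output"
  },
  "meta": {
    "notes": [
      "wiring transcribed from the published NSCLC circuit schematic; ambiguities pinned by the published score tables",
      "PTEN inhibition enters AKT as OR(PI3K, NOT PTEN): loss of the suppressor alone activates AKT (release semantics), as the published PTEN stuck-at-0 output vector [0000000] requires",
      "PLCG->PKC branch is a dead end kept so PKC-targeting miRNAs are mapped; it matches the published tables where PKC inhibition is inert"
    ],
    "case": "nsclc"
  }
}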