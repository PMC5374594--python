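{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "oncocircuit combinational netlist",
  "description": "Formal description of the JSON netlist dialect accepted by oncocircuit.load_circuit. The loader enforces these constraints (plus structural ones: acyclicity, reference resolution, contiguous fault labels) with built-in validation.",
  "type": "object",
  "required": ["name", "inputs", "outputs", "gates"],
  "properties": {
    "name": {"type": "string"},
    "inputs": {
      "type": "array",
      "items": {"type": "string"},
      "uniqueItems": true,
      "minItems": 1
    },
    "outputs": {
      "type": "array",
      "items": {"type": "string"},
      "uniqueItems": true,
      "minItems": 1
    },
    "gates": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "kind", "inputs"],
        "properties": {
          "id": {"type": "string"},
          "kind": {"enum": ["AND", "OR", "NOT", "NAND", "NOR", "XOR", "BUF"]},
          "inputs": {"type": "array", "items": {"type": "string"}, "minItems": 1},
          "inverted_inputs": {
            "type": "array",
            "items": {"type": "integer", "minimum": 0},
            "uniqueItems": true
          }
        }
      }
    },
    "fault_sites": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["label", "line", "stuck"],
        "properties": {
          "label": {"type": "integer", "minimum": 1},
          "line": {"type": "string"},
          "stuck": {"enum": [0, 1]},
          "position": {"enum": ["pre_drug", "post_drug"]}
        }
      }
    },
    "drugs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["index", "name", "target"],
        "properties": {
          "index": {"type": "integer", "minimum": 0, "maximum": 6},
          "name": {"type": "string"},
          "target": {"type": "string"}
        }
      }
    }
  }
}
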