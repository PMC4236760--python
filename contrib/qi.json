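{
  "nodes": ["y", "s", "z", "r"],
  "edges": [
    {"from": "y", "polarity": "high", "to": "s", "mode": "activate", "rates": [1.0, 1.0]},
    {"from": "s", "polarity": "high", "to": "y", "mode": "activate", "rates": [1.0, 1.0]},
    {"from": "z", "polarity": "high", "to": "r", "mode": "activate", "rates": [1.0, 1.0]},
    {"from": "r", "polarity": "high", "to": "z", "mode": "activate", "rates": [1.0, 1.0]},
    {"from": "y", "polarity": "high", "to": "z", "mode": "inhibit", "rates": [1.0, 1.0]},
    {"from": "z", "polarity": "high", "to": "s", "mode": "inhibit", "rates": [1.0, 1.0]},
    {"from": "s", "polarity": "high", "to": "r", "mode": "inhibit", "rates": [1.0, 1.0]},
    {"from": "r", "polarity": "high", "to": "y", "mode": "inhibit", "rates": [1.0, 1.0]}
  ]
}
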