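{
  "c_tot": 0.5,
  "coupling_mode": "uncoupled",
  "kinetics": {
    "delta": 1.0,
    "gamma1": 100.0,
    "gamma2": 10.0
  },
  "n_inputs": 2,
  "nodes": [
    {
      "id": "node1",
      "layer": 1,
      "weights": {
        "x1": {
          "sign": "+",
          "w": 1.0
        },
        "x2": {
          "sign": "-",
          "w": 1.0
        }
      }
    }
  ]
}
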