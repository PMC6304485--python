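{
  "b_values": [0, 25, 50, 75, 100, 150, 200, 400, 600, 800, 1000],
  "echo_times_ms": [3.4, 9.3, 15.2, 21.2, 27.1, 33.0, 38.9, 44.8, 50.7,
                    56.6, 62.5, 68.5, 74.4, 80.3, 86.2, 92.1],
  "SI0": 1000.0
}
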