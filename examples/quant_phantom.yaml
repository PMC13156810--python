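# Measurement-friendly phantom geometry: fine in-plane grid and branches
# long enough to carry a healthy distal reference segment.
phantom:
  grid_shape: [112, 128, 128]
  spacing: [0.5, 0.35, 0.35]
  segment_length: 24.0
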