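{
  "name": "strong_enhancer",
  "comment": "Multi-histone-mark strong-enhancer shape: H3K4me1 and H3K27ac required, H3K4me2 optional, H3K4me3 excluded nearby. Center offsets are illustrative fixture values, not measured claims.",
  "params": {"max_results": 2000, "min_score": 0.0},
  "tracks": [
    {"name": "H3K4me1", "target": "H3K4me1", "type": "perfect", "centers": [0]},
    {"name": "H3K27ac", "target": "H3K27ac", "type": "perfect", "centers": [300]},
    {"name": "H3K4me2", "target": "H3K4me2", "type": "partial", "centers": [600]},
    {"name": "H3K4me3", "target": "H3K4me3", "type": "negative", "negative_distance": 1000}
  ]
}
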