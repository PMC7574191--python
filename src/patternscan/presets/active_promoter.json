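{
  "name": "active_promoter",
  "comment": "Multi-histone-mark active-promoter shape: H3K4me3 required near the TSS, acetylation marks optional. Center offsets are illustrative fixture values, not measured claims.",
  "params": {"max_results": 2000, "min_score": 0.0},
  "tracks": [
    {"name": "H3K4me3", "target": "H3K4me3", "type": "perfect", "centers": [0]},
    {"name": "H3K9ac", "target": "H3K9ac", "type": "partial", "centers": [200]},
    {"name": "H3K27ac", "target": "H3K27ac", "type": "partial", "centers": [450]},
    {"name": "TSS", "target": "TSS", "type": "valid_area"}
  ]
}
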