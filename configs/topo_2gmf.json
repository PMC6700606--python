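{"loop_residues": [88, 96, 105, 113, 121], "tail_residues": [43, 48, 53], "tail_split_index": 1, "native_signature": [[0, 1], [1, -1]], "switch_width": 0.2}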