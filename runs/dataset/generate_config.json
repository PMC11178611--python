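{"blob_radius_range": [9, 3], "dropout_rate": 0.0, "method": "xrelevancecam", "out_dir": "runs", "seed": 0, "stages": ["layer1", "layer2", "layer3", "layer4"], "threshold_fraction": 0.2}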