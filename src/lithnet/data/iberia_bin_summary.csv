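bin,n_types,n_sample
8600-8401,14,107
8400-8201,14,226
8200-8001,13,170
8000-7801,24,449
7800-7601,21,417
7600-7401,26,77
7400-7201,26,117
7200-7001,22,79
7000-6801,17,30
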