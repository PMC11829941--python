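# Carcinoma subtyping preset (S=256)
S: 256
h: 768
k: 4
d: 1280
encoder_layers: 12
encoder_heads: 12
encoder_ffn_width: 3072
num_classes: 2
backbone: scratch-random
trainability_policy: normalization-only
pos_seq: true
pos_wsi: false
seed: 0
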