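# quiescent growth, driver-independent invasion, small sanctuary (R=20)
b: 0.7
s: 0.1
mu: 0.001
d1: 0.1
d2: 0.69
R: 20
detection_radius: 90
max_voxels: 60000
growth_variant: quiescent
selection_variant: birth
seed: 0
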