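# proliferative growth, driver-dependent invasion, large sanctuary (R=60)
b: 0.7
s: 0.1
mu: 0.001
d1: 0.1
d2: 0.9
R: 60
detection_radius: 90
max_voxels: 60000
growth_variant: proliferative
selection_variant: birth
seed: 0
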