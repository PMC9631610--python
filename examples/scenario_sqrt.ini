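# GC-process scenario: growing perturbations c(t) = sqrt(t)/2
[run]
a = -2
b = 1
F0 = 0.5
T = 1
n_steps = 1000
n_paths = 5
seed = 1
method = em

[schedule]
kind = sqrt
coefficient = 0.5
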