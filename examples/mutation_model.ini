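# Stochastic Luria-Delbruck scenario: moderate noise amplitude
[run]
P0 = 1
mu = 5
k = 1
p = 0.5
T = 1
n_steps = 1000
n_paths = 5
seed = 1
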