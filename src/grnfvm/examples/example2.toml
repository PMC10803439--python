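# Mutual activation of two genes (symmetric toggle with activating Hill
# cross-regulation).  The domain lengths are not part of the published
# parameter set; L = 400 is a few multiples of the unregulated protein scale
# (km/gamma) * b = 153.
name = "example2"

[model]
n = 2
km = [3.4e-3, 3.4e-3]
burst = [18.0, 18.0]

[[model.regulation]]
form = "hill_univariate"
regulator = 2
K = 70.0
H = -4.0
eps = 0.2

[[model.regulation]]
form = "hill_univariate"
regulator = 1
K = 70.0
H = -4.0
eps = 0.2

[[model.degradation]]
form = "constant"
rate = 4.0e-4

[[model.degradation]]
form = "constant"
rate = 4.0e-4

[grid]
N = [400, 400]
L = [400.0, 400.0]

[solver]
gamma_ref = 4.0e-4
t_final = 125000.0
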