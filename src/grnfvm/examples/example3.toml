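# Mutual repression of two genes (symmetric toggle switch with repressing
# Hill cross-regulation).  L = 400 covers the unregulated protein scale
# (km/gamma) * b = 128 with headroom; the published set prints no L.
name = "example3"

[model]
n = 2
km = [3.2e-3, 3.2e-3]
burst = [16.0, 16.0]

[[model.regulation]]
form = "hill_univariate"
regulator = 2
K = 45.0
H = 4.0
eps = 0.15

[[model.regulation]]
form = "hill_univariate"
regulator = 1
K = 45.0
H = 4.0
eps = 0.15

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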