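# Single gene with positive self-regulation (activating Hill feedback).
name = "example1"

[model]
n = 1
km = [3.2e-3]
burst = [16.0]

[[model.regulation]]
form = "hill_univariate"
regulator = 1
K = 45.0
H = -4.0
eps = 0.15

[[model.degradation]]
form = "constant"
rate = 4.0e-4

[grid]
N = [2000]
L = [300.0]

[solver]
gamma_ref = 4.0e-4
t_final = 125000.0  # tau = t * gamma_ref = 50
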