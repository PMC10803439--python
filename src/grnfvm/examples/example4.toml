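# Self and mutual regulation with generalized (two-regulator) Hill
# functions: gene 1 is activated by protein 1 (H11 = -4) and repressed by
# protein 2 (H12 = 2); gene 2 is activated by protein 1 (H21 = -6) and
# repressed by protein 2 (H22 = 2).  Leakages are listed per gene in the
# corner order (both regulators saturated, second only, first only):
# gene 1 -> (eps11, eps12, eps13), gene 2 -> (eps21, eps23, eps22).
# The published set prints no L; the choices cover the unregulated protein
# scales (km/gamma)*b = 100 and 400.
name = "example4"

[model]
n = 2
km = [4.0e-3, 8.0e-3]
burst = [10.0, 20.0]

[[model.regulation]]
form = "hill_generalized"
regulators = [1, 2]
K = [45.0, 45.0]
H = [-4.0, 2.0]
eps = [0.002, 0.02, 0.2]

[[model.regulation]]
form = "hill_generalized"
regulators = [1, 2]
K = [70.0, 70.0]
H = [-6.0, 2.0]
eps = [0.002, 0.2, 0.1]

[[model.degradation]]
form = "constant"
rate = 4.0e-4

[[model.degradation]]
form = "constant"
rate = 4.0e-4

[grid]
N = [400, 400]
L = [300.0, 1000.0]

[solver]
gamma_ref = 4.0e-4
t_final = 125000.0
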