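# Bacterial competence in B. subtilis: self-activating master regulator
# ComK (gene 1) represses ComS (gene 2); MecA-mediated degradation is
# shared, giving the rational state-dependent degradation rate
# gamma_i(x) = delta_i*Gk*Gs / (Gk*Gs + Gs*x1 + Gk*x2).
# Derived rates: km1 = (alpha_k + beta_k)/b1 = (0.0028 + 0.049)/2,
# km2 = beta_s/b2 = 0.057/5, eps1 = alpha_k/(alpha_k + beta_k), eps2 = 0.
# The published set prints no L; the choices cover the low-ComK state and
# the heavy ComS excursion tail.
name = "example5"

[model]
n = 2
km = [0.0259, 0.0114]
burst = [2.0, 5.0]

[[model.regulation]]
form = "hill_univariate"
regulator = 1
K = 100.0
H = -2.0
eps = 0.05405405405405406

[[model.regulation]]
form = "hill_univariate"
regulator = 1
K = 110.0
H = 5.0
eps = 0.0

[[model.degradation]]
form = "competence_rational"
delta = 1.4e-3
gamma_k = 500.0
gamma_s = 50.0

[[model.degradation]]
form = "competence_rational"
delta = 1.4e-3
gamma_k = 500.0
gamma_s = 50.0

[grid]
N = [400, 400]
L = [500.0, 1500.0]

[solver]
gamma_ref = 1.4e-3
t_final = 35714.0  # tau ~= 50
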