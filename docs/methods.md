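# Methods

## Model

We consider an `n`-gene regulatory network in which each gene `i` produces
protein in bursts at transcription rate `kₘⁱ cᵢ(x)` (1/time), with burst
sizes drawn from an exponential distribution of mean `bᵢ` (protein units),
and degrades with rate field `γᵢ(x)` (1/time).  The regulation functions
`cᵢ` are signed Hill functions with leakage: a positive Hill coefficient
`H` means the regulator represses the gene (c falls from 1 to ε), a
negative `H` means activation (c rises from ε to 1).  The mRNA level is
already eliminated: `bᵢ = kₓⁱ/γₘⁱ` summarizes translation per transcript,
which is valid when mRNA turns over much faster than protein
(`γₘ/γₓ ≫ 1`); the package records but does not enforce this ratio.

The protein PDF `p(t, x)` then satisfies a transport + jump-integral
equation (degradation drift toward the origin, bursty production jumping
up one coordinate at a time).  Solutions are nonnegative and conserve
total probability.

## Discretization

The domain is truncated to `[0, L₁) × … × [0, Lₙ)` and divided into
equidistant cells `K_α` of widths `hᵢ = Lᵢ/Nᵢ`; the state variables are
cell averages `p_α`.  Multi-indices are 1-based (`αᵢ = 1…Nᵢ`); flat
indices are lexicographic with the last dimension varying fastest, fixed
so exports are reproducible bit-for-bit.

Three coefficient families enter:

* **Burst kernel averages** `b_{α,j}ⁱ` of `βᵢ = ωᵢ − δ`, computed from the
  exact exponential antiderivative (no quadrature): the self coefficient
  of an interior source is `−(2/h)e^{−h/2b}`, interior receivers at offset
  `d` get `(1/h)[e^{−(d−1/2)h/b} − e^{−(d+1/2)h/b}]` (a geometric series
  with ratio `e^{−h/b}`), and the weights are `h/2` on the self term and
  `h` otherwise.
* **Cell averages of `cᵢ` and `γᵢ`**, by default midpoint values
  (sanctioned for smooth coefficients because conservativity only depends
  on the burst averages); a tensor-product Gauss-Legendre rule of order 5
  is available via configuration for rapidly varying coefficients.
* **Degradation face rates**: the flux `∂/∂xᵢ[γᵢ xᵢ p]` is approximated by
  the upwind face difference `(γ_{α+eᵢ} x^{i+1/2} p_{α+eᵢ} − γ_α x^{i−1/2}
  p_α)/hᵢ`; the first cell's lower face sits at the origin, so its outflow
  vanishes identically.

**Boundary correction.** On the truncated domain the upper burst tail
would leave the grid.  We route all overshooting burst mass into the last
cell of the affected dimension (the protein count saturates at `Lᵢ`), and
the last cell's own-burst coefficient becomes zero.  This is the unique
redistribution that is simultaneously faithful to saturation and exactly
conservative — every source column of the burst operator sums to zero
analytically, and to machine precision in floating point.  Alternative
redistributions (e.g. suppressing out-of-domain bursts at the source)
would perturb the stationary solution at the order of the tail mass; the
reproduction of the published error table validates this choice
empirically.

**Assembly.** Translation invariance of the burst averages means each
dimension needs only `O(Nᵢ)` distinct coefficients; the generator is
assembled from per-dimension 1-D pattern matrices lifted by Kronecker
products and scaled by per-source-cell averages of `cᵢ` and `γᵢ`, giving
`O(nnz)` assembly.  The structural nonzero count has the closed form
`(n + 2 + ΣNᵢ − Σ2/Nᵢ)·ΠNᵢ/2`, which the implementation reproduces
exactly and uses for memory estimates.  Column sums are verified at
assembly time against `10⁻¹⁰·max|diag|`; a violation aborts (an optional
rebalance flag exists for exploratory work but silently repairing
conservation would mask bugs).

## Structure and long-time behaviour

The assembled matrix is Kirchhoff (Metzler, zero column sums), its
compartmental graph is strongly connected (degradation chains downward,
bursts jump upward past any gap), and for `n ≥ 2` the graph is the
Cartesian product of the per-dimension 1-D graphs.  Viewed as a
single-species-complex reaction network it has `N` complexes, one linkage
class and stoichiometric rank `N − 1`, hence deficiency zero.  These facts
give a unique strictly positive equilibrium, monotone decay of the
entropy-like Lyapunov function `V(p, p̄) = Σ (p log(p/p̄) + p̄ − p)` and
contraction in L1.  `check_structure` verifies all of them numerically;
the stoichiometric rank uses a dense SVD below a work bound of 4×10⁷
(edge count × node count) and the incidence-rank identity
`rank = #nodes − #weak components` above it.

## Stationary solve

The equilibrium solves `Γ̂ p̄ = e₁` where `Γ̂` replaces the first row of
`Γ̃` with `h·1ᵀ` (any `N−1` rows of a Kirchhoff matrix with simple zero
eigenvalue are independent, so `Γ̂` is nonsingular).  The default is a
sparse direct LU factorization — the 1-D matrix is lower-Hessenberg, so
fill-in is benign even at `N = 5000`; a GMRES+ILU option exists for large
2-D grids.  Components in `[−10⁻¹², 0)` are clipped to zero (rounding
dust); anything more negative raises, since a valid Kirchhoff matrix
cannot produce it.  An independent route, `stationary_by_integration`,
iterates the backward-Euler resolvent from the uniform PDF until the
per-step L1 change falls below tolerance; the two routes agree to `10⁻⁶`
in L1 on every fixture tested.

## Time integration

The system is stiff: superdiagonal degradation rates grow like `γL/h`.
The integrator is fixed-step backward Euler with the LU factorization of
`(I − Δt Γ̃)` computed once.  For a Kirchhoff generator the resolvent is
nonnegative with unit column sums, so every step conserves mass exactly,
preserves nonnegativity, and (being a Markov map fixing p̄) cannot
increase the Lyapunov function or the L1 distance between two solutions —
the qualitative theory survives discretization in time exactly, not just
asymptotically.  The default step is the spectral-scale estimate
`1/max|diag|`, capped so a horizon takes at most 20 000 steps.  Times are
raw internally; the CLI reports the dimensionless `τ = t·γ_ref` alongside.

## Analytic reference and the error metric

For the single-gene Hill model with constant degradation the stationary
density `C ρ^{a(1−ε)/H} x^{aε−1} e^{−x/b}` is evaluated in log space with
the logistic form of `ρ`, normalized on the truncated `[0, L]` (consistent
with the FVM's conservation domain; normalizing on `[0, ∞)` is available
behind a flag but injects O(tail) discrepancy).  The normalization splits
the domain and applies a Gauss-Jacobi rule with the exact power-law weight
on the singular segment.  The printed symbol for the rate parameter `a` is
ambiguous between the raw `kₘ` and the dimensionless `a = kₘ/γ`; because
the finite-volume equilibrium depends only on the ratio `kₘ/γ`, comparing
both candidate densities against a converged FVM solution resolves the
reading empirically (`resolve_convention`), and the dimensionless one
matches to `~10⁻³` while the raw one is off by orders of magnitude.

The error metric is the relative L2 distance over mesh midpoints, with
unweighted sums, exactly as printed in the reference table.  Near the
origin the closed-form density varies steeply, so the reference can be
sampled either at the first midpoint or as the first-cell average (the
finite volume's own semantics); both are implemented and the validation
tries both, recording which matched.  At `N ≤ 2000` the midpoint
convention reproduces the published errors within ~6%; at `N = 5000`,
`L = 300` the first-cell-average convention is the one that matches
(2.3%), consistent with the published table having been computed with a
cell-average-like reference near the singular origin.

## Bundled parameter sets

Five example networks ship as TOML fixtures: (1) single-gene positive
feedback; (2) mutual activation; (3) mutual repression; (4) self/mutual
regulation with generalized two-regulator Hill functions; (5) the
*B. subtilis* competence circuit with shared MecA-mediated degradation,
`γᵢ(x) = δᵢΓₖΓₛ/(ΓₖΓₛ + Γₛx₁ + Γₖx₂)`.  All printed rate parameters are
encoded verbatim.  The published 2-D sets do not print domain lengths; the
fixtures fix them once at a few multiples of the relevant protein scales
(mutual activation/repression: `L = 400` vs unregulated means of 153 and
128; example 4: `L = (300, 1000)` vs means 100 and 400; competence:
`L = (500, 1500)` covering the low-ComK state and the ComS excursion
tail).  Structural results are insensitive to these choices; quantitative
2-D comparisons are not possible anyway since no 2-D reference values are
printed.

In the generalized Hill functions of example 4 the printed form of the
second gene's regulation contains two apparent typographical slips (a
regulator exponent attached to the wrong variable, and a leakage index
that would otherwise never appear); the implementation uses the symmetric
corrected form, equivalent to bilinear interpolation of the corner
leakages in the two saturation variables `w = x^H/(K^H + x^H)`.

## Validation scales

The test suite exercises the full published error table for the
single-gene example (`N` up to 5000, `L ∈ {300, 350, 400}`), the
structural suite for all five fixtures at `Nᵢ ∈ {16, 50}`, mass
conservation along trajectories at reduced resolution (1-D `N = 64`, 2-D
`24²`), and the 2-D joint-PDF properties (unit mass, nonnegativity,
protein-exchange symmetry of the symmetric networks) at `100²`.  These
sizes were chosen to keep the default run in about a minute while still
covering every structural claim at more than one resolution.

## Known limitations

* Bursts are exponential and jump one coordinate at a time; no
  cross-protein jumps and no non-exponential burst distributions.
* Meshes are equidistant; no adaptivity.  Resolution is the main error
  source near sharp or singular features of the density.
* In double precision the far tail of sharply peaked equilibria
  underflows to zero even though the exact equilibrium is strictly
  positive; the solver clips only `[−10⁻¹², 0)` and treats anything more
  negative as an assembly bug.
* The closed-form reference exists only for `n = 1`; multidimensional
  results are validated structurally (mass, positivity, symmetry,
  graph products), not against exact densities.
* Time-integration accuracy is first order (backward Euler); the scheme
  is meant for stationary computation and qualitative transients, not
  high-order time accuracy.
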