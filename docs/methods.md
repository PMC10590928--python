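# Methods

## Model and assumptions

The package models tobacco uptake and cessation in a closed-but-for-births
population divided into susceptible smokers M, a snuffing (smokeless
tobacco) class L, irregular smokers N, regular smokers O and quitters P.
Transmission-like progression is bilinear (mass-action contacts χ₁ML and
χ₂LN); everything else is linear. The right-hand side is therefore constant
+ linear + bilinear, which is what makes the homotopy expansion terminate in
finite convolutions at every order.

Summing the equations gives the exact bookkeeping identity
Σᵢ rhsᵢ = θ − λ(M+L+N+O+P) − μL − σN: recruitment minus natural deaths minus
the two tobacco-attributable death flows. This identity holds for arbitrary
(including negative) states and is asserted to 1e-12 in tests.

Two textual ambiguities in circulating statements of this model were
resolved in favour of the equations: ρ is the regular→quit rate (not a death
rate of the snuffing class), and the extra death rate μ applies to the
snuffing class only. The default initial conditions are (68, 40, 30, 20, 15);
these are the values consistent with the first-order series coefficients
(e.g. γ·30 − (β+ρ+λ)·20 = −0.980). A variant with the regular and quit
compartments interchanged (O₀=15, P₀=20), which also circulates, is exposed
as `InitialState.variant_quit_swapped()`.

## Fractional operator

The ABC derivative of order χ ∈ (0, 1] has the non-singular Mittag-Leffler
kernel; its companion integral is

    I_AB[g](t) = (1−χ)/K · g(t) + χ/(K·Γ(χ)) ∫₀ᵗ g(v)(t−v)^{χ−1} dv ,

a weighted sum of the function itself and its Riemann–Liouville fractional
integral. The normalization K(χ) must satisfy K(0)=K(1)=1; the package
defaults to K ≡ 1 (the standard convention, and the one that makes series
coefficients directly comparable across χ), configurable to any positive
value.

All solution terms live in the truncated fractional basis
e_k(t) = t^{kχ}/Γ(kχ+1). On this basis the AB integral is the exact linear
map e_k ↦ ((1−χ)e_k + χe_{k+1})/K, and products close via
e_i·e_j = B(i,j;χ)·e_{i+j} with B = Γ((i+j)χ+1)/(Γ(iχ+1)Γ(jχ+1)). Only
multiples of a single χ arise, so no general Mittag-Leffler machinery is
needed. Coefficients are plain floats at one fixed χ per series;
χ-symbolic bracket forms at orders 1–2 are recovered by structured
projection (`extract_bracket_scalar`) rather than by symbolic algebra.

A consequence worth flagging: because I_AB[g](0) = (1−χ)g(0)/K ≠ 0, the
series solution of the integral-equation form takes the value
ω₀ + (1−χ)/K·rhs-dependent terms at t = 0 rather than ω₀ exactly, whenever
χ < 1. This is visible in the order-1 bracket {1−χ + χt^χ/Γ(χ+1)}, which
equals 1−χ at t=0. The trajectory CSV therefore starts exactly at the
initial conditions only at χ = 1; at lower orders the t=0 row is shifted by
O(1−χ). This is a property of the ABC formulation itself, not of the
implementation.

## q-HATM recursion

The Laplace-domain machinery of q-HATM is eliminated analytically: the
s-domain factor (1/K)(1−χ+χ/s^χ) acting on a transform is exactly I_AB
acting on the basis, so the runtime recursion is

    ω₀ = initial data,
    ω₁ = −h·I_AB[F₀],
    ωᵣ = (n+h)·ωᵣ₋₁ − h·I_AB[Fᵣ₋₁]   (r ≥ 2),

with k_r = 0 for r ≤ 1 and n for r > 1 folded in, and Fᵣ₋₁ the
order-(r−1) homotopy polynomial: convolutions Σᵢ Mᵢ⊗L_{r−1−i} and
Σᵢ Lᵢ⊗N_{r−1−i} for the bilinear terms, linear terms applied at index r−1,
and the constant source θ entering only F₀ (homotopy factor 1−k_r/n). A
uniform sign convention is used for the nonlinear operator across all five
equations — the one consistent with every low-order coefficient.

Parameters that matter:

- **χ** (dimensionless, default 1.0 for coefficient extraction; the CLI
  sweeps {0.7, 0.8, 0.9, 1.0}): fractional order; memory strength.
- **h** (dimensionless, default −1): convergence-control parameter. h = −1
  with n = 1 is the standard choice and makes the χ=1 series the Maclaurin
  series of the classical solution. The `h_curve` diagnostic tabulates the
  truncated value at a probe time against h; a flat plateau marks the
  admissible region.
- **n** (integer ≥ 1, default 1): homotopy denominator; the assembled series
  weights term r by (1/n)ʳ. Choices with n + h = 0 give identical assembled
  series at χ = 1 (tested for (1,−1) vs (2,−2)).
- **R** (default 6 in the CLI): truncation order. Series truncation is
  silent; each ωᵣ has basis degree ≤ r, so R ≥ the number of iterations
  loses nothing at the reported orders.

Divergence is detected by a coefficient-magnitude guard (10¹²) and raised as
an error naming the compartment and order, rather than propagating overflow.

## Validation strategy

No closed-form solution exists, so correctness rests on independent oracles
that share no code with the series algebra:

- **Taylor oracle**: the exact integer-order Maclaurin recursion
  (r+1)a_{r+1} = c·δ_{r0} + A·a_r + convolutions, in plain polynomial
  arithmetic. At χ=1, n=1, h=−1 the q-HATM coefficients must satisfy
  c_r = r!·a_r exactly; asserted to 1e-9 for R ≤ 8 on the default model and
  on ten seeded random rate sets.
- **RK4 oracle**: fixed-step classical Runge-Kutta; the assembled χ=1
  series at R=10 matches it to better than 1e-5 sup-norm on t ∈ [0, 1].
- **Singular-kernel quadrature**: the AB integral evaluated directly from
  its defining integral, with the substitution u = (t−v)^χ removing the
  endpoint singularity; the basis-map implementation agrees to 1e-8 across
  χ ∈ {0.3, 0.5, 0.7, 0.9}.
- **Integral-equation residual**: |ω(t) − ω₀ − I_AB[rhs(ω)](t)| on a grid.
  It decreases (non-strictly) with R and reaches round-off (<1e-8, measured
  ~1e-13) once truncation is inactive on the window. The package reports
  this diagnostic instead of claiming a convergence radius in t, which is
  not known for this series.

The random model fixtures (`oracles.random_model`) have bounded entries
(|·| ≤ 1, dimension ≤ 4) so their series behave on t ∈ [0, 0.5]; randomness
is always seeded.

Negative compartment values can occur in truncated series (most visibly on
long windows at low R); they are reported — as a CLI warning and in
`ResidualReport.min_values` — never clamped, so truncation artifacts stay
visible.

## Numerical choices

- Γ evaluation via log-Γ and t^{kχ} via exp(kχ·ln t), so high-order terms
  neither overflow nor lose accuracy; t = 0 is handled by e_k(0) = δ_{k0}.
- Equality tolerance in tests is absolute 1e-9 unless a tighter identity
  (1e-12) holds exactly.
- Bracket extraction projects the term onto the known bracket shape and
  rejects (at 1e-9 relative misfit) terms that do not match; the order-2
  extraction first removes the (n+h)-carry, so it works for any (n, h),
  not only n + h = 0.
- The CLI time window t ∈ [0, 1] with 101 points and the χ sweep
  {0.7, 0.8, 0.9, 1.0} are conventional defaults; nothing in the model
  fixes a window, and users studying longer horizons should raise R and
  watch the residual diagnostic.

## Limitations

- The solver is a truncated series, not a time-stepping integrator: accuracy
  degrades with t and must be judged by the residual report, not assumed.
- For χ < 1 there is no independent trajectory reference in the package (a
  fractional Adams–Bashforth integrator would be future work); fractional
  correctness rests on the exact basis identities plus the quadrature oracle.
- Stability/equilibrium analysis, reproduction numbers and optimal control
  are out of scope; so is fitting the rates to data.
- Figure captions circulating with this model describe the snuffing class as
  declining, while the series' first-order term gives L a positive initial
  slope (+5.560 at t=0 with h=−1). The package plots what the series says.
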