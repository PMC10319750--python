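# Methods

## Model

Two two-level systems (daughter DNA and mRNA, each a tautomeric
double-well qubit) start in the entangled pure state
`alpha|00> + beta|11>` with real nonnegative amplitudes,
`alpha^2 + beta^2 = 1`. Each qubit couples linearly to an independent
reservoir of bosonic modes initialized in the vacuum. Working in the
interaction picture and expanding the per-channel propagator to second
order in the coupling, the reservoir traces out to leave an X-form reduced
density matrix in the product basis {|00>, |01>, |10>, |11>} whose
elements decay exponentially with per-channel rates Gamma_i and precess
with the summed tunnel splittings Delta_1 + Delta_2 (see the package
README for the explicit elements). This is the two-channel analogue of
single-qubit amplitude damping: the doubly excited population L44 decays
through both channels, the single-excitation populations L22, L33 are fed
by one channel and drained by the other, and the |00><11| coherence decays
at half the total rate.

Assumptions inherited from this construction:

* weak system–bath coupling (second-order perturbation theory; no
  higher-order corrections);
* zero-temperature reservoirs (vacuum initial state, no thermal
  occupation);
* no direct DNA–mRNA interaction after separation — all correlation is
  inherited from the initial state;
* phases of alpha and beta are unobservable in every reported quantity
  (only alpha^2, beta^2, alpha*beta appear), so amplitudes are stored as
  moduli.

## The two L11 conventions

The perturbative bookkeeping that produces the closed-form elements leaves
the ground-state population fixed at `L11 = alpha^2`, so the trace decays
to `alpha^2 + beta^2(e^{-G1 t} + e^{-G2 t} - e^{-(G1+G2)t})`. The package
exposes this as `mode="paper"` for fidelity with the source closed forms,
and a `mode="trace_preserving"` default that routes the decayed population
into |00> (adding `beta^2 (1-e^{-G1 t})(1-e^{-G2 t})` to L11), restoring
unit trace and positive semidefiniteness. The concurrence is identical in
both conventions: for an X state it is
`2 max{0, |L14| - sqrt(L22 L33), |L23| - sqrt(L11 L44)}` and the branch
containing L11 is never the active one here (L23 = 0). A dedicated test
asserts this equality on a dense random grid. In paper mode the Wootters
functional is evaluated on the raw (trace-leaking) matrix, matching the
`2 alpha beta` prefactor of the closed form; the normalized variant is the
default for proper density operators.

## Concurrence, spin-flip spectrum, and sudden death

The general route forms `R = rho (sigma_y ⊗ sigma_y) rho* (sigma_y ⊗
sigma_y)`, takes its eigenvalues, clamps round-off negatives above -1e-12
to zero, sorts descending and returns
`max{0, sqrt(l1) - sqrt(l2) - sqrt(l3) - sqrt(l4)}`. For the model's X
state with vanishing inner coherences the spectrum is available in closed
form: `l1 = l2 = L22 L33`, `l3,4 = (sqrt(L11 L44) ∓ |L14|)^2`. (A common
shorthand writes these as `½[(2 L11 L44)^{1/2} ∓ (2 L14 L41)^{1/2}]`;
that form does not reproduce the numerical eigendecomposition and is not
used — the implemented closed form is validated against `numpy.linalg.eigvals`
to 1e-10 on random draws.)

The closed-form concurrence bracket
`2 beta e^{-(G1+G2)t/2} (alpha - beta sqrt((1-e^{-G1 t})(1-e^{-G2 t})))`
is clamped at zero, as the eigenvalue definition requires. When
beta > alpha the bracket has a unique finite root — entanglement sudden
death — located by Brent root-finding (xtol 1e-10) on the monotone factor
`sqrt((1-e^{-G1 t})(1-e^{-G2 t})) - alpha/beta`; for alpha >= beta the
concurrence decays asymptotically and the finder returns None. Decaying
exponential factors throughout are written as `1 - e^{-Gamma t}`: this is
the only reading under which the populations are nonnegative, the
concurrence is real, and the closed form agrees with the independent
eigenvalue route, which the test suite checks to 1e-8 on a grid of more
than five thousand parameter/time points.

## Bath integrals

* **Mode density.** `D(w, t) = (1/(2 pi t)) (sin(wt/2)/(w/2))^2`,
  implemented via `numpy.sinc` so the removable singularity at w = 0 is
  exact. Its normalization `int_0^inf D dw = 1/2` is checked against a
  dense Simpson sum with an analytic oscillatory-tail correction rather
  than generic adaptive quadrature, which cannot certify 1e-6 on this
  slowly decaying oscillatory integrand.
* **Decay rate.** `Gamma(t)` is the golden-rule integral of the Ohmic
  spectral density against `D(w, t)`, evaluated with `scipy.integrate.quad`
  on [0, 50 w_c] (the exponential cutoff makes the truncated tail < 1e-20
  of the integral), absolute tolerance 1e-12, subdivision limit 800 to
  resolve the O(t w_c / 2 pi) oscillations. It is linear in eta and
  |f01|^2 and inversely proportional to hbar_tilde, all asserted.
* **Principal-value shifts.** `F_-` has a Cauchy pole at w = Delta. The
  integral over the symmetric window [Delta - h, Delta + h], h = half the
  distance to the nearer domain edge, is rewritten as
  `int_0^h (J(Delta+u) - J(Delta-u)) sin(ut)/u^2 du`, whose integrand is
  continuous at u = 0; tails use plain adaptive quadrature. The scheme is
  validated against a paired-midpoint brute-force oracle on both a box
  spectrum and the Ohmic family. `F_+` is regular for Delta > 0.
  Quadratures that cannot certify their tolerance raise `QuadratureError`
  carrying the achieved error estimate.
* The per-mode coupling profile gamma_bar is only defined through
  `J = (pi/2) gamma_bar^2 D` and is exposed solely as the diagnostic
  inversion `sqrt(2J/(pi D))`; the dynamics never needs it separately.
  Tunnel splittings Delta_i are always direct inputs, never derived from
  the spectrum.

The constant Gamma_i used by the closed-form dynamics and the Gamma(t)
profile from the Ohmic integral are distinct surfaces: the package does
not decide which plateau value of Gamma(t) the constant should equal, it
exposes the profile (CLI `spectra` subcommand) as a diagnostic and takes
constant rates as inputs to the dynamics.

## Propagator elements and parity

The vacuum-preserving propagator elements are pure phases
`exp[-(i/hbar_tilde)(t dE_n - |f|^2 F_±(t))]`; the second-order level
shifts dE_0, dE_1 have no closed form at this order and default to zero —
they are global per-level phases that cancel in every reduced-state
observable. Parity selection (vacuum part connects equal-parity levels,
one-boson part opposite-parity) is exposed as a predicate and enforced by
construction: forbidden elements are never materialized.

## Units and the decoherence estimate

`UnitsSystem` carries the (M, R0, U0) scales of the double well and the
induced momentum, time and dimensionless-Planck-constant scales; the three
algebraically equivalent expressions for hbar_tilde are computed
independently and property-tested to 1e-12 relative agreement. The
thermal de Broglie wavelength defaults to the dimensionally consistent
`hbar / sqrt(2 m k_B T)` (the form the decoherence-time ratio
`t_D = t_R lambda_T / dx` needs to carry time units); the reciprocal
variant `hbar sqrt(2 m k_B T)` seen in parts of the literature is kept
behind `convention="as_printed"` for comparison only. Physical constants
are CODATA SI values; everything at model level is dimensionless.

## Sweeps and what the tests do (and do not) show

The sweep scenarios tie the channel rates to the splittings by a single
ratio kappa (`Gamma_i = kappa Delta_i`) over documented default grids —
kappa in {0.05, 0.1, 0.3}, Delta in {0.2, 1, 5}, t in [0, 20] with 400
steps, equal-weight initial state. Only qualitative orderings are
asserted: the survival-probability envelope
`alpha^4 + (beta^4 + 2 alpha^2 beta^2) e^{-(G1+G2)t/2}` is monotone in the
total rate, and the time for the concurrence to fall below 0.01 is
nonincreasing in kappa. These grids are design defaults, not fitted
values; passing them shows internal consistency of the closed forms, not
agreement with any measured biomolecular rate. The model itself idealizes
heavily — zero-temperature baths, weak coupling, no helicase back-action,
no proofreading — so no test here speaks to whether real transcription
complexes preserve coherence.

## Random-state fixture

Cross-checks of the Wootters procedure use reproducible random density
matrices built as `A A† / tr(A A†)` with A a complex 4×4 standard-normal
draw from `numpy.random.default_rng(seed)` — Hermitian, PSD, unit trace
by construction. This is test plumbing, not a model surface.

## Numerical conventions

* Eigenvalues within 1e-14 of zero are treated as zero before square
  roots; spin-flip eigenvalues below -1e-12 are an error, between -1e-12
  and 0 they are clamped.
* Density-matrix validation tolerances are 1e-12 (Hermiticity, trace,
  minimum eigenvalue).
* Time grids are uniform; the elements are closed-form, so no adaptive
  stepping is needed.
* CSV output uses `%.17g`, which round-trips IEEE doubles exactly (note
  pandas' default `read_csv` parser is itself lossy in the last ulp; use
  `float_precision="round_trip"` to recover values bit-exactly).
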