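# Methods

This note records the models implemented in `mgff`, the numerical choices
made where the procedure was genuinely open, and what the synthetic-data
validation does and does not establish.

## Interaction model

The pair potential is the 12–6 Lennard-Jones form plus Coulomb,

V(r) = 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] + q_i q_j k_e / r − c₄/r⁴,

in internal units nm / kJ·mol⁻¹ / e / ps (in which 1 kJ·mol⁻¹ per g·mol⁻¹ is
exactly (nm/ps)²; converters live at the I/O boundary only). The optional
attractive r⁻⁴ term mimics charge-induced dipole interactions in 12–6–4
models; c₄ is stored positive and subtracted, matching that literature's
sign convention. The Coulomb constant is fixed at k_e = 138.935458
kJ·nm/(mol·e²) (CODATA-derived); electrostatics are never adjusted —
optimization acts on the LJ parameters and on the combination rules only.

Unlike pairs use Lorentz–Berthelot rules, optionally scaled per partner
class: σ_ij = λ_σ(σ_i+σ_j)/2, ε_ij = λ_ε√(ε_iε_j). The registry hard-codes
only the two optimized sets (microMg, nanoMg) and the TIP3P oxygen
(σ = 0.315061 nm, ε = 0.6364 kJ/mol; hydrogens carry no LJ site). Literature
comparison sets are deliberately *not* hard-coded — their exact constants
are not reliably reproducible from public summaries — and are supplied as
TOML parameter files instead.

Forward-computing the printed pair constants from the self parameters
reproduces σ_io/ε_io and the scaled ε values to the printed precision;
σ_MgOP and the nanoMg σ_MgCl agree only to ~1×10⁻⁴ nm, which traces to
rounding in the published table (e.g. 1.8·(0.1025+0.4401)/2 = 0.48834,
printed as 0.4884). Tests assert at the tolerance the arithmetic supports.

## Hydration-shell structure

RDFs are histogram estimators over orthorhombic minimum-image distances,
normalized by ideal-gas shell counts; triclinic boxes are rejected. The
default 0.002 nm bin resolves the narrow Mg–O first peak to the precision R₁
is quoted at (±0.004 nm). Extremum detection runs on a 3-bin moving average
of g (no detection rule is standard; smoothing suppresses noise-induced
minima), the peak is refined by parabolic interpolation, and the coordination
number integrates the *unsmoothed* g trapezoidally with a zero node at r = 0.
Binning uncertainty (half a bin) and block spread are reported separately
rather than combined into one error bar.

Self-diffusion uses the Einstein relation D = slope/6 of the time-origin-
averaged MSD, least-squares fitted over a user-chosen lag window, with
block-averaged uncertainty. Coordinates are unwrapped by accumulating
minimum-image frame-to-frame displacements (valid while no particle moves
half a box length per frame). A Yeh–Hummer-type finite-size correction is
*not* applied automatically; it is an additive post-hoc term the caller can
compute, since it needs a viscosity the package does not estimate.

## Water-exchange kinetics

A water is committed **bound** to an ion when their distance falls below
r_bound and **unbound** when its distance to every ion exceeds r_unbound;
between the cutoffs the previous committed state persists. This hysteresis
suppresses barrier-recrossing noise, and computed rates are insensitive to
the exact cutoff values (verified ±10% → <5% on synthetic data). Defaults
r_bound = 0.28 nm, r_unbound = 0.40 nm bracket the first minimum of the
Mg–Ow RDF and the second-shell onset; both are explicit configuration.
Transitions are evaluated at native frame resolution, no interpolation.

The rate constant from the bidirectional transition count N is

p_B = n₁/(N_H₂O − n₁),  t_B = N_Mg · p_B · t_sim,  k = N / (2 N_H₂O t_B),

with n₁ = 6 the first-shell coordination number; t_B is the expected
first-shell residence time of one water and the factor 2 converts
bidirectional counts to exchange events. The closed form was validated
against all three published count→rate rows and the expected experimental
counts before being frozen (see the acceptance script). When no box
composition is given, the ideal 1 M MgCl₂ composition N_H₂O:N_Mg = 2160:39
(≈55.5:1) is assumed and echoed in all output; note k/N depends on N_Mg
because N is extensive. Errors use block averaging with two blocks by
default (std over blocks with ddof = 1, divided by √n_blocks).

The 1-D TST estimate k_TST = √(k_BT/2πμ)·e^(−F‡)/∫_well e^(−F)dr is provided
strictly as an upper bound: it assumes free thermal flight across the
barrier, while real (and synthetic) shell exchange is diffusive and
recrossing-rich.

## Kirkwood–Buff analysis

Running integrals G(r) = 4π∫₀^r (g−1)s²ds are trapezoidal and averaged over
a convergence window (default 1.0–1.5 nm, standard for converged
salt-solution RDFs). No tail extrapolation or finite-size closure is applied
by default. For the 2:1 electrolyte, salt–salt and salt–water integrals are
stoichiometric averages and a_cc = 1/(1 + ρ_s(G_ss − G_sw)). This convention
satisfies the ideal-solution limit a_cc = 1 and reproduces the qualitative
behavior that overly attractive cation–anion rules drive a_cc below
experiment; because the literature varies in whether molality- or
concentration-scale derivatives (and G_ww terms) are used, the combination
entering the denominator is a config enum (`ss-sw` default, `ss`), echoed in
every result. Errors use three blocks by default.

## Binding thermodynamics

Profiles are stored in k_BT. F is anchored by the mean over the outermost
10% of the grid, which must be flat to within 0.2 k_BT (otherwise the
profile is rejected as lacking a bulk plateau); this makes ΔG_b⁰
gauge-invariant. The bound region runs from the start of the grid to the
barrier top — an inner-sphere/outer-sphere split at the dividing surface —
rather than to a fixed radius; a spherical-shell 4πr² Jacobian is applied
(disable for pre-weighted profiles) and V⁰ = 1.661 nm³ is the 1 M
standard state. Whether an axial instead of spherical standard-state
correction was used upstream cannot be inferred from a profile alone; the
flag is part of the output provenance. Well and barrier are located by a
global minimum plus a hysteresis walk that requires 0.5 k_BT of prominence,
so sub-k_BT noise cannot fake extrema; positions are refined parabolically.
Halving the grid spacing moves ΔG_b⁰ by <0.01 k_BT on smooth profiles.

The experimental binding-affinity target derives from the dimethylphosphate
stability constant, ΔG_b⁰ = −ln(10)·log K; log K = 0.45 (the DMP value, not
the modular-RNA value 1.05 which bakes in a statistical factor) gives
−1.036 k_BT.

## Selection workflow

Step 1 keeps (σ_io, ε_io) candidates matching ΔG_solv and R₁ within
tolerance and n₁ exactly; default tolerances are ±5 kJ/mol (package choice)
and ±0.004 nm (the experimental uncertainty). Step 2 selects by
|log₁₀(k/k_exp)| or maximal k. Step 3 grid-searches λ pairs: Cl stage
minimizes |a_cc − 0.93| (default tolerance ±0.02, package choice), RNA stage
restricts to the R_b tolerance and then minimizes the ΔG_b⁰ error. Declared
ranges (σ_io 0.16–0.24 nm, ε_io 1.8–28 kJ/mol; λ_σ^Cl 1–2.6, λ_ε^Cl
0.01–1; λ_σ^RNA 0.97–1.23, λ_ε^RNA 0.08–1.04) are validated with warnings.
Ties break toward the smallest first, then second parameter, so selection is
deterministic. The search is parameterized in ion–water (σ_io, ε_io) space
with ion–ion values back-solved through the inverted combination rules
against TIP3P oxygen. The optimizer consumes CSV observable tables; it
never drives an MD engine, which is what makes the workflow desk-scale.

## Synthetic data: what green tests establish

The hopping generator models exchange as a per-water two-state
continuous-time Markov chain (exact exponential waiting times, discretized
to frames) embedded geometrically: bound waters jitter at R₁ = 0.21 nm
around fixed ions, bulk waters beyond R₂ = 0.46 nm, with the escape rate
chosen so the counting estimator is unbiased for the requested k_true.
Default conditions mirror the reference setup (t_sim = 1 μs, n₁ = 6, ideal
1 M composition). Exchange is memoryless and single-water; the concerted
two-water mechanism, realistic water dynamics, and any force-field
dependence are intentionally absent. Green pipeline tests therefore
establish the correctness of the labeling/counting/closed-form *estimator*,
not the realism of any particular force field's kinetics.

For the TST-bound benchmark, the matching PMF is constructed by inverting
the overdamped Kramers rate k = D√(F″_w|F″_b|)/(2π)·e^(−ΔF) at the physical
water self-diffusion constant (2.3×10⁻³ nm²/ps) for the barrier height
(≈14 k_BT at k_true = 8×10⁵ s⁻¹, a physically sensible value). TST on the
same profile replaces diffusive crossing with thermal flight and exceeds the
generating rate by the factor v_thermal·ℓ_barrier/D ≈ 4, so the upper-bound
property is a consequence of the physics, not of tuning.

RDF families (ideal, Gaussian shell, excluded volume) carry closed-form
n₁/R₁/G; step-like features are emitted bin-averaged so trapezoidal
integration never crosses a raw discontinuity. Analytic profiles carry
truths computed by adaptive quadrature and bounded scalar optimization on
the closed form — an independent route from the grid-based analyses they
validate. Brownian fixtures have exact per-step displacement variance
2D·dt. All generators are deterministic under a fixed seed and record their
ground truth in the returned object's metadata.

## Known limitations

- Orthorhombic periodic boxes only; triclinic input is rejected.
- MD-derived observables (ΔG_solv, simulated R₁, a_cc of real solutions,
  D₀ of real water models, PMF barrier heights) enter as *inputs*; the
  package validates its estimators structurally, not the published
  simulation values themselves.
- The GROMACS `.itp` emitter writes explicit pair overrides only; AMBER's
  12–6–4/LJ-edit mechanism is structurally different and out of scope.
- The RNA scaling class applies to every partner type supplied (hydrogens
  included) unless the caller restricts the partner table.
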