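# Methods

This note documents the models, conventions and numerical choices behind
pmfpath, in the spirit of a methods appendix: what is computed, under which
assumptions, and where the genuinely open design decisions were made.

## Unit system and constants

Energies are kcal/mol, reaction coordinates Å, temperatures K.
kB = 0.0019872041 kcal mol⁻¹ K⁻¹ everywhere; the Eyring prefactor uses
kB/h = 2.0836612·10¹⁰ s⁻¹ K⁻¹.  Default temperature 300 K.

## Analytic landscapes

The package's energy functions are analytic stand-ins for an expensive
electronic-structure energy: what matters for validating the *analysis*
layer is topology and smoothness, not chemical accuracy.  Five forms:

- `harmonic` — V = ½·s·Σ(xᵢ−cᵢ)²; the ½-convention stiffness makes the
  Gaussian algebra of the sampler tests exact.
- `double_well_1d` — V = h·(x²−a²)²/a⁴, barrier h at x = 0, minima at ±a;
  an optional orthogonal harmonic term embeds it in 2D.
- `two_basin_2d`, `psp_step1_like`, `psp_step2_like` — sums of inverted
  (an)isotropic Gaussians plus a broad quadratic confinement.

The `psp_step*_like` surfaces place their basins at the reaction-coordinate
positions characteristic of the two phosphoryl-transfer steps they emulate
(step 1: intermediate near OPO ≈ −1.3 Å, product near +1.0 Å; step 2:
−1.6 Å and +1.6 Å, both with the proton coordinate as second axis), with a
low anisotropic ridge shaping a plateau-like transition region between
them.  Basin depths, widths and the confinement are conventions of the
fixture chosen once for topology — at least two minima and one connecting
saddle, verified by the numerical stationary-point report — and imply
nothing about any measured energetics.  The built-in report
(`stationary_points`) polishes dense-grid candidates by Newton iteration on
the analytic gradient and classifies them by finite-difference Hessian
eigenvalues; it is the reference that downstream saddle and path tests
compare against.

`analytic_pmf` computes F(bin) = −kT ln ∫_bin exp(−V/kT) (integrating any
orthogonal axis over its full domain) by per-bin Gauss–Legendre quadrature,
node-doubling until successive refinements differ by < 10⁻³ kcal/mol.  It
is the exact oracle for the WHAM validation.

## Umbrella sampling

Protocol defaults mirror the standard workflow the package emulates:
window centers on a 0.1 Å grid inclusive of both range ends; harmonic bias
U = k·(x−c)² — the CHARMM restraint convention, *without* the ½ factor —
with k = 1000 kcal mol⁻¹ Å⁻² during equilibration and 200 during
production; 300 K; a 10 000-step equilibration and 60 000-step production
(preserving the 1:6 duration ratio of the 10 ps/60 ps protocol at one step
per abstract time unit), recorded every 10 steps so the series divides
into three equal blocks.  The restraint convention is deliberately shared
with the WHAM stage through a single function; consistency between bias
generation and unbiasing is what correctness requires, and the
no-½-factor choice reproduces the magnitudes a CHARMM-style restraint
produces for the stated k values.

Dynamics is Metropolis random-walk Monte Carlo on V + U at the window's
temperature: detailed balance gives the same Boltzmann measure an MD
thermostat would sample, which is the only property the downstream
analysis uses.  Proposals are isotropic Gaussians whose width is tuned
toward ~40% acceptance during equilibration (frozen for production);
proposals outside the landscape domain are rejected, which is Metropolis-
valid for a symmetric proposal.  Per-window random streams derive from
`SeedSequence([master_seed, window_index])`, so a window's trajectory is
bit-identical whether sampled alone or in a vectorized batch, and an
entire pipeline rerun reproduces byte-identical artifacts.

What the generator does *not* emulate: molecular geometry, solvent,
autocorrelation structure of real MD, or committor-relevant dynamics.
Passing tests therefore demonstrate the correctness of the estimators and
path algorithms, not the realism of any molecular model.

## Constrained scans

At each grid value the scanned coordinate(s) are harmonically restrained
(k = 1000 kcal mol⁻¹ Å⁻²) and all other coordinates minimized (L-BFGS-B)
until the orthogonal gradient is ≤ 0.001 kcal mol⁻¹ Å⁻¹; the reported
energy is the *unbiased* potential at the relaxed point — the restraint is
scaffolding, so profiles are potential-energy profiles.  Because the
scanned coordinate is restrained rather than clamped, relaxed points shift
by the finite-restraint factor s/(2k+s) toward the local minimum; on a
stiffness-1 landscape this is a 5·10⁻⁴ softening of the profile.
Each point warm-starts from the previous relaxed point (ascending order by
default).  This path dependence is a feature: when an orthogonal degree of
freedom switches basins mid-scan, the forward and backward branches
disagree and the profile jumps — the kink diagnostic that signals an
insufficient one-dimensional coordinate.  `profile_kink_report` lists
adjacent-point energy jumps above a threshold; `direction="both"` returns
the lower envelope of the two branches.

## WHAM

Standard self-consistent estimator on shared bins (left-closed [a, b);
a value equal to the final edge is out of range and dropped with a logged
count).  Bin width defaults to 0.02 Å — five bins per window spacing.
Bias energies are evaluated at bin centers with the production force
constant through the same `bias_energy` used by the sampler.  Iteration
stops when max|Δfᵢ| < 10⁻⁶ kcal/mol (f₁ ≡ 0 fixes the gauge); hitting the
iteration cap returns the result flagged non-converged rather than
raising.  Bins with fewer than `min_count` = 1 total samples are masked
and excluded from the min-shift, avoiding −∞.  Disconnected window
coverage is detected (connected components of the windows-over-bins
occupancy graph) and logged, since the per-component PMFs are then only
defined up to per-component constants.

Because the plain fixed point converges slowly on large 2D problems, the
solver first minimizes the equivalent convex likelihood
κ(g) = Σ_b M_b ln Σ_i Nᵢ e^{gᵢ−βUᵢᵇ} − Σᵢ Nᵢ gᵢ with L-BFGS and then runs
the fixed point from that start until the stated tolerance holds — the
convergence criterion, and hence the contract, is unchanged.

Block errors: each window's production series is cut into three contiguous
equal blocks (the series length must divide evenly — enforced), one WHAM
solve per block, blocks aligned by a least-squares constant offset over
the bins occupied in every block, and the per-bin sample standard
deviation (ddof = 1) across aligned blocks reported as the error.
Duplicated blocks give an exactly zero error grid; quadrupling the
production length lowers the spatial-median error.

## Minimum-energy paths on grids

Occupied bins are graph nodes; each node connects to its 4 (default) or 8
nearest neighbours; the edge weight is max(E_a, E_b) — the energy a step
between the two bins must reach.  Two objectives:

- `sum` (default): Dijkstra on summed edge weights, the plain reading of a
  shortest path on this weighted graph.  It requires non-negative node
  energies (the solver rejects grids that are not min-shifted; WHAM PMFs
  always are).  Note a genuine property of this objective: on broad
  plateau-like surfaces it can cross slightly *above* the lowest saddle if
  that shortens the path, because every extra edge adds its weight.
- `minimax`: the bottleneck path minimizing the highest edge crossed; its
  peak provably sits at the lowest possible crossing, i.e. the connecting
  saddle, and it is the variant to use when the transition-state location
  itself is the quantity of interest.

Ties in the priority queue break lexicographically on (distance, node), so
paths are deterministic.  Start/end default to the two lowest distinct
grid-local minima.  The profile's abscissa is the accumulated Euclidean
length between bin centers (the canonical reaction coordinate).
`locate_states` labels interior strict extrema alternately (plateau runs
collapse to their midpoint), reports the barrier as the highest transition
state minus the reference minimum (the first labeled minimum by default —
the state the transfer starts from) and the reaction energy as final minus
reference.  An optional odd smoothing window (edge-replicated moving
average) suppresses bin-scale statistical wiggles; the pipeline applies a
3-point window to WHAM-derived profiles because features below the block
error are noise, and reports on analytic surfaces use no smoothing.

## Chain of states

`reparameterize` resamples the polyline at equidistant arc length
(default 0.01 Å), keeping endpoints exact; the final segment may be short.
`synchronous_chain_minimize` updates all interior points per iteration by
a full-gradient descent step (capped at half the chain spacing per point)
followed by arc-length reparameterization, which absorbs the tangential
component — the net motion of the *path* is therefore orthogonal to
itself.  This string-style realization was chosen after the literal
projected-gradient step (central-difference tangents) proved unstable on
steep slopes: medium-wavelength chain kinks self-amplify through the
tangent estimate and the chain length diverges.  Re-spacing every
iteration is the stabilizer.  Backtracking halves the step whenever the
moved chain's maximum point energy would rise, measured before re-spacing,
making the max-energy-monotone guarantee exact per move (re-sampling can
change the discrete maximum by O(h²·|V''|), which is why it is excluded
from the guarantee).  Convergence is declared when the largest interior
projected gradient — gradient minus its component along the
central-difference tangent — is ≤ 0.1 kcal mol⁻¹ Å⁻¹.  The printed
tolerance this mirrors is dimensionally a gradient, and that is how it is
interpreted here.

`refine_peak` polishes the chain's interior energy maximum to a saddle by
alternating bounded line maximization along the local unstable direction
(initially the path tangent, then the Hessian's negative-curvature
eigenvector) with BFGS minimization in the orthogonal complement, until
|∇V| ≤ 10⁻⁸.  The saddle certificate requires exactly one negative
finite-difference Hessian eigenvalue; an uncertified point is still
returned, flagged.  This is a deliberately simple refinement adequate for
smooth 1–2D surfaces, documented as such — it is not a reimplementation of
conjugate-peak refinement for molecular systems.

## Reaction coordinates

`RCDefinition` is an ordered list of (±1, distance-label) terms; a
registry normalizes the label spelling variants that occur in practice
("P–OD-Asp11" vs "P–O-Asp11", "watO" vs "Wat-O", en-dashes vs hyphens) to
canonical keys.  Both step-2 proton-transfer variants ship
(`OHO_step2` with d(H–OT-Asp11), `OHO_step2_asp13` with d(H–OD-Asp13)):
the source analyses use both and neither is privileged.  The bundled
stationary-state tables carry per-component exactness flags: one printed
row is internally inconsistent by one unit in the last printed decimal,
and the tests assert exact reproduction everywhere else and
one-unit agreement there.  Table comparisons round half away from zero at
the printed precision.  `project_profile` keeps path order — a projection
that doubles back is preserved, and the monotonicity/injectivity report
makes corner cutting visible instead of silently re-sorting.

## Rates

ΔG‡ = kB·T·ln[(kB T/h)/k] and its exact inverse, transmission coefficient
fixed at 1.  Rate units are explicit tags ("1/s", "1/min"); there is no
unit guessing.  The reference conversion — a 20 min⁻¹ turnover at 343.15 K
(the "~70 °C" of the measurement, a choice exposed as a parameter) —
gives 20.9 kcal/mol.

## Pipeline and problem sizes

`run_pipeline` executes landscape → windows → sampling → WHAM (+ block
errors) → minimum-free-energy path → stationary report, writes every
artifact as plain TSV with a config-hash header, and is byte-identical
across reruns with the same master seed.  The bundled `step1_demo`
configuration covers the step-1-like surface with 29×23 windows at 0.1 Å,
2 000 + 6 000 steps per window (stride 10) and 0.05 Å bins — sizes chosen
so the full demonstration completes in about a minute on one CPU while
still showing every stage at realistic density.  Test problem sizes follow
the same principle: the statistical suites use 10⁴–10⁵-step productions
where the claim under test is statistical (variance calibration, PMF
recovery at ≤ 0.15 kcal/mol RMS, error shrinkage), and analytic fixtures
elsewhere.

## Known limitations

- The sampler is Monte Carlo: it shares the Boltzmann measure with MD but
  not its time correlation, so autocorrelation-sensitive error analyses
  (beyond block averaging) are out of scope.
- The summed-weight path objective is length-sensitive (see above); barrier
  *locations* on plateau-like surfaces should use the minimax variant.
- One-bin localization of PMF basin positions is only meaningful when the
  per-bin curvature signal exceeds the statistical noise; the tests choose
  bin widths accordingly.
- `refine_peak` assumes a smooth analytic landscape with an interior
  maximum bracketed by the chain; it is not a general-purpose saddle
  search.
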