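# Methods

## The model class

`psfkit` operates on mass-action kinetic models of signal transduction built
from two reaction shapes: reversible complex formation (A + B ⇌ AB, rates
kon/koff) and enzymatic conversion through an explicit intermediate
(S + E ⇌ SE → P + E, rates kon/koff/kcat), plus three degenerate forms
(irreversible binding, first-order conversion, one-step decomposition).
Every scheme is expanded into elementary single-arrow steps; a step of total
reactant order m carries a rate constant in nM^−(m−1) s^−1. Concentrations
are in nM, time in s — the only unit reading under which the bundled model's
rate constants and totals are mutually consistent.

The central requirement on a model is *weak reversibility* in the
operational sense: every species must be both produced and consumed by some
step. Together with conservation of mass this guarantees that the system
settles to a finite steady state for any constant input, which is what makes
the transfer-function transformation well defined. `check_weak_reversibility`
verifies the property; conserved *moieties* (multiplicity-weighted species
groups) are declared explicitly and checked numerically along trajectories
(drift < 1e−6 relative in the tests).

## Protein signaling functions

A **psf** maps the *total* concentration of a designated input species to
the settled concentration of any target species. For an isolated binding or
(reversible) enzymatic reaction, the curve is a saturating hyperbola in the
input total; embedded in a full system it is reshaped by competing reactions
(a "systemic psf"). Curves are fitted with

    y(x) = y0 + Y · xⁿ / (Cⁿ + xⁿ)

by derivative-free (Nelder–Mead) least squares over (Y, log C, log n, y0),
with a linear fallback chosen when the line fits at least as well or when the
fitted C exceeds 10× the sampled grid maximum — in that regime the sweep only
saw a short section of the full curve and the hyperbolic parameters are not
identified. Falling psfs carry Y < 0. Fit initialization: y0 at the curve's
flat end, |Y| = observed span, C at the half-range grid point, n = 1;
optimizing log C and log n enforces positivity. The signal-transmission
strength at an input level x is the fit's analytic slope, plus the fractional
output change for a stated input factor (for the n = 1 hyperbola at x = C a
doubling of input yields a gain of exactly 1/3, at x = 19C only 1/39).

## Steady state, sweeps and numerical choices

Steady state is defined pragmatically: every species above a floor of
1e−6 nM must change by less than 2% relative over a trailing 100 s window,
checked on a 10 s cadence jointly for all species. Integration uses SciPy's
BDF with the analytic Jacobian of the mass-action rate law (rate constants
in the bundled model span ~1e−12 to 1e2, so a stiff method is mandatory);
default tolerances rtol = 1e−8, atol = 1e−10, chosen so that declared moiety
totals drift by < 1e−6 relative over the longest runs (observed drift is
~1e−13). Negative excursions from the solver are clipped to zero before rate
evaluation. Oracle tests that demand 1e−6 agreement with closed forms use a
tightened criterion (rel. change 1e−7 over 200 s) rather than the pragmatic
default.

Input sweeps integrate each grid point independently from the declared
initial totals with the input's total replaced by the grid value (no
pre-equilibrated basal state); grids are logarithmic by default (n = 20)
so the low end of a hyperbola is resolved. Two-input sweeps produce a
matrix; per-input dependence is quantified by a main-effect variance
decomposition (variance of the row/column means over total grid variance)
rather than a full PCA — with two inputs the first component carries the
same information.

## Delays and the EC band

The delay of a species under an input step is measured by equilibrating at
the pre-step total, applying the step instantaneously at t = 0 (increases
raise the free input pool; decreases drain the free pool first, any
remainder proportionally from the input-containing complexes), integrating
well past settling, and reporting the **last** time the trajectory sits
outside the ±5% EC band around the new steady-state level (EC95 for rises,
EC5 for falls). Using the last band exit rather than the first crossing
makes the measure well defined under transients. The band is relative to
the new steady-state *value* by default — the reading under which decreases
come out slower than increases, because a decaying species must approach a
small number within a small band; a ±5%-of-total-change band is available
as an option (`band="change"`) and is the natural reading for species that
start from zero, where the two coincide.

For the bundled model's delay table the calcium condition matters: with the
declared resting total (1 μM) the calcium-bound cyclase complex keeps a
large slow tail (delays of hundreds of seconds), while under the high-Ca
condition (8 μM) used throughout the sweep analyses its delay collapses to
a few seconds. The delay workflow therefore defaults to total Ca = 8 μM;
both configurations can be run from the CLI.

## Discrete state-change simulation

Measured maximal delays are binned into time scales (default 10/300/600 s,
matching the three delay groups the bundled model exhibits); each species is
assigned the smallest bin covering its maximal delay. The discrete simulator
then advances a piecewise-constant input schedule by setting each species to
its psf lookup value (interpolated linearly in log-input on logarithmic
grids, bilinearly for two inputs) at every multiple of its interval, with
linear interpolation in time between updates. By construction the discrete
trajectory lies inside the psf range and converges to the psf value under a
held input; the companion ODE comparison quantifies the error at the update
times. What the lookup model *cannot* represent is a transient overshoot —
the test suite constructs a fast-binding/slow-sink toy whose ODE response
overshoots its steady state and verifies that the discrete model misses it.

## Modularity

A species is **nonresponsive** to an input when the whole sweep moves it by
less than 10% of its own level (the threshold is configurable; 10% matches
the "no response" wording of the source analysis). A responsive species
becomes an **inactive link** beyond its cutoff input — the level at which its
fitted psf has covered 90% of its full excursion (EC90 for rising, EC10 for
falling targets; for an ideal n = 1 hyperbola the cutoff is 9C). Cutoffs are
computed from the fit's full range, so a linearly-responding species has no
cutoff within the sweep. Modules are connected components of the species
graph restricted to active species, with reaction schemes acting as
conduits. On the bundled model this reproduces: rising inactive-link counts
with rising input (interconnectedness is highest at low input), complete
nonresponsiveness of the receptor/G-protein branch to calcium, and the
saturation ordering in which receptor-proximal species cut off at higher
inputs than distal ones.

## The bundled striatal model

The built-in system is a 40-scheme model of dopamine- and calcium-driven
DARPP-32 regulation in striatal neurons (D1 receptor → Golf → AC5 → cAMP →
PKA on one arm; Ca → calmodulin → PP2B/CaMKII/PDE1 on the other; both arms
converging on DARPP-32 phospho-forms pThr34/pThr75 and on PP2A). Inputs are
total dopamine and total calcium. The PP1 branch of the original published
system is excluded (its release step dissolves a ternary complex in one
step, outside the two reaction shapes used here), and an AMP → ATP
regeneration step closes the nucleotide loop so weak reversibility holds.
Species names are opaque identifiers: each binding row consumes exactly the
stoichiometry it is written with (one Ca per calmodulin-ladder event, four
in the PP2A–Ca association), so the calcium and cAMP contents suggested by
names like Ca2CaM are deliberately *not* declared as conserved moieties.
The PKA holoenzyme bookkeeping does conserve: the regulatory-subunit species
carries multiplicity 2 in the adenine pool, making the full
ATP/cAMP/AMP/complex pool exactly conserved.

## Known limitations

- Three printed delay values for the receptor–ligand complex are ~2× slower
  than this reconstruction produces under every configuration we can
  document; the discrepancy is insensitive to the calcium condition and to
  the EC-band reading and propagates nowhere (the species stays in the
  fastest time-scale bin).
- The reconstructed free-calcium level under the high-Ca condition
  (~103 nM) sits above the 64–69 nM of the source analysis; the
  alternative multi-ion stoichiometry reading overshoots in the other
  direction (~7 nM), so the as-printed reading is kept.
- Whether the two pathway modules separate completely under calcium input
  depends on the response threshold: at the 10% default the
  calmodulin→PDE1→cAMP integration route (12–28% response) keeps the
  active graph connected.
- Steady-state semantics only: sub-resolution input fluctuations and
  transient amplitudes are out of scope for the lookup simulator by design.
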