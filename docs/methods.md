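# Methods

## Problem

`bogeom` performs gradient-free searches for two kinds of critical points of
a molecular potential energy surface (PES):

* the **global minimum (GM)** of the ground electronic state S0 within a
  box-bounded internal-coordinate search space, and
* the **minimum-energy conical intersection (MECI)** between S0 and the
  first excited singlet S1 — the lowest point of the seam on which the two
  states are degenerate.

The motivation for avoiding gradients is that energy oracles of interest —
measurements on noisy intermediate-scale quantum (NISQ) hardware, or
high-level wavefunction methods without analytic gradients — return noisy
or gradient-free energies, which breaks conventional Newton-type geometry
optimization. Bayesian optimization (BO) needs only energy values.

## The campaign loop

Each iteration performs five steps:

0. *(once)* Build an initial dataset of collision-screened geometries with
   oracle energies (`init_dataset`).
1. Fit a Gaussian-process (GP) surrogate to all data so far (`regression`).
2. Propose one candidate geometry by two-stage acquisition maximization
   (`bo_loop.propose_candidate`): draw `n_random = 2000` uniform geometries
   inside the bounds, rank them by acquisition value, keep the top
   `n_select = 200` as starts, locally maximize the acquisition with
   L-BFGS-B under the box bounds from each start, and return the
   best-scoring optimized geometry that has no atomic collision (no atom
   pair strictly closer than 0.5 Å; the comparison is strict, so a pair at
   exactly 0.5 Å is kept). If every optimized geometry collides, the whole
   stage repeats with fresh draws (at most 10 attempts).
3. Evaluate the energy oracle at the candidate (optionally through the
   uniform-noise wrapper).
4. Apply the termination rule (below).

### Objectives

Both searches maximize. The GM objective is −E(S0). The MECI objective is
−C with the penalty cost

    C = (E(S0) + E(S1)) / 2 + (E(S1) − E(S0))² / α.

The first term prefers low-lying geometries, the second drives the states
towards degeneracy; α (kcal/mol) sets the balance. Small α makes the
penalty dominate: every near-degenerate geometry, stable or not, looks
equally good once the objective is standardized, so campaigns drift to
"degenerate but unstable" structures. Large α lets the average-energy term
displace the optimum off the seam. Moderate α (25–75, default 50) works
best; this trade-off is exercised by the test suite on the shipped
6-coordinate benchmark, where the near-degenerate set is a 4-dimensional
manifold and the small-α failure mode is structurally present. On a
2-coordinate surface the degenerate set is an isolated point, so small α is
harmless there — a deliberate illustration that the α sensitivity is a
property of the search-space dimensionality, not of the cost function
itself.

### Acquisition functions

Over the GP posterior mean μ(x) and standard deviation σ(x):

* **PI** (default): the probability of improvement over the incumbent
  f* = best *observed* objective value, P(f(x) ≥ f*) = Φ((μ − f*)/σ).
  At σ = 0 the value is the indicator of μ > f*; a tie counts as no
  improvement so exactly re-proposed points score zero. (A widely
  reproduced typographical form of this formula has the sign of the
  argument flipped, which would be the complement of the stated
  probability; the definition, not the typo, is implemented.)
* **UCB**: μ(x) + β·σ(x) with β ≥ 0 (β = 0.1 is the only setting we found
  competitive with PI, consistent with reports for this class of search).

Local maximization uses analytic gradients of μ and σ with respect to the
coordinates (closed-form for the RBF kernel), convergence tolerance 1e−6
on the acquisition value and an iteration cap of 200 per start.

### Termination

Checks happen at fixed intervals: every 5 iterations for GM, every 50 for
MECI. At a check the running best is stored — the lowest observed E(S0)
over all candidates for GM; for MECI the lowest observed E(S1) among
candidates whose observed gap E(S1)−E(S0) is strictly below 3.0 kcal/mol.
The campaign stops once the stored value is identical at `patience = 3`
consecutive checks ("not updated in three consecutive checks": the first
store counts as the first of these), or unconditionally at
`max_iterations = 1000`. MECI checks at which no candidate passes the gap
filter leave the patience counter untouched; a campaign that never stores
anything ends with status `no_ci_found` rather than an error. Ties never
reset patience (updates must be strict), and among equal E(S1) values the
earlier iteration is kept.

The reported result is the stored best: for GM, the candidate with the
lowest observed E(S0); for MECI, the last stored gap-filtered structure.
Observed (possibly noisy) energies drive both the filter and the ranking,
as they must when the oracle itself is noisy.

## The GP surrogate

Isotropic RBF kernel over standardized inputs, standardized objective,
plus an always-present observation-noise variance (floor 1e−6 in
standardized units) for conditioning and for noisy oracles. Hyperparameters
(length-scale ℓ, signal variance s², noise variance σn²) maximize the log
marginal likelihood by full-batch Adam in log-parameter space: learning
rate 0.2, exactly 100 epochs, initialized at ℓ = 1, s² = 1, σn² = 1e−2.
The fit is deterministic (no random restarts) and is redone from scratch
every iteration; the epoch count is a step budget, not a convergence test,
so the likelihood is only guaranteed not to end below its initial value,
which the tests assert. Cholesky factorization failures escalate a jitter
term before raising a conditioning error. The predictive standard deviation
is that of the latent function (observation noise excluded) and is clamped
at zero against numerical negatives.

## Internal coordinates

Geometries live in Z-matrix internal coordinates: distances (Å), angles
(degrees, [0, 180]), dihedrals (degrees, [−180, 180], IUPAC right-hand
rule, 0° = syn). Conversion to Cartesians places atom 1 at the origin,
atom 2 on +z, atom 3 in the xz-plane; colinear reference frames raise a
degenerate-frame error. Dihedral bounds are treated as a plain box — no
periodic wrap-around during sampling or acquisition optimization — which
matches how such search spaces are conventionally printed and keeps the
optimizer inside one branch. Abstract (non-molecular) spaces are first-class
so that analytic model surfaces can be searched; collision checks are
defined `False` there.

## Shipped oracles

`TwoStateModel` couples two multi-dimensional quadratic diabats V1, V2
(force constants k, minima a/b, offset Δ) linearly through one designated
coordinate, W = c·q_c. The adiabatic energies

    E∓ = (V1 + V2)/2 ∓ sqrt(((V1 − V2)/2)² + W²)

are degenerate exactly where V1 = V2 and q_c = 0, giving a true conical
intersection with a closed-form minimum-energy point whenever the diabats
differ in only one non-coupling coordinate (`analytic_meci`). The
ground-state GM oracle (`reference_gm`) is a dense grid scan plus L-BFGS-B
refinement — a test oracle, not part of the method.

Frozen benchmark parameters:

* **2D** (`benchmark2d`): k1 = (30, 15), k2 = (20, 12), a = (1, 0),
  b = (3, 0), Δ = 10, c = 6 on q2; bounds [−2, 6] × [−3, 3].
  GM at (1, 0) with E = 0; MECI at (2, 0) with E = 30 kcal/mol — well
  separated, both interior, and the MECI region within ~50 kcal/mol of the
  GM, the energy scale typical of small-molecule S0/S1 crossings.
* **6D** (`benchmark6d`): same functional form with six coordinates,
  diabats differing along the first ("tuning") coordinate and coupling on
  the last ("dihedral-like") one; MECI at q = (2, 1, 0.8, −0.5, 0.5, 0)
  with E = 16 kcal/mol, GM at a with E = 0; bounds
  [−6, 10] × [−4, 6]⁴ × [−5, 5]. This surface reproduces the
  dimensionality of a four-atom molecule's internal-coordinate space and
  carries the extended near-degenerate manifold that makes the α trade-off
  visible. Two calibrations tie it to the molecular regime it emulates.
  First, the diabatic offset keeps the moderate-α argmin of C within the
  3 kcal/mol storage filter (gap ≈ 1.8 at α = 50), as observed for real
  small-molecule intersections; a much larger offset would park the α = 50
  optimum just outside the filter and starve the storage rule. Second, the
  bounds are wide enough to include extreme-energy regions (the analogue
  of short-contact molecular geometries at thousands of kcal/mol) and a
  second, far less stable seam point at q1 = −5. These regions are what
  make a too-small α harmful: the squared-gap penalty then spans several
  orders of magnitude, the standardized objective hides the mean-energy
  term from the surrogate, and campaigns stall at degenerate but unstable
  structures — the behaviour real molecular searches show. On a tame box
  (or the 2D surface, whose degenerate set is a single point) small α is
  harmless, which localizes the α sensitivity in the energy range and
  dimensionality of the space rather than in the cost function.

### Noise model

`NoisyOracle` adds independent uniform noise on [−w, +w] kcal/mol (default
half-width w = 2.0, the error magnitude reported for energy measurements on
a present-day superconducting quantum processor) to each state energy.
Draws for E(S0) and E(S1) at the same geometry are independent — whether
hardware errors on the two states correlate is not established, and
independence is the conservative choice. The wrapper owns a seeded stream,
so subtracting a regenerated stream recovers the clean energies exactly,
and campaigns are bit-reproducible from one master seed (sampler, surrogate,
proposal and noise streams are all derived sub-seeds).

## Evaluation

Found-vs-reference deviation is reported as energy differences
(found − reference, kcal/mol) and RMSD (Å) after optimal superposition
(centroid translation + proper rotation via determinant-corrected SVD).
When the reference exists as two mirror-image conformers, the reflected
reference is also superposed and the smaller RMSD reported. Atoms are
matched by Z-matrix identity; there is no permutation search, so
symmetry-equivalent atom relabelings are counted as deviations — a known
limitation.

## What the synthetic benchmarks do and do not show

The analytic surfaces are smooth, exactly quadratic away from the seam,
and noiseless unless wrapped. They validate the machinery — surrogate
correctness, acquisition behavior, the proposal and termination rules,
noise robustness — under conditions where the true optima are known
independently. They do not exercise electronic-structure pathologies
(S1 discontinuities near the intersection at linear-response level,
multiple low-lying intersection seams, basis-set artifacts), nor the cost
profile of real oracles where one energy evaluation dwarfs the BO
overhead. Passing tests therefore certify the optimizer, not any
particular quantum-chemistry backend.

## Problem sizes used by the test suite and acceptance script

Campaign experiments use the full proposal protocol (2000 random draws,
200 optimized starts, 100-epoch refits) on the shipped surfaces, with
initial sets of 20 structures (2D) and 71 structures (6D), three repeat
campaigns per condition (five per condition for the noise comparison), and
an iteration cap of 250 for the 6D MECI campaigns — enough for up to five
termination checks, which the patience rule needs at most two of beyond
the first qualifying check. Initial sets are drawn in `mixed` mode: half
uniform over the bounds, half Gaussian-perturbed copies of the first
diabat's minimum (scatter 0.5 coordinate units per abstract coordinate).
This emulates what cheap reaction-path or dynamics pre-sampling started
from a lower-level-theory minimum actually delivers — broad coverage plus
structures near every low-lying basin — which such campaigns rely on: with
a purely uniform seed the GM search can terminate inside whichever well
the initial draw happens to favour. These sizes keep a full verification run in
the tens of minutes on one CPU while preserving every rule of the method.

## Numerical choices

* Collision threshold comparisons are strict (`<`), so 0.5 Å exactly is
  feasible.
* Standardization falls back to scale 1.0 for constant columns (degenerate
  constant-objective datasets still fit).
* Top-k start selection is deterministic (stable argsort); an optional
  Boltzmann-weighted mode (temperature = score standard deviation) exists
  for comparison.
* Duplicate candidate geometries are legal dataset rows; the GP noise term
  absorbs them.
* `analytic_meci` returns the lower-energy real root of the seam quadratic
  and raises a no-intersection error when the diabats never cross at zero
  coupling.
* Sub-seeds derive from the master seed through `numpy.random.SeedSequence`
  with fixed keys, so campaign j is identical across machines.
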