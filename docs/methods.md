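# Methods

## The model

Two or more macromolecular bodies interact through a pairwise
implicit-solvent potential evaluated over inter-body, body–ion and
ion–ion atom pairs (intra-body pairs are constant under rigid motion and
excluded):

    U(r) = 4·λ·ε_ij [(σ_ij/r)¹² − (σ_ij/r)⁶]  +  k_e q_i q_j exp(−κr)/(ε_r r)

* **Mixing**: Lorentz–Berthelot (σ arithmetic, ε geometric), the
  convention of the amber/gaff force-field family whose parameters the
  user-supplied tables are expected to follow.
* **λ (LJ rescaling)**, default 0.1, range (0, 1]: flattens the landscape
  so a 300–600 K ladder samples body arrangements without melting
  anything.  λ multiplies ε_ij only — charges are never rescaled.
  `rexchange.scan_lambda` reports swap acceptance per rung over pilot
  runs for λ ∈ {0.05…0.3}; the choice of a "reasonable" acceptance is
  deliberately left to the user.
* **κ (inverse Debye length)**, Å⁻¹: computed once from the ionic
  strength (default 0.145 mol L⁻¹, physiological saline) at the
  reference temperature 298 K and **held fixed across replica
  temperatures**.  Recomputing κ per rung would give each rung a
  different landscape and break swap comparability; κ is treated as a
  property of the electrolyte, and this is a logged assumption.
* **ε_r (dielectric)**, default 78.5 (water at 298 K), configurable.
* **Cutoff**, default 12 Å: both terms are truncated *and shifted* to
  zero at the cutoff, keeping the energy continuous so dynamics pick up
  no heating artifact at the cutoff sphere.  With `cutoff=None` the bare
  forms are returned (used by closed-form tests).  A neighbor list is
  not needed at the system sizes this package targets; correctness is
  defined by an O(N²) double-loop oracle in the tests.
* **Boundaries**: no periodic box.  An optional harmonic bounding sphere
  (radius R, stiffness k, default off) keeps mobile ions — and, when
  `confine_bodies` is set, body centers of mass — near the region of
  interest, since an implicit-solvent search samples relative
  arrangement, not bulk solution.

## Rigid-body dynamics

Bodies carry mass, center of mass, a unit quaternion, principal inertia
moments and body-frame angular momentum; world coordinates are exactly
R(q)·x_body + com at all times, so intra-body geometry is preserved to
machine precision by construction.  Integration is BAOAB Langevin:

* translation — velocity Verlet on the COM;
* rotation — the no-squish symplectic splitting: exact single-axis
  free-rotor flows applied in the order (3,2,1,2,3) with half steps on
  the outer axes.  This conserves |L| exactly for a free rotor and gives
  NVE energy drift < 10⁻⁴ relative over 10⁴ steps at dt = 1 fs
  (asserted in the tests);
* Ornstein–Uhlenbeck velocity randomization on the linear and angular
  momentum channels of every mobile body and on the ions.  Friction
  default 1 ps⁻¹ — implicit solvent implies solvent friction; with
  `ThermostatSpec(kind="none")` the integrator is time-reversible NVE.
* **Timestep** default 2 fs: with internal modes frozen, the fastest
  motions are inter-body well oscillations.
* **Degenerate inertia**: point bodies (single atoms) skip rotation
  entirely; linear bodies suppress rotation about the degenerate axis.
* **Units**: Å, ps, g mol⁻¹, kJ mol⁻¹, elementary charge, K throughout;
  the single conversion constant (1 kJ mol⁻¹ = 100 g mol⁻¹ Å² ps⁻²)
  lives in `rbrem.units`, and eV-denominated spring constants are
  converted at the API boundary (5 eV Å⁻² → 482.4 kJ mol⁻¹ Å⁻²).

## Parallel tempering

Replicas hold a strictly increasing temperature ladder (default
300/400/500/600 K).  After every `swap_interval` (default 1 ps) of
dynamics, neighbor rungs of alternating parity attempt Metropolis swaps
on the total sampled potential; accepted pairs exchange *temperatures*
(velocities rescaled by √(T_new/T_old)), so temperatures migrate between
replicas while the ladder multiset is conserved at every instant.
Replicas advance serially round-robin with independent counter-based RNG
streams, so results are independent of execution order and a parallel
runner would be bit-identical.  The lowest-energy configuration over all
recorded samples is tracked continuously and is the product of the
search.  The acceptance rule itself is the canonical parallel-tempering
Metropolis criterion — the natural choice given the method's replica-
exchange lineage.

## The protocol loop

One round = parallel tempering → lowest-energy snapshot → relaxation at
λ = 1.  The relaxation stage of the reference workflow is explicit-
solvent all-atom dynamics, which is *not* reimplemented: each round
exports a handoff package (best-configuration PDB plus a YAML config
with λ restored to 1) and can ingest an externally relaxed PDB; absent
one, a short internal implicit-solvent NVT run at 300 K with λ = 1
keeps the pipeline runnable end to end.  Rounds stop early when the
superposed all-atom RMSD between successive best configurations falls
below the convergence threshold (default 2.0 Å — "the same or very
similar" quantified; a non-finite threshold disables early stopping).
The reference stage schedule is 40 ns equilibration, three rounds of
16 ns tempering (counted per replica) + 4 ns relaxation, 16 ns
production — 116 ns total; `total_duration` implements exactly this
arithmetic.

## Steered pulls and Jarzynski

The collective variable is the RMSD of a chosen atom set from a
reference geometry; by default the optimal (Kabsch) superposition is
removed first, since without alignment rigid drift of the group would
masquerade as unfolding — the reference workflow does not state its
convention, so both are implemented behind the `align` flag.  The bias
U = ½k(ξ − c(t))² moves its center linearly; work is accumulated as the
discrete form of ∫(∂U/∂t)dt (the restraint-center displacement energy at
fixed coordinates), and the gradient of the fitted RMSD is exact at the
superposition optimum by stationarity, with forces set to zero below
ξ = 10⁻⁸ Å to handle the origin singularity.  Default schedule: 0 → 25 Å
at 1.25 Å ns⁻¹ with a 5 eV Å⁻² spring (a 20 ns pull).

The pulled group is propagated as flexible point particles under a
harmonic elastic network built from its starting geometry (all pairs
within 8 Å, default stiffness 100 kJ mol⁻¹ Å⁻², atoms freezable as
anchors) — a CV on a fully rigid body would be constant.  Nonbonded
forces from the static environment on the pulled group are not included;
the module's purpose is the schedule/work/Jarzynski machinery, which is
what the tests validate.  `jarzynski_estimate` computes
ΔF = −k_BT ln⟨e^(−W/k_BT)⟩ with log-sum-exp stabilization; a single work
value is returned as-is with a `single_pull` flag, since exponential
averaging of one pull is vacuous.

## Synthetic inputs and what the tests do (and do not) show

All test inputs are generated by `builders`:

* **Nanotubes** — zigzag (n,0) only, radius a·n/(2π) with a = 2.46 Å;
  the axial rise is adjusted so every C–C bond measures exactly a/√3
  after rolling (the flat-sheet mapping would shorten rolled chords by
  ~0.005 Å).  Tip functional groups are *not* synthesized — the linker
  chemistry is not specified well enough to fabricate — so
  functionalized tubes enter as ordinary PDB bodies.
* **Telomeric sequence** — the printed strands GGG(TTAGGG)ₙ and
  CCC(ATTCCC)ₙ, emitted verbatim; 3-D duplex coordinates are out of
  scope.
* **i-motif fixture** — a geometric test object, not a folded molecule:
  six stacked C:C⁺ pairs, each presenting three parallel donor–acceptor
  contacts at 2.9 Å with linear D–H···A geometry, 3.1 Å stacking rise.
  Only the hydrogen-bond-bearing atoms have meaningful geometry, which
  is exactly what the hydrogen-bond counter (default criterion: heavy
  distance ≤ 3.5 Å, ≤ 20° deviation from linearity) and the RMSD CV
  need.
* **Toy systems** — one- to few-atom rigid bodies with configuration
  spaces small enough for brute-force scans.

Consequently, passing tests demonstrate that the machinery is correct —
energies match an independent double loop to 10⁻⁹, the integrator is
symplectic and canonical (KS test against the exact radial Boltzmann
density), tempering reproduces its analytic acceptance law and finds
grid-scan minima that a single 300 K walker cannot reach, and pulls
recover analytic free-energy differences.  They do **not** demonstrate
force-field realism for DNA or nanotubes: per-atom charges and LJ
parameters are user data (the reference parameterization is
amber-derived and unpublished), and the package ships only coarse toy
tables.

## Problem sizes and numerical choices in the test suite

Chosen as desk-scale defaults: the Boltzmann check samples 10⁶ Langevin
steps (2 ns at 2 fs) of a probe ion around a frozen LJ site, thinned to
~475 samples; the double-well search runs 4 replicas × 200 ps against a
0.25 Å grid-scan oracle, with the barrier set to ~12 k_BT at 300 K so a
single-temperature run of equal length stays trapped while the hot rungs
cross within tens of ps; the Jarzynski ensemble is 200 pulls of 5 ps
each in a trap translated far from the CV origin (radial-entropy
correction ~0.5 kJ mol⁻¹, well inside the 2 k_BT acceptance band); the
quasi-static pull (2 ns) is compared both to the two-spring closed form
½·k_eff·Δ(c−r₀)² (5%) and to a radial-quadrature partition function
(1%).  All stochastic tests are seeded and deterministic.

## Known limitations

* Explicit-solvent stages are handoff contracts, not simulations; the
  internal fallback relaxes with the same implicit model at λ = 1.
* No reciprocal-space electrostatics, no polarizability, no bonded
  terms; the screened-Coulomb form is the model, not an approximation
  toggle.
* `smd` ignores environment nonbonded forces on the pulled group.
* Chiral (n,m≠0) nanotubes, mmCIF input, bond perception and
  protonation-state assignment are out of scope (protonated and neutral
  cytosine variants are distinct inputs/tables).
* The hydrogen-bond counter needs resolvable hydrogens for the angle
  test and falls back to distance-only otherwise.
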