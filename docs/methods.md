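# Methods

## Model

The simulation is a lattice kinetic Monte Carlo model of multivalent
protein self-assembly.  One particle stands for one sticker-spacer chain;
its internal degrees of freedom are integrated out into three parameters:
a valency λ (number of saturable sticker bonds it can engage, typically
3–6 for multivalent proteins), a specific-bond energy ε_sp, and a weak
isotropic contact energy ε_ns that mimics the spacer/linker attraction.
All energies are in kT (there is no separate temperature parameter), all
rates in s⁻¹, and the lattice constant is 1.

Particles occupy distinct sites of an L × L square lattice with periodic
boundaries and a von Neumann (4-site) neighborhood.  The state is the
occupancy grid plus a *multiset* of specific bonds over adjacent particle
pairs: two neighbors may share more than one bond provided neither side
exceeds λ, reflecting that each chain carries several adhesive domains.
Every occupied adjacent pair additionally contributes one ε_ns contact
(once per pair, not per direction).

### Events and rates

* **Monomer hop.**  Each empty neighboring site is one event at rate
  k_diff·exp(−E_p), with E_p = (engaged bonds)·ε_sp + (occupied
  neighbors)·ε_ns the particle's *total* interaction energy.  A hop severs
  all bonds and contacts of the mover, so the Boltzmann factor prices the
  full escape from its cage.  The default convention is rate-per-direction
  (an isolated particle leaves at total rate 4·k_diff);
  `move_rate_convention="total"` divides by 4.
* **Cluster translation.**  Every adjacency-connected cluster of size
  S ≥ 2 may translate rigidly by one site, per direction, at rate
  k_diff/S — larger droplets diffuse proportionally slower.  A direction
  is feasible only if every target site is empty or belongs to the same
  cluster; colliding translations are simply absent from the event list,
  so clusters merge by diffusing into adjacency, not by overlap.  Size-1
  "clusters" are excluded (their motion is the monomer hop).
* **Bond formation** at rate k_bond per unordered adjacent pair with
  spare valency on both sides (one event per pair, not per free slot).
* **Bond breakage** at rate k_break = k_bond·exp(−ε_sp) per bond,
  counting multiplicity.  k_break is always derived, never stored, so the
  bond-level detailed-balance ratio exp(ε_sp) holds by construction.

Blocked moves are never enumerated: under a variable-time-step scheme a
null event would silently stretch the time axis.

### Gillespie dynamics

Each step re-enumerates the full feasible event set, draws
δt = −ln(z₂)/r_total (z₂ uniform in (0,1], drawn first), then selects the
event at position z₁·r_total in the cumulative rate list.  Re-enumeration
after every event is the correctness baseline; the compiled kernel
(`_kernel.py`) keeps exactly these semantics on flat arrays and is proven
event-for-event equivalent to the readable reference implementation on
randomized states (tests).  Two kernel-level devices do not change the
process law:

* equal-rate monomer hops of one particle are stored as a single
  aggregate entry whose interval is subdivided exactly at draw time;
* at snapshot boundaries the kernel stops without firing and redraws the
  waiting time on resumption — exponential waiting times are memoryless,
  so the restart is statistically exact.

Each trajectory uses one named RNG stream (`default_rng((seed, 7919))`)
for the dynamics, decoupled from the stream that places the initial
configuration (`default_rng(seed)`); identical seeds give bit-identical
trajectories within an engine.  The two engines consume their streams
slightly differently around snapshot ticks and accumulate rates in
different orders, so they are statistically — not bitwise — equivalent,
and the suite checks them against each other only through distributional
tests and the shared enumeration oracle.

## Observables

* **Clusters** are connected components of occupied sites (adjacency, not
  bond topology), labeled with the Hoshen-Kopelman union-find scheme and
  canonically ordered (descending size, ties by smallest member id).
  Adjacency is also what the cluster-translation events use; since every
  bond joins adjacent sites, bonded particles are always co-clustered,
  and a bond-connectivity definition would only subdivide clusters whose
  members touch without bonding — a transient situation at the studied
  densities.  We use the adjacency definition uniformly.
* **L_clus** = (largest cluster size)/N_tot.  **S_clus** distributions are
  pooled over snapshots and replicates into right-inclusive bins on
  (0, 1] (20 by default).
* **Intra-cluster density** φ_clus = S/(πR_g²) uses the 2D radius of
  gyration of the member sites as the droplet disk area, the direct 2D
  analogue of a volume-based density.  Clusters are first unwrapped
  across the periodic seam by BFS with minimal-image offsets.  Sizes
  below 4 give a degenerate R_g and return NaN; clusters spanning ≥ L/2
  along either axis are flagged percolating and excluded from droplet
  statistics.  Reported as φ_clus/φ_lattice: ≫1 for droplets, →1 for a
  system-spanning network.
* **Exchange times.**  A burial opens when a particle reaches full
  coordination (4 occupied neighbors) and closes when it next reaches 0;
  the completed passage times pooled over particles and replicates give
  the mean first-passage exchange time, the model's analogue of FRAP
  recovery.  Repeated burials never nest.  Burials still open at t_end
  are counted as censored and excluded from the mean — censoring can only
  bias the naive mean *low*, so a Kaplan-Meier restricted-mean lower
  bound that includes the censored intervals is provided as a cross-check,
  and the censoring fraction is always reported.  Events are pooled
  across particles (a per-particle average would weight rarely-buried
  particles equally with droplet cores); per-particle grouping is
  available through the logged particle ids.
* **Phase classification** of a replicate-averaged parameter point:
  *macrophase* when mean L_clus ≥ 0.5 (largest cluster holds at least
  half of all monomers), *NoPS* when mean L_clus ≤ max(5/N_tot, 0.05)
  *and* mean bonds per particle < 0.5 (largest cluster at the
  few-particle level with negligible crosslinking), otherwise
  *microphase*.  The 0.5 macro threshold is the operational
  system-spanning criterion; the NoPS cutoffs are package choices sized
  to the random-adjacency background at the studied densities, and all
  three are keyword arguments, not constants.

## Parameter defaults

| parameter | default | meaning |
| --- | --- | --- |
| k_diff | 1 s⁻¹ | free-diffusion rate; the fundamental timescale — only k_bond/k_diff matters |
| k_bond | 1 s⁻¹ | bond-formation rate per eligible pair |
| ε_ns | 0.35 kT | weak spacer attraction, far below the ~1.76 kT lattice-gas condensation threshold, so clustering is sticker-driven |
| L | 100 (50 in the study-condition runs) | lattice side; a convention, chosen ≫ cluster sizes |
| t_end | 7200 s | 2 simulated hours, a biologically relevant window |
| snapshot_interval | none | record only initial and final states unless asked |

The lattice size and the periodic boundary condition are conventions of
this implementation (boundaries chosen to match the usual simulation-box
convention and to avoid edge effects in the 4-neighbor burial criterion);
both are configurable.  L ≥ 3 is required for dynamics so that adjacency
is unambiguous.

## Sweeps and seeding

Sweeps run the Cartesian grid with each replicate seeded as
`SeedSequence((base_seed, cell_index, replicate_index))` truncated below
2³¹, so results are independent of execution order and any cell can be
reproduced in isolation.  Replicate failures are recorded per cell and do
not abort the sweep.  The critical interaction strength ε* of a sweep row
is the smallest grid ε_sp whose replicate-mean L_clus reaches 0.5 (NaN if
never reached); the diffusion scan varies k_diff at fixed k_bond and
fixed simulated duration, mimicking a solvent-viscosity change.

## Bead-spring evaluators

The off-lattice companion force field is implemented as static energy
evaluators (no integrator): harmonic stretching k_s·Σ(r−r₀)² over
consecutive beads (k_s = 5 kT/Å², r₀ = 4.5 Å for chain bonds; a
`half_prefactor` flag switches to the ½k(r−r₀)² convention, since the two
conventions differ by a factor 2 in the quoted ~4 kT bond-breakage energy
and the literature uses both); cosine bending κ·Σ(1−cos θ) (κ = 2
kcal/mol); and a 12-6 Lennard-Jones with plain truncation at 2.5σ
(σ = 4.2 Å linker, 20 Å domain, Lorentz arithmetic mean for mixed pairs —
a package choice), excluding directly bonded pairs.  Specific bonds form
stochastically between free complementary domains within 22.5 Å (each
domain holds at most one bond; candidate pairs are visited in RNG-shuffled
order for tie fairness) and break with probability 1 beyond 2.2 Å of
stretch, or never in the irreversible mode.  Internal energies are
kcal/mol; spring constants quoted in kT/Å² convert at 310 K
(1 kT = 0.61596 kcal/mol).  All quantities are rotation- and
translation-invariant to 1e-8 relative (tested under random rigid
transforms).

## Problem sizes in the test suite

The heavy checks run at the study conditions (λ=5, φ_lattice=0.04, L=50,
k_bond=k_diff=1 s⁻¹) with replicate counts sized for a laptop-scale run:
20 trajectories of 10 simulated hours for the exchange-time ratio, 10
replicates per grid point for the ε_sp scan, 3–8 replicates for the
control, valency-ordering, diffusion and convergence checks.  Statistical
assertions are phrased with the corresponding Monte-Carlo error bands
(3σ binomial bands, bootstrap confidence intervals, KS tests at
α = 0.01) and fixed seeds.

## What the simulations do and do not show

The generator-free design (all inputs are parameters) means every result
is a property of the model, not of data.  The model deliberately omits:
chain conformational degrees of freedom (one lattice particle per chain —
linker stiffness and solvation effects enter only through ε_ns),
heterotypic mixtures (one species), 3D geometry (the burial criterion and
densities are 2D), hydrodynamics, and any coalescence pathway other than
diffusion-into-contact.  Conclusions about droplet *size distributions
versus time* therefore transfer to real systems only at the level of
mechanism (valency exhaustion, kinetic trapping, diffusion-limited
growth), not of absolute numbers.  The bead-spring module evaluates
energies of supplied conformations; it does not generate dynamics.

One finite-size caveat: at the default system sizes (10²–10³ particles)
the moderately-bonded multi-cluster state is stationary on the 2–4 h
window (mean L_clus changes by < 0.01), but in the strongly-bonded
droplet regime (ε_sp ≳ 3 kT) the size-scaled cluster-diffusion channel
still merges droplets occasionally, so the mean largest-cluster fraction
creeps upward on multi-hour windows.  With only a handful of droplets in
the box a single merge moves L_clus by tens of percent; convergence
statements therefore refer to the multi-cluster microphase band, and
absolute coarsening rates at strong bonding should be read as
system-size dependent.
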