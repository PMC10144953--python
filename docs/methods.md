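# Methods

## Model

The system is a melt of coarse-grained single-head/single-tail lipids
(N_H hydrophilic H beads followed by N_T hydrophobic T beads on a linear
chain) mixed with single-bead nanoparticles (N), in a cubic periodic box
of side D at total bead density ρ.  All quantities are in reduced DPD
units: lengths in the pair cutoff r_c, energies in k_BT, masses in the
bead mass m, time in τ = √(m r_c²/k_BT).

Pair forces are the standard DPD triple — soft conservative repulsion
a_ij (1 − r/r_c) r̂, pairwise drag −γ w²(r)(r̂·v_ij) r̂ and random kicks
σ w(r) ζ_ij Δt^(−1/2) r̂ with w(r) = 1 − r/r_c — acting only inside the
cutoff.  σ² = 2 γ k_BT makes drag + noise a momentum-conserving
thermostat.  Bonded beads feel F = k_s (1 − r/r_s) r̂; head-bead triples
feel the gradient of k_θ (θ − θ₀)².  Integration is the modified
velocity–Verlet scheme: positions advance with the current force, the
new force is evaluated at a predicted velocity v + λΔt f, and the
velocity is corrected with the mean of old and new forces.

### Parameters (defaults)

| parameter | value | units | meaning |
|---|---|---|---|
| a_ii / a_ij | 25 / 100 | k_BT/r_c | like/unlike repulsion (χ = 0.286·Δa ≈ 21.45) |
| γ, σ | 4.5, 3.0 | reduced | thermostat (σ² = 2γk_BT enforced) |
| k_s, r_s | 120, 0.7 | k_BT/r_c², r_c | bond spring |
| k_θ, θ₀ | 6, π | k_BT, rad | head bending |
| Δt | 0.01 | τ | time step |
| λ | 0.65 | – | velocity-prediction factor (empirical choice for σ = 3) |
| ρ | 3 | beads/r_c³ | bead density (the standard DPD convention matching a_ii = 25) |
| D | 30 | r_c | production box side |
| φ_NP | 0–0.15 | – | nanoparticle count / D³ |

ρ is a convention, not a measured quantity: a_ii = 25 at ρ = 3
reproduces water-like compressibility in the DPD literature, so ρ = 3
is fixed and nanoparticles *displace* lipid beads at constant total
density, n_lipids = round((ρD³ − N_NP)/(N_H+N_T)).

### Numerical choices

* **Pair noise.** ζ_ij is generated by a counter-based hash
  (splitmix64 of seed, step, i, j with i < j canonical) rather than a
  sequential RNG stream.  One draw per pair per step is shared
  antisymmetrically, so momentum conservation is exact by construction,
  results are independent of pair-iteration order (the cell-list and
  all-pairs paths agree to round-off), and every run is reproducible
  from its seed.  The noise distribution is Gaussian(0,1) by default
  with a unit-variance uniform option; both are valid DPD noises.
* **Neighbour search.** A linked-cell list with cell edge ≥ r_c,
  rebuilt every step (Δt = 0.01 keeps displacements ≪ r_c), emitting an
  explicit in-range pair list consumed by a single pair-physics kernel;
  boxes with fewer than 3 cells per side fall back to the all-pairs
  path.  Kernels are numba-compiled.
* **Coincident beads.** The soft potential is finite at r = 0 but the
  force direction is undefined: overlapping *non-bonded* pairs get zero
  force and a log entry; a zero-length *bond* is an error (bonded beads
  must never coincide under the spring).
* **Straight angles.** At θ = θ₀ = π the 1/sin θ factor in the bending
  gradient cancels against (θ − θ₀); the implementation clamps sin θ
  from below and obtains the correct zero-force limit at the potential
  minimum.
* **Dissipative force under the integrator.** Evaluated once per force
  computation at the predicted velocity; no self-consistent iteration.

## Observables

* **Density profiles** are per-species histograms normalised by the bin
  volume (axial: D·D·Δz; radial: annulus volume), conserving counts
  exactly.
* **Order parameter.** ⟨P₂(cos θ)⟩ with θ between the chain direction
  and z.  The chain direction is the unit vector from the first head
  bead to the last tail bead of the bond-unwrapped chain (a head-segment
  option exists); a chain is binned by its first head bead's z.  Empty
  bins are NaN, never zero.
* **Gyration tensor.** Per chain, the second moment of the unwrapped
  bead positions about the chain centre of mass (bead-averaged); the
  reported component is the square root of the chain-averaged squared
  component.  This is the only reading of the chain-count normalisation
  that yields chain-sized components.
* **Pressure and tension.** p_αβ = (1/V)[Σ m v_α v_β + Σ_pairs F_ij,α
  d_ij,β] with minimum-image separations.  The dissipative and random
  pair forces are included in the instantaneous virial by default (the
  pair sum runs over all pair forces); a conservative-only option is
  provided since conventions differ.  The three-body angle term is
  decomposed onto its two bond vectors — exact because the three angle
  forces sum to zero.  σ_z = p_zz − (p_xx + p_yy)/2.  The z-resolved
  profile uses the Irving–Kirkwood line-segment partition (pair virial
  spread over slabs ∝ path length inside each slab; kinetic part binned
  by bead position), which makes the slab-width-weighted mean equal the
  global σ_z identically; a cheaper midpoint-assignment option shares
  the same identity.
* **Peak/domain extraction.** Local maxima of the tension profile are
  split into large/small by a two-means threshold on peak heights;
  consecutive large-peak spacings are assigned to head or tail domains
  by the dominant bead species between them, and per-type means are the
  domain sizes.

## Synthetic fixtures

Every analysis stage is testable in seconds against configurations with
closed-form expectations: an ideal gas (flat density ρ, kinetic
pressure ρk_BT, σ_z = 0), rigid chains with prescribed orientation
distributions (⟨P₂⟩ exactly 1, −0.5, or the sample mean), collinear
chains (Rg along the axis = √(s²(n²−1)/12) for spacing s), a perfect
lamellar stack (square-wave density, order parameter 1), a filled
cylinder (flat inside, zero outside), and a two-species half-box slab
(positive tension localised at its two interfaces after a brief
relaxation).  Each fixture carries its expectation values, and all are
deterministic per seed.  What the fixtures do *not* emulate: thermal
interface roughness, finite-χ interpenetration, chain-conformation
distributions — agreement on fixtures validates the estimators, not the
equilibrium physics, which is exercised by the dynamic tests below.

## Validation and problem sizes

The test suite validates, at desk scale (seconds to a few minutes per
test):

* per-pair force laws against closed forms and a central-difference
  gradient oracle for the bending term;
* the integrator against the exact ballistic limit and a 100×-finer
  time-step reference for a bonded-pair oscillation;
* momentum conservation (< 10⁻⁸/bead over 10⁴ steps with all force
  terms active) and cell-list/all-pairs equivalence (10⁻¹², N ≤ 200);
* the thermostat: the pure a = 25, ρ = 3 fluid (N = 3000, 10⁴ steps)
  holds kinetic temperature 1.00 ± 0.03;
* the equation of state: the measured excess pressure of the same fluid
  is within 10% of the Groot–Warren fit 0.101·a·ρ².  (The measured
  coefficient at ρ = 3 is ≈ 0.092 — reproduced independently here by a
  Metropolis Monte Carlo estimate of the same potential — consistent
  with 0.101 being the large-density asymptote of the fit.)
* the exact slab/global tension identity and all fixture expectations.

The nanoparticle-concentration trend is tested at a deliberately small
scale: D = 18 (one lamellar period, N ≈ 17,500), preassembled stack,
6000 steps, plateau = final half of the tension series, comparing
φ_NP ∈ {0, 0.05, 0.15}.  Two properties of this scaled system matter:

1. **Chain stiffness.** With bending applied to the head triple only,
   the preassembled flat stack loses long-range lamellar order within
   ~20 τ at D = 15–18 while staying microphase-separated locally
   (unlike-contact fraction ~0.06 vs ~0.36 for a mixed melt); flat
   lamellae of a head fraction-0.23 chain re-anneal only on the
   multi-thousand-τ timescale of the full protocol.  The scaled trend
   test therefore stiffens all triples (`angle_scheme="all"`, a
   documented configuration of the builder), which makes the lamella
   indefinitely stable at this size.
2. **Box strain.** A one-period box pins the lamellar period, so the
   absolute σ_z carries a strain offset.  The asserted trend is the
   monotone decrease of the interfacial-stress *magnitude* |σ_z| with
   φ_NP, which is the scale-robust form of the decreasing-tension
   result.

What this scaled test does **not** show: the absolute plateau tensions,
the growth of Rg_zz and of the head-domain size with φ_NP — those
emerge from the period adjusting to the nanoparticle load, which a
pinned one-period box suppresses.  They require the full-scale
protocol (D = 30, 3×10⁵ steps, several seeds), which
`dpdmelt.experiment.run_experiment` drives end to end but which is an
overnight computation.

## Known limitations

* Melt only — no explicit solvent beads; single-tail architecture only.
* Nanoparticles are single beads; no size or shape variation.
* Tension analysis assumes planar (z-normal) interfaces; no stress
  analysis in curved/hexagonal geometry.
* The two ζ-noise options cover the common conventions, but no
  correlated or non-Markovian thermostats.
* Phase identification is by inspection of profiles, not automated.
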