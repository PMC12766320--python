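# Methods

## The model

`nemp` implements a machine-learned interatomic potential based on
message passing with rotationally equivariant features, in which the
Clebsch–Gordan (CG) tensor product — the expensive step of equivariant
architectures — runs once per *atom* instead of once per *neighbor pair*.
Each atom couples its own equivariant features with those of a *virtual
summed node* that aggregates its neighbors' features under learned edge
coefficients.  All tensors entering the product have shape
(N_atom × N_lmc × N_c), where N_lmc = (l_max+1)² counts the angular
slots and N_c the channels; the edge-space scheme that couples every
neighbor pair individually carries an extra N_neigh axis on both
operands, so at a coordination of 10 it allocates and multiplies ten
times as many elements.  The package contains a single-layer
edge-equivariant reference (`nemp.eemp`) that shares every convention and
is used as the correctness and complexity oracle for that claim.

### Architecture

For a configuration with atomic numbers Z and positions R (Å):

1. **Pair embedding.**  A learned per-element vector e_Z feeds a
   two-layer perceptron on the symmetric pair combination
   [e_i + e_j, e_i ⊙ e_j], giving a pair representation σ_ij; a second
   perceptron maps σ_ij to three coefficient heads c^R, c^χ, c^ρ (each of
   width N_c).  σ depends only on the unordered element pair.
2. **Radial basis.**  R_n(r) = sin(f_n · r/r_c)/r · f_cut(r), with
   trainable frequencies f_n initialised at nπ and a degree-6 polynomial
   envelope f_cut with f(0)=1 and vanishing value, first and second
   derivative at r_c.  Radial features are gated per channel by c^R.
3. **Initial layer.**  An edge network F_edge (two-layer perceptron with
   SiLU, or a single affine map in the `linear` variant) maps
   [c^χ, c^R ⊙ R(r)] to edge coefficients χ⁰ with one slot per l plus one
   invariant slot, multiplied by f_cut so every edge quantity vanishes
   smoothly at the cutoff.  Node equivariants are EC-weighted spherical
   harmonic sums ψ⁰[i, lm, c] = Σ_j χ⁰[ij, l, c] Y_lm(r̂_ij); node
   invariants are the plain EC sums.
4. **Message-passing layer t** (repeated T times):
   a. edge invariants from the neighbor features,
      IJ_ρ[ij, l, c] = Σ_m Y_lm(r̂_ij) ψ[j, lm, c];
   b. refined ECs χᵗ = F_edge([c^ρ, c^R ⊙ R, χ^{t−1}, IJ_ρ]) · f_cut,
      partitioned into ψ-, ρ- and virtual-node subsets;
   c. node invariants: the EC sums together with the contraction
      Σ_m B[i, lm, c] ψ^{t−1}[i, lm, c] per l, where
      B[i, lm, c] = Σ_j χᵗ_ψ[ij, l, c] Y_lm(r̂_ij);
   d. central-node equivariants: B itself;
   e. virtual summed node: Ĩ[i] = W_{Z_i} · Σ_j χᵗ_∼[ij] ⊙ ψ^{t−1}[j],
      with an element-dependent channel-mixing matrix W;
   f. message M[i] = B[i] ⊗_CG Ĩ[i], a channel-wise tensor product with
      one learnable weight per coupling path (l1, l2)→lf and channel;
   g. ResNet update ψᵗ = ψ^{t−1} A_{Z_i} + M B_{Z_i} with element-dependent
      channel mixes (A initialised near identity, B small).
5. **Readout.**  A per-element two-layer perceptron maps the
   concatenation of all layers' node-invariant features to an atomic
   energy, plus a learnable per-element reference energy initialised by
   least squares on the training compositions.  E = Σ_i E_i.

Forces are exact derivatives −∂E/∂R obtained by reverse-mode automatic
differentiation through the whole graph (`nemp.autodiff`, a small
tape-based engine on numpy whose vector-Jacobian products are themselves
tape operations, so the mixed second derivatives needed for force-loss
training come out of the same machinery).

### Symmetry guarantees, including bit-level ones

* Translation: only displacement vectors r_ij enter; the energy is
  invariant to machine precision for arbitrary shifts, and bit-identical
  whenever the shift preserves the displacement vectors bitwise (tests
  use dyadic-grid positions, where this is decidable).
* Rotation: real spherical harmonics with real-basis CG coupling; every ψ
  block transforms by the real Wigner-D matrices (the test oracle
  `wigner_d_real` satisfies Y(R·u) = D(R) Y(u) by construction), and the
  energy is invariant to ≤1e−10 eV in float64.
* Permutation: *bit-exact*, by canonicalising every floating-point
  accumulation order: edges are sorted per node by (distance, vector),
  segment sums accumulate in that order, atomic energies are sorted by
  value before the total-energy sum, and the single output-width-1 matrix
  product in the readout avoids the BLAS gemv kernel (whose results
  depend on row order at the last ulp).
* Smoothness: every edge quantity carries the cutoff envelope, so E and F
  are continuous as neighbors cross r_c (tested at the 1e−8 eV level over
  a 1e−6 Å crossing step).

### Real-basis algebra conventions

Real spherical harmonics in the standard Condon–Shortley-free convention,
ordered m = −l..l (slot l²+l+m).  Complex CG coefficients come from the
Racah closed form evaluated in exact rational arithmetic under the square
root; real-basis blocks are obtained by conjugating with the
complex→real change-of-basis matrices, with a fixed −i phase applied to
the blocks of odd l1+l2+lf (which the conjugation leaves purely
imaginary).  Each (l1,l2)→lf block is orthonormal.  There is no parity
label: all (l1, l2) → lf ≤ l_max couplings are admitted, with one
learnable weight per path and channel.  Wigner-D blocks are built from
z-y-z Euler angles and the explicit small-d sum, conjugated to the real
basis; sympy's Racah and small-d implementations serve as independent
oracles in the tests.

### Defaults

l_max = 2, T = 3 layers, N_c = 32 channels (16 in the benchmark fits
below), r_c = 5.0 Å, envelope degree p = 6, hidden width 32, float64 for
inference and testing, float32 for training throughput (the deployment
precision; gradient agreement with float64 is ~1e−6 relative).  A single
integer seed controls parameter initialisation, data splits and batch
order; training at fixed precision and thread count is bit-reproducible.

## Synthetic data: what it emulates and what it does not

`nemp.synthetic` generates labeled datasets from analytic potentials so
that the full train/evaluate/MD loop runs with exactly known ground
truth.  Pair terms (Lennard-Jones, Morse) are labeled with closed-form
forces; the three-body term is a *hub-localised Axilrod–Teller*
triple-dipole: for every hub atom and unordered pair of its
within-cutoff neighbors, the canonical AT form
C9 (1 + 3 cosθ_i cosθ_j cosθ_k)/(r_ij r_ik r_jk)³ gated by the cutoff
envelope of the two hub-adjacent sides, with the third side given by the
law of cosines and deliberately *not* cutoff-limited.  All terms carry
the same smooth envelope the model uses, so the labels live in the same
finite-cutoff function class and fits have no truncation floor.  Forces
for the three-body term are exact tape derivatives; a closed-loop line
integral of the force (Simpson quadrature) vanishes, confirming the
labels are conservative.

The benchmark suite (`make_benchmark_suite`) fixes four datasets:

* `lj_dimer_scan` — 60-point radial curve of an Ar-like LJ dimer
  (ε = 0.1 eV, σ = 2.5 Å, r_c = 5 Å); a pure capacity/overfit probe.
* `morse_trimer` — 300 displaced Morse triangles (D_e = 0.5 eV,
  a = 1.5 Å⁻¹, r_e = 2 Å).
* `at_cluster_8` — 625 "star clusters": one hub atom plus seven shell
  atoms at independent random radii (2.65–2.95 Å) and random directions
  with every shell–shell separation ≥ 3.0 Å, labeled with LJ
  (ε = 0.05 eV, σ = 2.2 Å) plus the hub-AT term (C9 = 2800 eV·Å⁹) at
  r_c = 3.0 Å.
* `lj_box_periodic` — 100 frames of 32 LJ argon atoms in an 11.45 Å
  periodic cube.

The star-cluster construction is the point of the angular probe and was
arrived at deliberately.  Three designs that look like angular probes are
not: (i) a three-body term on a within-cutoff-complete graph is a
function of graph-visible distances, so an invariant (l = 0)
message-passing model represents it exactly; (ii) small displacements
around a single base geometry leave the hub angles locally determined by
the visible distances, so a flexible invariant model interpolates them;
(iii) even with a short cutoff, shell–shell contacts inside the cutoff
pin most angular degrees of freedom through rigidity.  The final
geometry eliminates all three: the only within-cutoff distances are the
seven hub radii, and resampling directions at fixed radii shows the
conditional variance of the three-body forces is ≈100% of their total
variance — a *measured, training-free* information floor, meaning the
best possible distance-only model is left with the full three-body share
of the force standard deviation.  C9 is set from two measured
ratios — a fully trained distance-only model retains ≈52% of the
three-body force content (its model-class floor: its forces are radial
with radii-dependent magnitudes), while the full model's optimization
leaves ≈9% — placing the three-body share of the total force standard
deviation at ≈48%, the midpoint of the window where the angular model
succeeds clearly (≤5% of total) and the distance-only model fails
clearly (≥20% of total).

What passing these benchmarks does *not* show: anything about chemical
accuracy on real quantum-mechanical data (element diversity, charge
transfer, long-range electrostatics, label noise), dataset scales beyond
a few hundred frames, or wall-clock performance of GPU-scale
implementations.  The complexity results are about operand *sizes*
(instrumented element counts), not timings.

## Training

Loss = w_E · mean((ΔE/N_atom)²) + w_F · mean(ΔF²) with defaults
w_E = 1, w_F = 10; per-atom energy normalisation balances mixed-size
batches.  Adam with an exponentially decaying learning rate; the
returned model is the best-validation snapshot (best-train-loss snapshot
when no validation split is requested, paired with the parameters from
the top of the epoch whose loss was measured).  The 9:1 train/valid
split is the default.  Gradients of the force loss require mixed second
derivatives of the energy and are evaluated by a second reverse sweep
over the first sweep's tape.

Benchmark fit protocols (chosen once, stated here as the package's own
problem sizes): the cluster fits use l_max ∈ {0, 2}, T = 2, N_c = 16,
hidden width 64, r_c = 3.0 Å (matching the data-generating interaction
range), 500 epochs, batch 100, learning rate 0.012 → 5e−5, force weight
100, float32, identical for the full model and the ablation; the dimer
overfit uses N_c = 32, hidden 64, 800 epochs, no validation split.

## Molecular dynamics

Velocity Verlet; NVT adds a single Nose–Hoover chain (length 1) with
mass Q = g·kB·T·τ² (τ defaults to 100·dt) in the symmetric
quarter/half-step splitting, and its conserved quantity
E_pot + E_kin + ½Qξ² + g·kB·T·η is logged.  Initial velocities are a
seeded Maxwell–Boltzmann draw with center-of-mass motion removed and are
never rescaled mid-run in NVE.  Units: Å, fs, amu, eV
(1 amu Å²/fs² = 103.642696 eV).

The neighbor list used during dynamics is the Verlet-skin buffered list:
built at r_c + skin, filtered to r_c every step, rebuilt either when an
atom has moved more than skin/2 since the last build (`auto`) or every
fixed n steps with a hard safety check that raises if the skin guarantee
was violated in between.  The fixed-interval mode is the refresh-interval
contract of a pipelined neighbor-list update — force evaluation on a
slightly stale but provably sufficient list — without any host/device
machinery.  With adequate skin the two modes produce bit-identical
trajectories.

RDFs use the ordered-pair histogram normalised by the ideal-gas shell
expectation N_A (N_B − δ_AB)/V · 4πr²dr per frame and require
r_max below half the smallest cell height.  Temperature averages use
blocked standard errors (20 blocks after a 20% burn-in).

## Numerical choices and edge cases

* Isolated atoms: empty neighbor sums give zero features and a finite
  per-element energy; energies are strictly size-consistent across
  non-interacting fragments.
* Zero-length direction vectors are rejected; atoms at zero separation
  raise in the toy potentials.
* Cell-list neighbor search handles arbitrary (including skewed and
  smaller-than-cutoff) periodic cells by explicit ghost-image
  enumeration bounded by lattice-plane spacings; it must agree with the
  exhaustive brute-force oracle as a set of (i, j, shift) triplets, and
  pairs are sorted (node, distance, vector) for reproducibility.
* CG tables are generated in float64 regardless of working precision and
  cached per l_max.
* The checkpoint is a single `.npz` with a JSON header (format version,
  hyperparameters, element table) plus all parameter arrays; load(save)
  reproduces energies bit for bit.

## Known limitations

* The tape engine favors clarity over throughput; practical scales are
  thousands of edges per batch on one CPU core.
* Differentiable spherical harmonics are implemented to l = 3
  (closed-form Cartesian polynomials); the oracle harmonics support
  arbitrary l.
* No stress tensor, long-range electrostatics, charge equilibration or
  barostat; three-body toy labels are restricted to open boundaries.
* The edge-equivariant reference is a single layer used for oracle
  comparisons, not a trainable baseline architecture.
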