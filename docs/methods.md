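# Methods

## Problem setting

In a local atomic-orbital (AO) basis, the effective one-electron Schrödinger
equation takes the matrix form **H** **c**_m = ε_m **S** **c**_m, where
**H**_{μν} = ⟨φ_μ|Ĥ|φ_ν⟩ is the Hamiltonian (Fock/Kohn–Sham-like) matrix,
**S**_{μν} = ⟨φ_μ|φ_ν⟩ the overlap, ε_m the molecular-orbital energies and
**c**_m the orbital coefficients.  The package learns the map from a molecular
geometry to (**H**, **S**, E, **F**) with a message-passing neural network, and
derives everything downstream of that map — orbital spectra, Löwdin
populations and bond orders, multipole moments, broadened densities of states,
orbital-energy gradients, Langevin dynamics and HOMO–LUMO gap design — from
the predicted matrices.

## Synthetic reference generator

Quantitative ab-initio reference data is out of scope; the generator instead
produces data with the same *structure*: smooth geometry dependence, exact
block-wise rotational covariance of **H** and **S** under real Wigner
matrices, and energies/forces consistent with the matrices.

* **Overlap and moment integrals.** Contracted spherical Gaussians with
  angular momenta up to l = 3.  One-electron integrals are assembled from 1-D
  Obara–Saika recurrences over Cartesian primitives, transformed to real solid
  harmonics, and renormalized so diag(**S**) = 1 exactly.  The
  Cartesian→spherical coefficient matrices are derived numerically at import
  time by exact least-squares projection of degree-l monomials onto sampled
  real spherical harmonics (orthonormal, no Condon–Shortley phase, m ordered
  −l…+l); this avoids a hand-typed coefficient table and fixes one consistent
  phase convention for integrals, Wigner rotations and the test oracles alike.
* **Hamiltonian.** An extended-Hückel / Wolfsberg–Helmholz form,
  H_{μμ} = h_μ, H_{μν} = ½K(h_μ + h_ν)S_{μν} with K = 1.75 and per-shell
  on-site energies h (eV).  Because H is an affine function of S, it inherits
  S's exact rotational covariance — the property the augmentation scheme
  assumes of the reference theory.
* **Energy and forces.** E = 2Σ_occ ε_m + Σ_{i<j} a·exp(−d_ij/d₀) (closed
  shell, doubly occupied orbital-energy sum plus a short-range pair
  repulsion); **F** = −∇E by central finite differences with step 10⁻⁴ Å,
  which balances truncation against round-off in double precision.  Forces
  are translationally consistent to <10⁻⁴ eV/Å.
* **Toy systems.** H₂ (contracted s basis), a bent water-like 3-atom molecule
  (s+p on the heavy atom) and a planar 4-atom chain (s+p).  Each system's
  repulsion amplitude was chosen once so its shipped template geometry is
  near mechanical equilibrium of the synthetic surface (templates were
  relaxed on that surface); this makes random-distortion sampling around the
  template behave like configuration sampling near equilibrium.  Degenerate
  frontier spectra (< 10⁻⁸ eV) and interatomic distances < 0.5 Å are rejected
  during dataset generation so orbital-resolved targets stay well defined.
* **What the generator does not emulate:** self-consistency (no SCF), electron
  repulsion integrals, charged/open-shell states, and realistic chemical
  accuracy.  Passing tests therefore demonstrate that the learning pipeline
  recovers a smooth, exactly covariant matrix-valued map — not that it
  reproduces ab-initio chemistry.

## Network

Three stages (widths configurable; desk-scale defaults B = 64, D = 4, T = 3,
hidden width 64, cutoff r_c = 5 Å, radial grid spacing Δμ = 0.25 Å,
γ = 10 Å⁻²):

1. **Atomic environments.** Element embeddings a_Z ∈ R^B refined by T
   continuous-filter convolution blocks: x_i ← x_i + mlp(Σ_{j≠i} linear(x_j)
   ∘ W_filter(r_ij)), with W_filter(r) = mlp(g(r))·f_cut(r), g a Gaussian grid
   over [0, r_c] and f_cut the cosine cutoff (exactly zero at r ≥ r_c, C¹
   smooth).  All activations are shifted softplus ssp(x) = ln(½eˣ + ½).
2. **Pair environments.** 2L+1 interaction blocks, one per angular-momentum
   order λ = 0…2L (L is the basis's maximal angular momentum).  Each block
   builds a symmetric pair feature h_ij = ssp(linear₂[linear₁(x_i) ∘
   linear₁(x_j) ∘ W_filter(r_ij)]), updates the atom representations
   additively, and forms invariant pair coefficients p_ij = mlp_pair(h_ij) +
   Σ_{m∉{i,j}} mlp_env(h_mj) + Σ_{n∉{i,j}} mlp_env(h_in).  The environment
   sums exclude self-pairs (h_jj is undefined in a pairwise construction) and
   run over the cutoff neighbor list.  Coefficients are projected onto D
   directions: ω⁰ = p ⊗ 1_D (isotropic), ω^λ = [p ⊗ r̂_ij]W^λ for λ > 0 with a
   distinct learned 3×D projection per λ.  Products Ω^l = Π_{λ≤l} ω^λ carry
   angular momentum up to 2L.
3. **Heads.** Strictly linear maps from Ω^l to n_ao,max² off-site block
   entries (summed over l) and, via a neighbor sum, to on-site blocks; blocks
   are cropped to each atom's true orbital count, scattered into the full
   matrix and symmetrized H = ½(H̃+H̃ᵀ) (so predictions are *exactly*
   symmetric).  The overlap head is identical except that its on-site blocks
   are learned per-element constants initialized to the identity (the
   analytic self-overlap of normalized AOs).  The energy is an atom-wise MLP
   sum E = Σ_i mlp_E(x_i); forces are its exact negative position gradient.

The network uses only interatomic distances and unit bond vectors, so atom
representations and pair coefficients are rigorously rotation- and
translation-invariant and the full forward pass is permutation-equivariant.
Full rotational covariance of the matrix *blocks* is **not** hard-wired; it is
learned from rotation augmentation (below), and the tests measure how well.

### Automatic differentiation

No GPU autodiff framework is part of the dependency stack; the package ships
a small tape-based reverse-mode engine on numpy (`autodiff.py`).  Backward
functions are themselves composed of the engine's primitives, so gradients
are differentiable again — required because the force term of the training
loss contains dE/dr and must itself be differentiated with respect to the
parameters (double backprop).  Model forces and orbital-energy derivatives
are therefore analytic, and the tests verify them against central finite
differences at 10⁻⁴ tolerance.

## Training

Combined loss per sample:
‖H−H̃‖²_F + ‖S−S̃‖²_F + ρ|E−Ẽ|² + (1−ρ)/n_atoms Σ_i ‖F_i + ∂Ẽ/∂r_i‖².
Adam with initial rate 10⁻³, mini-batch 8, ρ = 0.1; the learning rate decays
by 0.8 after `patience` (default 15) epochs without a relative validation
improvement of 10⁻⁴ (the tolerance avoids float-noise resets), and training
stops at lr ≤ 5·10⁻⁶ or the epoch cap.  The model with the lowest validation
loss is kept.  Variable-size molecules are handled by iterating samples
within a batch and accumulating gradients, not by padding; the result is
identical and simpler in a numpy engine.

**Rotation augmentation.** Each epoch draws a fresh Haar-uniform rotor per
training sample (normalized Gaussian quaternions, seeded) and rotates the
record: positions and forces by R, each shell-pair block by
D^(l_μ) M D^(l_ν)ᵀ.  Real Wigner matrices D^(l) are built from the
(y, z, x)-permuted rotation matrix by the Ivanic–Ruedenberg recursion; the
transpose convention on the right factor is the one fixed by the analytic
oracle S(R·mol) = rotate(S(mol)), which the test suite checks to 10⁻⁸.

## Derived properties

* **Spectra** from the symmetric generalized eigenproblem via S^(−1/2);
  degenerate blocks are rotated to a triangular form by a QR factorization
  and every column's leading coefficient is made positive, making
  coefficients reproducible.  Coefficient comparisons elsewhere should use
  absolute cosine similarity (sign/phase freedom).
* **Löwdin analysis**: P^L = S^{1/2} P S^{1/2}; charge_i = n_val(Z_i) −
  Σ_{μ∈i} P^L_{μμ}; bond order b_ij = Σ_{μ∈i,ν∈j} (P^L_{μν})².  Nuclear
  charges are valence counts, consistent with the valence-only density of
  the generator (full-Z use is possible by passing a different map).
* **Moments**: dipole (Debye) and plain second moment (Debye·Å, non-traceless;
  a traceless Buckingham form is provided as an option) from the order-1/2
  moment integrals; origin handling keeps neutral-system dipoles origin
  independent.
* **Orbital-energy gradients** by first-order perturbation theory,
  dε_m/dr = c_mᵀ(∂H/∂r − ε_m ∂S/∂r)c_m, with matrix derivatives from the
  autodiff graph for the network and from central finite differences for the
  analytic generator; a guard refuses orbitals separated by < 10⁻⁶ eV.
* **DOS**: mean over frames of unit-area Gaussians at each orbital energy.

## Dynamics and gap design

Langevin dynamics uses BAOAB splitting (friction γ = 1/τ with τ = 100 fs by
default, 0.5 fs timestep, 300 K), chosen for accurate configurational
sampling at practical timesteps; with T = 0 and τ = ∞ it reduces exactly to
velocity Verlet, the limit used for energy-conservation (drift < 10⁻³ eV over
1000 × 0.1 fs steps) and time-reversibility (10⁻⁶ Å) checks.  Initial
velocities are Maxwell–Boltzmann with the center-of-mass motion removed at
initialization only; no bond constraints.  The same integrator runs on any
force provider (generator or trained model).

Gap optimization performs gradient ascent/descent on ε_gap = ε_LUMO − ε_HOMO
with backtracking (step halves when the objective moves the wrong way, grows
25% after accepted moves), so accepted-gap traces are monotone by
construction.  Trials that bring atoms closer than 0.5 Å are rejected like
failed steps: the surrogate surfaces are not meaningful there and the Hückel
gap would otherwise grow without bound as distances shrink.

## Problem sizes and numerical choices

Defaults used by the test suite and the acceptance script: 200 water-like
records (σ = 0.05 Å) with a B = 64, T = 3, L = 1 model trained ≤ 30 epochs
with augmentation; 100 random eigenproblem instances; 50 geometries × 5
rotations for the covariance oracle; ≥ 24 primitive pairs spanning all
l-combinations up to d for the quadrature oracle (tensor-grid midpoint rule,
superalgebraically convergent for Gaussians); 20 000 thermostatted MD steps
at 0.5 fs on the water-like system.  These sizes exercise every code path on
a single CPU core while keeping the whole pipeline reproducible from fixed
seeds.

## Known limitations

* The AO phase/ordering convention is self-consistent but need not match any
  particular quantum-chemistry code's convention; matrices imported from
  external programs would need a basis-order/phase mapping first.
* The network predicts off-site blocks only for atom pairs inside the cutoff;
  beyond-cutoff blocks are exactly zero.  Appropriate for the compact toy
  systems; large molecules would need a larger r_c.
* Rotational covariance of the matrix blocks is approximate (learned), with
  quality measured by the rotated-validation loss ratio; only the generator
  is exactly covariant.
* The pure-numpy engine is serial and desk-scale: paper-scale widths
  (B ≈ 1000) are configurable but not practical here.
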