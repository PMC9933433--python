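# Methods

## The quantity being modelled

The atomic polar tensor (APT) of atom *i* is the 3×3 matrix

P_i[ξ, ζ] = ∂M_ξ / ∂r_{iζ},

the derivative of the simulation cell's total dipole moment **M** with
respect to that atom's Cartesian position.  It is the per-atom embodiment of
the IR selection rule: by the chain rule the dipole velocity along a
molecular-dynamics trajectory is

Ṁ(t) = Σ_i P_i(t) · v_i(t),

so any set of atomic velocities, or any projection of them, can be promoted
to a proper IR intensity by weighting with the corresponding APTs.  The
absorption spectrum follows from the Fourier transform of the
dipole-velocity autocorrelation,

n(ω) α(ω) = β / (6 ε₀ V c) ∫ ⟨Ṁ(0)·Ṁ(t)⟩ e^{−iωt} dt,

with β = 1/k_BT and V the cell volume.  In this velocity form the harmonic
quantum correction factor is already contained; the package applies no
further frequency-dependent factor and always reports n(ω)α(ω) jointly,
making no attempt to separate the refractive index.

The package implements the three stages of the workflow: (1) *labelling* —
APTs by central finite differences of a pluggable total-dipole backend;
(2) *regression* — an E(3)-equivariant message-passing network predicting
each atom's APT from its local environment; (3) *spectroscopy* — assembly
of Ṁ(t) from predicted APTs and velocities, spectra, and group
decompositions.  An electronic-structure code would normally stand behind
the backend contract; here an analytic toy dipole surface with closed-form
APTs plays that role, so the full loop is testable on a desk.

## Finite-difference labelling

Central (two-sided) differences with displacement h displace one Cartesian
coordinate at a time: six dipole evaluations per atom, 6N per
configuration, and the unperturbed geometry is never needed.  The default
h = 0.01 Å is exposed as a setting — it is a convergence parameter, and
`displacement_check` audits it by comparing two displacements (on a dipole
surface linear in positions the deviation is zero; on a smooth nonlinear
surface it follows the h² truncation law).  Displaced geometries are never
re-wrapped into the cell, because wrapping hops between branches of the
multivalued periodic dipole and corrupts the derivative; the backend
contract requires branch consistency under sub-displacement perturbations.
Backends that can provide analytic derivatives (DFPT-style) may expose an
`analytic_apt` capability which bypasses differencing; the finite-difference
path remains the reference path.

## The equivariant regressor

The APT transforms as a parity-even rank-2 Cartesian tensor: translations
leave it unchanged, rotations act as P → R P Rᵀ.  The regressor enforces
this structurally rather than by augmentation.  Node features are direct
sums of real O(3) irreps (ℓ ≤ 2, both parities, 20 channels each by
default, 8 in the desk-scale studies).  A message-passing layer contracts
neighbor features with spherical harmonics of the edge direction through
Clebsch–Gordan couplings, weights each path by a learned radial profile
(Gaussian shells under a cosine cutoff envelope), sums messages on the
receiving node with a fixed 1/√(avg. neighbors) normalisation, mixes
channels linearly per irrep together with a self connection, and applies a
gated nonlinearity (silu on even scalars, tanh on odd scalars, sigmoid
gates on ℓ > 0).  After two layers a linear readout emits one even scalar,
one even axial vector (ℓ=1) and one even deviator (ℓ=2) per atom — the
irreducible parts of the predicted tensor, recomposed to Cartesian form by
an orthogonal change of basis.  Odd scalars are unreachable from scalar
species embeddings within two layers and are omitted (they would be
identically zero).

Implementation notes.  The network, its reverse-mode differentiation and
the Adam optimiser are implemented directly on NumPy arrays; gradients are
verified against central finite differences in the test suite.  Real-basis
Clebsch–Gordan couplings are generated numerically as the one-dimensional
null space of the equivariance constraint over a fixed set of rotations,
with a fixed normalisation and sign convention; the ℓ=2 Wigner matrices
come from conjugation in an orthonormal symmetric-traceless matrix basis.
Neighbor graphs use the minimum-image convention when the cutoff is below
half the smallest cell height and exact periodic-image enumeration
otherwise (small toy cells legitimately produce several images of the same
neighbor, including an atom's own image); edges are sorted deterministically
so floating-point summation order, and hence every reported number, is
reproducible for a given seed.  One seed drives weight initialisation and
batch shuffling and is recorded in the results' provenance.

Training follows the reference protocol: Adam at initial learning rate
0.01, reduced by a factor 0.1 when the validation MSE has not improved for
10 epochs; the loss is the mean squared error over tensor components (the
Cartesian and irreducible component MSEs coincide because the decomposition
is orthogonal); one batch is one configuration; an epoch is one pass over
the training configurations; histories report raw e² units.  Targets are
conditioned per species by subtracting the species-mean isotropic part
(mean trace/3 times the identity) and dividing by a single scalar standard
deviation.  A per-component affine normalisation would condition slightly
better but breaks exact rotation equivariance of the composed predictor
(the offset is a fixed tensor); the isotropic/scalar form commutes with
rotations, which is why the symmetry suite can assert deviations at the
10⁻⁵ relative level and observe round-off instead.

## Spectral estimation

The autocorrelation uses the biased (divide-by-N) estimator, computed by
FFT and verified against the direct O(N²) lag sum to 10⁻¹⁰ relative.  The
retained lag range (default: half the series) is tapered with a Hann window
and zero-padded fourfold before the one-sided cosine transform; the biased
estimator plus taper keeps spectral leakage low on short trajectories.  All
of these are explicit settings.  With temperature and volume given, the
prefactor above is applied in SI and the result is n(ω)α(ω) in cm⁻¹;
otherwise spectra are normalised to unit maximum.  Multiple trajectories
are averaged at the ACF level.  A requested wavenumber grid beyond the
Nyquist limit 1/(2·c·dt) raises, mirroring the sampling-theorem bound that
dictates how often APTs must be available (≈ 4.8 fs for a 3500 cm⁻¹
stretch).  Group decompositions build per-group dipole velocities
Ṁ_g = Σ_{i∈g} P_i (Π_i v_i) — optionally with per-atom 3×3 velocity
projectors that must sum to the identity — and return auto- and symmetrised
cross-spectra; since the whole pipeline is linear in the correlation
function, the terms reconstruct the total spectrum pointwise (checked to
10⁻⁸ relative).

Velocities can come from the integrator (exact, preferred) or from central
differences of periodicity-unwrapped positions; both paths are provided
because trajectory archives differ in what they store.  The
route-equivalence benchmark deliberately uses exact integrator velocities
on both routes so that it isolates the regression error in the APTs rather
than time-discretisation error; the positions-derived path is validated
separately against integrator velocities.

## The synthetic water system

The generator emulates the reference scale — 128 molecules / 384 atoms in a
periodic cubic cell sized from the density (default 0.9982 g/cm³) — while
staying fully analytic.  Molecules sit on a jittered periodic sublattice
(simple cubic or checkerboard, whichever gives the larger nearest-neighbor
distance) with random orientations and a guaranteed O–O separation above
2.5 Å.  Dynamics are velocity-Verlet with harmonic bonds
(k = 0.412 u fs⁻², r₀ = 0.9572 Å) and angles (k = 0.040 u Å² fs⁻² rad⁻²,
θ₀ = 104.52°) plus a soft C² intermolecular O–O repulsion; the constants
are documented package constants chosen to put the stretch band near
3500 cm⁻¹ and the bend near 1600 cm⁻¹ (single-molecule Hessian modes: 1619,
3475, 3525 cm⁻¹), so Nyquist logic and spectral windows are exercised at
realistic wavenumbers.  They are not claims about real water.  Energy drift
(chunk-averaged total energy, first versus last 10% of a run) stays below
10⁻⁴ relative at a 1 fs step.  The Hessian behind the normal-mode
wavenumbers is computed by central differences of the analytic gradient.

The toy dipole is M = Σ q_i(geometry) r_i with per-molecule neutrality, so
it is single-valued by construction and finite differencing needs no branch
bookkeeping — the periodic-branch subtlety is exercised only through the
backend contract.  The fixed variant (q_O = −0.8 e) has APT ≡ q_i·I and
makes central differences exact at any displacement.  The fluctuating
variant moves charge along each O–H bond in proportion to its elongation,
q_O = q_O⁰ + a(δ₁+δ₂), q_Hk = −q_O⁰/2 − a·δ_k, giving closed-form APTs with
orientation-dependent bond dyadics (q·I ± a b⊗û).  The coupling a sets the
third-derivative scale of the dipole surface and therefore the h²/6·f‴
truncation error of the labelling stage; a = 0.004 e/Å keeps the h = 0.01 Å
error near 4×10⁻⁷ e at thermal geometries.  Because targets are normalised
per species by a single scalar, the learning problem is analytically
invariant to a, so this choice does not soften the regression benchmarks;
it is, however, far below physical charge-flux magnitudes, which is one of
several ways the toy is not water (no intermolecular polarisation, no
dissociation, harmonic bonds, no nuclear quantum effects).  Passing tests
therefore demonstrate the machinery — labelling, equivariant regression,
spectral assembly and their mutual consistency — not chemical accuracy for
any real system.

## Problem sizes of the shipped studies

The desk-scale studies use deliberately small systems: learning curves
train on 4/9/18/27 snapshots of 16-molecule boxes for 50 epochs with 8
channels per irrep and a 3.5 Å cutoff (the toy APT is strictly
intramolecular, so this cutoff is generous for the toy while keeping graphs
small); the route-equivalence benchmark trains on 9 snapshots of
32-molecule boxes and predicts along an 8 ps, 1 fs trajectory (8000 × 96
atoms).  The production-scale defaults (6 Å cutoff, 20 channels, 100
epochs) remain the package defaults.  Each benchmark fit uses two
independent initialisations and keeps the one with the lower validation
MSE: the plateau-scheduled optimiser occasionally freezes in an early
plateau (the learning rate collapses before the loss escapes), and restart
selection on validation data is the standard remedy; test data never enter
the choice.  With these sizes the learned models
reach held-out component RMSEs near 6×10⁻⁵ e against a structural target
spread of ~10⁻³ e, and the spectrum from predicted APTs matches the
exact-dipole reference to ~0.01% relative L2 — the desk-scale analogue of
validating a surrogate against its reference.

## Known limitations

* No electronic-structure backend ships with the package; reproducing a
  DFT-referenced accuracy requires supplying such a backend and is out of
  scope.
* The regressor trains on one CPU in NumPy; it is faithful but not a
  performance substitute for GPU frameworks at production scale.
* Committee/ensemble training, active learning, uncertainty estimates, and
  polarizability (Raman/SFG) outputs are not implemented.
* `velocities_from_positions` cannot detect a true displacement larger than
  half the cell between frames (it raises only in the marginal detectable
  case); store velocities or sample densely enough.
* With a single message-passing layer the axial (ℓ=1) output is
  structurally zero; two or more layers are required for full rank-2
  output, matching the default.
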