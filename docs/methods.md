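# Methods

This note documents the models implemented in helixpack, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions a user should know before trusting a result.

## Units and constants

Structure coordinates are stored in Å (PDB native); membrane and
free-energy quantities are reported in nm.  The only Å↔nm crossing is the
converter pair in `helixpack.units`, used at module boundaries.  Thermal
energy uses the CODATA Boltzmann constant k_B = 1.380649×10⁻² pN·nm/K;
at the default simulation temperature of 310 K, kBT ≈ 4.280 pN·nm.
Non-bonded energies are reported in kJ/mol with the Coulomb prefactor
138.935 kJ·nm/(mol·e²).

## Elastic-network normal modes

The protein is reduced to its Cα atoms.  Every pair of nodes closer than
a cutoff (default 8 Å) is joined by a Hookean spring of uniform stiffness
k = 1 (mode shapes are k-independent; energies are relative).  The
Hessian is assembled from 3×3 super-elements k·u uᵀ on the unit
inter-node vectors and diagonalized in full.  Covalent links recorded on
a composite structure (e.g. a crystal-structure ectodomain joined to an
NMR transmembrane fragment) always receive a spring, regardless of
distance.  Note that a single such spring constrains one of the six
relative rigid degrees of freedom of two otherwise disconnected bodies;
it restores connectivity, not rigidity.

Numerical rank: eigenvalues with |λ| < 10⁻⁸·λ_max are clamped to zero.
A connected three-dimensional structure then shows exactly six zero
modes; a disconnected network is analysed anyway but warns with the
component count.  Modes are numbered from 1 including the rigid modes,
so "mode 7" is the first internal mode.  Deformation energy at unit
modal amplitude is ½λ.

### Hinge detection

For a chosen mode: (1) per-residue displacement 3-vectors are read off
the eigenvector; (2) residues with amplitude above the median are split
into two groups by the sign of their projection onto the first principal
axis of the displacement set; (3) the hinge is the longest contiguous run
of residues below the 25th amplitude percentile lying sequence-wise
between the two groups; (4) the anticorrelation is the cosine between the
group mean displacements.  All four thresholds are exposed in
`HingeConfig`.

Two robustness decisions, made here because any momentum-conserving mode
of two elastically coupled rigid bodies is partly rotational:

* a rotating domain flips the projection sign of a few of its own
  residues, so the groups' sequence extents are percentile-trimmed (10%)
  before the between-groups window is formed;
* the few softest internal modes (bending about two axes, twist,
  stretch) are near-degenerate, and which lands at index 7 can swap
  under small coordinate changes; `find_hinge_mode` scans modes 7–12 and
  returns the first with a detectable hinge.

A mode that moves the molecule as one block — one direction group empty
or tiny, groups not anti-correlated (threshold −0.25), interleaved in
sequence, or no quiet residues between them — yields a "no hinge"
report, not an error.  A uniform rod is correctly rejected this way: its
free-free bending modes have in-phase ends and an anti-phase middle, so
the direction groups interleave.

### Verification

Eigenvalues are checked against an independent oracle: central finite
differences of the analytic gradient of the explicit pairwise energy
E = Σ k/2(|r_i−r_j|−d⁰_ij)² on ≤10-node random structures (relative
tolerance 10⁻⁶), plus orthonormality, translation invariance, positive
semidefiniteness, and the analytic two-node dimer (single internal mode
with λ = 2k).

## Free-energy estimation from pulling work

Work is integrated by the trapezoid rule over the **guide** (dummy-point)
coordinate — the stiff-spring convention — not the instantaneous
molecular coordinate.  Repeats are aligned on a common grid by linear
interpolation over the intersection of their coordinate ranges and
re-zeroed at the grid origin.

Two estimators act on a `WorkTraceSet` (works stored in kBT):

* exact: ΔF = −(1/β)·log[(1/M)·Σ exp(−βW_i)], evaluated via log-sum-exp;
* second-order cumulant: ΔF = ⟨W⟩ − (β/2)·Var W, exact for Gaussian work
  and far less biased at M = 10.  The variance uses the unbiased M−1
  divisor by default; with M = 10 the divisor is material, so it is a
  keyword argument.

`barrier_height` reports the profile's global maximum minus the deepest
minimum preceding it in grid order (the pull approaches contact as the
grid advances); a profile whose maximum sits at the first grid point has
no barrier and returns `None`.  The result is invariant under constant
shifts.

## Closed-form diffusion and feasibility arithmetic

For a free 2-D random walk, σ² = 4Dt (the 2-D Green's function of
diffusion).  With D = 0.25 nm²/µs and t = 2 ns: σ = 0.0447 nm,
3σ = 0.1342 nm, and the characteristic drift speed 3σ/t = 0.0671 nm/ns.
Decomposing the walk into steps of the integration time step dt gives the
instantaneous speed V = √(4D/dt) = 22.36 nm/ns at dt = 2 fs; a steering
speed should stay about an order of magnitude below V
(`recommended_pull_speed`, a recommendation rather than an identity).
A barrier of B kBT at temperature T under constant force F requires a
displacement B·k_B T/F — ≈34 nm for 400 kBT at 310 K and 50 pN.
Contact-distance geometry: envelope radius = final COM distance/2,
monomer effective radius = bare contact distance/2, lipid shell
thickness = their difference.

## Synthetic generators

All generators are pure functions of their seed.

**Hinged dumbbell.**  Two cubic-lattice blocks (spacing 5 Å; axial and
face-diagonal springs brace every face, making each block rigid) joined
by a shallow helical coil (rise 1 Å, radius 3.2 Å, 36°/node; springs
reach the fourth sequence neighbour).  The coil is the sparsest
connectivity we found that is three-dimensionally rigid — a consecutive-
only chain of central-force springs provably carries exact transverse
mechanisms and would add spurious zero modes — yet it is axially
compliant like a coil spring, so the lowest internal mode is an
anti-phase displacement of the two domains with its amplitude node inside
the linker, which is the pattern the hinge detector targets.  Defaults
n1 = n2 = 30, linker = 10: equal domains keep both domains' amplitudes
comparable, so the quiet amplitude quartile falls in the linker rather
than inside the heavier domain.

**Membrane patch.**  A point-atom slab (default 10×6×4 nm, midplane
z = 0) with lipid tail atoms Poisson-sampled at a baseline density
(default 100 atoms/nm³, the order of the cytoplasmic-leaflet chain
density the profiles are meant for).  Inside a contrast region
(defaulting to the stretch between the two embedded helices) the density
is (1+c)× the baseline — c = 0.2 reproduces the ~20% packing contrast of
interest.  An optional channel thins the slab (and its head-group
surfaces) between the monomers.  Snapshots are the base configuration
under small per-frame jitter (0.03 nm), nine frames at 100 ps spacing by
default, matching the microstate-averaging protocol; the jittered frames
share one Poisson draw, so recovery tests use single-draw counting
statistics.  What this does **not** emulate: lipid connectivity and
anisotropy, water, electrostatics, or any correlation between density and
thickness — passing recovery tests shows the *profilers* are unbiased at
known contrast, not that MD would produce that contrast.

**Langevin puller.**  One particle on a prescribed analytic profile F(x)
(ramp + Gaussian bumps + contact well, in kBT) pulled by a harmonic guide
(default 300 pN/nm) moving at constant speed, integrated by
Euler–Maruyama with dt = 1 ps, friction γ = 1 pN·ns/nm and T = 310 K.
These values give D = kBT/γ ≈ 4.3 nm²/ns, so the quasi-static regime is
reached at desk-scale speeds (seconds of runtime); they are deliberately
*not* the diffusivity of a membrane protein — the generator validates
estimators, it does not simulate integrin kinetics.  The integrator
refuses dt·k/γ > 0.5 (Euler stability) and reports the bound.  The guide
spring sets a resolution limit √(kBT/k) ≈ 0.12 nm: features narrower
than this (the cliff-like contact well) are smeared, which is why
recovery tests assert profile agreement only where the profile is
resolvable and assert the *barrier* elsewhere.  The default profile
carries a ~4 kBT principal bump — a deliberate desk-scale stand-in for
the hundreds-of-kBT barriers of the real membrane system, which no
sampler could cross by design.

**Gaussian work sets.**  i.i.d. Gaussian endpoint works on a two-point
grid; the closed form ΔF = μ − βσ²/2 makes them the independent oracle
for both estimators.

## Trajectory analyses

Density profiles count atoms in slab-shaped bins along the line joining
two reference points (bin width × 2·transverse half-width × leaflet
z-interval); the per-snapshot counts divided by bin volume are averaged
over frames, and the binned counts conserve the slab total exactly.
Leaflet membership is a user-supplied z-interval (default the lower half
of the slab, the cytoplasmic side); no automatic leaflet assignment is
attempted.  Thickness maps subtract per-bin mean head-group z between
leaflets and report empty bins as NaN, never zero.  Window averaging is
a truncated boxcar (±window/2, inclusive; default 0.5 nm).  Group–group
non-bonded energies use plain truncation at 1.2 nm, Lorentz–Berthelot
combining and a fixed relative dielectric — comparative numbers for
synthetic atoms, not force-field-faithful energies.  Lipid-shell
tracking follows chain COMs against a monomer COM with membership frozen
at the first frame.

## Problem sizes

Default test and acceptance runs use: dumbbell structures of 64–100
residues (Hessians ≤300×300, full `eigh`), membrane patches of ~2.6×10⁴
point atoms over 9 snapshots, pulls of 10 repeats at three speeds (4, 1,
0.25 nm/ns; ≤16 000 steps each, vectorized across repeats), and 10⁵
repeats for the Gaussian Jarzynski limit.  The full suite runs in well
under a minute on one CPU.

## Known limitations

* The elastic network is Cα-only, unweighted and uniform-k; no
  mass-weighting or solvent damping, so eigenvalues are relative spring
  units, not frequencies.
* The hinge detector assumes exactly two moving blocks; multi-domain
  proteins need per-mode inspection.
* PDB output is fixed-format: residue numbers above 9999 per chain are
  rejected (the membrane generator spreads large tail clouds over
  several chains for this reason).
* The selection mini-language is deliberately minimal: `name`, `chain`,
  `resname`, `resid N`/`resid A:B`, combined with `and` only.
* `estimate_pmf` interpolates work curves linearly between samples;
  heavily sub-sampled traces bias steep features.
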