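# Methods

`alveofem` is a desk-scale finite-element laboratory for one question in
dental biomechanics: *how does the way the periodontal ligament (PDL) and
the trabecular tissue are represented change the strains predicted in the
alveolar and cortical bone of a loaded molar region?*  Because the original
study geometry (a micro-CT scan of a human hemi-mandible) is not available,
the package generates a synthetic tooth-in-socket geometry with the same
material topology and re-runs the comparative experiment on it.

## Model

All materials are homogeneous, isotropic, linear elastic, in a consistent
mm–N–MPa system; strains are reported in microstrain (1 με = 1e-6).
The continuum is discretised with 10-node (quadratic) tetrahedra,
straight-sided with mid-edge nodes at edge midpoints, integrated with a
4-point Gauss rule (exact for the constant-Jacobian element).  PDL fibres
are two-node tension-only bar elements: an active fibre of modulus `E`,
cross-section `A` and rest length `L0` contributes the axial stiffness
`E·A/L0` along its axis; a shortened fibre contributes nothing.

Six variants share one mesh and differ only in material assignment:

| material            | fibrous PDL | solid PDL | no PDL  | structure  | bulk |
|---------------------|-------------|-----------|---------|------------|------|
| cortical bone, tooth| 17000/0.3   | 17000/0.3 | 17000/0.3 | —        | —    |
| trabecular bone     | —           | —         | —       | 17000/0.3  | 526/0.3 |
| trabecular filling  | —           | —         | —       | 1e-4/0.3   | 526/0.3 |
| PDL matrix          | 1/0.45      | 49/0.45   | 17000/0.3 | —        | —    |
| PDL fibres          | 1000/0.35   | absent    | absent  | —          | —    |

(E in MPa / Poisson ratio.  The fibre Poisson ratio is recorded but unused:
axial-only elements have no transverse response.)  "No PDL" fuses the tooth
to the socket.  The 49 and 526 MPa values are *calibrated* quantities on
the original anatomy: the solid-PDL and bulk moduli were chosen there so
that the crown displacement under the occlusal load matches the
fibrous+structure reference.  `calibrate_variants` reproduces that
procedure on the synthetic geometry (bracketed Illinois iteration on log E,
matching the displacement magnitude of the load-patch centroid node to 1%);
the recovered values on the default synthetic mesh (≈75 MPa solid PDL,
≈3.6 GPa bulk) differ from the published ones because the geometry does —
they are reported, never asserted.

### Tension-only iteration

All fibres start active.  After each linear solve the axial elongation
δ = (u_root − u_bone)·n̂ is evaluated; fibres with δ < −δ_tol are
deactivated, fibres with δ > +δ_tol reactivated (δ_tol = 1e-12·L0), until
the active set is unchanged (cap 50 iterations; on detected cycling the
visited set with the smallest total complementarity violation is kept).
The converged set satisfies complementarity: no active fibre shortened, no
inactive fibre elongated.  On toy problems the iteration reproduces the
unique consistent set found by exhaustive enumeration.

### Linear solver

Constraints (all zero-valued) are applied by row/column elimination.
Systems up to 20k DOF are factorised with SuperLU.  Larger systems use
conjugate gradients preconditioned by a two-level method built for
elasticity: nodes are aggregated into geometric boxes, the tentative
prolongation carries the six rigid-body modes of each aggregate (the
near-nullspace), one damped-Jacobi step smooths it, the Galerkin coarse
operator (≈9k DOF) is factorised directly, and the fine level is smoothed
with degree-3 Chebyshev.  This converges reliably even with the 17000 :
49 : 1e-4 MPa material contrasts and the thin PDL shell (relative residual
1e-9; a converged solve is additionally verified to balance applied loads
and reactions to 1e-6 relative).

### Strain recovery

Element strains are quadrature averages.  Nodal values are recovered two
ways: volume-weighted averaging over adjacent same-material elements (never
across material interfaces, so bone-surface values are not blurred by the
PDL), and superconvergent patch recovery (per-node linear least-squares fit
of the adjacent quadrature-point strains), which converges one order faster
where the field is smooth and is what profiles and point samples use.
Principal strains are the eigenvalues of the strain tensor (ε1 ≥ ε2 ≥ ε3);
the effective strain is √(2/3 e:e) of the deviator.

## Synthetic geometry

A structured hex grid over a corpus block is deformed by a local radial map
around each tooth axis so that two grid rings land exactly on the root
surface and on its offset by the PDL thickness; each hex is split into six
tetrahedra (Kuhn subdivision, conforming across the grid) and promoted to
tet10.  The PDL is therefore a one-element shell of exact 0.25 mm nominal
thickness (local measurements stay within [0.20, 0.30] mm; the variation is
the faceting of the circular interface).  The root is a tapered (optionally
elliptic) cone with a flat apical cap, also wrapped in PDL; above the
crest only the root core continues into the crown, so tooth and bone never
share nodes — the ligament is the only connection (in an early version the
crown touched the crest ring, which rigidly welded the tooth to the socket
and suppressed tooth mobility ten-thousand-fold).

Default dimensions (chosen once as anatomically plausible desk-scale
values; the original study's specimen dimensions are unknown): corpus
12×12 mm cross-section, 30 mm high; root 12 mm long, radius 3.0→1.2 mm;
crown 4.5 mm; cortical shell 3.0 mm; element size 1.5 mm.  The shell
thickness sits at the upper end of the plausible 2.5–4 mm range for the
inferior mandibular cortex because a one-element-thick shell bending over
the soft bulk core is numerically unresolvable at this element size; two
quadratic elements through the shell make mid-corpus surface strains mesh-
convergent to a few percent.

A fixed-extent dense ("alveolar") bone ring surrounds each socket out to
the blend ring of the radial map, so the five-material layout is *identical
at every mesh resolution* — a prerequisite for a meaningful convergence
check.  At the default element size this ring necessarily spans the full
block width (its minimum extent is the root radius plus two cells), which
makes the alveolar process a solid dense block rather than the thin
cortical plates of real anatomy.  This is the main known limitation of the
desk-scale geometry; its consequences are discussed below.

The trabecular interior is labelled by a jittered orthogonal plate lattice:
element centroids are scored by distance to the nearest lattice plane and
thresholded at a volume-weighted quantile, so the realised trabecular-bone
volume fraction matches `1 − porosity` to element quantisation.  Plate
positions are seeded; the whole geometry is a pure function of
(parameters, seed).  In "bulk" variants both trabecular labels receive the
same material, so the lattice realisation does not influence those results.

## Loads and boundary conditions

Occlusal case: 500 N (a maximal bite force) spread with equal nodal weights
over a ~1 mm patch at the crown centre, directed corono-apically; the
mesial/distal crown faces are held mesiodistally (tooth-to-tooth contact).
Orthodontic cases: 1 N on the buccal crown face, directed distomesially or
buccolingually, with the contact constraints removed.  In all cases the cut
faces of the corpus are held mesiodistally and a fixed 4×1.5 mm patch at
the base of each cut face is fully fixed.  The support patches are defined
by physical extent, not node count: point- or line-supports make global
compliance diverge under refinement, which would invalidate any
convergence statement.

## Fibre network

Bone-side PDL interface nodes are grouped by normalised socket depth into
crestal (s < 0.10), horizontal (0.10–0.25), oblique (0.25–0.90) and apical
(> 0.90) bands — proportions from descriptive periodontal anatomy, and
configurable.  Every bone-side node spawns a crossed pair: one fibre
towards an apically inclined target direction, one coronally (group
inclinations 30°/0°/45°; apical fibres converge on the apex with a ±20°
spread).  The partner is the nearest admissible root-side node within a 20°
search cone (widened once to 40° before skipping; candidates are capped at
2 mm so fibres stay local to the ligament gap).  Ties break on the smallest
node id; the network is deterministic and mirror-symmetric on symmetric
sockets.  Fibre cross-sections realise a prescribed ligament fibre volume
fraction (default 0.60, inside the anatomical 50–75% range): the pair at a
node with tributary area a gets A = φ·a/2 per fibre.  On the default mesh
this yields 1946 fibres on the loaded molar, the same order as the
reference model's 2112.  Because the faceted interfaces are coarse,
node-to-node fibre lengths exceed the 0.25 mm gap by up to ~60% off the
aligned directions, and fibre volume bookkeeping inherits that factor.

## What the synthetic model does and does not show

The package reproduces the study's *mechanical structure* — the variant
matrix, the calibration, the load cases, the extraction surfaces — on a
geometry whose socket environment is much stiffer and smoother than real
alveolar bone.  Consequences, measured on the defaults:

* Tooth mobility orders as published: under 1 N the fused tooth moves
  ~0.0015 μm in its socket, the solid PDL permits ~0.10 μm, the fibrous
  PDL ~0.13 μm; the fibrous socket-strain peak exceeds the solid one by
  ~60% (the published factor is two- to three-fold).
* Fused-socket orthodontic strains stay within the published ±10 με band.
* The large *absolute* socket-strain amplification with a PDL (one to two
  orders of magnitude in the original) does not reproduce: it relies on
  strain concentrations at a rough, trabecular-backed socket surface
  resolved at 40 μm.  On the smooth desk-scale socket the PDL-present
  strains sit close to the fused baseline, and the solid-PDL model can even
  fall below it (the ligament shields the wall from the global bending
  field).
* Under the occlusal load, compressive strain around the alveolar process
  is *higher without* a PDL (the original reports the same local
  reversal), while the published 100–500% with-PDL excess in the superior
  corpus — a thin-plate bending effect — does not appear on the solid
  dense block; the measured superior-third median excess is negative.
  Tensile strains in the crest region are higher with a PDL, as published.

The mesh-convergence audit (element size halved, solid+bulk variant)
samples ε1, ε3 and effective strain at five fixed points on the buccal
cortical surface in the mid-process band, offset 4.5 mm mesially from the
load plane.  Near the supports, beneath the apex, and at the crest rim the
desk-scale model is pre-asymptotic (changes of tens of percent persist);
the chosen band converges to ≈3%.  The asymmetric Kuhn tet split also
leaves node-level error noise of a few percent between the nominally
symmetric buccal and lingual surfaces.

## Reproducibility and sizes

Every stochastic step (lattice jitter) derives from the run seed; meshes,
networks and reports are bit-reproducible for fixed configuration.  The
default model has ≈8.4k tet10 elements (≈40k DOF) and solves in seconds to
tens of seconds per variant; the halved-element-size mesh (≈66k elements,
≈200k DOF) is used only by the convergence audit.  These sizes were chosen
so the full 6-variant × 3-load matrix, the calibration and the convergence
audit run comfortably on a single CPU.
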