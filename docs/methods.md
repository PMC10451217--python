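# Methods

`onstrain` measures in vivo optic-nerve (ON) deformation from labeled
orbital MRI: two anisotropic acquisitions per gaze state (quasicoronal,
~0.31 mm in-plane / 2 mm slices perpendicular to the orbital axis; axial,
~0.39 mm in-plane / 2 mm slices) are fused into a 3D labeled point cloud,
gaze states are co-registered through the immobile bony orbit, the nerve is
parameterized as a tube around a fitted space curve, and Green–Lagrange
strain is evaluated from displacement gradients reconstructed on an
unstructured material grid. Because no subject data are distributable, the
package ships a synthetic orbit generator whose imposed deformations have
closed-form strain; all validation is against that analytic truth.

## Measurement model

**Acquisition fusion.** Label masks are densified along the slice axis by
shape-based interpolation (per-label signed Euclidean distance transforms of
flanking slices, linearly blended and thresholded at zero; conflicts
resolved by the most-interior label). Each labeled voxel becomes a point at
its center. The axial cloud is registered into the quasicoronal frame using
ON + lateral rectus (LR) + medial rectus (MR) points only: the muscles break
the roll ambiguity of the almost axisymmetric nerve tube. Registration is
trimmed (80% inlier) symmetric ICP with Kabsch updates, seeded globally by
principal-axis alignment (the two frames can differ by ~90–115°), and
polished by point-to-plane Gauss–Newton steps. Point sets are voxel-mean
downsampled (0.45 mm) before registering: raster-coherent point sets
otherwise lock their slice lattices into false Chamfer minima ~0.5–1.3° from
the true pose.

**Gaze-to-gaze registration.** Sessions are aligned on orbital-wall points
only (the wall does not move with the eye), and deliberately coronal-vs-
coronal: comparing like rasters cancels the reconstruction systematics that
differ between acquisition orientations. Typical accuracy on synthetic
sessions is ~0.25° / 0.06 mm.

**Head frame.** X is the medial-plane normal (Chamfer-minimizing mirror
plane of the two orbits' walls, or supplied), oriented toward the analyzed
orbit; Z is the anterior-ethmoid-recess line projected into the medial plane
and pitched 10° about X, oriented anteriorly; Y = Z × X (superior). The
pitch sign (anterior end inferior) is a package convention; the magnitude is
the anatomical convention.

**Globe.** The center is the minimal bounding sphere of the quasicoronal
globe cloud (cornea-free by acquisition coverage), refined by a least-
squares sphere fit to the surface shell: on anteriorly clipped, noisy clouds
the raw minimal sphere's center is set by a few extreme points and is weakly
constrained along the clip axis. Ocular orientation is the corneal apex /
antipode line; both are soft extreme-patch centroids (weights ramp over
0.6 mm below the extremum) so the estimate is geometry- rather than
noise-dominated. Duction is the horizontal-plane angle of that axis
(positive = abduction); duction *change* is additionally (and primarily)
read from the horizontal rotation of the LR–MR insertion chord, whose 24 mm
baseline makes it the steadier estimator. Torsion change is the change of
the insertion chord's elevation angle, which is exactly invariant under
horizontal duction and so decouples from the duction estimate. Insertions
are the anterior band-end patch centroids of the muscle clouds.

**Nerve parameterization.** ON centroids are computed in 0.35 mm bins along
the globe-center-to-apex axis (sparse bins merged). The globe–ON junction
is the intersection of the anterior nerve axis (total-least-squares line
through the eight most anterior centroids) with the globe surface; the
pipeline intersects a least-squares sphere fitted to the (denoised) hull
vertices rather than raw hull facets, whose noise-scale orientation couples
badly with the obliquely incident ray. The pseudo orbital apex comes from
the large-adduction state, where the nerve is straight: the nerve line is
intersected with a right circular cone fitted to the posterior third of the
wall, and the point is held fixed (in the common frame) for all gaze states
of the orbit. Junction + centroids + apex (projected onto the posterior
nerve axis to discard its lateral error) are knots for a least-squares
cubic B-spline with iterative foot-point reparameterization; the basis is
kept ~6× sparser than the knots so centroid noise does not inflate arc
length. Tortuosity is fitted arc length over the junction–apex chord.

**Cross-sections and the material grid.** Stations are placed at equal
normalized *chord* positions between junction and apex. This is the
material correspondence the fixed imaging planes actually provide, and it is
the choice that makes a nonuniform axial strain profile observable at all:
stations at equal normalized *arc* length redistribute arc uniformly by
construction, so any deformation would read as uniform stretch. At each
station, points within a one-spacing slab are projected onto the plane
normal to the tangent; the section is re-centered on the slab centroid
(removing fitted-curve ripple), its convex-hull boundary is resampled at 36
polar angles, and the polar radius is smoothed by a 2-harmonic Fourier fit
(plus Savitzky–Golay along the path). The material grid is
(station × 12 angles × 3 radial shells ρ ∈ {⅓, ⅔, 1}); radii are normalized
per station by the smoothed boundary radius, and the polar origin is a
fixed lab direction projected into each section plane for *both*
configurations — torsion is negligible during horizontal duction, and a
globe-borne angular origin would rotate with duction and twist the
correspondence. Three stations at each end are excluded (partial-volume
truncation at junction and apex).

**Displacements, gradients, strain.** u = deformed − reference position of
each matched grid point, in the registered common frame. Before
differentiation, u is smoothed by a per-ring Fourier projection (harmonics
≤ 2; exact for affine and quadratic fields restricted to a circle) and a
quadratic-preserving Savitzky–Golay filter along the path (window 21
stations ≈ 11 mm): boundary-extraction jitter is station-local while true
displacement fields vary on multi-millimetre scales, and unsmoothed jitter
rectifies into a positive bias of the quadratic strain term. Gradients are
then reconstructed by the 6-nearest-neighbor directional-derivative scheme:
unit neighbor directions form V (3×6), each axis e is expressed as e = VK
with K = (VᵀV)⁺Vᵀe, and the gradient combines the forward-difference
directional derivatives with the same coefficients. The scheme is exact for
affine fields whenever the neighbors span 3-space; near-coplanar systems
(spanning residual > 1e-6 or cond(VᵀV) > 1e8) are flagged and excluded.
Strain is E = ½(∇u + ∇uᵀ + ∇uᵀ∇u) — the ½ factor is the standard
convention and the one consistent with ~5% strain accompanying ~5%
elongation; a compatibility flag evaluates the same sum without it.
Tangential strain is ZᵀEZ with Z the reference station tangent. Summaries
are mean ± SE (SD/√n) in five regions of equal initial length, G1 at the
globe through G5 at the apex.

**Sheath diameters.** ON, CSF-outer (sheath inner) and sheath outer
best-fit circle radii are estimated per station from angular-bin radius
quantiles of the ON and sheath-annulus clouds, inverted under the
area-uniform sampling model (extremes would be noise statistics); the
ONS inner/outer diameters are reported relative to the ON diameter.

## Synthetic orbit generator

The generator emulates the study's inputs, not MR physics: geometry,
labels, anisotropic grid sampling in two randomly offset acquisition
frames (axial offset ≤10°/5 mm), and truncated-Gaussian boundary jitter
(0.1 mm SD, clipped at 3 SD) standing in for segmentation noise.

The canonical left orbit (head frame, mm): rigid globe = 12 mm scleral
sphere + corneal cap protruding 1.5 mm (the cap makes orientation
observable); nerve = 1.5 mm-radius tube around a constant-slope helical
path (one full turn, amplitude 0.9 mm) from the junction (3° nasal of the
posterior pole) to the orbital apex, 26 mm of arc, tortuosity ≈ 1.024;
CSF gap and dural sheath annulus (2.3 / 2.9 mm); LR and MR bands from the
equator insertions to anchors inside the posterior cone; orbital wall =
cone (half-angle 25°) with vertex at the apex, given cos 2φ ellipticity
(8%) and sin 3φ ripple (4%) — a perfect cone would leave wall-based
registration free to spin about the orbital axis, which real orbits do not
permit. The helix is the one perturbation with *constant* slope whose
offset vanishes at both ends, so normalized arc length coincides with
normalized chord position and the fixed-plane correspondence is exactly
material on the reference.

Gaze states rotate the globe about the vertical head axis (positive =
abduction), optionally add torsion about the center–junction line (which
the nerve ignores, matching the observed insignificance of torsion), and
deform the nerve by one of three modes with closed-form Green–Lagrange
fields, all built on rotation-minimizing-frame (twist-free) tube
coordinates, in which the fiber stretch is
λ = |C₁′|(1 − a κ_N1 − b κ_B1) / (|C₀′|(1 − a κ_N0 − b κ_B0)) and
E = ½(λ² − 1) T₀T₀ᵀ exactly:

* `rigid_only` — the nerve swings rigidly about the apex to follow the
  junction (the globe's translation acquires the radial correction needed
  to keep the tether length constant; the recorded ground-truth translation
  is the actual one). E ≡ 0.
* `uniform_stretch` — the adduction regime: the nerve straightens onto the
  junction–apex chord and every fiber along the path stretches by 1 + m;
  centerline tangential strain is exactly ((1+m)² − 1)/2, with the exact
  off-axis correction from unbending the helix.
* `cantilever_bend` — the abduction regime: after the rigid swing, the
  transverse helical slack grows as B(c) = A + m c² of the chord fraction,
  with every material point keeping its chordwise station. Displacement is
  largest at the globe (the swing), tangential strain is ~0 at the globe
  and grows monotonically toward the apex, and tortuosity increases —
  the qualitative pattern reported for abduction. The default validation
  magnitude m = 1.8 mm puts apex-region strain at the upper end of the
  reported abduction regime and keeps adjacent region-mean gaps (≥0.005)
  above the measurement noise floor.

Ground-truth displacement and strain maps agree with central-difference
differentiation to ~1e-9 absolute (validated per mode); a rigid scene's
strain is identically zero by construction.

What the generator does **not** model: MR intensity/bias/k-space, partial
volume beyond raster sampling + boundary jitter, inter-subject anatomical
variability, vertical ductions, nerve torsion, or sheath mechanics.
Passing tests therefore demonstrate the *measurement chain's* geometric
fidelity at the study's sampling, not robustness to segmentation error or
anatomical variation.

## Numerical choices and known limitations

Problem sizes: validation scenes are sampled at the study's native
resolution (0.312/0.390 mm in-plane, 2 mm slices, interpolation factor 6);
an end-to-end gaze-pair analysis runs in ~20–30 s. The small fixture bundle
uses a coarse near-isotropic grid, thinned below 20k points.

Achieved accuracy at those conditions, measured against the analytic truth:
registration ~0.25°/0.1 mm; apex ~0.2–0.5 mm; junction ~0.1–0.3 mm
(incidence-dependent); globe center ~0.03 mm; duction change ~±1°;
translation components ~±0.08 mm; torsion ~±1–3° (the insertion markers are
the limit); regional mean tangential strain ±0.006 typical, with occasional
regions at ±0.01–0.02. The dominant residual error is a ~2 mm-periodic
systematic from slice interpolation of the tube (the original slice
spacing), which survives as a per-station strain oscillation of ±0.02
before displacement smoothing; region means inherit whatever phase lands in
each fifth of the nerve. Steep bend profiles are additionally flattened
~10–25% near the apex by the combination of path-spline smoothing and
displacement smoothing, so the measured monotone increase can stall between
mid regions whose true means differ by less than ~0.006. These limits are
honest properties of the measurement at MRI-like sampling; the strain
validation suite asserts tighter targets (±0.005, strict monotonicity) and
a few of those checks fail marginally, which is reported as-is rather than
tuned away.

Other conventions: right-handed mm coordinates everywhere; voxel (0,0,0)
center at the stack origin; reflections never returned by registration
(SVD sign correction) and appear only, explicitly, in the medial-plane
mirror; Welzl-style exact minimal enclosing sphere (order-invariant);
Nelder–Mead over (azimuth, elevation, offset) for the medial plane, seeded
by the centroid bisector; convex-hull collinear ties resolved by Qhull's
deterministic processing; all random choices (subsampling, multistart
order) are seeded and runs are bit-reproducible.
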