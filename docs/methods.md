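# Methods

## Coordinate conventions

All geometry lives in a right-handed laboratory frame with its origin at
the intersection of the primary beam and the sample.  Defaults — beam
propagation along (0, 0, 1), goniometer rotation axis (+1, 0, 0) with
right-handed sense — are a stated convention of this package, overridable
by any format class.  Positions are millimetres, wavelengths angstroms,
and all angles at public interfaces degrees (image headers store degrees;
radians appear only inside the math).  Vector pairs are always
(fast, slow).  A panel's origin is the outer corner of pixel (0, 0) on the
front (sample-facing) sensor surface.  Pixel coordinates are continuous
with pixel centres at half-integers; the integer index of a continuous
coordinate is its floor.

## The d-matrix projection

A panel's geometry is the 3×3 matrix d = [f | s | o].  Projection of a
scattered ray direction onto the panel solves d·(x, y, 1)ᵀ ∝ s by a single
matrix inverse: v = d⁻¹s, intersection (v₁/v₃, v₂/v₃).  v₃ ≤ 1e-10 (in
d⁻¹s units) is treated as "no intersection" — the ray is parallel to the
plane or exits through the back hemisphere.  A panel plane passing through
the lab origin makes d singular and is reported as degenerate geometry
rather than silently regularized.  Detector-level lookup returns the
lowest panel id among inside-limits hits (a deterministic tie-break for
panels that overlap in projection; nearest-panel selection would be a
defensible alternative, not adopted) and returns "no hit" as a value, not
an exception, because prediction off-detector is a normal outcome.

Panel axes must be unit and mutually orthogonal to 1e-7; violations are
rejected at construction instead of re-orthogonalized, because silent
repair hides format bugs.  Hierarchies are resolved by composing each
ancestor group's frame (rotation columns: fast, slow, fast×slow, plus
translation) depth-first; the flat panel order is the depth-first leaf
order.

## Parallax correction

For thick sensors the photon converts below the entry surface, displacing
the recorded position along the in-plane component of the incident ray.
The adopted model is first-principles Beer–Lambert slab absorption: the
ray from the sample to the front-surface point makes angle θ with the
panel normal (cos θ = |ŝ·n̂|), traverses path T = t₀/cos θ inside a sensor
of thickness t₀ (mm) and linear attenuation coefficient μ (mm⁻¹), and
converts at mean depth along the ray

    t̄ = 1/μ − T·e^(−μT) / (1 − e^(−μT)),

the first moment of the truncated exponential on [0, T].  The recorded
position is the entry point plus t̄·(ŝ − (ŝ·n̂)n̂) expressed in panel
coordinates.  t̄ is evaluated with expm1 so the thin-sensor limit
(t̄ → T/2 as μT → 0) is numerically stable; both limits t₀ → 0 and μ → ∞
collapse the mapping onto the simple pixel-size division.  Depth is
measured *along the ray* (not along the panel normal); this is a design
choice of this package, verified against a numerical-quadrature oracle in
the tests.  The correction direction uses the ray toward the queried point
itself, since the true diffracted ray is unknown at this layer; the
inverse mapping is therefore a fixed point, solved by iteration
(tolerance 1e-8 mm, at most 20 iterations — in practice 3–4 suffice
because the offset varies slowly across a pixel).

## Scans, sweeps and grouping

Scans are 1-based inclusive image ranges with a start angle and a
per-image oscillation width; a still has width 0.  Two scans append only
when the image numbers are consecutive, the widths equal, and the second
scan starts where the first ends within 1e-3·Δφ (absolute floor 1e-6°) to
absorb header rounding.  Filename sequences are detected by replacing the
last run of digits in the name with a placeholder; files sharing the
resulting template are sweep candidates ordered by that number.  Within a
format class, consecutive candidates merge into a sweep when their beam,
detector and goniometer models compare equal (1e-9 absolute on vectors,
exact on integer fields) and their scans append; a gap in numbers or
angles splits the sweep, stills are never merged even when models match,
and sweeps never span filename templates (re-numbered continuation runs
are not bridged).  Grouping sorts canonically by (template, number), so
the result is independent of input order.  Sweeps, sets and all their
subsets are flyweight views holding a reference to one shared reader, and
a sweep's models are single shared objects.

## Format plugins

Format classes form a tree rooted at a universal anchor; children only
specialize, so a class understands a file only if its whole ancestor chain
does.  Lookup returns the deepest understanding class, first-registered
winning among equal depths.  `understands` is header-only by contract —
interrogation runs over many files and must never touch pixel data.  The
two beamline-variant classes (reversed rotation axis; 2θ arm) gate on the
detector serial number; the gate values (915, 926) are synthetic fixture
constants configurable per class, since the mechanism rather than any
particular constant is the contract.  On the 2θ arm the header beam centre
is recorded at the 2θ offset, so the child class rotates the parent's
whole panel frame by −2θ about lab (1, 0, 0); the arm axis and sense are
this package's convention.  SMV beam centres are interpreted in
millimetres, X along fast and Y along slow — one documented dialect;
pixel-unit variants would be further subclasses.  A plugin directory of
`.py` files is loaded at startup (CLI flag `--plugin-dir` or
`DXT_PLUGIN_DIR`); each file is executed and its format subclasses
registered parents-first; a broken plugin is logged and skipped, never
fatal.

## Serialization

One JSON document schema (version "1") covers bare model sets and full
datablocks, discriminated by a top-level `kind`.  Keys are emitted sorted
and floats at full repr precision, so a document re-serializes to
identical text after a round trip.  Unknown keys are retained on read and
re-emitted.  Loading re-runs every constructor invariant (unit axes,
orthogonality, positive sizes) and names the offending field; a stored
hierarchy must flatten to exactly the stored panel list.  Pixel data is
never embedded — image paths are stored relative to the document's
location.

## Synthetic data

The fixture generator emulates a compact rotation experiment: one
400×400 panel of 0.1 mm pixels 150 mm from the sample, beam centre
(20, 20) mm, λ = 0.9795 Å, 0.5°/image, flat background of 40 counts with
Poisson noise, spots of a few thousand counts.  Spots are arbitrary unit
rays, not Bragg reflections — there is no lattice and no Ewald-sphere
construction — each rendered as a 2-D Gaussian (σ = 1.5 px, truncated at
4σ) centred at the pixel position the package's own projection predicts
for its ray.  Random spot placement enforces a 16 px minimum separation
so each blob is individually resolvable; overlapping blobs have no
meaningful per-spot centroid.  All randomness flows from a single stated
seed and the SMV and HDF5 writers share one renderer, so identical specs
produce byte-identical pixels in both containers.  Consequences for what
the tests show: passing closure demonstrates geometric self-consistency
of generation and readback on clean, well-separated Gaussian spots; it
says nothing about real detector point-spread functions, spot overlap,
icing, or header dialects beyond the ones modelled.

Spot recovery uses an unclipped background-subtracted intensity-weighted
centroid over a window matched to the blob truncation radius (negative
residuals are kept; clipping them biases the centroid toward the window
centre), averaging the sweep's frames since the spots are static while the
noise is not.  At the default conditions (4000-count spots on a 40-count
background, 25 spots, 3 frames) the worst-case recovery measured over 20
independent seeds is ≈0.17 px and ≈1.1e-4 rad.

## Problem sizes and verification

The oracle-based checks run at desk scale, chosen as comfortably
convergent for each statistic: 1000 random panel/ray pairs for the
projection-vs-linear-solve comparison, 100×100 mm grids per strategy for
px↔mm inversion, a 7×6 (μ, T) grid against scipy quadrature, 20
input-order shuffles for grouping invariance, 200 randomized model draws
for serialization, 25 spots × 3 images for closure.  The whole suite and
the acceptance script each complete in a few seconds.

## Known limitations

Curved sensors, per-pixel distortion grids and optical-taper maps are out
of scope (the panel abstraction is a bounded rectangular plane; the
strategy layer is where a taper map would live).  The crystal model and
multi-axis (κ) goniometer parameterizations are not modelled — a single
arbitrary axis vector covers arbitrary orientation but not named axis
composition.  Energy dependence of μ is not modelled.  CBF/imgCIF binary
parsing is not implemented; only its geometric conventions are adopted.
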