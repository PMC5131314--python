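# Methods

This note records the models, conventions and numerical choices behind the
package, what the synthetic phantoms do and do not emulate, and the known
limitations.

## Coordinate and unit conventions

Stacks are `(z, y, x)` arrays with z the sample-translation (axial) axis.
All lengths are micrometres; volumes are reported in mm³. The default voxel
spacing is `(dz, dy, dx) = (16, 4, 4) µm`: a ~16 µm translation step between
frames, and a ~4 µm camera pixel (a 10 mm field of view on a 2,560-pixel
detector). Voxel `(i, j, k)` has its physical centre at
`(i·dz, j·dy, k·dx)`; a voxelized body contains a voxel iff that centre lies
inside the analytic surface. Orientation matrices act on `(x, y, z)`
vectors, columns being the directions of the `(a ≥ b ≥ c)` semi-axes, so the
identity orientation puts the major axis in the imaging plane.

Spacing on disk follows the precedence *explicit argument > sidecar JSON
(`{"spacing_um": [dz, dy, dx]}`) > TIFF tags*: an explicit, versionable
sidecar wins over writer-dependent tag conventions, and a stack with no
spacing at all is an error because every downstream quantity is physical.

## The phantom: what it emulates

A follicle is modelled as a radially layered star-convex body. Along each
direction `u` from the centre, the outer (thecal) surface lies at the
ellipsoid radius `r(u)`; the theca–gap, gap–granulosa and granulosa–antrum
interfaces lie at `r(u) − t(u)`, `r(u) − t(u) − g` and
`r(u) − t(u) − g − w`, where `t(u)` is the wall thickness, `g` the
delamination-gap width and `w` the granulosa width. The wall thickness
carries a smooth degree-2 angular modulation
`t(u) = t₀·(1 + m·[cos φ₀·(uₓ² − u_y²) + sin φ₀·2uₓu_y])`, bounded in
`t₀(1 ± m)`, so each follicle has a nondegenerate thickness distribution.
When the layers consume the whole radius the body degenerates into a solid
bright blob — that is how primary follicles (no antrum yet) are modelled.
The COC is a bright sphere placed tangent to the granulosa inner surface
(biting 2 µm into it so attachment survives voxelization). Vessels are
tubes of constant radius around polylines; egg nests are clusters of small
solid spheres placed by rejection sampling from the scene seed.

Intensity levels are abstract grayscale values ordered
`COC > theca > vessel > granulosa > background > gap ≈ antrum`; no
radiometric calibration is attempted.

Imaging physics is reduced to two effects. (1) The light sheet is thinnest
at its waist and thickens away from the centre of the field: the axial PSF
FWHM is interpolated **linearly** from 11 µm at the waist to 60 µm at 3 mm
lateral distance, clamped beyond — only two calibration points are
available, so a Gaussian-beam hyperbola is not forced on them. (The
alternative 16 µm waist calibration is available as a config value.)
Columns are binned into 24 quantized widths and filtered per bin. (2) Noise
is shot noise (Poisson at `photon_scale` photons per intensity unit,
default 2.0) plus additive Gaussian read noise (default 1.0 e⁻), giving
`Var = L/photon_scale + σ_read²` at level `L`; negative values are clipped
at zero.

Not emulated: refractive-index mismatch, scattering, vignetting, multi-view
fusion, and the ~4% clearing shrinkage beyond its static signature (the
delamination gap). Passing phantom tests therefore demonstrates geometric
and statistical correctness of the measurement chain, not robustness to
optical artefacts absent from the model.

Determinism: the scene seed fully determines the rendered stack and truth
manifest, bit for bit.

### Ground truth

Per follicle the manifest stores the analytic outer volume `(4/3)πabc`, an
inner-volume variant with the base wall subtracted, the analytic
equatorial major/minor ratio (from the 2×2 block of the rotated quadratic
form — the central plane is the maximal-area plane of an ellipsoid), the
per-angle wall thickness in the equatorial plane (360 outer contour points
against a 2,160-point inner contour, i.e. a purely geometric oracle
independent of any voxel grid), the COC diameter and centre, and the stage
implied by the equivalent diameter.

## Segmentation

Pipeline: Gaussian denoise (5 µm) → threshold (Otsu by default; absolute
override available) → morphological closing (12 µm ellipsoidal footprint,
scaled per-axis by the spacing) → 3D hole filling → watershed split of
touching follicles → 26-connected components → physical size filter
(default minimum equivalent diameter 40 µm) → vessel reclassification.
Component labelling uses 26-connectivity; boundary adjacency uses
6-connectivity (faces): robust components, thin consistent boundaries.

The watershed is seeded at **lumen cavities**: the enclosed dark regions of
the filled mask. One follicle contributes concentric cavities (gap and
antrum), so cavities closer than 20 µm are merged into one seed first; the
watershed (on the negated Euclidean distance transform in physical units)
runs only on components holding two or more seed groups, leaving isolated
follicles untouched.

Components below the size filter but within 40–100 µm and solid (no
enclosed cavity) are retained as `primordial_candidate` for egg-nest
counting only.

Vessels are separated from follicles by 3D elongation: the ratio of the
longest to second-longest principal axis of the component's voxel
coordinates (physical units) exceeds 4.0 for vessels, which thread many
planes, while follicles appear and disappear quickly along z. Perfectly
straight one-voxel filaments (degenerate second axis) count as vessels; a
single voxel counts as a follicle.

### Shell decomposition

Inside each labelled follicle, voxels are split into three intensity
classes (multi-Otsu on a 3 µm-smoothed crop): dark (gap, antrum, and the
dim blur margin the closing step leaves outside the shell), intermediate
(granulosa), and bright (theca and COC). The theca is the bright class
connected to the component's outer rind — the COC is bright too but floats
in the lumen and stays out. Because the upper multi-Otsu cut sits above the
half-intensity edge and erodes a blurred shell by one to two voxels per
side, the theca is grown back by a two-step dilation constrained to voxels
above the dark/bright midpoint; the dark gap blocks leakage into the
granulosa, and two steps cannot travel far where it does not (the thin gap
at the axial poles of a follicle, where the layer spacing falls below the
z-step). The delamination gap is then the dark band face-adjacent to the
theca inner edge; the lumen is the remaining interior (granulosa + antrum +
COC).

Degenerate cases are explicit decisions:

- **Solid blobs** (no cavity after a small closing of the theca, threshold
  2% of the component): returned shell-less; volume, asymmetry and staging
  remain valid, wall and COC metrics are absent (`None`, never zero).
- **Cracked shells** (a cavity exists once the shell is closed with an 8 µm
  footprint, but plain hole-filling leaks through a crack): raise
  `ShellNotClosedError` naming the follicle. A wall opening too wide for
  the closing step is indistinguishable from "no shell" without stronger
  priors and is treated as solid.
- The whole-follicle mask keeps the segmentation label (which tracks the
  half-intensity outer edge and therefore the true volume) and is united
  with the filled shell; compartments live inside the shell hull, so the
  blur margin belongs to no compartment. On exact (truth or manual) masks
  the margin is empty and theca ∪ gap ∪ lumen partitions the whole mask.

### COC detection

Within the lumen, a first Otsu cut separates dark antrum from the bright
population (granulosa lining and any COC). If that population's median is
well below its brightest tail (< 0.7× the 99.5th percentile), a second cut
midway between median and tail isolates the blob; otherwise the first cut
already did (small follicles whose lining fell below it) — unless "bright"
is most of the lumen, which is the lining itself and means no detectable
COC. Candidates must be solid (≥ 70% of their filled hull — a
mis-thresholded lining is a shell), within a 25–150 µm band (volume-
equivalent diameter ≥ 70% of the lower bound; maximal extent below the
upper), and attached — within 30 µm of the lumen surface, evaluated with a
single distance transform. The largest accepted blob is the COC (at most
one per follicle); it is grown back to its half-intensity edge (four
constrained dilation steps, blocked by the dark antrum) before sizing, and
everything else is reported as a candidate. An empty result is normal —
COCs are detectable in roughly 70% of follicles.

## Measurement conventions

- **Equatorial plane**: z-plane of maximal cross-sectional voxel count;
  ties break to the lowest index.
- **Asymmetry**: square root of the eigenvalue ratio of the second-moment
  matrix of pixel centres (µm) in the equatorial section. Reported as
  major/minor (≥ 1); the reciprocal is emitted alongside
  (`asymmetry_inverse`) so either plotting convention is available.
  Sections need ≥ 5 pixels; collinear sections are an error.
- **Wall thickness**: measured in-plane on the equatorial plane (matching
  the per-plane measurement procedure), not as a 3D surface-to-surface
  distance. Samples run from each outer-boundary theca pixel to the nearest
  pixel of the *inner edge* — the first interior non-theca pixels, where
  the dark delamination band begins. Measuring instead between two
  theca-pixel sets would bias a constant-width wall one pixel short from
  each side (≈ −4.5 µm at 4 µm pixels on a 100 µm wall); with the
  edge-pixel convention a voxelized 1 mm / 100 µm shell reads
  98.9 ± 1.2 µm. Distances are pixel-centre to pixel-centre; sub-pixel
  interpolation is out of scope and the error budget is one in-plane voxel.
  The search is a vectorized chunked minimum over squared physical
  offsets — identical arithmetic to a brute-force double loop, verified
  bitwise in the tests.
- **Orthogonal-chord estimate**: longest chord between boundary pixels on
  opposed rays through the section centroid (2° angular tolerance — the
  procedure mimics a manual caliper act, not an exact algorithm), then the
  perpendicular chord through its midpoint, sampled at 1 µm steps; the
  average of the two is returned.
- **COC diameter**: equivalent-circle diameter of the maximal-area plane of
  the COC mask. At the default 16 µm z-step, plane quantization alone can
  clip up to ~7% from a 45 µm COC's middle plane; measured errors on
  phantom COCs of 45–105 µm stay within 10%.
- **Staging**: the antral interval is closed (`d = 100 µm` and `d = 700 µm`
  both class antral); no open/closed convention is universal, so one is
  fixed and documented. A `primordial` label is only ever attached by the
  egg-nest counting pass — no diameter threshold separates primordial from
  primary, and none is invented.

## Cohort statistics

Per-stage volume summaries report n, mean, median and linearly interpolated
quartiles (`numpy.percentile` default), formatted `mean [Q1–Q3]` in mm³.
The oocyte growth curve defaults to the saturating hyperbola
`o = a·d/(b + d)` (oocyte size plateaus in large follicles); a log-linear
alternative is one flag away. When an independent validation point set is
supplied, R² and adjusted R² score the fitted curve against it — the
pattern used to compare measured growth data with literature values.
`adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1)` exactly. Size-trend
analyses are OLS of the response on `log₁₀ V` via statsmodels; slopes are
negative for both asymmetry and wall thickness in developing cohorts. No
hypothesis tests or p-values are produced.

The measurement-level cohort simulator draws per-stage lognormal volumes
with quartiles `[3.0, 5.0]·10⁻⁴` (primary), `[2.9·10⁻³, 3.8·10⁻²]`
(antral) and `[0.15, 2.63]` mm³ (Graafian); wall thickness
`84.7 − 19.6·log₁₀V ± 8 µm` (≈ 120 µm for antral through ≈ 90 µm for the
largest Graafian follicles); asymmetry `1.04 − 0.15·log₁₀V ± 0.12`,
clipped at 1; and COC diameter on the hyperbola `a = 125 µm, b = 210 µm`
± 8 µm, observed for 70% of follicles. With these noise levels the
log-volume regressions recover negative slopes in ≥ 95% of seeded runs at
n = 20, and R² values fall in the 0.6–0.9 range typical of small
morphometric cohorts. Note the per-stage lognormal spreads are wide
(σ ≈ 1.9–2.1 for antral/Graafian): a single n = 50 sample median scatters
by tens of percent, so median-recovery checks aggregate over seeds.

## Reference phantom cohort and problem sizes

The end-to-end reference scene (`example_cohort_spec`) covers
110×512×512 voxels (~1.8×2×2 mm of tissue) and holds ten follicles — three
solid primaries (62–86 µm), six antral (160–600 µm) and one Graafian
(939 µm) — plus two vessels, with default blur and noise. Wall thicknesses
scale with follicle size (25–90 µm): a 160 µm follicle cannot geometrically
carry the ~120 µm wall of a large antral follicle, so the 90–120 µm band
belongs to the large-follicle regime of the statistical simulator, not to
small imaging phantoms. COCs of 45–105 µm sit on the inner wall of the
antral/Graafian follicles. The full chain (render, segment, decompose,
measure, score) runs in well under a minute on one CPU within ~1.5 GB.
Streaming of full-depth acquisitions (600 planes) is exercised via
memory-mapped TIFF reads at reduced in-plane size; measurement tests use
bodies up to 2.5 mm equivalent diameter, voxelized in their own bounding
volumes.

## Known limitations

- Intensity-threshold shell extraction under blur retains a residual
  negative thickness bias of roughly one in-plane voxel (−4% on thick
  walls, up to −15% on 25 µm walls at default blur); measurements on exact
  masks are unbiased. Sub-pixel edge localisation would remove this and is
  deliberately out of scope.
- The vessel criterion is purely geometric; a vessel shorter than ~4
  diameters inside the volume would classify as a follicle.
- Watershed splitting relies on distinct lumens; solid (pre-antral)
  follicles that touch are not split.
- Atresia is not classified — no morphological criterion is available to
  implement honestly.
- The phantom's intensity ordering is fixed; stains or clearing protocols
  that invert contrast would need a parameter change, not new code.
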