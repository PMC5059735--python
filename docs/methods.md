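# Methods

## Shape descriptors

Particles are 8-connected components (the ImageJ convention; configurable
to 4) of the binarized mitochondrial channel, with components below
`min_particle_area_px` (default 4) discarded as shot-noise specks.

**Circularity** is the dimensionless `4π·area/perimeter²`, clamped at 1.
The perimeter uses the 4-direction Crofton estimator rather than boundary-
pixel counting, which systematically overestimates boundary length and
depresses circularity; the clamp absorbs the residual small-object bias
that can push few-pixel blobs slightly above 1.

**Aspect ratio** is the major/minor axis ratio of the moment-equivalent
ellipse. The second central moments are computed with each pixel modeled
as a unit square, adding 1/12 to both diagonal covariance terms; a solid
w×h rectangle then has variances exactly w²/12 and h²/12, a single pixel
is exactly isotropic (AR = 1), and 1-px-wide lines stay finite. Axes are
`4·sqrt(eigenvalue)`, so a filled ellipse recovers its own axes. This
differs from estimators that use raw discrete moments, which degenerate on
single-pixel and collinear particles. The implementation is checked against
a brute-force covariance computation on an exhaustive sweep of all fixed
polyominoes up to 8 pixels plus randomized larger masks, at 1e-9.

Both descriptors are exactly invariant under 90° rotations, flips and
translations of the particle mask, and the whole measurement is invariant
under global intensity rescaling because binarization is rank-based per
cell.

## Segmentation

Nuclei: Gaussian smoothing (σ = 2 px) → Otsu → hole filling → area filter
(≥ 200 px) → watershed on the (smoothed) distance transform seeded at
h-maxima of depth 2. Smoothing the distance map before the h-maxima
transform is essential: boundary wobble from photon noise otherwise spawns
spurious maxima that split elongated nuclei.

Cells: seeded watershed with the smoothed membrane channel as elevation
(membrane-bright ridges become basin boundaries) restricted to a foreground
support (Otsu on the smoothed membrane+mito composite, union the nuclei).
Including the mitochondrial channel in the support guarantees that
mitochondria-bearing cytoplasm always belongs to some cell. Thresholds are
global per image — the model assumes reasonably uniform illumination, and
no flat-field correction stage exists. Cells below 2000 px or touching the
image border (default policy) are removed, because truncated mitochondrial
networks would bias the descriptors; surviving labels are never renumbered,
keeping ids traceable.

Binarization of the mitochondrial channel is deliberately per cell: after
a white top-hat (disk radius 8 px) removes smooth background, Otsu's
threshold is computed over each cell's pixels separately, so dim and
bright cells are measured on equal footing. A cell with constant intensity
has no defined threshold and is omitted with a warning.

## Statistics

The unit of analysis is the cell. Per-cell descriptor means (unweighted
over the cell's particles) feed condition summaries (mean, sample SD with
n−1) and two-sided Welch t-tests; Student's pooled test can be selected in
the config but Welch is the default because equal variances across
conditions cannot be assumed. Stars follow 0.05/0.01/0.001. No
multiple-testing correction is applied — each comparison against the
control is reported on its own, which the reader should keep in mind when
many conditions are screened. Donor/experiment structure is not modeled
(no mixed effects); cells are pooled within a condition.

## Synthetic fields

The generator exists to validate the operators, not to photorealistically
imitate keratinocytes. A field contains disjoint star-convex polygonal
cells (radius sampled from 15–25 µm; interior placement preferred, with a
hex-grid fallback and border-clipped cells when crowded), one elliptical
nucleus per cell, and per-cell mitochondrial skeletons with a fixed total
length budget (250 µm) drawn at the nominal tubule width (0.4 µm).

A single fragmentation parameter f ∈ [0, 1] controls the phenotype. The
budget is split over `n_frag = round(2 + 38·f)` fragments (Dirichlet
shares, so fragment lengths vary around budget/n_frag while the per-cell
total stays exact). Each fragment is a serpentine-coiled tubule filling an
elliptical territory at a pitch equal to the tubule width; the territory
aspect interpolates from 6 at f = 0 down to 1 at f = 1. Coiling at
sub-resolution pitch makes the rendered fragment a compact filled region
whose moment aspect ratio tracks the territory aspect and whose
circularity rises smoothly with f — the minimal geometry that reproduces
the tubular-to-punctate descriptor axis while keeping every stated
invariant (exact length budget, fixed width, curves inside the cell and
outside the nucleus, disjoint fragments). Two deliberate feasibility rules:
the territory semi-minor axis is capped at 7 px so no structure is wider
than the top-hat scale of the measurement pipeline (a wider ribbon would
be hollowed by background subtraction — a real artifact the generator
should not manufacture), and territories too long for the cell's usable
chord are bent along an arc around the nucleus instead of being shortened.
At f = 0 a fraction of fragments (branch_prob = 0.15) grows a side spur
from its length budget, emulating branch points of hyperfused networks.
Fragments keep a 4-px guard gap so optical blur cannot merge them: ground
truth and pipeline therefore agree on particle counts, and recovery errors
measure binarization fidelity rather than geometry ambiguity.

Rendering: nucleus channel = filled ellipses; membrane channel = 2-px
bright boundary band plus dim cytoplasm (25% of ridge intensity); mito
channel = rasterized fragments with a per-cell staining-efficiency factor
(uniform 0.6–1.0). Each channel is convolved with a Gaussian PSF
(σ = 1.2 px), scaled to photon counts (200 at unit intensity), Poisson
sampled, plus Gaussian read noise (SD 3) and a constant offset (10).
Geometry and optics have separate seeds so a scene can be re-imaged.
Pixel size defaults to 0.2 µm, plausible for a 63×/1.42 NA confocal; the
descriptors themselves are dimensionless, so pixel size affects only
µm-denominated outputs.

What the generator does **not** model: photobleaching, chromatic shift,
uneven illumination, z-structure, cell motion, organelle texture, and
real network topology (no fission/fusion kinetics — f is a static dial).
Passing the validation suite therefore demonstrates that the operators
measure what they claim on resolvable, well-separated structures under
realistic shot noise; it does not certify performance on densely
overlapping networks beyond the optical resolution limit, where any
intensity-threshold method degrades.

## Validation experiments and problem sizes

Validation uses single-cell fields (512², one interior cell each) so that
"n cells per condition" maps to n independently seeded fields; 30 cells
per condition, mirroring common practice for this kind of quantification.
The suite checks, at these sizes: strict monotonicity of both condition-
mean descriptors over f ∈ {0, 0.25, 0.5, 0.75, 1}; automatic-pipeline
recovery of ground-truth condition means within 15% relative at
f ∈ {0, 0.5, 1}; agreement within 10% between the automatic and
supplied-mask routes on the same rendered fields; and p < 0.001 (Welch)
for both descriptors between f = 0.15 and f = 0.75 at 30 cells per
condition. Typical measured values: condition-mean circularity rises
≈ 0.24 → 0.91 and aspect ratio falls ≈ 7.3 → 1.2 across the f sweep, with
recovery errors ≤ 8%.

## Numerical and design notes

- Watershed, Otsu, top-hat, Crofton perimeter and connected components come
  from scikit-image/scipy; the descriptor moments, the per-cell
  binarization protocol, the generator and the statistics layer are
  implemented here.
- The top-hat uses a sequence-decomposed disk footprint (near-linear cost
  in radius).
- Particles straddling a cell boundary are assigned to the majority cell
  and never split; components entirely on background are dropped.
- Cells that end up with zero particles are omitted from statistics with a
  warning rather than contributing undefined means.
- Label images preserve label values through filtering; tables are written
  at 6 significant digits, and identical configs + seeds reproduce output
  CSVs byte-for-byte (the run manifest's timestamp is the only
  non-deterministic artifact).
- TIFF channel binding is by explicit config only; acquisition metadata is
  ignored by design. Whether the original acquisitions used a different
  bit depth or pixel size does not affect the dimensionless descriptors.
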