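# Methods

`nucleidetect` implements a segmentation-free, feedback-adaptive pipeline for
detecting, sizing, segmenting and tracking cell nuclei in 4D (3D + time)
fluorescence recordings of early embryos. This note documents the model and
its assumptions, the parameters that matter, the numerical choices made where
the design was genuinely open, and what the synthetic validation data does and
does not show.

## The detection model

Nuclei are modelled as bright, quasi-spherical blobs on a dark background.
Each 3D frame passes through:

1. **Preprocessing.** A 3D median filter (default window 5 × 5 × 3 voxels;
   smaller along z because the native sampling is coarser) removes impulsive
   bright spots such as chromatin speckles. The z axis is then resampled by an
   interpolating cubic spline so that voxels become approximately isotropic:
   the new slice count is `round(nz * dz / dx)` and the voxel size becomes
   `(dx, dy, dx)`. All later stages work on this isotropic grid.

2. **Candidate regions.** Otsu's global threshold (256 histogram bins over
   the frame's intensity range) separates foreground from background. The
   *candidate-region image* keeps the preprocessed intensities on the
   foreground mask and zeroes the background. No morphological cleanup is
   applied; later stages absorb mask imperfections.

3. **Adaptive Gaussian enhancement.** The candidate image is convolved with
   separable isotropic Gaussians whose support length `L` (voxels, odd) is
   tied to the spread by `sigma = (L - 1) / 6`, i.e. the kernel spans ±3σ.
   *Single-scale* mode uses one length `L_avg`; *multiscale* mode evaluates a
   ladder of lengths `L_min, L_min + dL, …` (capped and completed by
   `L_max`; even lengths are promoted to the next odd integer) and combines
   the responses voxelwise by maximum. Because the kernels are unit-sum
   (mean filters), the raw center response over a blob decreases
   monotonically with σ, and a plain maximum would always select the
   smallest — noisiest — scale inside every object. Responses are therefore
   weighted by `(sigma_s / sigma_0)^{3/2}` before the maximum, the
   unit-energy (matched-filter) normalization under which the scale matched
   to the local object size genuinely wins. With this weighting the
   multiscale output still dominates every unweighted single-scale response
   voxelwise, and a one-scale ladder reduces exactly to single-scale
   enhancement.

4. **Centroid extraction.** *Stage 1* computes, for every foreground voxel
   of the enhanced image, the characteristic ratio — the percentage of its
   in-bounds 26-neighbors with strictly lower intensity — and keeps voxels
   with ratio ≥ τ_r (default 100, i.e. strict local maxima; exact plateaus
   are kept when a voxel is ≥ all neighbors and > at least one, so perfectly
   symmetric objects are not lost). 26-connected components of the kept
   voxels are averaged into initial centroids (fractional coordinates).
   *Stage 2* extracts three orthogonal intensity profiles of
   `profile_length` voxels about each candidate (clipped at the frame
   bounds) and keeps the candidate iff at least a fraction τ_s (default 2/3)
   of the profiles is concave at the center: central value ≥ both endpoints,
   strictly above at least one (flat plateaus fail), and non-positive second
   central difference. *Stage 3* merges fragments by single-linkage grouping
   at distance τ_d, replacing each group by its unweighted mean.

5. **RGM sizing.** Around each centroid (rounded to the voxel lattice) the
   radial gradient magnitude is computed on the enhanced *candidate-region*
   image (background re-zeroed): `F(r)` is the mean intensity inside the
   concentric sphere of radius r, `A(r)` the mean over the annulus
   `(r−1, r]`, and `RGM(r) = |F(r) − A(r)|` for r = 1…r_max, with
   out-of-frame voxels excluded from every mean. RGM rises from the center,
   peaks at the object boundary and decays. The maximizing annulus
   `(r−1, r]` straddles the boundary: its inner radius r−1 bounds the object
   while r already lies in background, so the estimate is
   `r_opt = argmax − 1` (ties to the smallest r) and the diameter is
   `D = 2 · r_opt`. On an ideal binary sphere of radius R the maximizing
   annulus is `(R, R+1]` and the estimate is exactly R. The search range is
   `r_max = 1.5 · L_max / 2`, capped per centroid by the distance to the
   nearest frame border.

6. **Feedback.** Detections with `D < T_s` (default 10 voxels, diameter
   units, boundary inclusive) are screened out of the statistics; the
   min/mean/max diameters of the rest become the filter lengths for the next
   frame (`L_min = w·D_min`, `L_max = w·D_max`, `L_avg = w·D_mean`, odd-
   rounded; w = 1 for Gaussian filters), the Stage-2 profile length becomes
   the mean diameter, and τ_d becomes half of it. Only the first frame needs
   user-supplied lengths. If a frame retains no detections the previous
   parameters are carried forward with a warning.

Two readings of "the enhanced image" are deliberately separated: **centroid
extraction** (Stages 1–3) reads the enhanced image itself, where oversized
filter lengths genuinely bury small nuclei under neighboring response tails —
the documented failure mode of fixed-length filtering — while **sizing**
reads the re-masked enhanced candidate-region image, whose boundary
information comes from the scale-independent Otsu mask edge. This split is
what lets the feedback re-estimate correct lengths within a single frame even
when the initial lengths are wrong by a factor of five, while the same wrong
lengths progressively degrade a non-adaptive run.

### Variants

* **proposed** — multiscale enhancement, Stages 1–3, RGM feedback; the size
  threshold acts at an intermediate stage (feedback statistics only), so
  small true nuclei are not discarded from the output.
* **v1** — single-scale enhancement (length = fed-back mean diameter),
  otherwise as proposed.
* **v2 / v3** — simplified multiscale / single-scale: Stage 1 only, with the
  RGM size threshold as the final detection filter. These need no τ_s/τ_d
  but can drop small or low-contrast nuclei whose estimated diameter falls
  below T_s — their documented failure mode.
* `feedback=False` reproduces the fixed-length non-adaptive baselines for
  the robustness comparisons.

### Segmentation and tracking

Centroid-driven volume segmentation assigns to each final detection the ball
of its RGM radius, intersected with the Otsu mask; voxels claimed by several
balls go to the nearest centroid (ties to the lowest label). Tracking links
detections of consecutive frames greedily by ascending Euclidean distance
(each detection used once, links capped at 25 voxels) and chains the links
into trajectories; the population is assumed fixed, with unmatched detections
starting or ending tracks. Greedy matching equals optimal assignment whenever
displacements are below half the nearest-neighbor distance, which the tests
verify against a Hungarian oracle.

## Evaluation

Detection is scored per frame against ground-truth centroids with a spherical
window of radius `d_eval = 10` voxels: each GT point, visited in index order,
consumes the nearest unconsumed estimate inside its window (TP); then
`FP = n_est − TP`, `FN = n_gt − TP`, and sensitivity / precision / F-measure
follow. Precision with zero estimates is reported as 0 rather than NaN.
Additive-noise robustness uses white Gaussian noise of spread σ_n with
`SNR(dB) = 10·log10(mean(I²)/σ_n²)`, the clean-image mean-square power over
the noise variance.

## Synthetic data

The generator emulates the recorded embryo data: frames of 103 × 103 × 51
voxels at (0.8, 0.8, 2.0) µm; 2–32 nuclei rendered as soft-edged spheres
(smoothstep edge, ~2 voxels wide; the nominal radius is the half-maximum
radius) with per-nucleus peak intensities 140–200 on background 20;
impulsive bright speckles plus weak smooth modulation inside nuclei;
exponential fluorescence attenuation along z; and additive Gaussian noise at
a target SNR (default 15 dB). Anisotropy is physical: spheres are compressed
along z in voxel units and recover their shape after z-isotropization.
Divisions replace a parent by two daughters of radius `parent / 2^{1/3}`
(volume conserving) that appear about one child diameter apart after
anaphase and drift to roughly two diameters over three frames. A
collision-relaxation pass keeps all nuclei non-interpenetrating (nuclei are
solid bodies; without this the ground truth would contain permanently fused
pairs that no detector could resolve). Blastocyst-stage frames confine the
nuclei to the frame's inscribed ellipsoid (scaled by `ball_frac`), because
cells pack inside the roughly spherical embryo volume.

Validation problem sizes were chosen to exercise every mechanism at desk
scale: a 20-frame sequence stepping 8 → 32 nuclei with diameters ~12.6–25.4
isotropic voxels for the accuracy and parameter-robustness experiments, a
32-nucleus condensed frame for the noise sweep (8 levels spanning ≈40 → 5 dB),
and 100 single-sphere trials for radius recovery.

What passing on this data shows — and what it does not: the synthetic nuclei
are geometrically ideal spheres with exact ground truth, so the experiments
isolate the algorithmic claims (matched-scale enhancement, boundary-accurate
sizing, one-frame parameter recovery, the failure of fixed oversized
lengths). Real recordings add mis-segmented ground truth, non-spherical and
overlapping nuclei, depth-dependent blur and photobleaching, none of which
the generator models; absolute F-measures on real data will be lower and the
evaluation window matters more.

## Numerical choices and edge cases

* σ–L map: `sigma = (L−1)/6` (support spans ±3σ); recorded prominently so it
  can be swapped.
* Convolution and median borders: edge replication, avoiding rim suppression
  of near-border nuclei and darkened borders that would bias Otsu.
* Even fed-back lengths round up to the next odd integer (symmetric kernels
  need odd support).
* Cubic z-interpolation is an interpolating cubic spline; it reproduces
  polynomials up to degree 3 exactly and conserves the intensity integral to
  well under 1% on smooth data.
* Otsu on a constant frame raises (no bimodality); the pipeline converts
  this into an empty frame result that carries the previous parameters.
* An all-zero RGM profile yields radius 0 and flags the detection invalid;
  invalid detections contribute no voxels to segmentation.
* Ties: RGM argmax to the smallest radius; segmentation overlaps to the
  nearest centroid, then the lowest label; greedy linking by ascending
  distance with stable ordering.
* The whole pipeline is seed-free and deterministic; all randomness lives in
  the synthetic generator, which derives every draw from the scene seed.

## Known limitations

* Sizes are quantized to even diameters (`D = 2·r_opt` on an integer radius
  grid); sub-voxel radii are out of scope.
* The spherical shape assumption is structural: elongated or mitotic figures
  are sized by their dominant radial extent and segmented as balls.
* The simplified variants (v2/v3) inherit the size-threshold failure mode
  for nuclei with diameters near T_s.
* Tracking has no division handling; a daughter pair appearing between
  frames starts new tracks.
* The first frame depends on user-supplied initial lengths only through its
  own detections; pathological initial values (an order of magnitude beyond
  any object size) can still merge neighbors in frame 1, and recovery begins
  at frame 2.
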