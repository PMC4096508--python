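# nucleidetect

Segmentation-free, feedback-adaptive detection of cell-nuclei centroids in
4D (3D + time) fluorescence image sequences, with size estimation,
centroid-driven volume segmentation and nearest-neighbor tracking.

## Who this is for

Time-lapse confocal recordings of early embryogenesis (e.g. mouse embryos
from the zygote to the early blastocyst) show a few to a few dozen bright,
roughly spherical nuclei whose sizes shrink with every division round.
Direct detection methods — enhance the image with a blob-matched filter,
then read off local maxima — are fast and handle touching nuclei well, but
their filter lengths must match the object sizes, and a wrong choice
silently destroys the detection. This package closes that loop: the nucleus
sizes estimated in frame *t* become the filter lengths for frame *t + 1*,
so only the first frame needs user-supplied parameters and the method is
robust to large errors in them.

## The method

Per frame: 3D median filtering and cubic z-resampling to isotropic voxels →
Otsu foreground mask and candidate-region image → separable Gaussian
enhancement, either single-scale (length `L_avg`) or multiscale (voxelwise
maximum of matched-filter-normalized responses over lengths
`L_min, L_min+dL, …, L_max`) → three-stage centroid extraction (strict
26-neighborhood local maxima clustered by connectivity; orthogonal-profile
concavity filtering; single-linkage merging of fragments).

Sizing uses the **radial gradient magnitude**: about a centroid `c`, with
`F(r)` the mean intensity of the enhanced candidate image inside the sphere
of radius `r` and `A(r)` the mean over the annulus `(r−1, r]`,

    RGM(r) = |F(r) − A(r)|,   r = 1 … r_max,

peaks at the nucleus boundary; the inner radius of the maximizing annulus
is the nucleus radius and `D = 2·r_opt` its diameter. The min/mean/max of
the retained diameters are fed back as the next frame's filter lengths.
Projecting each detection's sphere onto the binary mask (overlaps to the
nearest centroid) yields the volume segmentation; greedy nearest-neighbor
association (links capped at 25 voxels) yields trajectories.

Detection is scored against ground-truth centroids with a 10-voxel
spherical window: sensitivity `TP/(TP+FN)`, precision `TP/(TP+FP)` and
their harmonic mean (F-measure).

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices and limitations.

## Worked example

Process a synthetic dividing-embryo sequence (8 → 32 nuclei, ~15 dB SNR)
and score it against its exact ground truth:

```python
from nucleidetect import synthetic, pipeline, evaluate
from nucleidetect.enhance import FilterConfig
from nucleidetect.image_io import to_isotropic

spec = synthetic.embryo_sequence(n_frames=20, n_initial=8, n_final=32, seed=7)
frames_gt = synthetic.render_sequence(spec)
frames = [v for v, _ in frames_gt]
gts = [to_isotropic(g, spec.voxel_size) for _, g in frames_gt]

results = pipeline.process_sequence(frames, FilterConfig(L_min=50, L_max=62))
for fr, gt in zip(results, gts):
    s = evaluate.score_frame(fr.detections, gt)
    print(fr.t, len(fr.detections), f"F={s.f_measure:.2f}",
          f"next lengths=({fr.next_config.L_min},{fr.next_config.L_max})")
```

The first lines show the feedback at work — frame 0 is processed with the
deliberately oversized lengths (50, 62), after which the estimated
diameters take over and every nucleus is found:

```
0 8 F=1.00 next lengths=(21,27)
1 8 F=1.00 next lengths=(21,27)
2 8 F=1.00 next lengths=(21,27)
3 8 F=1.00 next lengths=(21,27)
4 10 F=1.00 next lengths=(19,27)
...
19 32 F=1.00 next lengths=(13,17)
```

Eight detections at frame 0, all correct (`F=1.00`), and the fed-back
lengths (21, 27) match the true frame-0 diameter range of 20.0–25.4 voxels;
by frame 19 the population has stepped to 32 and the lengths have followed
the shrinking nuclei down to (13, 17). A fixed-length run
(`feedback=False`) with the same (50, 62) loses a fifth of its mean
F-measure on the same sequence.

There is also a CLI for directory-based use:

```sh
nucleidetect simulate --out data/ --frames 20 --seed 7
nucleidetect run --frames data/ --out results/ --variant proposed --track --dump-state
```

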