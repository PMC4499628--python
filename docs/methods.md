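# Methods

`avaplan` measures the aortic valve area (AVA) by planimetry on a single 2D
contrast-enhanced CT image reformatted at the valve plane. The clinical
motivation is aortic stenosis grading and pre-interventional sizing: the
echocardiographic continuity-equation AVA rests on a circular-LVOT assumption
and operator-dependent Doppler alignment, while direct CT planimetry measures
the anatomic orifice — but manual tracing is slow and poorly reproducible.
The semiautomatic pipeline here needs only three user clicks (one per
commissure) and is deterministic given image, seeds, and configuration.

## Pipeline

1. **Sinus-of-Valsalva (SOV) detection** (`avaplan.sov`). The valve sits
   near the image center, so a central window (`central_fraction`, default
   0.5 per axis) is cropped, binarized with Otsu's histogram threshold,
   components smaller than 700 pixels and components touching the window
   border are discarded, and the surviving component nearest the window
   center (ties: largest) defines the crop: its bounding box padded by
   `bbox_pad_fraction` (default 10%). All later stages run on this crop.
   The 700-pixel cutoff is a count, not a physical area, and uses the strict
   reading "smaller than": a 700-pixel object survives.

2. **8-bit normalization** (`avaplan.calcium.normalize_8bit`). The calcium
   threshold is defined through 256-bin histogram indices, so the cropped
   image is min–max rescaled to integers 0–255. Absolute HU calibration is
   deliberately not required (fixed HU thresholds are invalid under contrast
   anyway); the consequence is that all intensity-derived quantities are
   relative to the crop's own dynamic range.

3. **Contrast-adaptive calcium threshold** (`avaplan.calcium`). Five steps on
   the crop histogram: `im_max` = highest occupied bin; `max_h` = largest bin
   count; `t_calc_est` = first bin, scanning down from `im_max`, whose count
   reaches `max_h/3` (the upper shoulder of the blood-pool peak); `dr` = bin
   at which the cumulative count from bin 0 reaches half the pixels; and

       t_calc = t_calc_est + (im_max − t_calc_est) · f,
       f = 0.5 if dr > 0.7·im_max (bright image) else 0.2.

   The printed formula is read as interpolating between the estimate and the
   maximum — the only reading that keeps the threshold inside
   [t_calc_est, im_max]. "Reaching" is inclusive (≥) in both scans, and the
   branch tie `dr = 0.7·im_max` goes to the darker (lower-threshold, more
   conservative) branch. Calcified pixels are strictly above `t_calc`.
   For *exclusion* the calcium mask is additionally filtered to connected
   components of at least `min_blob_mm2` (default 1 mm², the conventional
   minimum-lesion area in calcium scoring): a histogram-derived threshold
   inevitably flags the extreme upper tail of blood-pool noise, and those
   isolated pixels are not calcified *areas*. The raw per-pixel detector
   remains available unfiltered.

4. **Adaptive binarization** (`avaplan.pipeline.adaptive_binarize`).
   Foreground iff intensity > local mean (window 31 px) + offset. The offset
   default is 10 gray levels: with offset 0 a noisy homogeneous region is
   foreground with probability ≈ ½, which shreds the edge map downstream;
   10 levels is ≈ 2 SD of the strongest noise the validation phantoms use
   while leaving the ≈ 100-level leaflet–lumen contrast untouched.

5. **Seeded GVF snake** (`avaplan.snake`). The initial contour is the
   circumcircle through the three commissure seeds, sampled at `n_vertices`
   (100) points. Its interior masks the binarized image (first masking);
   interior holes are then filled (`fill_holes`, default on), because a
   local-mean threshold turns the middle of a wide homogeneous bright region
   into background (the window sees no edge) and those false holes would both
   corrupt the edge map and survive into the area count. The edge map is the
   normalized gradient magnitude of the σ = 1 px Gaussian-smoothed masked
   binary; the gradient vector flow field diffuses it (μ = 0.2, explicit
   iteration with step 0.9/(4μ) — inside the explicit-scheme stability bound
   — up to 200 iterations or max update < 1e−3). The snake evolves
   semi-implicitly: tension α = 0.1 and rigidity β = 0.1 assembled into the
   cyclic pentadiagonal (circulant) internal matrix solved exactly per step
   via FFT, external force bilinearly sampled from the field, step τ = 1,
   vertices clamped to the image and resampled to uniform arc length every
   10 iterations (prevents bunching while the contour shrinks), stopping at
   mean displacement < 0.05 px or 500 iterations. None of these numerical
   constants comes from the source method description, which names the GVF
   snake but no parameters; all are the field's customary defaults and all
   are configuration-exposed.

6. **Double masking and object selection**. The converged contour masks the
   image again. The contour covers the *edge* pixels of the opening as well
   as its interior, so by default masking keeps the one-pixel ring under the
   contour line (`contour_covers_edge`); without it, strict-interior
   rasterization of a contour that converged onto the edge systematically
   sheds a ≈ 0.25 px boundary band. If the double-masked image contains more
   than one component, components below 40 mm² are removed and, of the
   survivors, only the one nearest the crop center is kept; a single
   component is accepted as the orifice directly (the filter exists to pick
   among *multiple* candidates, and an unconditional 40 mm² floor would
   declare every extremely stenotic valve a failure). No survivor raises a
   segmentation-failure error rather than returning something silently.

7. **Area**. Calcified pixels are removed from the final mask (default; a
   config switch moves the exclusion before the snake instead) and
   `area = pixel count × spacing_row × spacing_col / 100` cm². "Pixel size"
   is the per-pixel *area*, the only dimensionally consistent reading, so
   anisotropic spacing is supported.

A manual mode (`manual_planimetry`) rasterizes a hand-traced polygon with
the same fill rule and measures it identically, mirroring the comparator
workflow whose agreement the statistics module quantifies.

## Rasterization rule

Every polygon-to-pixels conversion (phantom truth, contour masking, manual
tracing) shares one rule: a pixel belongs to a polygon iff its center lies
inside (even-odd), with a fixed half-open convention for centers exactly on
an edge. Truth areas are therefore exact by construction and semiautomatic,
manual, and ground-truth areas are mutually comparable to the pixel.

## Synthetic phantoms

`avaplan.phantom` renders a contrast-enhanced aortic-root cross-section:
dark surrounding tissue (default level 30) with a smooth linear intensity
ramp (default 50 levels, kept below the leaflet level) emulating tissue
inhomogeneity; a bright contrast-filled SOV disc (level 180, default radius
14 mm); a darker leaflet plate (level 90) — a concentric disc reaching
`leaflet_thickness` (1.5 mm) plus `plate_margin` (2.5 mm) beyond the orifice
tips, modelling closed leaflet tissue between the free edges and past the
commissures; a bright triradiate orifice (a 6-vertex star, tip/waist ratio
0.45, scaled so its shoelace area matches the requested AVA); optional
calcium discs (level 250); and i.i.d. Gaussian noise clipped to the 12-bit
range. The three commissure points (orifice tip directions pushed outward by
the leaflet thickness — cusp junctions sit on the wall side of the leaflets)
are the natural seeds. The background ramp matters: a perfectly uniform
background would concentrate thousands of pixels in one histogram bin,
becoming `max_h` and dragging `t_calc_est` down the blood-pool shoulder — an
artifact of over-idealized synthetic tissue, not a property of real scans.

The validation sweep (`sweep_specs`) spans orifice areas 0.3–2.0 cm² (severe
stenosis to normal), spacings 0.4–0.7 mm/px, noise SD 0–5 levels, and 0–4
deposits, with the root radius growing with the orifice so the geometry stays
anatomically plausible (256² images).

What the phantoms do *not* emulate: partial-volume blur at boundaries, beam
hardening and calcium blooming, motion, anisotropic leaflet anatomy, and
textured (rather than smoothly ramped) surrounding tissue. Passing the sweep
therefore demonstrates correctness of the algorithmic chain under controlled
degradations, not clinical accuracy; on real scans the user-facing failure
modes (blooming inflating the calcium estimate, poor valve-plane selection)
remain.

## Agreement statistics

`relative_difference(a, b) = |a − b| · 100 / mean(a, b)` (%) summarizes
observer variability pair by pair (pairs with zero mean are excluded with a
warning). `bland_altman` reports the mean difference (bias), its SD (n−1
denominator), limits of agreement mean ± 1.96 SD, and a two-sided one-sample
t test of zero bias; the t-based 95% CI of the *mean* difference is reported
as a separate field because limits of agreement describe individual
differences, not the precision of the bias — the two are easily conflated.
With zero-variance differences the t statistic is undefined; p is reported
as 1 for zero bias and 0 otherwise so degenerate fixtures stay deterministic.

## Numerical choices and degenerate inputs

- GVF explicit step defaults to 0.9/(4μ); μ = 0 short-circuits to the raw
  gradient (already the fixed point). Divergence (non-finite field) raises.
- Snake internal system (I + τA) is strictly positive definite, solved via
  `scipy.linalg.solve_circulant`; collapse below 1 px² enclosed area raises.
- Collinear or duplicate seeds are rejected by a determinant test scaled to
  the seed coordinates.
- Constant images are rejected by normalization and by Otsu thresholding;
  all-background images raise a detection failure telling the user to crop
  manually.
- Component-distance ties in object selection are broken by size (largest
  wins), with distances rounded at 1e−9 to make the tie deterministic.
- Degenerate (zero-area) orifice polygons rasterize to empty masks and
  propagate to explicit segmentation failures, never silent zeros.

## Validation problem sizes

The shipped validation uses 20-phantom sweeps (256² px), 32² edge maps for
the solver-vs-Jacobi comparison, 100 random 24² masks for the filter
oracles, 10⁵ paired samples for limits-of-agreement coverage, and 1000
replicates of n = 25 pairs for bias recovery — sizes at which every oracle
is exactly computable while the whole suite runs in seconds.

## Known limitations

- The calcium threshold is relative to the crop's dynamic range; two crops
  of the same valve with different margins yield slightly different
  thresholds. This is inherent to the histogram-index construction.
- On an image with no calcium and visible noise, the threshold still flags
  the brightest tail of the blood pool; the minimum-deposit-area filter
  absorbs this for exclusion purposes but the raw detector over-reports.
- The snake assumes the three seeds bracket the orifice; seeds placed inside
  the orifice produce an initial circle that cannot recover the full area
  (the first masking is the seed circle's interior).
- Strictly 2D: valve-plane selection from the CT volume is upstream of this
  package and typically the dominant source of clinical error.
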