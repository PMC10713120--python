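# Methods

## Scope and model

`nmjquant` quantifies synaptic puncta — small bright fluorescent spots marking
pre- and postsynaptic termini of neuromuscular junctions — in calibrated
two-channel confocal z-stacks, and their object-based co-localization. The
underlying model is deliberately simple: a punctum is an 8-connected
foreground component of a per-slice binary mask; apparent "clustered" puncta
are resolution-limited fusions of several termini and are split along local
intensity maxima; co-localization is fractional pixel overlap between a
punctum and the other channel's foreground on the same slice. Analysis is
strictly 2-D and per-slice: a physical punctum spanning several z-slices is
counted once per slice. This matches the per-slice tally convention of the
workflow the package reimplements; 3-D linking across slices is a known
limitation and possible future extension.

## Coordinate and geometry conventions

Coordinates are (row, column), 0-based, pixel centers at integer positions.
A pixel belongs to a polygonal ROI when its center lies inside **or on** the
polygon boundary (shapely point-in-polygon; deterministic for every integer
coordinate). One 2-D ROI applies to all slices of a stack. Puncta clipped by
the ROI boundary are kept and flagged, not excluded — exclusion would bias
counts downward near the boundary.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `pixel_size_um` | 0.21 | µm/px | calibration; priority: config > TIFF tags > default (warned) |
| `z_step_um` | 0.44 | µm | informational only (no axial measurement) |
| `gaussian_sigma` | 1.0 | px | denoising blur, applied independently before thresholding and before maxima detection |
| `trim_fraction` | 0.10 | — | histogram tail trimmed per end before the linear stretch |
| `despeckle_area_um2` | 0.043 | µm² | components at or below this area are noise |
| `max_area_um2` | 4.0 | µm² | clustered if area strictly above |
| `min_circularity` | 0.65 | — | clustered if strictly below |
| `max_aspect_ratio` | 2.5 | — | clustered if strictly above |
| `maxima_prominence` | 10% of slice dynamic range | intensity | noise tolerance of peak detection; the largest divergence risk against other implementations, hence configurable (`--prominence`) |
| `max_rounds` | 10 | — | recursion cap per declustering lineage |

All shape thresholds are strict comparisons, so a punctum at exactly
(4 µm², 0.65, 2.5) is single. The cluster rule is an OR across the three
conditions — the logical complement of the single-punctum criterion. At the
reference calibration one pixel is 0.0441 µm², slightly above the 0.043 µm²
despeckle cutoff, so despeckling removes nothing there; at marginally finer
sampling it strips single-pixel specks. The cutoff comparison is "at or
below", tolerant to float rounding at the exact boundary.

## Numerical choices

* **Blur**: `scipy.ndimage.gaussian_filter`, reflect padding (avoids edge
  darkening), float64 output; σ = 0 is the identity.
* **Contrast stretch**: the trimmed interval `[NMin, NMax]` maps linearly
  onto `[0, bit-max]` with saturation outside; integer inputs are rounded
  back to their dtype; constant slices pass through with a warning.
* **Otsu**: `skimage.filters.threshold_otsu`; foreground is strictly greater
  than the threshold; first-argmax tie-breaking matches an exhaustive
  between-class-variance scan (asserted on random images in the tests).
  Constant slices yield an empty mask at the pipeline level (there is nothing
  to separate) and an error at the operation level.
* **Connectivity**: 8-connectivity everywhere (components, plateaus,
  despeckle).
* **Perimeter**: Moore boundary tracing over boundary pixel centers,
  orthogonal steps 1, diagonal steps √2; thin bars are traversed out and
  back (1×n bar → 2(n−1)); single pixels have perimeter 0 and circularity
  1.0 by convention. This chain-code estimator keeps thin bars strongly
  non-circular, which library estimators tuned for bulky regions do not.
* **Aspect ratio**: major/minor axis of the second-moment ellipse
  (scikit-image regionprops); collinear pixel sets have minor axis 0 and
  aspect ratio +inf (always clustered); single pixels are 1.0. Circularity
  and aspect ratio are computed in pixel units — both are scale-invariant
  under the square-pixel assumption.
* **Maxima detection**: candidates are pixels (or equal-valued plateaus) not
  exceeded by any 8-neighbour inside the punctum; each plateau contributes
  one seed at its centroid-nearest pixel (lexicographic tie-break). Walking
  candidates by decreasing brightness, an accepted peak suppresses every
  not-brighter candidate connected to it through pixels above
  `peak − prominence`. Labels 1..k are assigned in decreasing brightness.
* **Expansion**: per claimed-pixel index, probe directions in the fixed
  order top-left, left, bottom-left, below, bottom-right, right, top-right,
  above, interleaving seeds in ascending label order; first claim wins.
  This yields a disjoint, pixel-conserving, 8-connected partition with one
  seed per region, identical on every platform. A defensive repair splits a
  disconnected region into components (unreachable under the stated order;
  covered by property tests).
* **Declustering loop**: worklist; clustered puncta with ≥2 prominent maxima
  are replaced by their expansion children (re-measured, re-classified,
  re-enqueued); with ≤1 maximum they become `unsegmentable` and are retained.
  Every split strictly shrinks the largest piece, and `max_rounds` bounds
  pathological lineages, so termination is guaranteed. Unsegmentable puncta
  are included in totals and co-localization by default
  (`exclude_unsegmentable` drops them from both the tally and the other
  channel's foreground).
* **Tally**: co-localized at threshold t means overlap fraction strictly
  greater than t/100 for t < 100, and exactly 1.0 at t = 100. Fractions are
  pixel-count ratios (calibration cancels). Counts accumulate over slices
  per ROI per channel, in both channel directions independently.

## Synthetic data

The fixture generator renders Gaussian or exact rectangular spots on a flat
background (8-bit, background 8, peak 180), placed on a coarse grid of
32-px cells so unrelated spots can never merge, with optional additive
Gaussian read-out noise clipped to the bit range. It emulates the features
the pipeline actually exercises — isolated bright puncta, fused multi-peak
clusters, elongated single-peak ridges, planned cross-channel coverage — and
deliberately not the optics of a real microscope: no PSF anisotropy, no
axial blur, no autofluorescence background structure, no intensity
heterogeneity between puncta. Passing tests therefore demonstrate
correctness of the algorithmics on well-posed inputs, not robustness to
every artefact of real acquisitions.

Specifics worth knowing:

* **Rectangular spots** (5×10 px) exist so overlap fractions are exact by
  construction: a partner rectangle shifted by whole columns covers exactly
  k/10 of its pair, and blur + Otsu recovers the rectangle pixel-exactly,
  so threshold-boundary tests (exactly 50%, exactly 100%) are sharp.
* **Gaussian spots** default to σ = 3 px with fused neighbours 10 px apart:
  an isolated spot stays under the 4 µm² area cap (single), a fused pair
  exceeds it (clustered) while keeping aspect ratio under 2.5, and the
  inter-peak saddle is deep enough to clear the default prominence.
* **Disease-contrast sets** emulate a depleted (motor-neuron-disease-like)
  group against a healthy group: Poisson spot counts per stack with means
  30 vs 21.5 per channel and planned pairing rates 0.40 vs 0.25, ten stacks
  per group, on one densely populated 256² optical section per stack. One
  slice per stack reflects the imaging reality that every analyzed slice
  contains tens of puncta; Otsu thresholding presumes a signal class, and a
  signal-free noisy slice would be binarized into spurious specks. The
  contrast is qualitative by design (group ordering, not absolute counts):
  absolute per-hemisomite counts in real data depend on the number of
  z-slices tallied and on acquisition settings, so they are not a
  reproduction target at these desk-scale problem sizes.

## Design choices that were genuinely open

* The two printed formulations of the cluster rule (conjunction vs "any
  condition") are contradictory; OR is used because only OR complements the
  single-punctum criterion exactly.
* The find-maxima noise tolerance has no published value; a relative default
  (10% of slice dynamic range) is robust across bit depths but will not
  numerically match any particular hand-tuned absolute tolerance.
* Seed-claim tie-breaking interleaves seeds in ascending label order within
  each probe direction; label order follows peak brightness. Any fixed order
  is defensible; this one makes the brightest terminus expand first.
* The blur before maxima detection is applied to the raw slice, not to the
  already-blurred one from thresholding; the two stages are independent.
* Whether unsegmentable clusters belong in the tally is ambiguous; they are
  included by default (dropping them discards real signal area) with a
  switch to exclude.

## Problem sizes

The test suite and acceptance script run on synthetic stacks of 1–3 slices,
128²–256² pixels and up to ~36 spots per channel — two orders of magnitude
below a real acquisition (1024², 80–100 slices) but spanning every code path.
The pipeline scales linearly in slices × pixels; nothing in the
implementation depends on frame size.

## Known limitations

* No 3-D punctum linking (per-slice double counting across z is inherited
  behaviour, not a bug).
* No background subtraction, deconvolution or flat-field correction.
* Otsu thresholding misbehaves on slices without genuine signal (it will
  binarize noise); the pipeline does not currently detect this condition
  beyond the constant-slice guard.
* Shape descriptors assume square pixels.
* The perimeter estimator under-measures very small blobs (circularity caps
  at 1.0), which is harmless for classification but makes absolute
  circularity values of few-pixel puncta uninformative.
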