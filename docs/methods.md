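# Methods

This note records the concrete models, conventions and numerical choices
behind voxelpipe, in the spirit of a methods appendix: what is computed,
why the defaults are what they are, and what the synthetic tests do and
do not demonstrate.

## Images and conventions

An image is a dense 2D or 3D raster with one of eleven pixel kinds
(`bit`, signed/unsigned 8/16/32/64-bit integers, `f32`, `f64`), per-axis
spacing in millimetres, and a flat string metadata map.  Indexing is
0-based with x fastest; a 3D volume is the stack of its 2D slices along
z, matching how slice stacks are numbered on disk.  `bit` images store
one boolean per voxel — no bit packing; simplicity and addressability win
over memory here.

Filters are values: parameters are validated and frozen when a filter is
created from its descriptor string, outputs are fresh images, inputs are
never mutated, and spacing/metadata ride along unchanged unless an
operation's contract says otherwise.  The virtual storage pool used by
`tee`/`load` is an explicit per-run object rather than a process global,
which keeps concurrent pipelines and tests independent; pool entries do
not persist across CLI invocations.

### Descriptor grammar

`name:key=value,key=value`, chains joined by `+`, values containing
`,:+[]` bracketed as `[...]`.  The grammar is this package's own dialect
(chosen for shell friendliness and round-trippability); it makes no
claim of byte compatibility with any other tool's syntax.  Values are
kept as raw tokens by the parser and typed by the registry's parameter
declarations, so the same introspection data drives validation and the
auto-generated help.

## Border policy: clipped windows everywhere

Every neighborhood operation uses only the in-volume part of its window:
morphology ignores out-of-bounds offsets, median/mean/MLV statistics run
over the clipped window, and the separable binomial kernel is truncated
and renormalized to sum 1 at borders.  The policy was chosen to make
streamed and in-core results *identical*: a streaming filter flushing the
stack tail sees exactly the same clipped windows the in-core filter sees,
so no mirrored or extrapolated ghost slices are needed.  Constants are
preserved everywhere, including corners.

## Specific filters

* **Gaussian** — the 1D kernel of half-width w is binomial,
  `C(2w, k) / 4^w`, applied separably per axis.  It is the discrete
  Gaussian whose variance grows as w/2; w = 0 degenerates to the
  identity.
* **Median** — lower median for even-count (clipped) windows, which keeps
  integer images integer-exact and makes results deterministic.
* **Mean-least-variance (MLV)** — for each voxel, among all clipped
  `(2w+1)^rank` windows whose center is within Chebyshev distance w of
  the voxel, the window with the least population variance contributes
  its mean.  Ties go to the smallest center in (z, y, x) scan order.
  This is the classic edge-preserving mean-of-least-variance
  construction: windows straddling an edge have high variance, so flat
  windows on the voxel's own side win and edges survive smoothing.
* **Labeling** — components are numbered 1..L in first-encounter scan
  order; `selectbig` breaks size ties toward the smaller label.
  Connectivity shapes are restricted to 3^rank structuring elements
  (4n/8n, 6n/18n/26n); larger spheres are available for morphology but
  not as connectivity.
* **Bandpass** — values outside [min, max] are set to min
  (clamp-to-floor).  Whether the historical tools clamp or zero is not
  documented anywhere we could check; the choice is flagged as dialect.
* **Distance transform** — exact Euclidean distance to the nearest true
  voxel (computed via the exact EDT in SciPy), optionally scaled by the
  per-axis spacing to yield millimetres.  Thickness maps are read off
  the transform of the complementary tissue mask; at 0.028 mm isotropic
  voxels a map value of 97.2 voxel units corresponds to
  97.2 × 0.028 ≈ 2.7 mm.

## Streaming (FIFO) filters

A streaming filter buffers at most `span` slices: 2w+1 for median and
Gaussian, 4w+1 for MLV (an output voxel depends on candidate window
centers up to w slices away, each reaching a further w), 1 for the
`byslice` adapter that runs an arbitrary 2D chain per slice.  Output
slice j is emitted as soon as its clipped window is complete, i.e. when
input slice j+w arrives (minimum fill w+1); once the buffer holds `span`
slices the oldest is dropped after each push — the distinction between
minimum fill (start emitting) and maximum fill (start dropping) is what
keeps both the memory bound and slice-count conservation exact.
`finalize` flushes the tail with the same clipped windows and propagates
down the chain; pushing after finalize, double finalize, and re-reading
a slice source are protocol errors.  The Gaussian prefilters each slice
in-plane on ingestion, so its buffer holds 2D-filtered slices and the
z-pass is a plain 1D correlation over the buffer.

Because spans depend only on filter parameters, peak retained slices for
a chain is the sum of the spans — instrumented in the implementation and
surfaced by `stackfilter -V info`.

## Adaptive fuzzy c-means

The objective is `J = Σ_p Σ_k u_k(p)^m (I(p) − g(p) v_k)²` over
memberships u (Σ_k u_k = 1), ascending centroids v, and a positive
multiplicative gain field g, restricted to the foreground (intensity
> 0).  One iteration updates, in order: memberships by the standard
inverse-distance rule `u_k ∝ d_k^(−2/(m−1))`; centroids by the exact
least-squares solution `v_k = Σ u^m g I / Σ u^m g²`; and the gain by the
membership-weighted ratio estimate `g_raw = I / (Σ u^m v / Σ u^m)`,
smoothed and renormalized to mean 1 over the foreground.  Iteration
stops when the maximum relative centroid change drops below `tol`
(default 1e-4) or after `max_iter` (default 50); non-convergence is
reported, not raised.

Choices that matter:

* **Initialization** is deterministic: centroids start at the
  (k + 1/2)/K quantiles of the foreground intensities.  No random
  restarts, so every run is exactly reproducible.
* **Fuzziness m = 2**, the standard choice; the membership rule then
  reduces to inverse squared distances.
* **Gain smoothing scale.**  The raw ratio field is smoothed by a
  foreground-weighted (masked, renormalized) separable binomial kernel
  of half-width `gain_smooth_w = 128`, i.e. σ ≈ 8 voxels per axis.  The
  scale is the load-bearing parameter: it must sit well above the size
  of tissue structures (so the field cannot absorb class contrast) and
  below the scale of the inhomogeneity.  Kernels around σ ≈ 2 voxels
  demonstrably fail — the field swallows per-class structure and
  centroids collapse — while σ ≈ 6–8 recovers a ±20 % synthetic bias to
  a few tenths of a percent.  With `gain=False` the field is pinned at 1
  and the algorithm is plain FCM.
* **Background** (intensity ≤ 0) is excluded from centroid and gain
  estimation and hard-assigned to the nearest centroid in the returned
  memberships, so membership normalization holds everywhere.
* **Monotonicity.**  With the gain fixed, the alternating updates
  descend J monotonically; the smoothed gain step is a projection, not
  an exact coordinate minimizer, so with `gain=True` descent holds only
  up to a small tolerance.  The tests assert both regimes.

## Region growing and brain extraction

Seeded growth runs breadth-first under the chosen connectivity with a
deterministic (z, y, x) FIFO order.  Two stopping rules are provided:
*threshold* (accept a candidate iff its intensity ≥ t) and *downhill*
(accept iff it is not brighter than the accepted voxel it is reached
from).  The downhill rule compares against the local predecessor rather
than the originating seed — the two readings differ and both are
reasonable; the local rule was chosen because it makes the result a pure
fixed point of a monotone neighborhood predicate (and is what the
brute-force oracle computes).  Both rules are exposed, so either
interpretation can be tested.

`brain_extract` chains, in fixed order: gain-corrected 3-class FCM →
white-matter (brightest-class) membership → binarize at `pthresh`
(default 0.5) → erode → label → largest component → region growing on
the corrected image → close → open → mask.  Shapes default to 6n.  The
growth threshold defaults to the midpoint of the two brightest centroids
(`"auto"`), which is self-calibrating across intensity scales; a number
overrides it, `None` selects the downhill rule.  A probability threshold
above 1 produces an empty white-matter mask and the pipeline degrades
gracefully to an empty output mask rather than failing.  Errors inside a
stage are re-raised annotated with the stage name.

## Synthetic phantoms

The generators produce concentric-sphere volumes with per-compartment
constant means, a smooth multiplicative bias field, additive Gaussian
noise, and exact ground-truth masks; they are pure functions of their
parameters and seed.

* The **bias field** is `1 + a · mean_axis cos(πx/(X−1))`: one half
  cosine period per axis, extrema exactly 1 ± a at the two corners where
  all cosines align (so the amplitude is directly assertable), and a
  first-order gradient across centered objects.
* **Noise** is applied to the object compartments only; the background
  stays exactly zero.  This is deliberate: the segmentation foreground
  convention is "intensity > 0", and a zero background is what masked or
  air-background data looks like to it.
* The **head phantom** (scalp 120 / skull 40 / brain 200, σ = 5,
  bias ± 20 %) emulates the T1 ordering in which white matter is the
  brightest class surrounded by darker bone; the **three-class phantom**
  (50/125/200) is the clean parameter-recovery target; the **tooth
  phantom** (enamel 200 / dentine 120 at 0.028 mm voxels) feeds the
  thickness chain.

What the phantoms do *not* model: partial-volume voxels at compartment
boundaries, Rician noise statistics, anatomically shaped compartments,
or scanner artifacts beyond a smooth multiplicative field.  Passing the
recovery tests therefore demonstrates the estimators' correctness under
their stated model, not their robustness on clinical data.

## Problem sizes in tests

The test suite and the acceptance script use 32×32×12 stacks for
streaming equivalence, ≤ 12³ volumes for the brute-force oracle
comparisons (the oracles are exhaustive loops), and 64³ phantoms for
segmentation, brain extraction and thickness — sizes at which every
claimed property is already fully exercised while the whole suite stays
fast enough to run habitually.

## Known limitations

* Streaming supports single-pass filters only; iterative or
  frequency-domain methods are out of scope by design.
* Connectivity labeling is limited to 3^rank neighborhoods.
* PNG/TIFF IO is 2D gray-scale only; NIfTI covers volumes.  `bit`
  volumes are written to NIfTI as u8 (the format has no 1-bit type).
* The FCM gain model is purely multiplicative and smooth; additive
  shading or discontinuous coil profiles are not representable.
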