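# Methods

`segquant` segments single-channel microscopy images of cells and counts the
cells individually, including cells that touch. The pipeline has three
obligatory stages — histogram threshold selection, union segmentation, and
iterative-erosion quantification — and two optional clean-up filters (noise
blob removal and boundary smoothing) that are enabled by default.

## Threshold selection from the slope difference distribution

The image histogram is treated as a mixture of unimodal class distributions
(background plus one or more object classes). After bringing the image into
integer [0, 255] range, the 256-bin histogram `P(x)` is normalised by its
fullest bin and smoothed by a low-pass DFT filter of bandwidth `W`: Fourier
coefficients `k ∈ [0, W] ∪ [256−W, 255]` are kept, the rest zeroed, and the
magnitude of the inverse transform is the smoothed histogram `P′(x)`.

At each gray level `i` two least-squares line slopes are fitted to the `N`
bins on either side. The slope difference distribution (SDD)

    s(i) = a1(i) − a2(i),   i = N+1 … 255−N,

with both fit windows parameterized outward from `i`, has a local **maximum
at each class centre** (histogram rising then falling) and a local
**minimum at each gray level separating two classes**. A threshold is
selected by (1) taking the `K_c` largest-magnitude SDD peaks as the class
centres, (2) identifying the background class as the peak nearest the
histogram mode (the background dominates the pixel count), and (3) returning
the most negative SDD valley strictly between the two peaks bounding the
requested separation case (case 1: background vs. objects; case `m ≥ 2`:
object class `m−1` vs. `m` along increasing intensity).

Sign convention: written with both slopes on ascending gray levels the
difference `a2 − a1` would invert the peak/valley roles (class centres would
be minima); the outward-window form above is the one under which "peaks are
cluster centres, valleys are thresholds" holds, and is what the package
implements throughout.

Two behaviours of the SDD drive parameter choice:

* the valley position between two classes moves smoothly and monotonically
  with `N`, while peak positions are nearly `N`-invariant;
* a large `N` suppresses small peaks and merges adjacent ones, so `N` also
  acts as a scale selector for how many classes the SDD resolves.

### Pseudo extrema

Smoothing a histogram with flat stretches produces small harmonic ripples
("pseudo" peaks and valleys). They are rejected by magnitude. Two regimes
matter:

* histograms made of **isolated spikes** (e.g. synthetic flat-region images)
  ring strongly — the sidelobe extrema reach roughly 15–20% of the principal
  magnitude. The extremum classifier
  (`SlopeDifferenceDistribution.dominant_peaks/valleys`) therefore uses a
  relative cut of 0.25 by default;
* **continuous** histograms of practical images ring far less, while a
  minority pixel class may produce a real peak at only ~10–15% relative
  magnitude. Rational calibration therefore counts peaks at a 10% cut.

Both cuts are explicit, configurable parameters.

### Calibration of (N, W)

With ground-truth masks, `calibrate_grid` scans `N ∈ [3, 60]`, `W ∈ [2, 50]`
exhaustively (step 1) and keeps the pair maximising the mean F-measure
between the automatic binarization and the truth; ties resolve to the
smallest `W`, then smallest `N`. The F-measure is computed from the overlap
ratios `P = |S∩M|/|M|`, `R = |S∩M|/|S|` and equals the Dice coefficient
`2|S∩M|/(|S|+|M|)` identically. When the intensity and gradient thresholds
are both calibrated, each is scored against its own reference (the cell
region mask, and the truth contours dilated by 1 px, respectively).

Without ground truth, `calibrate_rational` starts from the defaults
`N = 15, W = 10` and increases `N` until the SDD shows exactly as many
dominant peaks as the image has pixel classes, exploiting the
peak-suppression behaviour above.

## Gradient image and union segmentation

Edges are enhanced with the classic integer 3×3 Sobel kernels (no 1/8
normalisation — the gradient magnitude image is rescaled to [0, 255] from
its own maximum before thresholding, so kernel scale cancels) with
replicate-edge padding to avoid spurious border responses. The intensity
mask `S_I` (≥ `T0`; inverted for dark-cells-on-bright-background via the
polarity flag) and the gradient edge mask `S_g` (≥ `T1`) combine per image
type:

| case | combination | when |
|------|-------------|------|
| 1 | `S_I and not S_g` | touching cells, per-cell boundaries not closed (most images) |
| 2 | `not S_g` | closed per-cell boundaries (e.g. muscle fibers) |
| 3 | `S_I` | little touching or overlap |

The case and polarity are per-image-type configuration, never auto-detected.

## Noise blob filter

`N_l` erosions followed by `N_l` dilations (default `N_l = 3`) with the
4-connected radius-1 diamond element — a morphological opening by the
`N_l`-fold iterated diamond. Threadlike blobs of half-width below `N_l`
vanish; massive blobs survive with at most slight corner chamfering (an
opening restores exactly those shapes that are unions of translates of the
effective element — an l1-ball is restored exactly, a square loses a few
corner pixels). The operation is idempotent and anti-extensive.

## Boundary smoothing filter

Rough boundaries and interior holes fragment cells into several seeds
during iterative erosion. The filter:

1. traces every outer contour (8-connected components, clockwise) and every
   hole contour (enclosed 4-connected background, counterclockwise) by
   Moore-neighbour tracing with Jacob's stopping criterion, coordinates
   0-based (row, col) at pixel centres;
2. deletes contours not longer than the shape-noise threshold `T_sn`
   (default: a quarter of the mean outer-contour length) — deleting a hole
   contour fills the hole, deleting an outer contour removes the blob;
3. low-pass filters each surviving contour's row- and column-coordinate
   sequences with a periodic DFT of bandwidth `W_b` (default 10; the `k = 0`
   coefficient is untouched, so the centroid is conserved to rounding);
4. refills blobs from the smoothed contours by even-odd scan-fill plus the
   contour pixels themselves (which makes the unfiltered trace→rebuild
   round trip exact for hole-free masks). Contours too short for the
   requested bandwidth are smoothed at the largest admissible bandwidth, or
   kept as-is.

## Iterative-erosion quantification

Starting from the filtered mask, each iteration first extracts every
connected component whose area is already below the area threshold `S_0`
(it is taken whole as one cell seed and removed), then erodes the remainder
once with the diamond element. Necks between touching cells thin twice as
fast as cell radii, so clumps split into separate components before the
bodies vanish; the loop terminates because erosion strictly shrinks a
nonempty mask. Seeds accumulated over iterations are pairwise disjoint, and
each reported cell centre is the arithmetic mean of its seed's pixel
coordinates.

`S_0` defaults to the mean connected-component area after `pre_erosions`
erosions of a copy of the mask. `pre_erosions` (default 6) should exceed
the half-width of typical inter-cell necks: the pre-erosions then split
touching clumps before areas are averaged, so `S_0` is a mean over
separated single-cell cores. Averaging over still-connected clumps inflates
`S_0` and makes clumps fall below it before their necks erode through,
which merges touching cells into one seed. With very small `S_0` the
opposite failure appears: residual fragments pinched off late in the
erosion become spurious seeds.

## Evaluation

Each ground-truth cell region is classified by the number of identified
centres whose nearest pixel carries that region's label: exactly one → true
positive, more than one → false positive (over-segmentation), none → false
negative. The three counts partition the truth cells, so TP + FP + FN =
100%. Centres falling in the background belong to no region and do not
enter the rates.

## Synthetic data

Two generators provide all test inputs.

**Three-class images** (default 200×200): flat background at gray 50 with
two rectangular objects at 120 and 220, optionally degraded by additive
Gaussian noise and an iterated box-filter blur. Default object areas are
comparable to the background (≈ 23% and 27% of pixels) so all three classes
produce clearly dominant SDD extrema while the background keeps the
pixel-count majority that background identification relies on.

**Cell fields** (default 256×256, 20 cells): bright ellipses (axes 9–14 px,
gray 200) on a darker background (gray 60) with additive Gaussian noise
(σ = 6), plus the defects the optional filters target: 4 touching pairs
placed tip-to-tip (long axes along the join, boundaries overlapping 2 px,
giving a genuine erosion-separable neck), 8 threadlike noise polylines of
thickness ≤ 2 px (half attached to cell boundaries; curvature kept small
and each thread verified to vanish under the default opening, so they stay
"tenuous"), periodic radial boundary roughness (relative amplitude 0.06,
frequency 7), and 6 small interior holes (radius 2) punched into the
rendered image only — the ground truth keeps the full cells. Noise σ, blur
window and object sizes are generator choices; they are not measurements of
any particular instrument.

What the generator does **not** model: point-spread blur, shot noise,
intensity gradients/vignetting, textured cell interiors, cell clusters of
three or more, and out-of-focus artifacts. Passing tests demonstrate the
method's mechanics (threshold placement, filter behaviour, clump
separation) under controlled conditions, not performance on any particular
real microscope's data.

## Numerical choices

* Rescaling rounds half-up; images already integer in [0, 255] pass through
  unchanged so histogram bins keep native gray levels.
* SDD extrema are located by sign changes of the discrete derivative;
  plateaus report their leftmost index; steps below 1e-12 of the histogram
  amplitude count as flat.
* Smoothed contour coordinates round half-up to the pixel grid.
* Erosion/dilation treat out-of-image pixels as background.
* Grid calibration scores failures (no admissible valley) as F = 0 and
  continues.

## Known limitations

* Case 1 with an interior background class (objects both darker and
  brighter than the background) separates the background from the side
  holding more classes and refuses exact ties.
* Cells whose contact necks are as wide as the cell body (heavily merged
  clumps) cannot be separated by erosion seeding.
* A threshold exists only between detected class peaks; images whose class
  counts the SDD cannot resolve at any `N ∈ [3, 60]` raise a calibration
  error rather than guessing.
* The area gate `S_0` is global; fields mixing very small and very large
  cells need a manually chosen `S_0` or per-region processing.
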