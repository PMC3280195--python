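# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates. It is written for maintainers who need to know
*why* the code does what it does, not just what it does.

## Model and assumptions

The stack is N grey-value image pairs of a single field of view. All
misalignment is assumed to be a rigid 2-D translation per image: the
acquisition geometry (fixed specimen, repeated incubation/wash/bleach
cycles) produces drift but no rotation, scaling or deformation, and the
framework deliberately offers no wider transform class. Phase-contrast
images are registered because their content is tag-independent; each
fluorescence image inherits the translation estimated for its phase
partner, on the assumption that the two members of a pair are acquired
aligned.

Coordinate convention: origin top-left, x = column rightward, y = row
downward. `Translation(dx, dy)` applied to an image produces
`out[y, x] = img[y − dy, x − dx]`; the registration result is the
translation applied to the *target* so it lands on the reference. Pixels
without source data become 0, which is also what the realigned stacks show
as blank border rows/columns.

## Similarity: mutual information

Alignment quality of a candidate translation is the mutual information
`MI = H(A) + H(B) − H(A,B)` of the joint intensity histogram, computed
**only on the geometric overlap** of reference and shifted target so the
statistic stays comparable as the intersection changes. Intensities are
binned linearly over each image's own range into `nb = 64` bins — a robust
default for 8/16-bit microscopy after range normalisation; constant images
degenerate to a single bin rather than an error.

Entropy is Shannon, in bits, by default. Hartley entropy (log₂ of the
number of occupied bins) is available via `measure="hartley"`: the joint
histogram construction is the standard Shannon-MI registration framework,
so Shannon is the default, but the coarser Hartley variant is kept for
comparison because it is sometimes preferred for heavily quantised data.

## Optimiser: compass pattern search

A derivative-free compass search polls the four axis neighbours of the
incumbent at distance `mesh` (opportunistic: the first strict improvement
is taken). Success moves the incumbent and expands the mesh ×2; failure
contracts it ×0.5. Every accepted step has length exactly `mesh`, so the
stopping rule "step between consecutive accepted points < θ_Δτ" is
implemented as "stop once mesh < θ_Δτ"; hitting `max_iter` (200) first is
reported as non-convergence, not an exception. Defaults: initial mesh 4 px,
θ_Δτ = 0.01 px. Sub-pixel candidates are evaluated by resampling the target
with Keys cubic convolution (a = −0.5, the Catmull-Rom member, which
interpolates and reproduces linear ramps exactly), separably: one 4-tap
correlation per axis with edge replication, then an exact integer
relocation with zero fill. In block registration the poll is clamped to
max(|dx|, |dy|) ≤ margin − 3 so the sampled centre patch never reads the
window border or the 2-px kernel support.

## Robust block registration

K disjoint reference blocks of side S are laid out row-major on a
⌈√K⌉-grid, spread evenly with a small reserved slack so a retry can shift
the whole layout diagonally (deterministic jitter S/4, clamped to the
reserve) without leaving the frame. Defaults K = 9, S = 200 px: the
compromise between runtime and accuracy identified for this parameter
family. The window excess `margin` defaults to 20 px — enough headroom for
the ±10 px drift regime.

Outlier rule: block k is an outlier iff its translation is more than ω px
(default 1) from *every* other block's. Exclusion is only trusted when
outliers are a minority (< K/2); a majority disagreement instead keeps all
blocks and triggers the retry. The confidence is
`σ = sqrt(mean‖τ_k − τ̄‖²)` over non-outlier blocks (population
normalisation; a single scalar combining x and y). `σ >
sigma_threshold` (default 1 px) also triggers the retry; a second failure
flags the pair as unregistrable while still reporting the lower-σ attempt's
consensus. σ is also an honest error bar: the final accuracy cannot
meaningfully beat the spread of the block estimates.

## Registration graph and RIMO

With translations only, shifts compose as vectors: registering N−1 images
to an arbitrary reference r determines every pair via
`Δ_jk = Δ_rk − Δ_rj`. The matrices are filled in the upper triangle and
reflected with a sign flip, making skew-symmetry and path independence
exact by construction; changing the initial reference offsets all rows
consistently and cannot change the selected RIMO.

The non-overlap of two equal h×w frames offset by (Δx, Δy) has closed form
`2(h|Δx| + w|Δy| − |Δx||Δy|)` while they intersect and `2hw` otherwise;
it is a metric on footprints (identity, symmetry, triangle inequality —
property-tested, and verified exhaustively against a brute-force pixel
count on integer shifts). The RIMO minimises the summed distance to all
other images. The objective uses the exact form by default — the scaled-l1
variant `2(h|Δx| + w|Δy|)`, which exceeds it by exactly `2|Δx||Δy|`, costs
the same at this scale, so the approximation is offered (`mode="l1"`) but
not preferred. Ties break to the smallest index. Per-image reports include
the shift magnitude to the RIMO, the loss as a percentage of the worst case
2hw, and the percentage of frame area outside the common overlap (two
plausible normalisations of "percentage loss of information"; both are
emitted). Images whose shift magnitude exceeds `distant_threshold`
(default 10 px) are flagged as candidates to set aside.

## Synthetic drift generator

The generator emulates stage drift on a fixed specimen: each synthetic
image is a crop of one base image whose centre is displaced by a uniform
real-valued shift in [−10, +10]² px, sampled sub-pixel with the same Keys
kernel (sub-pixel centres are required for real-valued ground truth to be
meaningful). A quarter of the images (drawn without replacement, disjoint
subsets) get gamma correction with γ ~ U(0.5, 2) applied on range-normalised
intensities; a quarter get Gaussian blur (σ = 1 px, 5×5 kernel); the rest
are only translated. Everything is reproducible from one seed.

The default base image is procedural: standardized mixtures of smoothed
white noise at a cell-scale band (σ = 8 px) and a granular band
(σ = 1.5 px), min-max scaled to [0, 255]. This gives an informative
histogram (> 3 bits at 64 bins) and a smooth, unimodal MI surface. A user
may substitute a real phase-contrast image. What the synthetic stacks do
**not** reproduce: the pixel-level noise, sharp organelle edges and
staining variability of real phase contrast, uneven illumination, focal
drift, or tissue damage between cycles. Consequently the benchmark error on
synthetic stacks (≈ 0.003–0.005 px mean absolute at θ_Δτ = 0.01) is an
optimistic bound — on real texture the MI surface is rougher and accuracy
degrades toward the 0.1 px scale; passing tests demonstrate correctness of
the machinery and the sub-pixel regime, not field accuracy.

Benchmark problem sizes: the accuracy benchmark uses n = 100 images of
768×768 px (the smallest frame hosting the default 3×3 layout of 240-px
windows) from an 840×840 base; validation-suite examples use further
down-scaled layouts (e.g. K = 4, S = 48, margin = 10 on ≈300 px frames),
chosen so the whole suite runs in a couple of minutes while exercising the
identical code paths.

## Other numerical choices

- **RMS composite diagnostic**: `sqrt((1/(3B)) Σ[(R−G)² + (G−B)² + (B−R)²])`
  over B pixels — the mean over the three channel pairs, so the value is on
  the grey-level scale and invariant under channel permutation. It is
  evaluated on the common footprint of the three channels; otherwise the
  blank borders introduced by shifting dominate the score.
- **Degenerate inputs**: constant images bin into a single histogram cell
  (entropy 0); empty overlap raises; an all-outlier block set raises rather
  than silently averaging; stacks need N ≥ 2 and unique tag names.
- **Determinism**: layouts, retries, tie-breaks and the generator are all
  deterministic given their inputs and seed; repeated runs are
  byte-identical.

## Known limitations

- Translations only; no rotation/affine/non-rigid estimation.
- Equal frame sizes across the stack are required (also by the closed-form
  footprint distance).
- No multi-resolution pyramid: convergence relies on the MI surface being
  well-behaved within the initial mesh scale; pathological textures may
  need a larger initial mesh.
- Non-uniform focus (autofocus failures) is not modelled or corrected.
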