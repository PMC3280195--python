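# mtalign

Robust sub-pixel alignment of multi-tag fluorescence / phase-contrast image
stacks, with automatic selection of the reference image that maximises the
overlap of the aligned stack.

## The problem

Sequential-staining microscopes (e.g. toponome imaging systems) record one
image pair per biomolecular tag: a fluorescence image `F_j` showing where
the tag binds, and a phase-contrast image `I_j` of the same field whose
content is tag-independent. Runs last hours, so mechanical drift, washes and
temperature changes translate the field of view between cycles. Any
co-localization analysis of the `F_j` is meaningless until the stack is
aligned — and because every alignment discards the non-overlapping border,
the *choice of reference image* decides how much signal survives.

`mtalign` implements the three-stage framework for this setting (stacks of
N ≥ 2 tags; pure translations, which is what this acquisition geometry
produces):

1. **Robust pairwise registration.** The phase images carry the alignment
   signal. For a reference/target pair, K disjoint square blocks of side S
   from the reference are each registered independently inside co-located
   larger windows (side S + 2·margin) of the target by maximising the
   mutual information `MI = H(A) + H(B) − H(A,B)` of the joint intensity
   histogram over translations, using a derivative-free compass pattern
   search with Keys bicubic resampling for sub-pixel candidates. A block
   farther than ω px from every other block is an outlier (default ω = 1);
   the consensus translation is the mean of the non-outlier blocks and the
   standard deviation σ of those blocks is a confidence value. High σ
   triggers a retry with a jittered block layout, then a quality flag.
2. **Registration graph.** N−1 registrations against an arbitrary reference
   `r` determine every pairwise shift by vector composition
   `Δ_jk = Δ_rk − Δ_rj`, stored as skew-symmetric N×N shift matrices.
3. **RIMO selection and realignment.** Two h×w frames offset by (Δx, Δy)
   fail to overlap on area `d = 2(h|Δx| + w|Δy| − |Δx||Δy|)` (or `2hw` if
   disjoint) — a metric on image footprints. The Reference Image with
   Maximal Overlap is `r* = argmin_r Σ_j d(C_r, C_j)`; the whole stack
   (phase and fluorescence) is then realigned to `r*` straight from the
   matrices, with no further registration.

A seeded synthetic-data module generates ground-truthed drift stacks
(uniform shifts in ±10 px; a quarter gamma-corrupted with γ ∈ [0.5, 2], a
quarter Gaussian-blurred with σ = 1 on a 5×5 kernel) for validation.

## Worked example

```python
from mtalign import (RunConfig, SyntheticConfig, generate_stack, make_base_image,
                     register_stack, select_rimo, realign_stack,
                     rms_channel_difference, intersection_slices)

base = make_base_image(280, 280, seed=7)
cfg = SyntheticConfig(n_images=4, crop_size=(220, 220), shift_range=5.0, seed=7)
stack, truth = generate_stack(base, cfg)

params = RunConfig(K=4, S=48, margin=10)          # down-scaled block layout
mats, results = register_stack(stack, ref_index=0, config=params)
rimo = select_rimo(mats, 220, 220)
aligned, applied = realign_stack(stack, mats, rimo.rimo_index)
```

Printing the per-pair results and the diagnostics of this exact run gives:

```
true shifts (x, y):
  syn_1: (+1.251, +3.972)  gamma(0.9545)
  syn_2: (+2.757, -2.748)  none
  syn_3: (-1.998, +3.736)  none
  syn_4: (-4.947, +3.212)  blur
pair syn_2 -> syn_1: consensus (+1.520, -6.727), sigma 0.0187, outliers []
pair syn_3 -> syn_1: consensus (-3.270, -0.242), sigma 0.0310, outliers []
pair syn_4 -> syn_1: consensus (-6.219, -0.781), sigma 0.0366, outliers []
objective per candidate: [8221.7, 14434.8, 7973.4, 10530.7]
RIMO: syn_3
RMS channel difference: 24.619 -> 2.856
```

Reading it: the consensus for `syn_2` (+1.520, −6.727) reproduces the true
relative drift (2.757−1.251, −2.748−3.972) = (+1.506, −6.720) to ~0.015 px,
with σ ≈ 0.02 px confidence and no outlier blocks. `syn_3` minimises the
total non-overlap objective, so it becomes the reference, and realigning to
it drops the RMS channel-difference misalignment score (computed on the
common footprint of the first three tags) from 24.6 to 2.9 grey levels.

The same pipeline is available from the shell for stacks on disk
(TIFF/PNG images listed in a CSV/TSV/YAML manifest with columns
`tag, phase_path, fluor_path`):

```sh
mtalign simulate --out stack/ --n 4 --crop-size 220 --base-size 280 --seed 7
mtalign register --manifest stack/manifest.csv --out reg/ --K 4 --S 48 --margin 10
mtalign select-rimo --matrices reg/shift --height 220 --width 220 --out rimo/
mtalign apply --manifest stack/manifest.csv --matrices reg/shift --rimo-index 2 --out out/
mtalign report --pairs reg/pairs.json --rimo rimo/rimo.json
```

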