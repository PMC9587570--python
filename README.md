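# angioseg

Unsupervised vessel segmentation and diameter tracking for coronary
angiography frames.

Coronary angiographs show the arteries as dark curvilinear structures on a
brighter, unevenly lit background cluttered with catheters, guidewires and
soft-tissue shadow. Global binarization fails on such frames: one threshold
cannot serve regions whose background level differs by tens of gray levels.
`angioseg` implements a locally adaptive, unsupervised pipeline that
segments the vessel tree, removes disconnected clutter, and reports the
vessel diameter along its course — the quantity clinicians read to locate
and grade a stenosis.

## Method

The pipeline runs in five stages on a single grayscale frame (nominally
512 × 512):

1. **Tiling** — the frame is divided into 32 × 32 subimages *p*(i, j)
   (a 16 × 16 grid).
2. **Tile classification** — each tile is labelled *vascular* or
   *nonvascular*. The stage is pluggable (a CSV of per-tile labels from
   any external model is accepted); the built-in reference heuristic labels
   a tile vascular when its exact two-cluster intensity split has centre
   separation ≥ 40 gray levels and a dark fraction in [0.05, 0.80].
3. **Regional parameter expansion (RPE)** — for each vascular tile, the
   exact 1-D two-means threshold δ of its pixels is computed (the optimal
   two-cluster split of scalars is an interval in sorted order, so the
   global within-cluster-SSE optimum is found by a cut scan — no Lloyd
   iteration, no seed sensitivity). The tile's dark pixels (< δ) seed an
   8-connected flood fill that grows through the surrounding 3 × 3 tile
   block, admitting any pixel below δ. The union over vascular tiles is
   the vessel mask. Because δ is only ever applied next to where it was
   estimated, and growth requires connectivity to the seeds, the expansion
   tolerates illumination gradients and never picks up detached clutter;
   it also recovers vessel pixels in tiles the classifier missed.
4. **Optimal cover tree (OCT)** — a *cover* is a maximal run of mask
   pixels cast from a region-boundary pixel along one of five directions
   (down, up, horizontal, 45° down-right, 45° up-right); its Euclidean
   length estimates the local diameter. Two rules stabilise selection on
   jagged binarized edges: consecutive covers may differ by at most 45°
   in orientation and must agree in length within a tolerance; otherwise
   the previous direction is preferred, else the shortest chord. Selected
   covers are chained into spanning trees (one per black region), trees
   with 8-adjacent covers are merged, and only the tree with the longest
   node path — the main vessel — is retained; every other black region is
   pruned as noise.
5. **Diameter profile** — the covers along the main tree's longest path
   give an ordered diameter profile (pixels), rendered as a colour-coded
   overlay (quantile bins, blue = narrow … yellow = wide).

No training data is required. A synthetic-phantom generator with exact
ground truth (vessels of known centreline and width, illumination
gradients, noise, blob and guidewire distractors) makes every stage
testable end to end.

## Worked example

```bash
angioseg synth --seed 5 --out-dir demo            # phantom + ground truth
angioseg run --image demo/image.png --out-dir demo/out
```

which prints:

```
classified tiles: 31 vascular of 256
rpe[flood_fill]: 7806 vessel px
oct: 4 trees, 77 rule fallback events, 7179 vessel px after pruning
profile: 441 samples, median diameter 12.73 px, minimum 2.00 px
```

Reading the output: 31 of 256 tiles were called vascular; regional
expansion produced a 7 806-pixel mask; the cover stage built 4 spanning
trees (the vessel plus three pieces of clutter), kept the longest-path
tree and pruned the rest down to 7 179 pixels; the remaining vessel has a
median diameter of 12.7 px along its 441-cover path (the 2 px minimum
sits at the tapered vessel tip). `demo/out/` holds the pre- and post-prune
masks, the cover forest (`covers.json`), the per-cover diameter profile
(`profile.csv`), the colour overlay and the echoed run configuration.

Scoring against the generator's ground truth:

```bash
angioseg eval --pred demo/out/mask_post.png --truth demo/truth_mask.png
```

```json
{
 "precision": 1.0,
 "recall": 1.0,
 "false_positives": 0
}
```

Each stage can also be run in isolation (`angioseg segment`,
`angioseg trace`) and everything is available as a library:

```python
from angioseg import RunConfig, run_pipeline
result = run_pipeline("frame.png", RunConfig())
print(result.profile.median)
```

## Scope and limitations

Diameters are reported in pixels; frames carry no physical calibration.
Crossing or overlapping vessels are not resolved, and genuinely
disconnected secondary vessels are pruned together with the noise — both
faithful to the single-main-tree design (a `keep_top_n` escape hatch
retains more trees if wanted). See `docs/methods.md` for the model
details, parameter defaults and the phantom generator's assumptions.
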