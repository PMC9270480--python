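# mammotile

Detector-agnostic, multi-scale, multi-resolution, context-aware tiled
inference for finding small lesions in very large grayscale images (the
mammography regime: ~3328 × 4096 px, 50–100 µm pixels), together with
FROC evaluation under the center-in-box hit criterion and a synthetic
phantom generator for desk-scale experiments.

The pipeline:

1. **preprocess** — Otsu-based breast segmentation and tight cropping,
   with an exact crop record for mapping boxes back to the raw frame.
2. **pyramid** — scale pyramid (1.0 / 0.5 / 0.25 by default) and
   systematic full-coverage strip tiling (1024 px along the long axis,
   full short axis; the last strip is anchored to the image edge so no
   pixel is ever lost).
3. **detect** — a pluggable detector contract (`image -> scored boxes`)
   plus a classical difference-of-Gaussians reference detector whose
   bounded sigma band emulates a fixed receptive field; per-scale runs
   remap every box to the full-resolution frame and de-duplicate across
   tile seams with NMS.
4. **fuse** — cross-scale combination: Weighted Box Fusion (score-weighted
   average boxes, cluster scores rescaled by `min(N, T)/T`), plain NMS,
   and NMS with a score floor.
5. **evaluate** — exact FROC curves (threshold sweep over unique scores)
   with sensitivity-at-FPI readouts; a prediction hits a lesion iff its
   box *center* lies inside the ground-truth box.
6. **phantom / experiments** — seeded 16-bit phantoms (breast-shaped
   foreground, parenchyma-like texture, raised-cosine lesions of given
   physical size, optional benign distractors) and scripted ablations:
   resolution negation (pyramid rebuilt by upsampling the 0.25× level),
   single-scale-only, fixed-resolution context comparison, and per-scale
   pre-fusion analysis.

## CLI

```sh
mammotile simulate --n-images 4 --seed 1 --sizes 6,10,20 --out-dir data/
mammotile preprocess --in data/phantom_0000.png --out crop.png --record rec.json
mammotile tile --in crop.png --scales 1.0,0.5,0.25 --tile-len 1024 --out-dir tiles/
mammotile detect --in data/phantom_0000.png --out preds.csv
mammotile fuse --method wbf --sources 3 --in s1.csv --in s05.csv --in s025.csv --out fused.csv
mammotile evaluate --pred fused.csv --gt data/gt.csv --out-prefix results/eval
mammotile ablate --which resolution --seed 1 --n-images 8 --out report.json
mammotile run --images-dir data/ --gt data/gt.csv --out-dir results/run
```

Formats: 16-bit PNG/TIFF images; ground truth CSV
(`image_id,x_min,y_min,x_max,y_max,size_mm`) or COCO-style JSON;
predictions CSV (`image_id,scale,x_min,y_min,x_max,y_max,score`). Boxes
are 0-based half-open float pixel rectangles, y-down.

## Notes on the experiment harness

The ablations are *re-inference* experiments with a fixed classical
detector: the manipulated factor is what the pipeline feeds the detector
(native vs upsampled-from-0.25× pyramid levels, which scales run, how
much context one tile covers), never the detector itself. The bundled
experiment configuration pairs a scaled-down phantom geometry
(1024 × 832 px at 280 µm — a 1/16-area analog preserving the 4/2/1
tile-count gradient at `tile_len=256`) with a detector whose hard
response threshold lies between a small lesion's degraded post-negation
response and its native response, making resolution loss irreversible to
the detector in the same way a fixed network cannot recognize
blurred-away fine structure.
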