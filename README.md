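# vesicletrack

Single-particle tracking of undyed, point-like vesicles in grayscale
confocal movies: Laplacian-of-Gaussian spot detection, distance-matrix
frame-to-frame linking with merge/branch/appearance/disappearance handling,
and trajectory kinematics (velocity, speed, traveling distance, moving
range). A seeded synthetic-movie generator provides ground truth so the
whole pipeline is testable without experimental data.

## Pipeline

1. **image_io** — read TIFF/PNG frame sequences (directory with naturally
   sorted numeric names, or a multi-page stack); RGB files with identical
   channels are reduced to channel 0. Coordinates are 0-based (row, col).
2. **detection** — LOG filter (zero-sum kernel, positive response on bright
   blobs) → normalize response to [0, 1] → threshold (>=, configurable
   bound) → iterative flood-fill labeling (4- or 8-connectivity) → size
   filter → unweighted pixel-mean centroids, 1-based per-frame indices.
3. **linking** — full distance matrix between consecutive frames; row/column
   minima below a strict cutoff classify segments as regular, merge,
   branch, end, or begin. The multi-cutoff search runs ascending cutoffs
   and freezes matches made at smaller cutoffs, so slow vesicles are
   resolved before fast ones.
4. **trajectory** — the TRJ compound store of `[iframe, pid1, pid2]`
   segment rows. Tracing: frame 1 seeds trajectories; per frame, link →
   resolve merged tails (longest trajectory survives, ties to the lowest
   id) → insert segments (branches continue the parent along the nearest
   segment and spawn new trajectories for the rest). Trimming frees unused
   capacity.
5. **postprocess** — trajectories × frames matrix (0 = absent; each row's
   non-zero entries are one contiguous block), life filtering, and
   per-trajectory kinematics/summary tables.
6. **synth** — scripted point tracks (oscillation or drift, plus scripted
   merge/branch/vanish/appear events) rendered as Gaussian spots with
   seeded noise; byte-identical frames for a fixed seed.

## CLI

```sh
vesicletrack simulate --out run --n-tracks 10 --n-frames 20 --motion drift \
    --drift-speed 2 --shape 256 256 --min-spacing 44 --seed 11
vesicletrack detect   --input run/frames --out run
vesicletrack track    --input run/frames --out run --cutoffs 5,10,20
vesicletrack analyze  --out run --dt 1.0 --min-life 3
vesicletrack sweep    --input run/frames --out run/sweep --bounds 0.3,0.5,0.7
```

Outputs are CSVs with a `# key = value` provenance header:
`detections.csv` (frame, vesicle_id, row, col, size), `trj.csv` (serialized
trajectory store), `trajectory_matrix.csv`, `kinematics.csv` (per-sample
vx, vy, speed, s, R), and `summary.csv` (life, mean speed, final range,
final distance; population in the header). `sweep` writes binarization
overlays for tuning the detection threshold by eye. All commands accept a
flat YAML config via `-c`; command-line options override it. Identical
config + input gives byte-identical outputs.

Defaults: `log_sigma 2`, kernel `2*ceil(3σ)+1`, threshold `0.5`,
`min_blob_size 4`, 8-connectivity, cutoffs `[5, 10, 20]` px, `dt 1.0` s
(a warning is logged when dt is left at its default).

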