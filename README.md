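# retnorm

Normative retinal-thickness analysis for mouse SD-OCT volumes.

Longitudinal OCT studies of mouse models — here the C57BL6/129S wild type
and the 3xTg-AD model of Alzheimer's disease, followed monthly from one to
four months of age — need a normative reference to decide whether an
individual retina is unusually thick or thin. `retnorm` implements that
analysis chain for segmented Micron IV-style volumes (512 B-scans x 512
A-scans, 1024-pixel depth axis spanning 1.4 mm):

1. **Thickness maps.** Given the nine boundary surfaces delimiting the
   eight segmented layers (RNFL-GCL, IPL, INL, OPL, ONL, IS, OS, RPE), the
   thickness of layer ℓ at en-face position (r, c) is the axial boundary
   distance `t_ℓ(r,c) = (z_{ℓ+1} − z_ℓ) · Δz` with `Δz = 1400/1024 μm` per
   depth pixel; the total retinal thickness (TRT) spans the full stack.
   Left eyes are mirrored into the right-eye convention so the left/right
   map halves are always temporal/nasal retina.
2. **Quality screening and blocks.** Per-pixel validity rules
   (non-negativity, physiological bounds, a robust median/MAD score cut)
   emulate the screening applied to real segmentations. Maps are cropped
   512→510 and averaged over nine 170x170 blocks; a block is retained iff
   ≥ 90% of its 28,900 values are valid (inclusive).
3. **Normative database.** Because block and whole-area summaries are
   close to Gaussian (checked with a Kolmogorov-Smirnov test), each cell
   of the reference is just `(mean, SD, n)`, keyed by group, eye, age,
   layer and region. The published whole-area tables for both groups and
   the cohort weights ship with the package.
4. **Statistics.** Welch t-tests (two-sided, tiers 5%/1%/0.1%) between
   groups, a paired nasal-vs-temporal block-column contrast, and a
   one-within-factor repeated-measures ANOVA over the four ages
   (`F = MS_time / MS_subject×time`, Greenhouse-Geisser reported
   alongside) with Tukey HSD pairwise age contrasts on the
   within-subject error term.
5. **Deviation maps.** An individual block thickness `t` scores
   `z = (t − μ)/σ` and the two-sided normative p-value
   `p = 2(1 − Φ(|z|))` — `p = 1.00` at the reference mean, shrinking
   towards the tails. Renderings paint blocks blue (below) or red (above)
   with intensity `1 − p`.

A synthetic generator produces segmented volumes with the statistical
structure the analysis assumes (per-layer means at the level of the
published tables, nasal-temporal gradient, decline with distance to the
optic disc, per-pixel noise, injectable invalid regions), so the entire
chain runs and is tested without any acquisition data.

## Worked example

```python
>>> import retnorm as rn
>>> db = rn.load_packaged("wt")                      # published WT reference
>>> rn.aggregate_cells(db, ["IS", "OS", "RPE"], "WT", 4)
45.82
>>> cohort = rn.sample_cohort(db, "WT", "OD", 4, n_eyes=103, seed=1,
...                           anchor="TRT")          # synthetic cohort
>>> means = rn.pipeline.cohort_whole_area_means(cohort, "TRT")
>>> round(means.mean(), 2), round(means.std(ddof=1), 2)
(200.37, 2.37)
>>> cell = db.cell("WT", "combined", 4, "TRT", "whole")
>>> (cell.mean, cell.sd)                             # generating reference
(200.69, 2.4)
>>> score = rn.deviation_score(195.0, cell)
>>> round(score.z, 2), round(score.p, 3), score.direction
(-2.37, 0.018, 'below')
```

The outer-retina aggregate (IS + OS + RPE) of the packaged four-month
wild-type cells is 45.82 μm. A 103-eye synthetic cohort generated from the
packaged TRT cell and pushed through the full thickness pipeline recovers
the generating distribution (200.37 vs 200.69 μm mean, 2.37 vs 2.40 μm
SD), and an individual eye at 195 μm scores 2.4 SD below the norm with a
normative p of 0.018.

The same flows are available from the shell:

```sh
retnorm simulate --out sim/ --seed 5 --n-eyes 4 --age 2
retnorm build-normative --input sim/ --out db/
retnorm deviate --db db/normative_db.csv --volume sim/WT-m2-OD-000.tif \
    --layer TRT --out dev/
```

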