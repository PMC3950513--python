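# cellcoloc

Quantitative colocalization analysis for multi-channel fluorescence
images of live rod-shaped bacteria, built for the kind of question that
arises with chromosome-organizing machines in *E. coli*: does a protein
whose signal is partly diffuse (e.g. the topoisomerase IV subunits ParC
and ParE) preferentially sit at the foci formed by another complex
(e.g. the SMC-like condensin MukBEF, or a labelled *ori* locus), beyond
what chance coincidence inside a small cell would produce?

The pipeline follows a four-step design:

1. **Cell meshes.** Cells are segmented from a phase-contrast image
   (Otsu threshold, hole filling, opening, labelling) into per-cell
   pixel sets with a principal long axis; label images from an external
   segmenter can be injected instead.
2. **Localization, two ways.** Focus-forming channels are localized by
   candidate detection (robust in-cell intensity threshold) followed by
   elliptical Gaussian fitting to sub-pixel centroids — a cell may yield
   several foci or none. Diffuse channels are summarized by the single
   brightest in-cell pixel, which marks the site of longest residence
   time — exactly one per cell.
3. **Distances and nulls.** Per cell, the Euclidean distance from the
   target localization to the nearest reference focus. Matched
   random-placement controls are computed in the same cells: either a
   uniformly random in-cell pixel measured against the real foci, or an
   equal-count random focus set measured against the real target.
4. **Cumulative distributions.** Distances are accumulated into a
   cumulative curve over *all* cells; cells without a reference focus
   never colocalize, so the curve plateaus at the fraction of cells
   possessing a focus (the asymptote). The colocalization fraction is
   the curve's value at the threshold — 4 px (516 nm at 129 nm/px) for
   snapshots, strictly less than 2 px (258 nm) for time-lapse calls —
   with a 95% Wilson score interval, and a two-proportion z-test plus
   CI-overlap rule against the random control.

The statistic for a cell with target point `t` and reference foci
`{f_j}` is `d = min_j ||t - f_j||`, and the reported fraction is
`P(d <= d_thr)` over all cells, compared with the same quantity under
random placement.

A synthetic-scene generator (capsule-shaped cells, Gaussian spots of
known position, a tunable tethering probability between channels,
diffuse background fraction, Poisson shot noise) provides ground truth
for every stage, so the whole pipeline is testable without any
microscopy data. Line-scan profiles with a 5%-prominence peak rule and
time-lapse metrics (long-axis path length, strict 2-px colocalization
calls, cohesion time between replisome appearance and origin-focus
splitting) round out the analysis.

## Worked example

```sh
cellcoloc simulate --n-cells 500 --coloc-prob 0.75 --seed 1 --out scene/
cellcoloc coloc --scene scene/ --seed 2 --out results/
```

prints, after the second command:

```
measured 0.852 [0.818, 0.880] vs random 0.352 (p=1.40e-58, significant=True) over 500 cells
```

Read: in a scene where 75% of target points were tethered to a
reference focus (1 px tether sd), 85.2% of cells had their brightest
target pixel within 4 px of the nearest fitted reference centroid
(ground truth for this scene: 85.0% — tethered targets essentially
always fall within threshold, and a quarter of the untethered ones do
by chance); uniformly random in-cell pixels reproduce only 35.2%, and
the difference is significant both by the z-test and by non-overlap of
the 95% intervals. `results/` also contains the distance table, both
cumulative curves, and a `summary.json` with the fully resolved
configuration including every seed.

The same library surface is importable (`cellcoloc.analyze`,
`cellcoloc.simulate_scene`, ...) for scripted use.

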