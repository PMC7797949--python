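# evcoloc

Single-vesicle imaging and co-localization analysis for extracellular-vesicle
(EV) marker profiling.

EVs are cell-secreted vesicles of roughly 30–200 nm that carry surface markers
such as the tetraspanins CD9, CD63 and CD81. Ensemble assays (western blot,
bulk omics) average over the whole population and hide its heterogeneity. In
single-vesicle TIRF imaging, vesicles are immobilized on a passivated surface,
labelled with spectrally distinct fluorescent antibodies, and imaged one
channel per marker on an EMCCD; each vesicle appears as a diffraction-limited
spot. Which markers co-occur on the *same* vesicle is decided by
co-localization: two signals from different channels belong to one vesicle
when their centres, after channel registration, lie within a fixed radius.

`evcoloc` implements that analysis chain for pre-split per-channel TIFF
images, plus a synthetic-image generator with known ground truth so every
stage can be validated without a microscope:

1. **simulate** — vesicle populations with arbitrary marker-combination
   fractions, rendered as integrated 2D Gaussian PSFs with Poisson shot noise
   and Gaussian read noise, through per-channel chromatic transforms;
   fiducial-bead calibration fields.
2. **localize** — band-pass detection with a robust threshold, then sub-pixel
   localization by nonlinear least-squares fitting of
   `b + A·exp(−((x−x₀)² + (y−y₀)²)/2σ²)`.
3. **register** — mutual-nearest-neighbour bead matching and least-squares
   estimation of translation / similarity / affine channel transforms,
   applied to spot coordinates.
4. **colocalize** — greedy distance-threshold matching (default radius 3 px
   ≈ 300 nm at 100 nm/px) merging cross-channel spots into vesicle records;
   classification into the 2^K − 1 marker-combination subpopulations
   (7 classes for three markers).
5. **profile** — per-sample class-fraction profiles with across-field
   mean ± SD, marker-overlap (Venn) tables, two-sample t-tests, linear
   regression, Euclidean-distance hierarchical clustering, and t-SNE
   embedding of replicate fraction vectors.

## Worked example

Simulate a sample whose ground truth is 40% CD63 single-positive, 40%
CD9∙CD81 double-positive and 20% triple-positive vesicles, then analyze it
end to end:

```yaml
# cfg.yaml
channels: [CD9, CD63, CD81]
image_dir: data
bead_dir: data/beads
out_dir: out
seed: 3
n_fields: 3
acquisition: {field_shape: [200, 200]}
simulation:
  n_vesicles: 40
  brightness_mean: 2000
  class_fractions: {"CD63": 0.4, "CD9∙CD81": 0.4, "CD9∙CD63∙CD81": 0.2}
```

```sh
evcoloc simulate --config cfg.yaml   # writes TIFFs + ground-truth CSV
evcoloc run --config cfg.yaml        # register -> localize -> colocalize -> profile
```

prints

```
evcoloc INFO registered CD63 -> CD9: 20 beads, rms 0.0395 px
evcoloc INFO registered CD81 -> CD9: 20 beads, rms 0.0306 px
sim: 116 records
  CD9: 0.000 ± 0.000
  CD63: 0.368 ± 0.146
  CD81: 0.017 ± 0.015
  CD9∙CD63: 0.000 ± 0.000
  CD9∙CD81: 0.407 ± 0.106
  CD63∙CD81: 0.000 ± 0.000
  CD9∙CD63∙CD81: 0.208 ± 0.082
```

The registration lines report the bead-fit residual per non-reference
channel (well under the 3-px co-localization radius). Each subsequent line
is one subpopulation's fraction of all vesicle records, mean ± SD across the
three fields: the recovered profile (0.368 / 0.407 / 0.208) matches the
generating mix (0.40 / 0.40 / 0.20) to within counting noise at 40 vesicles
per field. `out/` holds the spot table, the record table with class labels,
the profile JSON and a run log with the config hash, seed and per-stage
counts.

The same analysis runs on real data by pointing `image_dir`/`bead_dir` at
per-channel TIFFs named `<sample>_f<field>_<channel>.tif`; omitting
`bead_dir` assumes already-registered channels (with a warning).

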