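# Methods

## Imaging model and coordinate conventions

All analysis is point-based in pixel coordinates of a reference channel.
Pixel (row *i*, col *j*) spans `[j, j+1) × [i, i+1)` with its centre at
`(x, y) = (j + 0.5, i + 0.5)`; `x` is the column axis. Output tables carry
both pixel and nanometre coordinates (`x_nm = x · pixel_size_nm`).

The simulator's forward model treats each vesicle as a point emitter:
vesicles (~100 nm) are well below the optical resolution, so finite vesicle
size is folded into the PSF width. A spot of integrated brightness *N*
contributes `N · photon_scale` expected counts distributed as the exact
pixel integral of an isotropic 2D Gaussian (erf differences, not a sampled
Gaussian), on a constant background. Noise is Poisson on the ideal image
(signal + background) followed by additive Gaussian read noise; EMCCD
excess noise and EM-gain statistics are not modelled separately — the
excess-noise factor can be folded into `photon_scale`, which is sufficient
for exercising detection and fitting behaviour. Each channel renders the
field through its own true channel transform (the inverse of the
correction that registration must recover), emulating chromatic shift,
rotation and scale between detector regions.

Defaults, chosen once as realistic single-molecule TIRF conditions:

| parameter | default | rationale |
|---|---|---|
| `pixel_size_nm` | 100 | makes the 3-px co-localization radius exactly 300 nm |
| `field_shape` | 450 × 450 px | a 45 × 45 µm field (≈2025 µm², close to the 2000 µm² standard analysis area) |
| `psf_sigma_nm` | 150 (1.5 px) | diffraction-limited emission ~0.55–0.7 µm through NA ≈ 1.45 plus finite vesicle size |
| `background_level` | 100 counts | moderate TIRF background |
| `read_noise_sd` | 5 counts | EMCCD-class read noise after gain normalization |
| brightness | lognormal, CV 0.25 | antibody copy-number variability; `AcquisitionParams.brightness_for_snr(s)` converts a target peak SNR to integrated brightness |
| `labeling_efficiency` | 1.0 per channel | sub-unity values emulate imperfect labelling (e.g. the ~85–90% triple-positive shortfall seen when one vesicle is stained with three colours of the same antibody) |

Camera pixel size and PSF width are declared assumptions of the simulator,
not measured properties of any instrument; they are mutually consistent
with the 3 px ≈ 300 nm co-localization rule.

Ground-truth positions are uniform over the field with a 5-px edge margin,
matching the edge exclusion of the detector, so every simulated vesicle is
in principle detectable. The per-field/per-channel RNG streams derive from
one seed via `numpy.random.SeedSequence` spawning; identical (spec, params,
seed) give bit-identical truth and images.

### What the simulator does not emulate

Non-affine optical distortion, TIRF evanescent-depth intensity variation,
photobleaching, defocus, surface-adsorption artefacts, vesicle aggregates
and free-dye background. Passing tests therefore demonstrate correctness of
the *analysis chain* under its stated model — detection, sub-pixel fitting,
registration, matching, statistics — not robustness to every real-data
pathology.

## Detection and sub-pixel localization

Candidates are local maxima of a difference-of-Gaussians band-pass
(`smoothing_sigma` = 1 px vs 4× that) exceeding
`median + threshold_k · 1.4826 · MAD` of the filtered image
(`threshold_k` = 5, standard single-molecule practice). Maxima within
`max(edge_margin, fit_window)` of the border are discarded; maxima closer
than `merge_radius` (2 px) keep only the brighter — two emitters closer
than ~2–3 px are below the resolution of a σ = 1.5 px PSF and are treated
as one signal throughout.

Each candidate is refined by Levenberg–Marquardt least squares of
`b + A·exp(−((x−x₀)² + (y−y₀)²)/2σ²)` over a (2·`fit_window`+1)² window
(`fit_window` = 4), initialized at the candidate pixel centre with a
moment-based σ and the window-border median as background. The model is an
isotropic single-σ Gaussian: sub-resolution emitters carry no usable
ellipticity information. Fits are marked invalid — and dropped, never
repaired — on non-convergence, non-positive amplitude, or a centre
migrating more than `fit_window/2` from the candidate. Reported
`intensity = 2πσ²A`; `snr = A / (1.4826 · MAD of fit residuals)`. The
quality filter keeps valid fits with `snr ≥ 5` and σ in [0.5, 3] px, in
deterministic order (descending intensity, ties by x then y). Under the
default model, noiseless localization is exact to <0.02 px and the Monte
Carlo RMS error at peak SNR 10 is ≈0.04–0.08 px, far below the 3-px
co-localization radius. Blank noise-only fields produce <10 (in practice 0)
spots per 2000 µm², matching the behaviour required of a passivated-surface
control.

Per-field counts are reported raw and rescaled to a standard 2000 µm²
analysis area so fields of different size are comparable.

## Channel registration

The first declared channel is the reference. Beads visible in all channels
are localized like any spots, paired with the reference channel by mutual
nearest neighbours within a match radius (default 5 px), and the transform
is fit by least squares. The default model is affine (6 parameters:
shift + chromatic scale/rotation/shear); translation and similarity
(Umeyama, via scikit-image) are available, and on the same pairs the fit
residual is non-increasing in model complexity. Collinear control points
make the affine solve rank-deficient and raise a registration error.
Correction is applied to spot *coordinates* — images are never resampled,
because all downstream analysis is point-based. With ≥20 beads at
registration-grade SNR, held-out mis-registration after correcting a ≤2 px
affine distortion is ≈0.03–0.05 px RMS, an order of magnitude under the
0.3 px budget assumed by the matching stage.

## Co-localization and classification

Cross-channel candidate pairs with centre distance ≤ `threshold_px`
(default 3 px) are processed greedily in ascending-distance order
(deterministic tie-break by channel and index). A pair is linked when
(i) neither spot already has a partner in the other spot's channel and
(ii) linking would not merge two groups that share a channel — rule (ii)
keeps every record at most one spot per channel, which is what "one
vesicle" means here. Linked groups become vesicle records; unlinked spots
become single-positive records, so the records partition the input spots
exactly.

Chains (A–B ≤ 3 px and B–C ≤ 3 px but A–C > 3 px) merge into one record
under the default *component* semantics, so the largest within-record
distance is bounded by twice the radius; *clique* semantics
(`ColocalizationParams(semantics="clique")`) instead requires every
cross-channel pair within a record to satisfy the radius. An *optimal*
matcher (per-channel-pair Hungarian assignment on distances within the
radius) is available; in the sparse regime where the distance rule is
unambiguous, greedy and optimal partitions coincide, and against an
exhaustive maximum-cardinality / minimum-total-distance enumeration the
greedy partition is identical on ≥95% of random small instances and always
in the separated regime. Spots of the *same* channel are never merged at
this stage; duplicate suppression is the detector's merge radius.

Records are classified by their label set into the 2^K − 1 canonical
classes (names joined with "∙" in declared channel order). Co-localized
fractions are reported both record-wise (multi-label records / records)
and signal-wise (spots in multi-label records / spots); the signal-wise
variant is what a "share of detected signals" quote refers to, and the
two differ whenever multi-label records exist. For independent uniform
channels the chance co-localized fraction follows the Poisson
approximation `1 − exp(−λπr²)` and the matcher reproduces it within
sampling error, which quantifies the false-co-localization floor at a
given spot density.

## Profiles and comparison

Per-field class fractions are averaged across fields (each field is one
replicate; mean ± sample SD, ddof = 1); fields with zero records are
excluded with a warning. Both the record-based fractions (default,
reported everywhere) and the underlying counts are available; marker
totals and overlap counts (`venn_counts`) are derived sums over classes
containing the marker(s).

Group comparison is the classical equal-variance two-tailed two-sample
t-test with significance flags at 0.05 and 0.01 and no multiple-testing
correction by default (per-pair starring convention); both-groups-constant
input degenerates to t = 0, p = 1 by convention. Correlation is ordinary
least squares with R² and the two-tailed slope p. Sample-level structure
uses Euclidean distances between mean-fraction vectors with agglomerative
clustering (complete linkage default, configurable) and deterministic leaf
order; per-replicate fraction vectors are embedded by t-SNE
(scikit-learn, default perplexity 16, fixed seed, raw fractions without
standardization) with a perplexity-sweep helper returning the final KL
divergence per value. All-identical observations yield a flagged
degenerate embedding rather than an exception.

## Pipeline, formats, determinism

The driver runs register (identity transforms with a warning when no bead
images are supplied) → localize → colocalize → profile for every
`<sample>_f<field>_<channel>.tif` group, skipping fields with missing
channels with a warning. Images are written/read as 16-bit grayscale TIFF
(values clipped to [0, 65535] and rounded — the only quantization in the
chain). Spot and record tables are CSV with a schema-version header
comment; profiles and comparisons are JSON. The run log records the tool
version, config hash, seed, registration residuals and per-stage counts.
All randomness flows from the single config seed through documented
SeedSequence derivations, so a fixed config + seed reproduces every output
table byte for byte.

## Validation problem sizes

The validation suite exercises the chain at: 300 vesicles/field × 9 fields
(≈0.15 spots/µm² — dense enough that a few percent of spots merge or
mis-link, which the ±0.03 fraction-recovery tolerance absorbs) for
end-to-end recovery; 5 fields × 60 triple-labelled particles for the
perfect-co-localization control; 25 beads for registration; 1000 random
≤10-spot instances for the exhaustive matching oracle; 10⁴ replicates for
t-test and null-R² calibration; and 20 blank fields for the false-positive
bound. These sizes were chosen so each property is measured with comfortable
statistical margin.

## Known limitations

* The detector cannot resolve emitters closer than ~2–3 px; at densities
  above ~0.2 spots/µm² fraction estimates degrade gracefully but visibly.
* Greedy matching is order-deterministic but not globally optimal in dense
  scenes; the Hungarian option mitigates per-pair, not per-triple.
* The affine registration model does not capture field-dependent
  (non-affine) chromatic distortion.
* Signal-vs-record denominators differ; consumers must pick one and say so
  (the package defaults to record-based fractions and labels both).
* t-SNE layouts are seed-dependent up to rotation/reflection; only
  neighbourhood structure is meaningful.
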