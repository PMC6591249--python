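# Methods

## Measurement model

Each animal is imaged once, in a single channel, as a 16-bit frame. The
quantity of interest is the reporter *concentration*, proxied by the mean
dark-corrected pixel value inside the segmented animal, minus the
population-mean autofluorescence of wild-type animals imaged with the same
optics. Writing `c` for the reporter emission rate per unit tissue depth
per second, `a` for the autofluorescence rate, `p(x, y)` for the normalized
optical depth of tissue at a pixel, and `g`, `τ` for camera gain and
exposure, the expected dark-corrected pixel value inside the animal is

```
E[ADU] = g · τ · (c + a) · p(x, y)
```

so the per-animal mean intensity estimates `g · τ · (c + a) · ⟨p⟩` with
`⟨p⟩` the mean depth over the mask. The percent effect between two cohorts
measured with the same threshold, optics and wild-type baseline is then the
percent difference of their mean `c` — provided `⟨p⟩` is consistent across
cohorts (see *Phantom geometry* below, which is exactly about making that
assumption hold the way the real chamber makes it hold).

## The synthetic instrument

`simcam` generates frames by the standard CCD chain: Poisson photon counts
with per-pixel expectation `(c + a) · p · τ`, multiplied by gain, plus a
per-pixel dark-current offset, plus Gaussian read noise, rounded and
clipped at saturation. Defaults (all free parameters of the simulator, not
values measured on any physical camera): gain 2 ADU/photon, exposure
0.05 s, dark level ~100 ± 5 ADU across pixels, read noise 2 ADU, 16-bit
range, frame 192 × 256 px at 2.7 µm/px.

Biology-side defaults: reporter base rate 2000 (arbitrary rate units;
weak-promoter regime, about 170 ADU of signal — low in the camera's
dynamic range so that stronger promoters stay linear with identical
settings); between-animal concentration CV 0.2, lognormal; autofluorescence
lognormal with CV 0.25 and channel-dependent mean — 200 for mCherry optics,
800 for GFP optics, encoding that tissue autofluorescence is several-fold
stronger under GFP excitation. Intron effects enter as a single
multiplicative factor on the cohort's mean concentration. Dark current and
read noise are channel-independent; only autofluorescence differs by
channel.

### Phantom geometry

The animal is a tube swept along a "U"-shaped centerline (two straight
arms joined by a semicircular bend), the pose the holding channel forces,
with small seeded jitter in position, rotation, arm length and bend radius.
The optical-depth profile across the body is that of a cylindrical body of
radius `R` *confined in a chamber of depth D*:

```
p(d) = min(2R·sqrt(1 − (d/R)²), D) / min(2R, D)
```

with `d` the distance to the centerline. Defaults: visible half-width
12 px (the 65-µm channel width at 2.7 µm/px), body radius 13.8 px (~75 µm
adult), chamber depth 18.5 px (50 µm). Because an adult is slightly wider
than the chamber is deep, the core of the body spans the full depth
(`p = 1`) and the profile falls off only within a couple of pixels of the
channel walls. This is deliberate and load-bearing: it reproduces the
property that one pooled segmentation threshold yields nearly identical
masks for cohorts of different brightness (single-frame mask-vs-truth IoU
≈ 0.999, cohort areas consistent across strains), which is what licenses
comparing mean voxel intensities between cohorts at all. The unconfined
special case (`2R ≤ D`) reduces to the pure cylinder chord
`sqrt(1 − (d/R)²)`; in that regime the Otsu threshold — which settles at
the midpoint of the background and foreground class means, about 0.42 of
the foreground peak — truncates proportionally more of the dim cohort's
tapered rim than the bright cohort's, attenuating recovered percent
effects by roughly 15% of their size. A free-floating-worm simulation is
therefore *not* a faithful model of this instrument, and the confined
profile is the default.

Depth is collapsed into `p` (no z-stack): the chamber is shallower than
the depth of field, so the camera integrates all signal along z.

## Calibration

Dark current is the per-pixel median over a stack of dark frames; for even
stack sizes the lower middle order statistic is taken, keeping integer
arithmetic. The estimate is an integer map; against a continuous "true"
dark level its accuracy is quantization-limited to ±0.5 ADU, so estimator
accuracy is assessed against ADU-quantized maps (sub-0.5-ADU max error at
1,000 frames and 2 ADU read noise), and error decreases with stack size.
Correction is plain subtraction with negatives preserved.

Linearity of the camera is assessed on a dilution series: levels whose raw
mean exceeds 0.95 × saturation are excluded outright (the explicit
operationalization of "operated in the linear range"); then the highest
remaining level is dropped greedily until an ordinary least-squares line
achieves r² ≥ 0.99 (configurable); the report carries slope, intercept,
r², the surviving levels and their fold range. Fewer than three surviving
levels is an error, not a report.

## Segmentation and summaries

The Otsu threshold is computed on the pooled pixels of every frame in a
promoter × fluorophore group: candidate thresholds are the 255 interior
edges of a 256 equal-width bin grid spanning the pooled min–max; the
intraclass (within-class) variance is evaluated on the raw pixel values;
ties resolve to the lowest candidate; foreground is strictly greater than
the threshold. Segmentation runs on dark-corrected images. Masks are
opened with a disk of radius 1 (removing isolated noise pixels), and the
largest connected component at least 50 px is kept — one animal per frame
by instrument design; anything smaller is "no animal detected" and the
frame is excluded and logged. Per-animal summaries are the arithmetic mean
of corrected pixel values in the mask and the mask area.

Animals far dimmer than their group (several CVs below the mean) can fall
entirely below the pooled threshold; they are excluded and logged, exactly
as a real all-dark frame would be.

## Statistics

- Percent effect: `100 · (mean(test) − mean(control)) / mean(control)` on
  corrected per-animal values — means, not medians, matching the convention
  of reporting mean-based percent increases alongside rank-based tests.
  CI: percentile bootstrap resampling animals within each group,
  default 5,000 draws, seeded. The estimator is invariant to rescaling all
  values and deliberately *not* invariant to shifts — the reason the
  correction chain exists.
- Mann-Whitney: exact mode enumerates the permutation distribution
  (tie-free, n ≤ 20); approximate mode uses the tie-corrected normal
  approximation with 0.5 continuity correction. At n = 8 + 8 the
  approximation's worst-case two-sided deviation from exact is 0.0109
  (enumeration over all U; the continuity-corrected form is the best of
  the standard variants).
- Kruskal-Wallis with tie correction; the all-tied degenerate input
  returns H = 0, p = 1 by limiting convention rather than 0/0.
- Dunn's vs-control comparisons on the joint midranks with the tie-term
  variance, Bonferroni-adjusted over the k−1 comparisons (capped at 1).
  Under a 5-group global null the familywise error stays at or below the
  nominal 5%.
- Two-way ANOVA: fixed effects with interaction, Type II sums of squares
  (classical decomposition when balanced), via statsmodels. For the
  GFP-channel analysis the intended factor semantics are intron status ×
  coding sequence, with the coding-sequence dependence of IME read off the
  interaction term.
- Holm-Sidak step-down: step i compares the i-th smallest p to
  `1 − (1 − α)^(1/(m−i+1))`; adjusted p-values are the running maximum of
  `min(1, 1 − (1 − p)^(m−j+1))`.

Percent effects are computed from animals pooled across (simulated)
experiments, not from per-experiment means averaged afterwards; with
day-batch effects absent from the generator the two coincide, but real
data with batch structure would make them differ.

## Intron extraction

Transcripts are assembled from GTF `exon` features (1-based closed
coordinates throughout; biotype from `gene_biotype` or `gene_type`,
whichever the dialect provides). Intron k of a start-sorted exon chain is
`[exon_k.end + 1, exon_{k+1}.start − 1]`; abutting exons yield no intron;
transcripts with overlapping exons are rejected with a reason rather than
silently merged. The protein-coding filter matches the biotype string
`protein_coding` exactly. Deduplication defaults to unique intron
coordinates per gene (with a supporting-transcript count);
per-transcript-occurrence counting is available, since published size
distributions do not always state which convention they use. Size
summaries give interpolated quartiles, the fraction at or below a short
cutoff (default 100 bp), and a histogram of log10 sizes — intron sizes
span orders of magnitude, so the log scale is the informative one.

## Closed-loop validation: what it shows and what it does not

The acceptance workflow programs effect multipliers of 1.4588, 1.4798,
1.83 and 1.5355 into the generator (the last with 10× base concentration
to emulate a much stronger promoter) and requires the full chain to return
the programmed percentages within ±5 points at 200 animals/group averaged
over 10 seeds; the measured values land within ±0.4 points. Bootstrap CI
coverage is checked at the generator's between-animal noise (94–95%
empirical at nominal 95%, 500 replicates, 100 animals/group). The dilution
series spans 256-fold with the top two levels clipping, and the assessor
reports the surviving 64-fold range.

These checks validate the *pipeline arithmetic* — calibration,
thresholding, correction and inference are mutually consistent and
unbiased under the generator's assumptions. They do not validate the
generator against real worms: real animals have internal structure (gut
granules, bright autofluorescent foci), nonuniform reporter distribution,
motion blur, optical PSF and scattering, day-batch effects, and body-size
variation, none of which are simulated. Passing here means the analysis
measures what the forward model emits; it cannot certify biological
accuracy on real images.

## Numerical choices and degenerate inputs

Seeded `numpy` Generators everywhere; identical seeds give bit-identical
frames, cohorts and bootstrap draws. Lognormal draws are parameterized by
arithmetic mean and CV (`σ² = ln(1 + cv²)`, `µ = ln m − σ²/2`); CV 0 is the
constant. Otsu on a constant pooled image, empty cohorts, mixed-channel
baselines, non-positive control means, sub-3-level dilution series, and
malformed GTF lines all raise with specific messages rather than returning
NaN. Bootstrap resamples with a non-positive control mean are dropped from
the percentile computation (they occur only in pathologically noisy
cohorts).

## Problem sizes

Default validation sizes — 200 animals per cohort, 10 seeds for recovery,
500 replicates for coverage, 1,000 frames for dark-map accuracy, 2,000
simulations for familywise error — mirror the scale of the study design
(cohorts of roughly 100–300 animals, 1,000 dark frames) while keeping a
full run on one CPU in a few minutes.
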