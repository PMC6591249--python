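# imequant

Whole-animal fluorescence quantification and intron-mediated enhancement
(IME) analysis for *C. elegans* microfluidic imaging, with a fully
synthetic, ground-truthed instrument simulator.

## The problem

Introns can boost the expression of the gene that carries them — IME. To
measure the effect *in vivo* one images hundreds of worms per strain in a
microfluidic chamber, quantifies each animal's mean fluorescence
concentration, and compares intron-bearing strains against an intronless
control. Between the camera and the biology sit several corrections that
make or break the measurement:

- **dark current** — per-pixel camera offset, estimated as the pixelwise
  median over a stack of no-light frames and subtracted from every image;
- **segmentation** — one Otsu threshold (minimum intraclass variance) is
  computed on the pooled pixels of *all* strains sharing a promoter ×
  fluorophore group, so segmentation cannot differ between the strains
  being compared; masks are opened and reduced to the largest component;
- **autofluorescence** — worm tissue fluoresces on its own (much more
  under GFP optics than mCherry optics); the population mean of wild-type
  animals imaged with identical settings is subtracted from every
  transgenic measurement;
- **linearity** — a fluorophore dilution series verifies the camera is
  operated in its linear range before any ratio is trusted.

The headline quantity per comparison is

```
percent increase = 100 · (mean(test) − mean(control)) / mean(control)
```

computed on background-corrected per-animal mean voxel intensities, with a
95% percentile-bootstrap confidence interval, plus the usual nonparametric
battery: Mann-Whitney rank-sum (exact or normal-approximate), Kruskal-Wallis
followed by Dunn's vs-control comparisons, two-way ANOVA with Holm-Sidak
step-down adjustment.

Because no imaging data ships with the original study, the package includes
a forward simulator (`imequant.simcam`) of the entire instrument — camera
gain/exposure/dark current/read noise/saturation, Poisson shot noise, a
U-posed worm phantom with a confined-body optical-depth profile, lognormal
between-animal variability, channel-specific autofluorescence — so that
every pipeline stage is verifiable closed-loop against known ground truth.
A GTF intron-extraction module (`imequant.introns`) reproduces the
genome-annotation side of the analysis (intron sizes of protein-coding
genes, log10 size distributions).

## Worked example

```python
from imequant import workflows

res = workflows.run_recovery_experiment(
    effect_multiplier=1.4588,   # programmed +45.88% reporter concentration
    channel="mcherry",
    n_per_group=200, n_wildtype=100, seed=1,
)
print(f"recovered {res.effect.percent_increase:.2f}% "
      f"(95% CI {res.effect.ci_low:.2f} .. {res.effect.ci_high:.2f}), "
      f"truth this experiment {res.truth_percent:.2f}%")
```

prints (seed 1):

```
recovered 44.58% (95% CI 39.01 .. 50.58), truth this experiment 44.76%
```

i.e. the full chain — simulate 200 + 200 + 100 animals, estimate the dark
map from 100 simulated dark frames, pool an Otsu threshold over the two
transgenic cohorts, segment, summarize, subtract the wild-type
autofluorescence baseline, and bootstrap the percent effect — recovers the
programmed +45.88% within sampling error.

Command line (`ime --help`): `ime simulate` writes TIFF cohorts with a
manifest and truth table, `ime calibrate` estimates a dark map from dark
TIFFs, `ime linearity` fits a dilution series, `ime quantify` segments a
manifest, `ime effect` computes corrected percent effects, and
`ime introns` extracts intron sizes from a GTF (Ensembl or GENCODE
dialect, gzip accepted).

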