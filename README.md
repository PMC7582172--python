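# protoconn

Seed-based resting-state functional connectivity (FC) analysis of how an
experience-dependent visual region — the putative visual word form area
(VWFA) in left ventral temporal cortex — is wired to the frontotemporal
language network, in neonates and adults. The package re-implements the full
analysis chain as a tested, reusable pipeline and drives it with a synthetic
multi-subject BOLD generator with known group-level coupling, so every stage
can be validated at desk scale without access to restricted infant/adult
consortium data.

## What it computes

For each subject, the BOLD run is smoothed within gray matter (Gaussian,
FWHM 3 mm), band-pass filtered (zero-phase Butterworth, 0.009–0.08 Hz) and
denoised with aCompCor (regression of the top 5 principal components of the
white-matter + CSF timeseries). Connectivity is Pearson correlation between
parcel mean timecourses, Fisher-transformed, z = atanh(r). On top of that:

- **Connectivity fingerprints** — a seed category's profile of mean z over
  four target categories, mean-centered; group pattern dissimilarity is the
  Euclidean distance between a subject's 4-vector and a reference group's
  mean, compared within vs between groups by two-sample t-tests.
- **Percentile-threshold Dice sweep** — seed-to-voxel FC maps inside a
  search space (e.g. ventral temporal cortex, VTC) binarized at the
  50th…95th percentile; overlap with each candidate parcel scored with the
  Sørensen–Dice coefficient 2|A∩B|/(|A|+|B|).
- **Group statistics** — two-way factorial ANOVA (group × target) with
  partial η² and noncentral-F confidence intervals, paired and pooled
  two-sample t-tests with Cohen's d and mean-difference CIs, BH/BY FDR
  control, and sex/motion (framewise displacement) matching of cohorts.

The synthetic generator plants a known cross-system latent coupling matrix
per group (language–VWFA strongest), a shared physiological nuisance signal
(also present in WM/CSF, which is what makes aCompCor identifiable), and
white voxel noise, so parameter recovery is checkable against ground truth.

## Worked example

```bash
protoconn all --quick --output scratch/demo --seed 3
```

runs the whole chain on a 4-subjects-per-group, 200-frame cohort and writes
tables, NIfTI maps and figures under `scratch/demo/`. The numbered drivers
under `analysis/` run the desk-scale study (12 per group, 300 frames) and
publish the headline tables into `results/`:

```bash
cd analysis && python 01_simulate_cohort.py && python 03_connectivity.py \
  && python 05_dice_sweep.py && python 06_group_stats.py
```

prints, among others (master seed 7):

```
atlas: 20 parcels in 8 categories after overlap resolution and tissue exclusion

group-mean category-level Fisher-z FC:
    seed   group   target   mean_z
language neonate     VWFA 0.438797
language neonate    faces 0.254249
language neonate   scenes 0.324419
language neonate  objects 0.434226
...
region with max mean Dice per percentile:
50    VWFA
...
95    VWFA

VWFA seed ANOVA:
             test  statistic  df1  df2    p_raw   effect
      anova_group   0.945178    1   88 0.333615 0.010627
     anova_target   5.410764    3   88 0.001834 0.155732
anova_interaction   2.048468    3   88 0.112896 0.065276
```

Reading this: the language network couples most strongly to the VWFA in both
groups — with neonatal object regions close behind, which is exactly the
planted generative structure — the VWFA parcel attains the maximum Dice
overlap with language-connected VTC voxels at every percentile threshold,
and the ANOVA target effect is significant with the factorial error df
N − g·t = 96 − 8 = 88 (df (3, 312) at the study's full 40-per-group scale).
Post-hoc paired t-tests on n = 12 report df 11 (df 39 at n = 40); group
comparisons report df n₁+n₂−2.

## Layout

- `src/protoconn/` — library: `synthetic`, `preprocess`, `atlas`,
  `connectivity`, `fingerprint`, `dice`, `stats`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers over the library
- `tests/` — pytest suite (unit, property and acceptance tests)
- `docs/methods.md` — model, parameters, numerical choices, limitations
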