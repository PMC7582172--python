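# Methods

This note documents the models, parameters and numerical choices behind
`protoconn`, and what the synthetic validation does and does not establish
about real data.

## The scientific question

In literate adults the visual word form area (VWFA) in left occipitotemporal
cortex responds selectively to written words. One account of how such an
experience-dependent region comes to occupy a predictable location is that
its connectivity with the frontotemporal language network is in place long
before reading: the region is "earmarked" by its wiring. Testing this with
resting-state fMRI amounts to two comparisons: (1) the language network
should correlate more strongly with the putative VWFA than with neighboring
ventral visual regions (face, scene, object areas), and (2) the putative
VWFA should correlate more strongly with language regions than with adjacent
frontotemporal systems (multiple-demand regions, speech cortex, A1) — in
neonates as in adults. The package implements this comparison chain
end-to-end and validates it against a generative model in which the answer
is known.

## Synthetic BOLD model

Each subject's run is built from latent signals, one per functional system
(language, VWFA, faces, scenes, objects, speech, A1, MD):

- Latents are white Gaussian series band-limited to 0.01–0.08 Hz and mixed
  by the Cholesky factor of a per-group coupling matrix `C_g` (symmetric,
  unit diagonal, PSD — verified at construction, rejected otherwise). `C_g`
  is the population correlation structure that parcel-level FC estimates
  converge to as runs lengthen.
- A voxel in system *s* receives `a·L_s(t) + b·P(t) + c·ε_v(t)`, with
  `a = 1` (signal gain), `b = 0.5` (physiological gain), `c = 2` (noise
  gain) by default. `P(t)` is a single band-limited physiological nuisance
  series shared by **all** tissue classes — including white matter and CSF —
  which is precisely what makes aCompCor identifiable. `ε` is white voxel
  noise. Voxels outside all systems carry only `b·P + c·ε`. Runs are
  standardized per voxel.
- The latent band sits inside the analysis band-pass (0.009–0.08 Hz) so
  that the pipeline's own filter does not destroy the signal whose recovery
  is being tested. The physiological signal is also placed in-band:
  out-of-band nuisance would be removed by the band-pass alone, and the
  aCompCor stage would have nothing left to do; in-band physiological power
  (respiratory/cardiac aliasing into the low frequencies) is the realistic,
  and the hard, case.
- Defaults: TR 0.72 s, T = 600 frames (desk scale). The acquisition the
  generator emulates (≈15-minute runs: 2300 frames at TR 0.392 s for the
  neonatal protocol, 1200 at 0.72 s for the adult one) is available through
  `tr_seconds`/`n_timepoints`.
- Motion is a six-parameter Gaussian random walk with per-group step scales
  (neonates 0.03 mm / 4·10⁻⁴ rad, adults half that), giving neonates the
  larger framewise displacement, as in real cohorts.

Gain rationale: with `c = 2`, voxel noise dominates single-voxel variance
(realistic for BOLD), while after averaging 8-voxel parcels and band-pass
filtering (which removes ~90% of white-noise variance at these settings) the
parcel-level attenuation of r is only a few percent, so group-mean Fisher-z
estimates track `atanh(C_g)` closely.

### Default coupling matrices

Both groups share a 0.15 baseline between all systems, with language–speech
0.45, language–A1 0.35, language–MD 0.30, speech–A1 0.45. The adult matrix
sets language couplings to VWFA/faces/scenes/objects at 0.50/0.30/0.25/0.30;
the neonate matrix at 0.45/0.30/0.27/0.42 — i.e. language–VWFA highest in
both groups, but neonatal object regions nearly as language-coupled as the
VWFA, mirroring the qualitative developmental dissociation the analysis is
meant to expose. These are configuration, not estimates: no public dataset
reports the parcel-pair FC distributions needed to calibrate them, so the
magnitudes are plausible round numbers fixed once.

Two special-purpose configurations exist alongside the default:

- `fingerprint_recovery_ground_truth()` — language–VWFA exceeds language–
  {faces, scenes, objects} by ≥ 0.15 in **both** groups. Used for
  parameter-recovery checks where the planted ranking must be unambiguous;
  under the default neonate matrix the VWFA-vs-objects margin (0.03) is
  intentionally within sampling noise, which is a statement about
  development, not a recoverable effect at n = 20.
- `planted_signal_ground_truth()` — language–VWFA 0.60, everything else at
  baseline. Used for the Dice-sweep recovery check: only the VWFA parcel's
  voxels carry the seed-coupled signal.

## Synthetic atlas

A (12, 12, 8) grid at 2.15 mm isotropic: white matter is the z = 0 slab,
CSF the z = 1 slab, gray matter z ≥ 2, with a small "cerebellum" carved out
of one gray corner. Twenty 2×2×2 parcels in eight categories (7 language,
5 MD, 2 faces, 2 objects, 1 each speech/A1/VWFA/scenes) are hand-placed on
three sheets: a ventral sheet holding the visual parcels inside the VTC
search space, a posterior sheet holding the temporal parcels, and a superior
sheet holding the frontal parcels. The temporal search space excludes the
VTC by construction, and the finalizer enforces this (the voxel-wise
temporal analysis must not re-test VTC voxels). An `include_overlap_pair`
switch widens FFA so that exactly one parcel pair (FFA/OFA, 16 vs 8 voxels)
overlaps, exercising overlap resolution.

## Preprocessing

Order: smooth → band-pass → aCompCor (configurable).

- **Smoothing** is Gaussian (FWHM 3 mm, σ = FWHM/√(8 ln 2) voxels),
  restricted to the gray-matter mask: out-of-mask values contribute nothing
  and the kernel is renormalized by its in-mask mass, so constants are
  preserved and edge voxels are not darkened. Renormalized masked smoothing
  conserves in-mask mass exactly only where the kernel support does not clip
  the mask boundary; the mass-conservation test is stated under that
  condition. Renormalization can be disabled by flag.
- **Band-pass** is an order-2 Butterworth (0.009–0.08 Hz) applied
  forward–backward (zero phase) after per-channel linear detrending. Filter
  gain is characterized on the steady-state central portion of a test
  signal; the reflection-padding transients at the series edges are not part
  of the filter's frequency response.
- **aCompCor** pools WM and CSF voxels, detrends and standardizes them, and
  takes the top 5 temporal principal components (computed from the
  voxel-side Gram matrix); gray-matter voxels are replaced by their
  least-squares residuals against these components plus an intercept. WM/CSF
  voxels are passed through unchanged. If fewer usable noise voxels than
  components exist, the count is reduced with a warning.
- **Framewise displacement** is the sum of absolute backward differences of
  the three translations plus 50 mm times the summed absolute rotation
  differences (arc length on a 50 mm sphere) — the standard motion scalar;
  the matching step pairs each neonate with the same-sex adult of nearest
  mean FD, greedily and without replacement (ties to the lowest adult id),
  which is the only deterministic 1-nearest-neighbor variant that yields
  distinct matched controls.

## Connectivity, fingerprints, Dice sweep

- Category-level FC averages **Fisher-z values** over all seed×target parcel
  pairs (transform first, then average). |r| within 10⁻⁷ of 1 is clamped
  before atanh with a warning; |r| > 1 is an error. Zero-variance parcels
  yield NaN rows with a warning; zero-variance voxels in seed-to-voxel maps
  get z = 0.
- The seed timecourse for voxel-wise maps is the mean over the **union** of
  the seed parcels' voxels (size-weighted).
- Fingerprints are 4-vectors of category-level z, mean-centered by default
  so they express pattern shape; distances between centered vectors are
  invariant to any common additive offset. Raw-vector mode is a flag.
- Dissimilarity: a subject's within-group distance uses the leave-one-out
  mean of their own group; their between-group distance uses the other
  group's full mean. The three group comparisons pair **disjoint subject
  sets** (e.g. adults' within-distances vs neonates' distances to the adult
  mean): if a group's within- and between-distances were compared over the
  same subjects, the two samples would be nearly perfectly correlated under
  the null (both dominated by the subject's own fingerprint noise) and the
  independent two-sample t-test would be degenerately conservative. The
  disjoint pairing preserves the quantities compared, matches the reported
  degrees of freedom (n₁+n₂−2), and keeps the test calibrated — which the
  null-calibration suite verifies.
- The Dice sweep thresholds the in-space z distribution at percentiles
  50…95 (step 5, configurable; linear-interpolation percentiles, strict >
  for binarization) and scores overlap with each candidate region as
  2|A∩B|/(|A|+|B|). The alternative literal reading 2|A∩B|/|A∪B| equals 2
  for identical sets and is available only behind an explicit
  `union_formula` flag for sensitivity analysis. Both-empty Dice is defined
  as 0 with a warning.

## Group statistics

- The two-way ANOVA defaults to the **factorial** form that treats every
  group×target observation as independent, giving error df N − g·t (320
  observations → df 312 with 40 per group and 4 targets); a true
  mixed-design decomposition (group against subjects-within-groups, df 78;
  target/interaction against the within-subject error, df 234) is available
  via `repeated=True`. The factorial form is the default because it
  reproduces the df structure of the design being reproduced; note that with
  positively correlated within-subject measures it is mildly conservative
  for within-subject effects.
- Partial η² = df₁F/(df₁F + df₂); its CI inverts the noncentral-F
  distribution in the noncentrality parameter λ (NaN-safe bisection;
  η² = λ/(λ+df₁+df₂+1)) and is clipped to always cover the point estimate.
- Paired Cohen's d uses the sd of differences; independent d uses the pooled
  sd. Degenerate inputs (zero-variance differences, zero pooled variance)
  raise rather than return infinities.
- FDR: Benjamini–Hochberg step-up by default, Benjamini–Yekutieli by option
  (delegated to statsmodels; an independent brute-force step-up serves as
  the test oracle).

## Validation design and problem sizes

The stochastic acceptance suites run at desk scale, chosen to keep the whole
suite practical on a single CPU while leaving comfortable statistical
margins:

- *Fingerprint recovery*: 50 cohorts, 20 subjects/group, T = 600, full
  preprocessing, recovery coupling matrices. Checked: VWFA ranked top in
  both groups' mean fingerprints and BH-significant paired VWFA-vs-faces/
  scenes contrasts.
- *Dice recovery*: 50 cohorts of 20 subjects, T = 300, planted-signal
  model, full preprocessing; VWFA must attain the maximum group-mean Dice
  at every percentile.
- *Null calibration*: 200 cohorts, 20 subjects/group, T = 200, identical
  couplings in both groups, preprocessing without smoothing (spatial
  smoothing mixes voxels upstream of parcel means and is irrelevant to the
  calibration of the group statistics; band-pass and aCompCor are retained
  because removing the shared physiological component decorrelates the
  within-subject errors that otherwise make the factorial interaction test
  conservative). Checked: raw-p significance rates of the interaction
  F-test and the three dissimilarity t-tests at α = 0.05.

## What passing does and does not show

The generator contains no hemodynamic response, no spatial autocorrelation
beyond the shared system/physiological signals, no scanner drift or motion
artifacts in the voxel data (motion tables are generated separately for the
matching machinery), and no between-subject variation in the coupling
matrices. Passing recovery and calibration therefore demonstrates that the
pipeline's estimators and tests do what they claim under their own model
assumptions — not that the preprocessing choices are optimal for real
acquisitions. Conversely, every algorithmic rule (overlap resolution by
smallest original parcel, tissue exclusion, z-then-average, leave-one-out
dissimilarity, percentile binarization, FDR step-up) is exercised against
independent oracles or closed forms and holds exactly.

## Known limitations

- Overlapping raw parcels survive a disk round-trip only as a label volume
  (later parcels win), so the on-disk pipeline assumes the default
  non-overlapping atlas; overlap resolution is exercised in memory.
- The repeated-measures ANOVA variant reports the classical mixed-design
  decomposition; no sphericity correction is applied.
- FD matching is greedy 1-NN without replacement, not globally optimal
  assignment; with a large control pool the difference is negligible.
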