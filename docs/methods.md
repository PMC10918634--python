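# Methods

`zoomsid` turns raw MALDI-ToF bone-collagen peptide-mass-fingerprint
spectra into ranked ZooMS taxonomic identifications. This note records
the models, parameter choices and numerical decisions behind the
implementation, and what the synthetic test bed does and does not show.

## Problem setting

ZooMS identifies (mostly archaeological) collagen by matching the masses
of taxon-diagnostic tryptic peptides ("markers", conventionally lettered
A–G, P1, P2) against a reference table of species → marker masses.
Spectra are acquired as technical triplicates of each digest; peaks are
singly charged, so m/z is read directly as peptide mass in Da.
Identification has to tolerate two systematic mass effects: instrument
accuracy (about ±0.3 Da) and Gln/Asn deamidation, which shifts the
aggregated isotope distribution up by ~+1 Da. Both are absorbed by the
asymmetric match window [−0.3, +1.3] Da used everywhere a sample mass is
compared to a reference or contaminant mass. The window is applied to
all markers regardless of their deamidation potential; this is
deliberately permissive and matches how compound shifts and
inter-laboratory variation present in practice.

## Preprocessing chain

Each replicate profile passes through, in order:

1. **Savitzky–Golay smoothing** — local cubic fit over a 21-point window
   (`sg_half_window=10`, `sg_poly_order=3`). Reproduces constants and
   ramps exactly; negative fit outputs are clamped to zero.
2. **SNIP baseline subtraction** — iterative peak clipping with windows
   shrinking from `snip_iterations=100` points down to 1 (the smoother,
   decreasing-window variant). Output is clamped non-negative.
3. **TIC normalization** — intensities divided by their sum, making
   replicates and samples comparable.
4. **Noise estimation** — windowed robust level: the spectrum is cut
   into 500-point blocks; each block's level is 1.4826 × median(|x −
   median(x)|) (a consistent σ estimator under Gaussian noise,
   insensitive to sparse peaks), interpolated back to the full grid with
   a small positive floor.
5. **Peak detection** — a point is an apex when it equals the running
   maximum over ±`peak_half_window=20` points, rises strictly above its
   left neighbour (plateaus keep their first point; the first grid point
   is never an apex), and exceeds `snr_threshold=3` times the local
   noise level.
6. **Monoisotopic picking** — peaks are clustered greedily along the
   mass axis at the expected isotopic spacing 1.00235 Da (relative
   tolerance 1e-4, cluster size 2–10). A cluster collapses to its
   lowest-mass member only when its intensity pattern correlates at
   least `mono_min_cor=0.95` (Pearson) with a modelled envelope. Only
   the maximal chain from each seed is tested; when it fails, the seed
   alone is spent and later chain members may still seed their own
   envelope — this way a stray shoulder bump just below a true
   monoisotopic peak cannot poison the collapse of the real envelope.
   Lowering `mono_min_cor` (0.94–0.90) admits weaker or
   deamidation-blurred envelopes at some false-collapse risk.

Replicates whose peak count falls below `replicate_min_peaks=5` or below
`replicate_median_fraction=0.5` of the group median are dropped
(quality control); the surviving *processed profiles* are averaged
pointwise (linear interpolation onto the union grid when axes differ),
and detection plus de-isotoping are repeated on the average to give the
final per-sample peak list. If no replicate survives, the sample is
flagged failed.

### Noise measurement inside the chain

One place where the implementation deliberately departs from the naive
reading of the chain: the SNR test inside `preprocess_sample` measures
noise on the **high-frequency component of the raw signal** (raw minus
smoothed intensity, windowed MAD, divided by the same TIC total), not on
the processed profile. Two artefacts make the processed profile a poor
noise yardstick: clamping negative residuals to zero halves the apparent
spread, and the SNIP baseline leaves a slowly wandering correlated
residue that simultaneously inflates local maxima and escapes a windowed
MAD. Measuring the raw high-frequency noise is conservative and keeps
"SNR ≥ 3" meaning what a spectroscopist expects. For the averaged
profile the noise level is the mean of the per-replicate levels — iid
noise would shrink by √n, but the systematic clipping residue does not,
so no √n credit is taken. The public `estimate_noise` function keeps the
plain windowed-MAD contract for callers who want the textbook estimator.

### Isotope model

Aggregated isotopic abundances are approximated by a Poisson
distribution with rate λ = 5.1e-4 × mass (averagine-style composition:
the rate is dominated by 1.1% ¹³C at ≈0.044 carbons per Da, plus smaller
¹⁵N/²H/³³S terms). This is adequate for correlating envelope *shapes* in
the 800–4000 Da range; it is not an elemental-composition calculator.

## Identification

The sample's monoisotopic peak list is discretized on a uniform mass
grid (default [800, 3700] Da, 0.1 Da bins, half-open) as a binary
indicator vector and smoothed with a discrete Gaussian (σ = 2 bins,
mass-preserving). Each reference species is discretized as a binary
vector that is 1 wherever a bin center lies inside the [−0.3, +1.3] Da
window of any of its markers. The candidate score is the Pearson
correlation between the two vectors; zero-variance vectors score 0. Of
the two possible readings of "binarize and window", the window is
carried on the **reference** side and the smoothing on the **sample**
side; grid extent, bin width and σ are configuration, and the package's
guarantees (rank ordering on the synthetic bed, oracle equality against
brute-force bin enumeration) are insensitive to them by construction.
The absolute correlation value is *not* comparable across grids or
datasets and is reported for ranking, not thresholding.

Marker matching is done in exact mass arithmetic, independent of the
grid: every (marker, peak) pair within the window is a candidate, and
pairs are accepted greedily by smallest |Δm| with each marker and each
peak used at most once. Matched-marker counts are distinct marker ids.
Contaminant scanning reuses the same window against the contaminant
list, reporting every hit (keratins, trypsin autolysis, matrix clusters,
casein, serum albumin).

Candidates are ranked by descending correlation. Exactly equal scores —
which arise structurally when species share their full in-window marker
footprint — share a rank and are all reported, beyond `n_top=3` if
needed; disambiguating such ties by geography or chronology is the
analyst's task (the tool only partitions the database by region:
Eurasia, Africa, New World). Status: **fail** with no matched marker
(candidates suppressed entirely), **tentative** with 1–4 matched markers
(manual inspection recommended), **ok** with ≥5.

## Evaluation

ZooMS taxa are free text and often compound ("Cervus/Saiga/Gazella
sp."), so labels are normalized (split on "/", strip " sp.", "?", "*",
case-fold) and a prediction matches a manual label when the atom sets
intersect. Fails on either side are excluded before any statistic.
Site accuracy is the match percentage; the weighted accuracy is
Σnᵢaᵢ/Σnᵢ (reported to 2 decimals). Correlation scores of true vs false
identifications are compared with Welch's unequal-variance t-test by
default (`equal_var=True` gives the pooled Student form); the choice of
Welch is deliberate because true/false groups are typically unbalanced
with unequal spreads.

## Synthetic data generator

The generator emulates the study conditions the pipeline is built for:
technical triplicates of one species' digest, with per-sample planted
marker masses (Gaussian mass error, sd 0.05 Da; deamidation +0.984016 Da
with probability 0.1 per marker), Gaussian peaks at constant resolving
power R = 10 000 (FWHM = m/R), optional Poisson-model isotope
envelopes, an exponentially decaying chemical baseline (amplitude 20,
~700 Da scale), iid detector noise (σ = 1 against marker peak heights of
~36–84, i.e. high but realistic SNR), 30 random decoy peaks and optional
contaminant peaks. Profiles run 800–3650 Da at 0.02 Da spacing; peak
heights and noise are redrawn per replicate, planted masses are not
(replicates are spots of the same digest). Everything is a pure function
of (config, seed).

Two generator properties are load-bearing for the test bed and worth
stating plainly:

- **Decoy peaks avoid marker windows.** Decoy masses are resampled until
  they are at least 0.3 Da clear of the [−0.3, +1.3] window of *every*
  marker in the database. Decoys model non-collagenous junk; keeping
  them out of marker windows makes the planted marker count an exact
  ground truth, which is what makes the ≤4-marker "never ok" property a
  property of the status rule rather than of decoy luck.
- **Planted truth is recoverable at zero noise**, which anchors the
  preprocessing oracle tests.

A note on detection thresholds: at the operating threshold SNR ≥ 3 a
long profile (~10⁵ points) lets a handful of borderline noise or
clipping-shoulder bumps through at SNR 3–4; these are harmless for
identification (they rarely land in a marker window — the rank-1
recovery rate is measured *with* them present) but they mean exact
peak-set recovery is only guaranteed for peaks held to SNR ≥ 10, which
is how the exact-recovery invariant is stated and tested.

What the generator does **not** emulate: ionization suppression and
detector saturation, mass-dependent intensity bias, correlated (pink)
noise, calibration drift across the plate, PTMs beyond deamidation, and
real marker biology — the shipped reference table's masses are synthetic
stand-ins (file names and docstrings say so). Passing the synthetic
acceptance bed therefore demonstrates the pipeline's correctness and
stability under its stated model, not field accuracy on real
assemblages; for real work, drop in a curated marker database and
contaminant list with the same CSV schema.

## Problem sizes and reproducibility

The seeded acceptance runs use 200 samples (5–7 planted markers) for the
rank-1 recovery rate, 60 samples (2–4 markers) for the few-marker
caution property, 100 random fixtures for the vectorization oracle, and
5 samples for the batch-determinism check; these sizes give stable
percentages while keeping a full run in the low minutes on one core.
All randomness flows from explicit integer seeds; repeated runs are
byte-identical, and every CLI run writes a manifest (resolved settings +
input hashes) next to its outputs.

## Known limitations

- Correlation scores are relative; no universal decision threshold
  exists or is attempted. Scores should be read within one dataset only.
- Closely related species separated by a single marker (or sharing a
  conserved ~3017 Da bovid peptide) can tie or swap ranks when that
  marker is missing; the tentative/fail logic and regional partitioning
  mitigate but cannot eliminate this.
- The mzML reader covers the profile/peak-array subset of the standard
  (32/64-bit float arrays, optional zlib); vendor binary formats are out
  of scope.
- Averaging assumes replicates share (or nearly share) a mass axis;
  strong calibration drift between replicates would smear peaks rather
  than be corrected.
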