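# Methods

`msicyto` implements a proteomic triage pipeline for thyroid fine-needle
aspirate (FNA) cytology analyzed by MALDI-TOF mass spectrometry imaging
(MSI). One linear-mode profile spectrum (m/z 3000–20,000) is acquired per
50 × 50 µm pixel of a cytospin preparation; a pathologist annotates regions
of interest (ROIs) containing thyrocyte clusters; a sparse logistic model
scores the probability that the sampled nodule is malignant. This note
documents the model, the processing conventions, the synthetic data the
package is tested on, and the design choices made where the problem was
genuinely open.

## Spectral preprocessing

Each pixel spectrum passes through a fixed chain, in this order:

1. **Baseline subtraction (median method).** `baseline(i)` is the median of
   the intensities in a centered window of `2·hw + 1` points (default
   `hw = 50`), truncated at the spectrum edges; the output is
   `max(0, y − baseline)`. The truncated-window semantics mean every output
   point is a statistic of observed data only. The default half-window is a
   package choice (none is canonical for linear-mode protein spectra); it is
   wide relative to the ~40 Da peak width so peaks are not eroded.
2. **Smoothing (moving average).** An unweighted mean over `2·hw + 1`
   points, `hw = 2` by default. A nominal half-width of 2.5 points cannot be
   realized by an integer window; 2 is the nearest feasible value and is
   exposed in `ProcessingParams`.
3. **TIC normalization.** Division by the total ion current (summed
   intensity), removing per-pixel scale (laser coupling, matrix
   crystallization). Pixels with zero TIC raise an *empty pixel* signal and
   are masked downstream — never scored as probability 0, which would bias
   pixel-level quartiles toward the benign side.
4. **Peak picking (S/N ≥ 6).** Local maxima strictly above their neighboring
   distinct values (plateaus count once, at their leftmost point), kept when
   apex / noise ≥ 6 (boundary inclusive). Noise is the scaled median
   absolute deviation, `1.4826 · MAD`, of the processed intensities — a
   robust estimator unaffected by sparse large peaks. A spectrum with zero
   estimated noise admits every positive apex.
5. **Low-intensity filtering.** Peaks below 0.0003 (post-TIC, boundary
   inclusive) are discarded as noise. The filter direction is interpreted as
   a noise floor; a `keep_below` switch provides the inverted comparison for
   compatibility with sources that state the rule the other way around.
6. **Peak alignment.** All peak m/z values across observations are pooled,
   sorted, and cut into clusters wherever the gap between adjacent values
   exceeds a relative tolerance (default 2000 ppm of the lower value) —
   one-dimensional single-linkage clustering. Each cluster becomes a feature
   at the intensity-weighted mean m/z. The default tolerance reflects
   linear-TOF peak widths (tens of Da at 10 kDa), which dwarf the ±30 ppm
   external calibration accuracy; it is configurable. Features absent from
   an observation are imputed as intensity 0, with a separate binary
   detection mask, because the prevalence filters are defined on detection,
   not intensity.

The running median is computed by a compiled sorted-window routine (exact,
including edge truncation; verified against a brute-force oracle in the
test suite), with a pandas rolling-median fallback implementing identical
semantics.

## Training observations

Training uses only ROIs containing epithelial cells. Per ROI, pixels are
processed individually and the profiles averaged pointwise (empty pixels
excluded); peaks are picked on the mean profile. Because patients
contribute very different ROI counts, each patient's ROIs are partitioned
into *equivalent groups* — 5 per benign and 4 per malignant patient, each
holding 1–7 ROIs — and the group-mean profiles become the observations:
9 benign patients × 5 groups + 9 malignant × 4 groups = 45 + 36 = 81
observations. The grouping algorithm is a deterministic greedy balance:
ROIs sorted by pixel count descending (seeded shuffle breaks exact ties)
are dealt to the group with the smallest running pixel total among groups
under the 7-ROI cap. This equalizes spectral support across groups and is
reproducible; the assignment rule itself is a package choice, as no
canonical rule exists.

Two detection-prevalence filters then screen features:

- **intra-patient**: a feature is present in a patient iff detected in
  ≥ 25% of that patient's ROIs (boundary inclusive; denominator = ROI
  count);
- **inter-patient**: a feature is retained iff present in ≥ 25% of benign
  patients **or** ≥ 25% of malignant patients (the union of the two
  class-representative sets). An intersection mode is available but
  non-default: the union reading matches the purpose of keeping features
  representative of either class, and the intersection would discard
  exactly the class-exclusive features the model needs.

## The malignancy model

A logistic regression with an L1 (Lasso) penalty, malignant coded 1:

    minimize over (β₀, β):  (1/n) Σᵢ log(1 + exp(−(2yᵢ−1)(β₀ + xᵢᵀβ)))
                            + λ ‖β‖₁

Features are standardized internally (mean 0, sd 1; constant columns
dropped); coefficients are reported back on the intensity scale. λ runs
down a 30-point geometric path from λ_max (the smallest penalty that zeroes
every coefficient) to λ_max/100, and is chosen to minimize the mean
cross-validated binomial deviance. CV folds (default 5) are stratified by
class and grouped by patient, so the several observations deriving from one
patient can never straddle a training/held-out split — the leakage that
per-observation folds would invite. Ties in CV deviance resolve toward the
larger (sparser) λ. These CV conventions (fold count, min-deviance rule,
internal standardization, patient grouping) are package choices, each
exposed in configuration.

Per fixed λ the fit is delegated to scikit-learn's saga solver and then
polished by a short deterministic full-batch proximal-gradient (ISTA) pass:
saga's step size scales with the inverse penalty, so at strong penalties it
leaves the unpenalized intercept measurably short of its optimum (the
all-zero-coefficient limit must give intercept = logit of the class
prevalence). The polish restores the joint optimum at negligible cost for
designs of this size and makes fits reproducible bit-for-bit (saga's
shuffling is seeded). An independently written FISTA solver serves as the
oracle in the test suite.

## Validation and triage

A fitted model scores a new specimen three ways, all on the same processed
pixel profiles:

- **ROI mode** — one probability per ROI mean spectrum;
- **whole-average mode** — one probability for the mean of every non-empty
  pixel, ignoring the morphological selection;
- **pixel mode** — one probability per non-empty pixel, rendered as a map
  (green = benign, red = malignant; masked pixels transparent).

Each mode yields a quartile summary. Quartiles use linear interpolation
between order statistics (numpy's default, the "type 7" rule); the choice
matters for small ROI counts and is configurable. The triage call compares
the third quartile (q3) with the gap observed between the training classes:
q3 < 7% reads benign, q3 > 28% malignant, and anything between is an
explicit *signal of alert* for pathologist review rather than a forced
binary call. The thresholds are an observed training gap, not a derived
rule; they are configurable defaults and the raw q3 is always reported.

## Synthetic cohorts

No public FNA MSI dataset with ROI annotations exists, so the package ships
a generator that emulates the statistical structure the analysis assumes,
with full ground truth. Per-pixel spectra are sums of Gaussian peaks (FWHM
40 Da, linear-TOF-like) on a 4000-point shared axis over m/z 3000–20,000,
plus a decaying-exponential baseline (amplitude 20 a.u., decay constant
3000 Da), i.i.d. Gaussian noise (sd 2 a.u., truncated at zero), a lognormal
per-pixel TIC multiplier (CV 0.15), and a per-patient mass-axis scaling
drawn uniformly within ±30 ppm (the instrument's external-calibration
accuracy). The peak panel holds 20 shared (nuisance) peaks, 2 benign-up and
3 malignant-up discriminant peaks — 5 planted discriminants in total — plus
per-patient *sporadic* peaks appearing in a random ~15% minority of that
patient's ROIs, which is what the intra-patient prevalence filter exists to
remove. Background (non-thyrocyte) pixels carry their own broad low-mass
spectral family (colloid/blood-like bumps), not silence, because the
documented failure modes stem from background *signal*.

Cohort geometry mirrors the training study: 9 benign patients with 5–22
ROIs of 3–39 pixels, 9 malignant with 4–19 ROIs of 3–162 pixels; pixel
counts are sampled log-uniformly so medians land near the observed medians
despite the long upper tail. ROIs are laid out as contiguous blocks in a
snake-ordered grid sized so background pixels make up a configured fraction
of the acquired area.

**Background fraction and adequacy.** The default background fraction is
0.2 for the standard scenario. The q3 triage statistic tolerates at most
25% off-target pixels before the third quartile lands on background rather
than thyrocyte probabilities; a *standard* specimen models an adequate
cytospin (the SIAPEC rule: at least 6 clusters of 10 thyrocytes), whose
background must therefore stay below that weight. Inadequate preparations
are exactly what the challenge scenarios model:

- **paucicellular** — malignant thyrocyte pixels cut to ≤ 10% of the
  standard count, grid unchanged;
- **heterogeneous_mixture** — every 4th thyrocyte pixel malignant,
  interleaved with ≥ 70% benign thyrocytes;
- **colloid_rich** — ≥ 75% background pixels with 3× elevated background
  signal.

All challenge specimens are labeled malignant; their pixel-mode q3 falls
strictly below that of an adequate malignant specimen under the same model,
reproducing the failure direction of difficult real aspirates.

The noise-free limit (noise, baseline, TIC variation, jitter, and sporadic
peaks all zero) produces identical spectra within each tissue class and a
linearly separable cohort, which the tests verify directly.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: detector physics and peak-shape asymmetry,
isotope structure, chemical noise correlated across m/z, within-class
biological heterogeneity beyond the planted panels, spatial intensity
gradients, and real protein identities. Synthetic results demonstrate that
the pipeline recovers known structure under its own assumptions, not
clinical performance.

## Numerical conventions and degenerate inputs

- Unsorted m/z axes are repaired (stable sort, intensities permuted
  consistently) rather than rejected; duplicate m/z values are an error.
- Intensities are stored as float32 on disk (imzML), float64 in memory;
  round-trips are exact at float32 precision. imzML UUIDs and run ids are
  derived from content/filename so identical runs write identical bytes.
- All-zero spectra raise typed signals (`EmptyPixelError`,
  `InadequateROIError`) that callers convert into masking, never into
  probability-0 scores.
- Quartile, filter, and S/N boundaries are inclusive (≥) throughout.
- Greedy-grouping ties, CV fold shuffling, and saga are all seeded; the
  full pipeline is a pure function of (inputs, config, seed), verified by
  hashing every output byte across repeated runs.

## Problem sizes

Default synthetic runs process roughly 8,000 pixel spectra of 4,000 points
per cohort; a full simulate–train–validate cycle completes in well under a
minute on one core, and the repeated-seed analyses in the acceptance script
in a few minutes. These sizes were chosen so the whole study design —
including the 45 + 36 observation arithmetic and the per-class ROI
statistics — runs at full fidelity on a desk machine.

## Known limitations

- The 7%/28% triage gap is carried over as a configurable default; on data
  from a different instrument or preparation it must be re-estimated.
- Single-linkage alignment can chain peaks across observations if peak
  density approaches the tolerance; the default panel spacing keeps
  clusters well separated, but dense real spectra may need a tighter
  tolerance or a different alignment strategy.
- The model is binary (benign vs malignant); indeterminate cytological
  grades are scored on the same probability axis, not modeled as classes.
- Nonzero-coefficient counts along the λ path are non-increasing for
  well-conditioned designs but can dip at genuine lasso coefficient
  crossings on small correlated designs.
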