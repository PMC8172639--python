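# Methods

## The split-sample design and what the package assumes

The analysis targets experiments in which every culture is divided so that
several measurement methods observe the same underlying biology. A *method*
is a route through three steps — sample preparation (Kn or Cm antibiotic
treatment for live-cell cytometry; FISH or HCR in-situ RNA labeling),
signal detection (flow cytometry or microscopy), and measurand (per-cell
protein fluorescence, RNA fluorescence, or estimated RNA count). The twelve
canonical routes are data, not code: a YAML validity table can redefine the
design. A *sample* is one culture: an inducible construct at one IPTG level
of the series {0, 5, 10, 20, 40, 100, 400, 1000} µmol/L, a constitutive
positive control, or an empty negative control, in one biological replicate.

Inference treats the cells that survive quality control as a random sample
of the culture. The only QC rule implemented is DAPI stainability: cells
with a DAPI signal below half the arithmetic mean of *all* cells of their
(method, sample, replicate) table are excluded. The mean is computed once,
before any exclusion; applying the filter twice with a recomputed mean can
exclude more cells and is deliberately not what the operation does. The
filter applies only where a DAPI column exists (microscopy tables).

## Resolvability (AUC)

`compute_auc(low, high)` is the Mann–Whitney U statistic of the
higher-stimulus sample normalized by n_high·n_low, i.e. the probability
that a random high-stimulus cell exceeds a random low-stimulus cell with
ties counted one half. The midrank tie convention matters because RNA
counts are small integers with many ties. Direction is never folded: values
below 0.5 report resolution in the unexpected direction. Profiles take one
AUC per adjacent level pair (seven for the 8-level series); a missing level
drops the touching pairs (never bridging the gap) and the average AUC is
the unweighted mean of the remaining pairs. The implementation is the
O(n log n) rank route; the test suite keeps an O(n²) brute-force counter as
an independent oracle.

## Dose–response

Each distribution is reduced to its median (robust to the heavy upper tails
of fluorescence data); mean and geometric mean are also reported. The
median's uncertainty is the variance over 1000 bootstrap resamples at the
original sample size. RPU normalization divides the background-subtracted
test median by the background-subtracted constitutive-reference median from
the same method and replicate; its variance follows from the first-order
delta method.

Hill fits minimize Σ wᵢ(yᵢ − offset − A·xᵢⁿ/(K½ⁿ + xᵢⁿ))² with bounds
A ≥ 0, K > 0, 0 < n ≤ 10, offset free. Weights are the inverse bootstrap
variances clamped into [g/10, 10g], where g is the geometric mean of the
finite positive inverse variances of the inducible samples within the
replicate; the clamp prevents a lucky near-zero bootstrap variance from
dominating the fit. Zero stimulus is used as-is (the model is defined at
x = 0); there is no log-x transform. Because the objective is multimodal in
(K, n), the optimizer multi-starts from offset₀ = min(y),
A₀ = max(y) − min(y), K₀ ∈ {geometric mean, min, max of positive x} and
n₀ ∈ {0.5, 1, 2, 4}, keeping the lowest weighted RSS. Exact noiseless data
are recovered to ≲10⁻¹² relative error.

Confidence intervals use the linearized covariance at the solution scaled
by the reduced chi-square, with the t quantile at m − 4 degrees of freedom.
Two choices deserve a note. Scaling by the reduced chi-square (rather than
trusting the bootstrap variances as absolute) is deliberate: median
bootstrap variances underestimate scatter around the fitted curve, and the
scaled covariance adapts to the realized residuals. And the t quantile
rather than z matters at this sample size: with 8 points and 4 parameters,
z-based 95% intervals covered the true K½ and n in only 15/20 seeded
refits, while t-based intervals achieve near-nominal coverage (17–18/20).
Fits that fail from every start return a flagged result, not an exception.

## Bias attribution

Method pairs differing in exactly one step are compared on matched
(replicate, adjacent-pair) AUC cells; ties are excluded (and reported) and
the higher/lower counts get an exact two-sided sign test,
p = min(1, 2·min(P(X ≤ min), P(X ≥ max))) for X ~ Binomial(N, ½), with
p = 1 when no cell is untied. For the measurand step, the default contrast
is protein vs labeled-RNA fluorescence — four pairs in the canonical design;
RNA count is a derived conversion of RNA fluorescence rather than an
independent split, so count-vs-fluorescence pairs are excluded by default
(`measurand_contrast=None` restores the fully general rule, eight pairs).

The Friedman test ranks parameter estimates within each block (replicate,
when method is the primary factor; method, when replicate is) and uses the
tie-corrected statistic

    Q = (k−1) Σⱼ (Rⱼ − n(k+1)/2)² / (Σᵢⱼ rᵢⱼ² − nk(k+1)²/4),

with a chi-square(k−1) p-value by default. Because the study design has
only three blocks, an exact conditional permutation null (all (k!)ⁿ
within-block rankings) is available and used in tests; for the fully
consistent 3×3 ordering the exact p is 6/216 ≈ 0.028 against a chi-square
approximation of 0.0498 — the approximation is genuinely rough at n = 3,
which is why both routes exist. Blocks with missing cells are dropped
listwise with a warning. Implemented in-package (rather than delegating to
scipy's version) because the test must accept k = 2 and offer the exact
null; scipy serves as an oracle in the tests for k ≥ 3 untied data.

The p-value calibration suite checks both tests at sizes where their
approximations are meant to hold (12 treatments × 3 blocks for Friedman;
500 paired cells for the sign test). At the study's own size of 21 paired
cells the exact sign test is discrete and conservative, so its p-values are
*not* uniform under the null there — by construction, not by defect.

## Transcript inference

Counts are fit by maximum likelihood to the standard negative binomial
P(n) = C(n+r−1, n) pʳ(1−p)ⁿ with continuous r > 0; given r the MLE of p is
r/(r + mean), so the likelihood is profiled over log r from the
method-of-moments start p₀ = m/v, r₀ = m²/(v−m). Under-dispersed samples
return a boundary result flagged Poisson-like with r capped at 10⁴.
Zero-count cells are retained — they pass DAPI QC and can be real biology.
Approximate standard errors come from the numerically observed information
matrix at the MLE. Burst frequency is f = r/τ_RNA with τ_RNA = 2.8 min by
default; burst size is b = (1−p)/p. Sample variances use the n−1
denominator throughout, consistently with `fano_factor`.

Binomial thinning (each molecule detected independently with probability
p_m) maps NB(r, p) to NB(r, p′) with (1−p′)/p′ = ε(1−p)/p: r — hence burst
frequency — is invariant, and fitted burst size scales by ε, so the
efficiency correction is b/ε. The closed forms E(Y) = μp,
Var(Y) = μp(1−p) + p²σ², Fano(Y) = 1 + p(σ²/μ − 1) imply that for two
methods differing only in efficiency, mean ratios and (Fano−1) ratios both
equal p_A/p_B. The estimator computes both per matched (sample, replicate)
— the (Fano−1) ratio only when both Fano factors exceed 1, the mean ratio
whenever both means are positive — in log space with percentile bootstrap
95% intervals (1000 resamples of the cells of each table), and reports the
exponentiated median of all available log ratios pooled across both
statistic types, samples and replicates (the median is monotone-invariant,
so log-space vs ratio-space does not change it), plus a bootstrap CI of
that pooled median. Absolute efficiency is the pooled ratio times the
reference efficiency assumed for the reference method (default 0.95).

Spot-intensity histograms from diffraction-limited imaging mix non-specific
and specific populations; `spot_intensity_mixture` fits a two-component
lognormal mixture by EM with component log-medians constrained to either
side of a user-supplied threshold (the threshold is a user input; no
automatic selection is attempted) and reports the specific mixture weight
and the fraction of total intensity carried by the specific component.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, with
defaults fixed once as the study conditions:

- Stimulus series {0, 5, 10, 20, 40, 100, 400, 1000} µmol/L; 3 replicates;
  20 000 cells per flow sample and 500 per microscopy sample (tests and
  examples pass smaller numbers for speed — the structure, not the scale, is
  what downstream code assumes).
- Latent RNA per culture: negative binomial via burst frequency and burst
  size that each follow a Hill curve in effective stimulus — frequency
  offset 0.12 min⁻¹, amplitude 0.9 min⁻¹; size offset 3, amplitude 7; both
  with K½ = 40 µmol/L, n = 1.7; τ_RNA = 2.8 min. These give latent means
  spanning ≈1–30 RNA/cell across the series, the regime of single-transcript
  counting in bacteria. The constitutive control bursts at fixed
  (f, b) = (0.7, 10); the negative control at (0.05, 1.5) to mimic sparse
  non-specific spots.
- Hybridization efficiencies 0.95 (FISH) and 0.341 (HCR), ratio 0.359.
- Protein: Hill (offset 300, amplitude 6000 a.u., K½ = 40, n = 1.7) with
  lognormal cell-to-cell noise of CV 0.35; constitutive level 5000 a.u.
  Hybridization preparations retain only part of the protein signal
  (retention 0.6 FISH, 0.8 HCR) with extra preparation noise, reproducing
  the observation that protein resolvability degrades after hybridization.
- Replicates differ only through stimulus-potency multipliers
  ρ = (0.8, 1.0, 1.25) on the IPTG concentration — the mechanism that shifts
  K½ by 1/ρ while leaving cooperativity and normalized amplitude alone.
- Detections differ by cell number and additive Gaussian background (flow
  mean 100 sd 60; microscopy mean 50 sd 20). RNA fluorescence is thinned
  count × per-transcript brightness (120 a.u., lognormal CV 0.25) +
  background. Microscopy tables carry lognormal DAPI (median 1000,
  σ = 0.25) with a 5% poorly permeabilized fraction at 0.2× median.

The split-sample contract is literal: all methods applied to one culture
share the same latent per-cell counts and protein levels, the two labeling
preparations are independent thinnings of the same latent counts, and
detections take nested subsets of the shared cell pool. Real split samples
contain *different physical cells* whose distributions (not values) are
shared; the generator's stronger per-cell sharing is intentional — it makes
the matched-ratio identities exact targets for testing — but means passing
tests do not exercise the extra sampling noise of disjoint aliquots. Other
things real data have that the generator does not: optics (PSF,
segmentation error), cell-cycle and size structure, RNA–protein per-cell
correlation (off by default; a config flag can couple them), and gating
artifacts. Randomness is one 64-bit seed; every culture and table draws
from a substream keyed by a stable SHA-256 hash of its identity, so adding
methods never perturbs existing tables.

## Pipeline

Stages run in dependency order (QC first; dose–response before bias; burst
fits before efficiency correction). A stage failure is recorded in the
manifest and its dependents are skipped while independent stages still run.
Outputs are plain CSVs plus a JSON manifest with the seed, config hash,
SHA-256 file checksums and machine-readable warnings (dropped blocks,
missing levels, boundary fits); identical config and seed reproduce
byte-identical tables. There is no workflow engine: every stage is an
ordinary library function, and the `brass` CLI is a thin wrapper.

## Known limitations

- The Friedman chi-square p-value is rough at 3 blocks; prefer `exact=True`
  there (feasible up to (k!)ⁿ ≈ 5×10⁵ enumerations).
- Hill CIs are from local linearization; strongly correlated (K, n) pairs
  at weak induction can under-cover even with the t correction.
- The NB boundary handling (r capped at 10⁴) flags rather than models
  under-dispersion; truncated-Poisson alternatives are out of scope.
- The efficiency estimator assumes the two methods differ *only* by
  efficiency; preparation-specific losses that change the latent
  distribution violate the ratio identity and are not detected.
- FCS/TIFF ingestion, segmentation, spot detection and the
  brightness-to-count calibration are out of scope: the package starts from
  pre-gated per-cell event tables.
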