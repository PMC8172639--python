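# brass

Bias and Resolvability Attribution using Split Samples: quantitative
comparison of single-cell and single-transcript measurement methods that are
run in parallel on splits of the same cultures.

When several methods (e.g. flow cytometry vs microscopy, FISH vs HCR RNA
labeling, protein vs RNA measurands) measure aliquots of one culture, the
culture-to-culture variability is shared between methods, so performance
differences can be attributed to individual steps of the measurement
process. `brass` implements the analysis side of that design for an
IPTG-inducible *E. coli* reporter measured over a stimulus series
(0–1000 µmol/L) with constitutive positive and empty negative controls, in
biological triplicate — plus a seeded synthetic experiment generator with the
same statistical structure, so the whole pipeline is testable without
laboratory data.

## What it computes

**Resolvability.** For each method, the AUC between single-cell
distributions at adjacent stimulus levels,

    AUC = P(signal_high > signal_low) + ½ P(signal_high = signal_low),

so 0.5 = complete overlap, 1.0 = complete separation in the expected
direction, 0 = complete separation the wrong way. Seven adjacent-pair AUCs
over the 8-level series form an AUC profile; their mean is the average AUC.

**Relative bias.** Distribution medians (with 1000-iteration bootstrap
variances) are optionally normalized to Relative Promoter Units,
RPU = (S_test − S_neg)/(S_pos − S_neg), and fit to the Hill equation

    Signal = offset + A·xⁿ / (K½ⁿ + xⁿ)

by weighted nonlinear least squares, with inverse-variance weights clamped
within a factor of 10 of their within-replicate geometric mean. Bias across
methods (blocked by replicate) and across replicates (blocked by method) is
tested per Hill parameter with tie-corrected Friedman tests; method pairs
differing in exactly one step (preparation P, detection D, measurand M) are
compared with exact two-sided sign tests on matched AUC cells.

**Single-transcript inference.** RNA-count distributions are fit with a
negative binomial P(n) = C(n+r−1, n) pʳ(1−p)ⁿ (two-state promoter
bursting), giving burst frequency f = r/τ_RNA (τ_RNA = 2.8 min) and burst
size b = (1−p)/p. Under binomial thinning with detection probability p_m
(hybridization efficiency), E(Y) = μp_m and Fano(Y) − 1 = p_m(σ²/μ − 1), so
mean ratios and (Fano−1) ratios of matched split samples both estimate the
efficiency ratio p_A/p_B; the pooled median over both statistic types and
all samples estimates it robustly, and burst size is corrected as b/ε while
frequency needs no correction.

## Worked example

```sh
python examples/05_bursting_and_efficiency.py
```

```
efficiency ratio (HCR:FISH): 0.356 [95% bootstrap CI 0.342, 0.367] from 48 pooled ratios
absolute HCR efficiency at 95% FISH reference: 33.8%

FISH microscopy rna_count @ 1000 umol/L:
  f = 0.991 /min, raw b = 9.96, corrected b = 10.49 transcripts/burst

HCR microscopy rna_count @ 1000 umol/L:
  f = 0.960 /min, raw b = 3.68, corrected b = 10.89 transcripts/burst
```

The two labeling methods observe binomially thinned copies of the same
latent transcripts (simulated efficiencies 0.95 and 0.341). The pooled
median of mean ratios and (Fano−1) ratios recovers their ratio (0.356 ≈
0.341/0.95 = 0.359); raw burst sizes disagree by that factor, while
efficiency-corrected burst sizes agree, and burst frequencies agree without
any correction. The other scripts in `examples/` walk through simulation,
AUC profiles, Hill fitting, and step attribution the same way.

A full pipeline run from the shell:

```sh
brass simulate --seed 1 --out data/
brass analyze --input data/events.csv --seed 1 --out results/
brass report --results results/
```

which writes `auc_profiles.csv`, `auc_summary.csv`, `hill_fits.csv`,
`friedman.csv`, `pairwise.csv`, `burst_fits.csv`, `efficiency.csv` and a
JSON manifest with the seed and config hash.

## Layout

- `src/brass/` — the library: `methods`/`events`/`io` (domain types, CSV
  event tables, QC), `simulate` (synthetic generator), `resolvability`
  (AUC), `dose_response` (medians, RPU, Hill), `comparison` (sign/Friedman
  attribution), `bursting` (negative binomial, thinning, efficiency),
  `pipeline` + `cli` (orchestration).
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — model assumptions, parameter defaults, numerical
  choices and limitations.
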