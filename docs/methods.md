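# Methods

## The monitoring problem and model

`ctmon` targets treatment monitoring with circulating tumour DNA (ctDNA)
in patients whose tumours carry no targetable mutation. The workflow has
two measurement layers and one decision layer:

1. **Baseline discovery (NGS).** A targeted amplicon panel (92 amplicons,
   22 genes) sequences baseline plasma cfDNA. A sample qualifies when its
   mean depth is ≥ 2000× (inclusive). Amplicons are judged by one uniform
   rule — mean coverage across qualified samples below a threshold
   (default 2000×, matching the sample rule, since no separate value is
   established) — and failing amplicons are blacklisted panel-wide. A
   variant is called when it is exonic, reported to COSMIC, not a benign
   SNP, not on a blacklisted amplicon, and its allele frequency
   AF = 100·k/N (variant reads over total position depth) is ≥ 1%.
   The AF is rounded to one decimal before thresholding by default: in the
   packaged fixture several retained rows print as 1.0% while their raw
   coverage ratio is slightly below 1% (e.g. 16/1667 = 0.96%), so the
   rounded comparison is the one that reproduces the published calls. The
   raw comparison is available via `round_before_threshold=False`.

2. **Longitudinal quantification (ddPCR).** Each called mutation gets a
   duplex mutant/wild-type droplet assay. With k of n accepted droplets
   positive and droplet volume v (0.85 nL, the QX200 convention — the
   exact value is configurable), the reaction concentration is
   c = −ln(1 − k/n)/v. Replicate wells are merged by summing counts
   *before* the Poisson step; averaging per-well estimates would be biased
   at low counts. Double-positive droplets count toward both channels.
   Fractional abundance is 100·c_mut/(c_mut + c_wt). Copies per mL plasma
   follow the volume chain: ×reaction volume (20 µL), ÷eluate loaded
   (8 µL), ×elution volume (100 µL), ÷plasma volume (1–2 mL; per-sample).
   Total cfDNA is quantified by the same machinery through a B2M
   reference assay, which is excluded from monitoring.

   Detection limits are empirical: the limit of blank is the smallest
   integer at or above the 95th percentile of blank-well positive counts,
   and the limit of detection is the lowest concentration whose Poisson
   count exceeds the LoB with 95% probability (LoD = ln 20/(v·n) when all
   blanks are zero). A measurement is flagged `below_lod` when its merged
   positive count does not exceed the LoB; the concentration is still
   stored, never nulled.

3. **The non-response rule.** For each mutation detectable at baseline
   (c₀ > 0 and above LoD), per-sample percent change is 100·(c_t − c₀)/c₀,
   with below-LoD follow-ups counted as zero (−100%). A mutation *flags*
   at the earliest pair of consecutive post-baseline draws both at or
   above 2× baseline — a twofold increase confirmed in the immediately
   next successive sample. A patient flags when any mutation does; the
   triggering mutation is the one confirming earliest (ties: higher
   baseline concentration, then lexicographic label). The flag day is the
   confirming draw; lead time is measured from the *first* exceeding draw
   to the first imaging on or after it. The fold threshold (default 2.0,
   i.e. ≥ +100% change — the conventional reading of "twofold or higher
   percentage increase"; the alternative +200% reading is deliberately not
   the default) and the 21-day imaging pairing window are parameters.

## Method agreement

NGS AF and ddPCR fractional abundance are compared on verified pairs only
(FA > 0); a mutation ddPCR cannot re-detect carries no ratio information.
Analysis is on the natural-log scale: the median log-ratio is
back-transformed (for skewed percent data this is the geometric analogue
of the median ratio), Bland–Altman bias is the mean log difference with
limits of agreement ±1.96 sample SD, and OLS regresses AF on FA. On the
packaged fixture 38 of 41 pairs are verified and the recomputed median
ratio from the printed, rounded values is 0.914. The published summary for
the same cohort quotes 0.95 (0.80; 1.11); neither that central value nor
its interval is exactly recoverable from the printed table (the interval
matches neither the min–max of per-pair ratios nor the limits of
agreement), so the package reports both min–max and LoA and asserts
nothing about which the published range denotes.

## The synthetic cohort generator

The generator supplies ground truth for every downstream stage. It
emulates the cohort structure the analysis assumes; defaults are fixed to
that structure and are not fitting knobs:

- 40 patients; sequencing succeeds with probability 0.9; 21/36 of
  sequenced patients have detectable ctDNA; mutation count per detectable
  patient drawn from weights (10, 5, 4, 1, 1)/21 over 1–5 (median 2);
  gene drawn as TP53 20/41, KRAS 13/41, other panel genes 8/41.
- Baseline AF (%) log-normal with median 2.5 and log-SD 1.0, clipped to
  [1, 75] — reproducing a median near 2.5% and a 1–71% range. Baseline
  mutant concentration is AF/100 × a log-normal wild-type background
  (median 6000 copies/mL, log-SD 0.8), so Table-like copies/mL values
  (tens to tens of thousands) emerge.
- Kinetics: c_m(t) = c_m(0)·exp(r_m t) with a shared patient rate —
  uniform in (0.025, 0.06)/day for non-responders, (−0.06, −0.015)/day
  for responders (3/21 of patients) — times a per-mutation jitter
  (relative SD 0.1, sign-preserving). Exponential kinetics with a shared
  rate is the simplest model consistent with roughly monotone per-patient
  trajectories; no published model exists.
- Schedule: draws at day 0 then every 28 days until progression, death or
  308 days; first CT uniform in [63, 77] days, then every 84 days. RECIST
  from the size trajectory: PD at ≥ 20% and ≥ 5 mm above nadir, PR at
  ≤ 70% of baseline, else SD. Tumour size links to total ctDNA burden by
  size(t) = size₀·(B(t)/B(0))^(1/3) — burden proportional to volume, size
  a linear dimension; the exponent is configurable.
- Measurement: droplet wells are multinomial over (mutant-only, wt-only,
  double, negative) with channel probabilities 1 − exp(−c·v), optionally
  inflated by a per-droplet false-positive rate; NGS allele counts are
  binomial at a log-normal depth (median 4000×). Twelve blank wells per
  assay support LoB/LoD estimation. An optional log-normal per-sample
  multiplier (`day_noise_sd`, default 0) models biological day-to-day
  variation, which is unstudied in this setting and therefore off by
  default.
- Reproducibility: one root seed; each patient gets a child stream seeded
  by (root, CRC32(patient id)), so cohorts are identical across runs and
  invariant to patient reordering.

What the generator does **not** emulate: clonal evolution or emerging
resistance mutations, copy-number effects, assay cross-reactivity,
pre-analytical variation (draw-to-spin time, extraction efficiency), or
irregular real-world sampling. Passing tests therefore demonstrate that
the pipeline's logic recovers known truth under its stated measurement
model — not that the workflow's clinical performance transfers to real
cohorts.

## Evaluation designs and problem sizes

- Generator calibration is checked on a 500-patient cohort (mutation-count
  median, gene fractions within ±0.05, AF median in [2.0, 3.0]%).
- The ground-truth-recovery experiment uses 200 patients with kinetics
  separated so |rate|·28 d ≥ ln 4 (every non-responder at least quadruples
  between draws) and no biological noise; the rule applied to the true
  concentration trajectories then attains sensitivity = specificity = 1.0
  by construction, and the experiment verifies the implementation achieves
  exactly that. Metrics are computed over evaluable patients: detectable
  at baseline with at least two post-baseline draws.
- The degradation experiment re-runs the measured (droplet) pathway at
  `day_noise_sd` ∈ {0, 1.5, 3.0} on a cohort with responder fraction 0.5 —
  a balanced stress design chosen so the PPV has enough true negatives to
  be estimable — and checks PPV and sensitivity are non-increasing in
  noise.
- Round-trip unbiasedness uses 200 wells at 50 copies/µL (2% tolerance);
  the Poisson linearisation is checked at occupancy ≤ 1% (1% tolerance).

## Numerical choices and degenerate inputs

- A fully positive well saturates the Poisson estimate; it is flagged
  censored-above with infinite concentration rather than silently clipped.
- Fractional abundance with both channels empty is undefined and surfaces
  as an error (NaN in merged outputs), not as 0 or 100.
- The LoD search solves P[Poisson(λ) > LoB] = confidence by bracketed
  root-finding on the survival function (tolerance 1e-12) and converts
  λ to concentration by λ/(v·n).
- Empty variant sets summarise to zero counts with medians reported as
  undefined rather than NaN arithmetic.
- Kaplan–Meier medians use the product-limit estimator (lifelines) with
  log-log confidence intervals; an all-censored cohort reports the median
  as not reached. Follow-up reverses the event indicator.
- Baseline is the latest draw at day ≤ 0; duplicate days within a patient
  are a validation error.

## Known limitations

- The per-patient volume chain (plasma volume, eluate loaded) is needed to
  re-derive copies/mL from droplet counts; the packaged fixture prints
  only the final concentrations, so its copies/mL column is used as given.
- Whether a confirmed increase may skip a missed intermediate draw is not
  specified in the source procedure; the stricter consecutive-draw reading
  is implemented.
- The RECIST per-organ lesion cap requires organ labels; without them the
  global top-five rule applies.
- The generator's median samples-per-patient is slightly below the
  published median of 4 because simulated non-responders progress at the
  first scan; the published per-patient sampling distribution is not
  available to match exactly.
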