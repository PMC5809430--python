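# Methods

This note documents the models and numerical choices behind
`phageprofiler`: what the synthetic experiment emulates, how each stage
computes what it computes, and where the design was genuinely open.

## The experiment being modelled

A substrate phage display screen displays a random hexapeptide between a
bead-capture tag and the phage body, on every copy of the PIII coat
protein. Protease treatment releases phage whose displayed peptide is
cleavable into the supernatant; sequencing the variable region of the
selected and unselected pools yields per-clone counts whose ratio
carries the cleavage signal. The library is encoded with NNK degenerate
codons (positions 1–2 uniform over A/C/G/T, position 3 uniform over
G/T), which reach all 20 amino acids through 31 sense codons and leave
amber (TAG) as the only in-frame stop available without a third-position
A. Because a stop truncates PIII and kills phage assembly, stop clones
are synthesised (expected in 1 − (31/32)⁶ ≈ 17.3% of inserts) but
essentially absent from displayed phage.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions used throughout the test suite and the acceptance script.

- **Library.** `n_clones` inserts drawn codon-wise from the NNK scheme;
  translation via the standard genetic code (taken from Biopython's
  codon table, never typed by hand). Clone abundances are log-normal
  with `abundance_log_sd = 1.0` by default: real screens report
  per-peptide counts spanning roughly two orders of magnitude, which a
  unit-σ log-normal reproduces; σ = 0 gives exactly uniform abundances.
  Stop-containing clones are retained in the truth record, flagged, and
  given zero display abundance.
- **Cleavage model.** A 6 × 20 position-weight table plus intercept;
  P(cleave) = logistic(b + Σₖ w[k, aaₖ]). The planted default used in
  tests is thrombin-like: +4 on Arg at position 4 over intercept −3,
  i.e. cleavage probabilities 0.73 vs 0.047 (≈ 15-fold contrast).
  With all weights zero the probability is constant and selection is
  provably a no-op after renormalisation.
- **Selection.** One saturating round: selected abundance ∝ input
  abundance × cleavage probability, renormalised. The overnight
  digestion this emulates runs to completion, so no partial-round
  kinetics are modelled; the consequence (shared with the real assay) is
  that rank among strongly cleaved peptides compresses.
- **Sequencing.** Paired 50-bp reads; the forward read is the sense
  strand from amplicon position 0, the reverse read the antisense strand
  from the 3′ end, both spanning the 18-nt variable region.
  Substitution errors only, independent per base and per mate at
  `per_base_error = 0.001` (Illumina error profiles are
  substitution-dominated, and the fixed-length amplicon gives indels no
  role the filters could see). Qualities are drawn uniform on Q30–Q40
  independently of error status by default; an `error_aware` mode emits
  Q0–Q4 at error sites so the quality filter has work to do.
- **Amplicon layout.** The three 8-bp orientation seeds are not
  published constants; they default to the first three 8-mers (offsets
  0/8/16) of a fixed synthetic 26-nt forward flank, and are carried as
  configuration everywhere.

What the generator does **not** emulate: phage amplification and
infectivity bias beyond the abundance skew, PCR chimeras, indels,
position-correlated quality decay, and lane effects. Passing tests
therefore demonstrate that the statistics recover a planted truth under
clean count noise — not that they are robust to every artefact of real
runs.

## Read filtering

Filters run in the order orientation → mate concordance → quality;
a pair failing several filters is tallied under the first, but pass/fail
is order-invariant (tested). Seed matching is exact — the error
tolerance is the redundancy of three seeds, not fuzzy matching. Both
mates' variable-region qualities must satisfy Phred ≥ 5 (the stringent
reading of "each position within the variable coding region"), with +33
encoding. Pairs whose variable region extends past a read end are
rejected and tallied separately as `truncated`; with the default 50-bp
geometry this cannot happen, matching the real runs. Coordinates are
0-based half-open internally; reported positions are 1-based.

The count table records stop-free passed reads; the QC report records
total pairs, per-reason rejections, stop reads and their codon breakdown
(TAG/TAA/TGA), and satisfies the conservation identity
`passed + Σ rejections = total` and `column sum + stop reads = passed`.

## Enrichment statistics

The stage re-implements a DESeq2-style NB Wald pipeline rather than
calling one, so it is self-contained and each step is testable; exact
numerical agreement with any DESeq2 release is not a goal (an
independent cross-check against pydeseq2 on a small table is part of the
test suite: size factors agree exactly, fold changes correlate > 0.95).

- **Min-total filter.** Peptides need ≥ 4 reads summed over all
  selected + unselected samples; the boundary is inclusive. No further
  independent filtering is applied.
- **Size factors.** Median-of-ratios over peptides positive in every
  sample, computed on the log scale (exp of the median log-ratio, the
  canonical form); identical columns get factor 1, a doubled column
  factor 2. If no peptide is positive everywhere the stage falls back to
  total-count ratios with a warning.
- **Dispersions.** Per-peptide method of moments on normalised counts,
  α̂ = max(0, (s²−μ)/μ²), with the variance pooled **within** condition
  so the selection effect does not masquerade as dispersion. A trend
  α(μ) = a/μ + b is fit by non-negative least squares over peptides with
  positive raw estimates, and the final value is the 50/50 blend of raw
  and trend (floor 10⁻⁸). With a single replicate per condition the raw
  estimate is unavailable and the trend (fit across conditions, hence
  signal-inflated) is used alone, with a warning.
- **Wald test.** Two-group NB GLM, log link, log size factors as
  offsets. The group log-mean MLE solves Σⱼ (yⱼ−μⱼ)/(1+αμⱼ) = 0 by
  damped Newton iteration (steps clipped to ±5, coefficients to a
  ±30 log₂ floor/ceiling); the two group parameters are orthogonal, so
  Var(log FC) = 1/I_sel + 1/I_unsel with expected information
  I = Σⱼ μⱼ/(1+αμⱼ). No pseudocounts anywhere: a group at zero runs to
  the coefficient floor while its information vanishes, so the standard
  error grows and the peptide simply fails to reach significance rather
  than producing an infinite fold change. Under a complete null with
  known dispersion the p-values are uniform to KS < 0.02 at 10⁴
  peptides (tested).
- **FDR and labels.** BH step-up (delegated to statsmodels, with NaN
  propagation); cleaved = p_FDR < α and log₂FC > 0, depleted = p_FDR < α
  and log₂FC < 0, else neutral, α = 0.05.

## Motif construction

- **Anchoring.** The generalised tie rule for multi-Arg peptides —
  choose the anchor minimising |pos − 3.5|, ties toward the lower
  position — reproduces the stated 3-over-4 preference and extends
  deterministically to every other configuration. `single_only` mode
  restricts to peptides with exactly one anchor. Frame labels follow
  Schechter–Berger: residue i maps to P(k−i+1) for i ≤ k and P(i−k)′
  for i > k, with per-label denominators in aligned frequency matrices.
- **Differential logo.** Per cell, d = f_cleaved − f_uncleaved and a
  pooled two-proportion z statistic
  z = d/√(f̄(1−f̄)(1/n₁+1/n₂)); calls at the two-sided normal quantile
  (α = 0.05). The two-proportion z is spelled out explicitly because the
  iceLogo-style display it feeds does not fix a formula. Cells with
  fewer than `min_support = 5` counts in **both** pools are called
  unpopulated regardless of z ("does not appreciably populate" is
  qualitative; 5 absolute counts is this package's threshold).
- **Binned profiles.** The enriched (log₂FC > 0) and depleted arms are
  binned separately — the display axis runs from most enriched through
  two significance regimes to most depleted — into one-decade bins of
  log₁₀ p_FDR, merging adjacent bins until each holds more than
  `min_bin = 10` peptides; an arm with too few peptides collapses to a
  single bin. Bins partition their arm exactly once (tested).
- **NNK expectations.** Residue frequency = codons/32 by enumeration;
  the 1/32 amber mass is reported separately so the 20-residue table plus
  stop mass sums to 1.

## Feature ranking

AUROC is the Mann–Whitney statistic (ties ½), computed from midranks.
Forward stepwise selection starts from the intercept, adds the candidate
maximising in-sample AUROC, and stops when the best improvement is below
`tol = 0.001` or at `max_features = 20`. Candidate fits are a batched
Newton/IRLS ridge-logistic solver (all candidates of one step solved in
a single vectorised pass); the ridge λ = 10⁻⁴ on non-intercept terms
bounds coefficients when presence features separate the pools perfectly,
which small cleaved pools routinely do. Evaluation is in-sample — the
analysis this mirrors reports a single AUROC without cross-validation —
and the stopping tolerance is this package's choice since no stopping
rule is stated. Negatives default to a size-matched uniform draw from
neutral peptides, seeded. Coefficient signs mark positive/negative
regulators of recognition.

## Pipeline, determinism, problem sizes

`run_all` executes extract → enrich → motif → classify, aborts with a
stage-tagged error, and is byte-identical across reruns at fixed seeds
(tested). Rank-order reports sort cleaved peptides by ascending p_FDR
with ties broken by |log₂FC| descending, then lexicographically — the
tie rule is fixed here because none is stated anywhere.

Problem sizes used by the test suite and acceptance script are chosen to
exercise every claim at desk scale: 10⁶ read pairs for the
error-suppression bound, a 10⁴-clone / 10⁶-read planted-motif pipeline
run, 10⁴-peptide null simulations, and 50 seeded replicates of the
planted positional-feature recovery. At these sizes the enrichment depth
is ~25 reads per clone per sample, enough to call the planted enriched
peptides but — deliberately — shallow enough that symmetric depletion
calls are rare: depleting a peptide to near-zero selected counts
inflates its Wald standard error, which is the documented zero-handling
behaviour, not a defect. Deeper simulated runs recover depleted calls.

## Known limitations

- Wald inference (no likelihood-ratio fallback), no Cook's-style outlier
  handling, no fold-change shrinkage, two-group designs only.
- The P1–P1′ cleavage site within a hexapeptide is not observed by the
  assay; anchored alignment presumes the anchor residue is P1.
- In-sample AUROC overstates out-of-sample discrimination; a k-fold mode
  exists on the solver but is not the default output.
- The generator's replicates are sequencing draws from a common pool
  (technical replicates); biological replicate variability must be
  injected through the dispersion parameter when simulating counts
  directly.
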