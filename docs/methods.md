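# Methods

## The assay model

`liqbio` models a patient-specific MRD assay: each tracked somatic variant
is amplified in triplicate with replicate-tagged primers, sequenced deeply,
and quantified by exact matching against a wild-type/mutant template pair.
The pipeline's statistical core makes three noise-control moves, in order:

1. **Read-level error suppression** by exact matching. A read counts as WT
   (or MUT) only if it contains the reference (or alternate) allele with at
   least 15 perfectly matching bases on each side, as a contiguous
   substring. A single substitution inside that window discards the read;
   substitutions outside it are irrelevant. This is a match-based filter —
   base qualities are never consulted.
2. **Replicate-level outlier exclusion.** Within a marker's triplicate,
   replicates whose VAF strictly exceeds the triplicate's own
   mean + 1 sample SD are excluded, and the marker VAF is the mean of the
   retained replicates. This targets PCR jackpot artifacts that inflate a
   single replicate.
3. **Marker-level background calibration.** Each marker's limit of
   detection is mean + 3 sample SD of nine background points (three healthy
   donors × triplicate) produced by the same pipeline; a marker VAF
   strictly below its LOD is excluded from the call.

The sample's MRD value is the highest surviving marker VAF; the sample is
positive when MRD ≥ 10⁻⁴ (inclusive). Both boundary conventions are
deliberate and recorded in output provenance: equality with the LOD keeps a
marker ("lower than" excludes), equality with the threshold is positive.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_len` | 140 bp | amplicon template cap; the mutation is centered as far as flanks allow |
| `min_flank` | 15 bp | perfect-match context required each side of the allele |
| `coverage` | 500,000× | reads per amplicon per replicate |
| `sd_multiplier_triplicate` | 1 | replicate exclusion at mean + k·SD |
| `sd_multiplier_lod` | 3 | LOD at control mean + k·SD |
| `n_control_donors` | 3 | donors × 3 replicates = 9 background points |
| `threshold` | 10⁻⁴ | MRD positivity boundary (inclusive) |
| `min_cfdna_ng` / `min_gdna_ng` | 15 / 660 ng | input minima per fraction |
| `max_gdna_ratio` | 1.0 | cfDNA samples with more gDNA than cfDNA fail QC |
| `alt_error_rate` | 10⁻⁵ | count-level post-filter background at the variant position |
| `per_base_error` | 10⁻³ | read-level uniform substitution rate |

All VAFs are dimensionless fractions; sample standard deviations use the
k−1 denominator throughout. Statistics: OLS R² with a two-sided slope test
for paired-fraction correlation; Mann–Whitney U (exact enumeration for
combined n ≤ 12 without ties, tie-corrected normal approximation otherwise)
for group comparison; α = 0.05, two-sided.

## The simulator

The generator has two tiers so that full-coverage behavior and end-to-end
read handling can both be tested at desk scale:

* **Count-level**: one binomial draw per replicate,
  `n_mut ~ Binomial(coverage, p + (1−p)·alt_error_rate)`. `alt_error_rate`
  models the *residual* rate at which a wild-type molecule is read as the
  specific alternate allele after exact-flank filtering has removed most
  raw sequencing error. No published figure exists for this quantity, so
  the 10⁻⁵ default is an assumption, prominently configurable.
* **Read-level**: actual FASTQ records — replicate tag + (mutant template
  with probability `true_vaf`, else wild-type), then uniform per-base
  substitution at `per_base_error` over the whole read. Read IDs encode
  ground truth for test introspection. Quality strings are constant because
  the pipeline is match-based.

The read-level model implies its own residual background: an error at the
variant base converts ref→alt with probability e/3, so the post-filter
conversion rate is `(e/3)(1−e)^(W−1)` for a window of W matched bases.
Recovery tests compare against this closed form rather than the raw
`true_vaf`.

What the simulator does **not** emulate: Ion Torrent homopolymer/indel
error structure, PCR duplicates and jackpots (the triplicate filter's real
target), GC or strand bias, fragment-length variation in cfDNA, and
donor-to-donor background heterogeneity. Passing tests therefore establish
the pipeline's arithmetic and its behavior under binomial sampling plus
uniform substitution noise — not its performance on real Ion Torrent data.

## Numerical and design choices

* **Window containment, not anchored matching**: reads are searched for the
  window as a substring, tolerating staggered read starts; each read is
  also tried reverse-complemented (flag-disableable). Ambiguous reads
  matching both windows are discarded.
* **Demultiplex attribution**: a tag-valid read that matches no template
  window is still attributed to an amplicon when exactly one amplicon's
  standalone 15 bp flank occurs in it (a single window error leaves at
  least one flank intact); it then counts as that amplicon's unclassified
  read. Reads matching nothing or several amplicons are unassigned; read
  totals are conserved across all buckets.
* **Centering tie-break**: for even-length windows two offsets are equally
  central; the window with the smaller genomic start wins. For multi-base
  ref alleles the centering target is the midpoint of the ref span.
* **Triplicate filter edge cases**: undefined VAFs (no classified reads)
  are dropped before statistics; a lone defined replicate is retained
  as-is; zero-variance triplicates are never pruned (strict inequality).
  The exclusion statistic is computed on VAFs, not raw counts.
* **VCF input** is left in anchored form at load; the anchor base is
  stripped (`pos`+1) before any sequence arithmetic.
* **Determinism**: every stochastic step takes a seed or an explicit
  generator; identical config + seed reproduce byte-identical output files.

## Test and acceptance problem sizes

The test suite runs the calibrate-and-call chain at the full 500,000×
coverage (count-level, 200 seeds per VAF grid point) and the read-level
end-to-end chain at 10,000× with 20 seeds per VAF — sizes chosen so the
whole suite completes in well under a minute while keeping Monte Carlo
standard errors far below the asserted tolerances. `scripts/acceptance.py`
uses the same sizes.

## Known limitations

* The measured detection behavior of the calibrated chain: true VAFs of
  3 × 10⁻⁴ and above are called positive in ~100% of simulations, while a
  clone at exactly 10⁻⁴ — the positivity boundary itself — is called in
  only ~70%: with mean + 1 SD replicate pruning and binomial noise at
  500,000×, a marker whose true fraction sits exactly on the threshold
  falls below it in a substantial minority of draws. The acceptance run
  reports the positive-call rate across the whole grid so this boundary
  behavior is visible rather than hidden.
* The triplicate outlier rule fires on ~50% of pure-noise triplicates (an
  order-statistics property of n = 3) and biases the marker VAF slightly
  downward; this conservatism is inherent to the rule, not to its
  implementation.
* One marker's LOD is only as good as its nine control points; batch
  effects between control and patient runs are not modeled.
* Cohort analyses assume one row per patient/timepoint and listwise-delete
  incomplete pairs, reporting the dropped count.
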