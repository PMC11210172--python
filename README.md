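# liqbio

Liquid-biopsy measurable residual disease (MRD) quantification for acute
myeloid leukemia (AML) by triplicate tagged-amplicon deep sequencing.

After induction or consolidation therapy, an AML patient in morphological
remission may still carry a small leukemic clone. `liqbio` tracks
patient-specific somatic variants — chosen from the diagnostic myeloid-panel
profile — in peripheral-blood fractions (plasma cell-free DNA and the
circulating cellular/gDNA fraction) and turns deep amplicon sequencing of
those loci into a single sample-level MRD value with a calibrated limit of
detection.

## Method

For each tracked variant a wild-type/mutant template pair is designed
(≤ 140 bp, mutation centered). Each locus is amplified in triplicate with
replicate-tagged primers (P1/P2/P3) and sequenced to ~500,000× per amplicon.
The pipeline then:

1. **Demultiplexes** reads by exact replicate-tag match and assigns them to
   amplicons by template matching.
2. **Classifies** each read as WT or MUT only if it contains the allele with
   ≥ 15 bp of perfectly matching flank on each side; everything else is
   discarded. The replicate VAF is `n_MUT / (n_MUT + n_WT)`.
3. **Filters triplicates**: replicates whose VAF exceeds the triplicate's own
   mean + 1 SD (sample SD) are excluded as PCR/sequencing jackpots; the
   marker VAF is the mean of the retained replicates.
4. **Gates on the LOD**: each marker's limit of detection is the mean + 3 SD
   of nine background points (three healthy donors × triplicate) run through
   the same pipeline; markers below their LOD are excluded.
5. **Calls MRD**: the sample's MRD value is the highest surviving marker VAF;
   the sample is positive when MRD ≥ 10⁻⁴.

Marker eligibility policies exclude variants that make poor MRD markers
(clonal-hematopoiesis genes such as *DNMT3A/ASXL1/TET2/SRSF2/BCOR*,
pan-myeloid genes such as *JAK2/CALR/MPL/STAG2*, VUS, and specific
preleukemic variants like DNMT3A p.Arg882His). Sample QC enforces the input
minima (15 ng cfDNA, 660 ng gDNA; gDNA/cfDNA contamination ratio ≤ 1).

A two-tier simulator (binomial count-level at full coverage; read-level
FASTQ with per-base noise) makes every stage testable without sequencing
data, and a `cohort` module reproduces the standard cohort analyses (paired
cfDNA-vs-CTC R², Mann–Whitney fraction comparison, concordance with flow
cytometry, marker kinetics and clearance).

## Worked example

`examples/03_calibrate_and_call.py` simulates the assay operating point —
nine healthy-control background points at 500,000×, then a patient sample
with a true tumor fraction of 5 × 10⁻⁴:

```
nine-point control background: mean=1.11e-05, LOD=2.73e-05
replicate VAFs: ['0.000534', '0.000518', '0.000518']
retained replicates (2, 3), marker VAF 0.000518, status detected
MRD value 0.000518 -> POSITIVE (threshold 1e-4)
```

The LOD (~2.7 × 10⁻⁵) is what this marker's background noise allows it to
resolve; the first replicate is pruned by the mean + 1 SD rule; the surviving
marker VAF clears both the LOD and the 10⁻⁴ threshold, so the sample is
MRD-positive. The other scripts in `examples/` cover marker eligibility,
template design + read-level quantification, and cohort reporting. The same
stages are available as a CLI (`liqbio design|simulate|quantify|calibrate|
call|report|run`).

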