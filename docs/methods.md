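# Methods

This note documents the statistical procedures, default parameters and
numerical conventions behind each `tecre` module, what the synthetic
generators do and do not emulate, and the design choices that were genuinely
open.

## Coordinates and interval primitives

All internal coordinates are 0-based half-open. GTF and RepeatMasker `.out`
(both 1-based inclusive on disk) are converted on read; BED writers emit the
internal convention directly. A single convention prevents off-by-one drift
across the pipeline.

`overlap_join(a, b, min_fraction_of_a)` reports pairs with ≥1 bp overlap
whose overlap covers at least the given fraction **of the first argument**
(conventionally the peak). `min_fraction_of_a = 0` is any-overlap mode and
exactly equals the fractional mode at f = 0; passing the repeat annotation
first gives fraction-of-TE instead. The 0.7 setting reproduces a
"70% of the peak inside the repeat" rule.

`closest_distance` measures bp gaps to anchor points (gene 3′ ends by
default). An anchor that lies within **or abuts** the half-open interval
(`pos == end`) is assigned distance 0 — a deliberate, documented deviation
from some bedtools builds that report 1 for abutting features; the rule is
unambiguous and testable. Ties break by smaller anchor coordinate, then
lexicographic id. Queries on chromosomes with no anchor are skipped with a
warning rather than raising, since repeat annotations routinely include
scaffolds absent from gene models.

## Family enrichment (peak sets × repeat families)

For one peak dataset, each repeat family with at least `min_instances`
(default 10) copies is tested with a one-sided Fisher's exact test on

|                    | overlapped by ≥1 peak | not overlapped |
|--------------------|----------------------|----------------|
| family instances   | k                    | n − k          |
| all other TE instances | K − k            | N − n − K + k  |

The counting unit is the **TE instance**, not the peak: family sizes span
orders of magnitude, and instance counting makes folds comparable. The
background is all other annotated TE copies, so the test asks whether the
family attracts peaks beyond the generic repeat background. P-values are
Benjamini–Hochberg adjusted across tested families within the dataset.
Fisher's exact on a hypergeometric table is discrete and therefore
conservative under the null; the null-calibration test checks the realized
family-level positive rate at BH 0.05 stays at or below 0.05.

The per-dataset tables assemble into a families × datasets matrix of
−log10(adjusted p), capped at 300 to avoid infinities; cells for untested or
absent (family, dataset) combinations are 0. A family enters the
"significant" subset when its adjusted p < α (default 0.05, configurable —
the cutoff is a free parameter of the analysis) in at least one dataset.
Downstream: k-means on row vectors (fixed seed, 10 restarts, labels
canonicalized by descending cluster mean), Spearman correlation between
dataset columns (average ranks; a constant column yields NaN, not an
exception), two-factor co-occupancy set algebra, and activity classification
with precedence promoter > enhancer > repressed:

- promoter-like: significant for a promoter mark (H3K4me3) AND the
  designated pioneer factor (TFAP2C role);
- enhancer-like: an enhancer mark (H3K4me1/H3K27ac) AND a coactivator
  (P300/MED1);
- repressed: a repressive mark (H3K9me3) and neither of the above.

Roles are configuration: an empty role disables its rule, a role naming a
dataset absent from the matrix is an error. `shortlist_candidates` keeps
families significant in **all** required datasets with an allowed label and
ranks them by summed −log10(adjusted p), ties broken by family name. An
optional interval mask drops blacklisted peaks before testing.

## Gene-end proximity and CNV burden

Distances run to the strand-aware 3′ terminus (max coordinate on +, min on
−) because the question is whether a repeat sits at a gene end where it
could donate a polyA signal; a TSS mode exists for completeness. The default
proximity threshold is 50 bp. A documentation constant ships for the
chr19:43,203,459–43,802,656 array window; every analysis takes its window as
a parameter.

CNV/SV records are filtered to ≥1000 bp and any overlap with the analysis
region (idempotent). Loss:gain ratios are normalized so the smaller side is
1, one decimal ("12:1", "2.8:1", "1:1.9"); zero denominators print as "L:0".
The burden statistic is the per-sample count of gain records (configurable
to summed gained bp) — the per-sample statistic is not dictated by the data
format, so it is a named option. Group comparison uses Mann–Whitney U,
two-sided: full enumeration of all C(n, n₁) labelings (exact even under
ties, via midranks) for combined n ≤ 16, scipy's normal approximation with
tie correction above. Event counts rather than affected-sample counts are
the default ratio unit.

## PolyA windows, consensus mapping and the paired test

Windows are 200 nt centred on the polyA site, read on the transcript's sense
strand and clipped at sequence ends. Instance-to-consensus mapping is a
global alignment with free end gaps, match +2 / mismatch −2 / gap open −5 /
gap extend −1 (Biopython's PairwiseAligner; ties broken deterministically by
taking the first co-optimal alignment). The scoring was chosen to be fully
specified and parameter-insensitive on substitution-only fixtures, where the
truth alignment is unique. The mapping lists matched/mismatched columns
only; identity below a configurable floor (0.5) flags the mapping
low-confidence without rejecting it.

Hexamer scanning works on the DNA alphabet (AAUAAA → AATAAA; RNA motifs are
transcribed on input) and reports all, including overlapping, occurrences.
The default motif set is the single core hexamer; the 12 common PAS variants
are available as an extended set and reported separately.

The co-occurrence statistic pairs, per instance window, the motif **count**
in the window with the count in the consensus region its alignment covers,
and applies a paired t-test (sd with n−1 denominator, df = n−1). Counts
rather than presence flags keep the statistic well defined when a window
carries multiple signals. Degenerate inputs: all-zero differences return
p = 1 with a warning (no signal anywhere); constant non-zero differences
take the infinite-t limit, p = 0 (signal in every instance, never in the
consensus).

Isoform grouping intersects each transcript's terminal exon (strand-aware)
with the family's copies, ranked proximal → distal along the transcript's
5′→3′ direction; rank labels default to "TE-proximal", "TE-distal" and are
configuration, since group naming conventions vary. A terminal exon
overlapping two copies takes the larger overlap, logged.

## Hydropathy and topology contrast

Profiles are sliding-window means of per-residue scale values (window odd,
default 19; unknown residues score 0). Transmembrane segments are maximal
runs of window-center scores ≥ threshold with at least `min_len` centers,
reported as center-residue spans (disjoint and sorted by construction).
Defaults: Kyte–Doolittle, threshold 1.6, min_len 15 — a classical, fully
specified parameterization; all four knobs are exposed. The negated
Hopp–Woods hydrophilicity scale is available as a cross-check with a
proportionally lower default threshold (1.0; its range tops at 3.4 vs 4.5).
Deep-learning topology prediction is out of scope.

`compare_isoform_topology` requires a shared prefix ≥50% of the shorter
sequence (isoforms of one locus), flags a C-terminal TM when a segment ends
within the final 40 residues, and reports tail lengths past the longest
common prefix.

## Combined TF dosage

Expression matrices are genes × samples on the log2 scale (log2(TPM+1)
preprocessing is provided; the offset is configurable). Each TF is
standardized across samples with the n−1 sample sd; the dosage score is
Z(TF1) + Z(TF2), making the result invariant to affine rescaling of either
TF. Pearson correlations take two-sided p from t = r√((n−2)/(1−r²)) with
df = n−2; |r| = 1 is reported as the p = 0 limit. n comes from the input
matrix — the operation assumes nothing about cohort size. Fisher's combined
probability uses the even-df closed form e^(−X/2)·Σ_{j<k}(X/2)^j/j! with
X = −2Σln pᵢ, verified against the chi-square survival function.

## Oligo specificity

The best ungapped local segment pair between a short query and each target
is found by scanning every diagonal (both target strands) for the
maximal-scoring run under reward +1 / mismatch −3, scores floored at 0. Raw
scores convert to bits = (λS − ln K)/ln 2 with λ = 1.374, K = 0.711 — the
standard ungapped Karlin–Altschul parameters for +1/−3 nucleotide scoring,
the unique common choice under which a perfect 21-nt match yields 42.1 bits
and a 15-nt run 30.2 bits. Reports rank targets by bits (ties by id) and
flag specificity when the top hit clears the runner-up by a configurable
margin (default 5 bits). No E-values: database size is irrelevant to the
within-set comparison, and gapped extension is a non-goal.

## Synthetic fixtures: what they emulate, and what they don't

Every generator is a pure function of (config, seed) — one global seed
expands to per-stage child seeds by fixed offsets — and each fixture ships a
truth table so recovery tests never re-derive ground truth.

- **TE annotation**: non-overlapping copies (uniform sorted-gap placement)
  of each family on a toy genome, uniform strands, lengths 150–450 bp
  (typical LTR-fragment sizes). Default study-scale fixture: 30 families ×
  100 copies on 10 Mb, keeping repeat space well under the 50% cap.
- **Peak sets**: background peaks uniform over the genome; an enriched
  family's footprint has its placement probability multiplied by the stated
  fold and renormalized, so the expected overlapped-instance fraction is
  monotone in fold. Peak widths are truncated-normal around the dataset
  mean (300 bp for TFs, 500 bp for broad marks). Not emulated: chromatin-
  state spatial autocorrelation, peak-width/signal correlation, mappability
  structure — so passing recovery tests demonstrates the statistics, not
  robustness to those artefacts.
- **PolyA instances**: 200-nt slices of a motif-scrubbed consensus at random
  offsets always covering the plant position, i.i.d. substitutions at the
  divergence rate (8% default, typical for a young ERV family), the exact
  hexamer written post-mutation with probability `plant_rate` (default
  12/14, the scaled instance-vs-consensus contrast). Substitution-only
  divergence keeps the truth alignment unique; indels are deliberately
  excluded so consensus-mapping tests have an exact oracle.
- **Expression**: TF latent values i.i.d. standard normal per sample,
  emitted empirically standardized so the pipeline's Z-scores reproduce them
  exactly (and the σ = 0 limit gives r = 1 exactly); target =
  a·Z₁ + b·Z₂ + N(0, σ); other genes pure noise; raw = 2^log2 so the log2
  path recovers the latent scale. With a = b = σ = 1 the population combined
  correlation is √(2/3). Defaults n = 18 samples, a patient-cohort scale.
- **CNV tables**: per-sample Poisson event counts with group-specific
  loss/gain rates, uniform sizes 1–20 kb inside the locus window. The
  burden-power fixture uses 21 vs 76 samples with a 3× gain-rate contrast.
- **Isoform pair**: polar core ending in a short apolar stretch plus a
  25-residue hydrophobic tail on the membrane form only — the minimal
  architecture of an APA-truncated transmembrane anchor.
- **Gene models**: two-exon genes whose 3′ ends are planted inside chosen
  repeat copies (distance 0) or >2.5 kb from any copy.

## Problem sizes

The default test-suite runs use 10 Mb genomes, 3,000 TE copies, 1,500 peaks
per dataset, 20 seeds for Monte-Carlo checks and 200 seeds for the dosage
recovery — sizes at which every planted effect is comfortably detectable and
the full suite completes in well under a minute per stage.

## Known limitations

- Enrichment significance depends on the all-other-TE background choice; a
  peak-shuffling empirical background is available as a cross-check mode
  only in the sense that null peak sets can be simulated and retested.
- The consensus aligner's tie-breaking follows the underlying library's
  deterministic enumeration order; co-optimal alignments can differ from
  other tools' tie rules (irrelevant for substitution-only data).
- Hydropathy topology calling is a classical heuristic; it flags candidate
  anchors, it does not predict topology.
- The CNV burden test treats samples as exchangeable within groups; no
  covariate adjustment.
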