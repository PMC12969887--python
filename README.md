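# tecre

Analysis toolkit for **transposable-element-derived cis-regulatory elements**
at tandemly duplicated gene arrays.

Endogenous retroviruses (ERVs) and other repeats are a recurring source of
regulatory innovation: a long terminal repeat (LTR) carried into a locus can
supply transcription-factor binding platforms (enhancers/promoters), and an
internal retroviral fragment can donate a polyadenylation signal that creates
new transcript isoforms — for instance turning a membrane-anchored protein
into a secreted one by truncating the transmembrane-encoding terminal exon.
`tecre` implements the computational machinery needed to characterize such
events end to end, for genomicists studying repeat co-option at loci like the
primate-specific PSG gene array on chr19q13:

- **Repeat-family enrichment** of ChIP-seq/ATAC-seq peak sets against a
  RepeatMasker annotation: per family, a one-sided Fisher's exact test on the
  2×2 table of TE instances overlapped by ≥1 peak (family vs all-other-TE
  background), Benjamini–Hochberg adjusted within each dataset; the per-family
  −log10(adj. p) matrix across datasets is then clustered (k-means), compared
  between datasets (Spearman), summarized for two-factor co-occupancy, and
  classified into promoter-like / enhancer-like / repressed activity from
  configurable mark rules, yielding a ranked candidate shortlist.
- **TE-to-gene-3′-end proximity**: strand-aware closest-distance of repeat
  copies to gene 3′ termini, with a <50 bp proximity criterion.
- **PolyA cis-element analysis**: 200-bp windows around polyA sites, global
  alignment with free end gaps onto the family consensus (coordinate
  lifting), AAUAAA hexamer scanning (scanned as AATAAA on DNA), and a paired
  t-test of motif counts in instances versus the aligned consensus region.
- **Isoform grouping** by which family copy the terminal exon overlaps, and
  **hydropathy-based topology comparison** (Kyte–Doolittle sliding window,
  transmembrane-segment calling) of membrane vs secreted isoforms.
- **Combined TF dosage**: per-gene Z-scores across samples, the summed
  Z(TF1)+Z(TF2) dosage score Pearson-correlated with a target gene
  (p via t = r√((n−2)/(1−r²))), plus Fisher's combined probability test.
- **Locus CNV burden**: size/region filtering of CNV/SV tables, loss:gain
  ratios in unit form, and a Mann–Whitney U test of per-sample duplication
  burden (exact enumeration for combined n ≤ 16).
- **Oligo specificity**: best ungapped local segment per transcript
  (all-diagonal scan, both strands, +1/−3 scoring) converted to
  Karlin–Altschul bits = (λS − ln K)/ln 2 with the ungapped constants
  λ = 1.374, K = 0.711.

Every stage has a seeded synthetic-fixture generator (`tecre.simulate`) that
plants the structure the stage is meant to recover — per-family peak
enrichment folds, polyA hexamers at known consensus positions, additive
two-TF dosage effects, group-specific CNV rates — together with a truth
table, so the whole pipeline is testable without any downloads.

## Worked example

```python
from tecre.simulate import simulate_te_annotation, simulate_peakset, simulate_expression
from tecre.enrichment import (ActivityRules, build_enrichment_matrix,
                              family_enrichment, shortlist_candidates)
from tecre.dosage import combined_dosage_correlation, fishers_combined

genome = [("chr1", 5_000_000), ("chr2", 5_000_000)]
te, _, _ = simulate_te_annotation(genome, 30, 100, seed=11)

# one family carries 8-fold peak enrichment in two TFs, the pioneer factor
# and the promoter mark
datasets = ("GATA3", "DLX5", "TFAP2C", "H3K4me3")
tables = [
    family_enrichment(
        simulate_peakset(te, genome, name, 1500, {"FAM007": 8.0}, seed=100 + i), te
    )
    for i, name in enumerate(datasets)
]
matrix = build_enrichment_matrix(tables, alpha=0.05)
rules = ActivityRules(promoter_marks=("H3K4me3",), pioneer=("TFAP2C",),
                      enhancer_marks=(), enhancer_coactivators=(),
                      repressive_marks=())
print(shortlist_candidates(matrix, required=("GATA3", "DLX5", "TFAP2C"),
                           allowed_labels=("promoter-like",), rules=rules))

# planted additive dosage effect: target = Z(GATA3) + Z(DLX5) + noise, n = 18
log2, _, _ = simulate_expression(200, 18, a=1.0, b=1.0, sigma=1.0, seed=11)
res = combined_dosage_correlation(log2, "GATA3", "DLX5", "PSG9")
print(f"r_combined = {res['r_combined']:.2f}, p = {res['p_combined']:.2g}")
print(f"Fisher's combined p = {fishers_combined([res['p_tf1'], res['p_tf2']]):.2g}")
```

prints

```
      family       activity      score
rank
1     FAM007  promoter-like  26.997474
r_combined = 0.91, p = 1.3e-07
Fisher's combined p = 7.6e-06
```

The shortlist recovers the planted family at rank 1 with the promoter-like
label (significant for the promoter mark and the pioneer factor), scored by
summed −log10(adjusted p) over the required datasets. The combined dosage
correlation (0.91 here) exceeds each individual TF's correlation, as expected
when the target responds additively to both factors; with a = b = σ = 1 its
population value is √(2/3) ≈ 0.816.

A thin CLI mirrors the library: `tecre simulate`, `tecre enrich`,
`tecre matrix`, `tecre proximity`, `tecre cnv`, `tecre polya`,
`tecre topology`, `tecre dosage`, `tecre oligo` (see `tecre --help`).

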