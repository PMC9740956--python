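# mutcand

Candidate-gene discovery for radiation-induced mutants of allotetraploid
peanut (and similar diploid-simplified designs): a reusable, tested
implementation of the multi-omics analysis that goes from per-sample variant
call sets and an expression count matrix to a short list of candidate genes
that both carry a deleterious ("large-effect") variant and show a concordant
expression change in two independent mutant lines.

## The analysis

The pipeline emulates a WT + two-mutant trio (one wild-type progenitor, two
mutagenised lines) sequenced against a common reference:

1. **Hard filtering** — GATK-style: a record is removed iff any present INFO
   metric violates `QD < 2.0 || FS > 200.0 || SOR > 10.0 ||
   MQRankSum < −12.5 || ReadPosRankSum < −8.0` (strict inequalities).
2. **Normalization and private sets** — variants are atomised (multi-allelic
   split, MNPs decomposed), trimmed and left-aligned; the *private*
   (mutagen-induced) set of a mutant is the keyed difference
   `mutant \ WT` on `(chrom, pos, ref, alt)`.
3. **Consequence annotation** — every variant is placed into one of seven
   genome element classes (coding exon > 5′ UTR > 3′ UTR > intron >
   promoter > terminator > intergenic) and CDS/splice variants get a
   consequence call: splice donor/acceptor (first/last 2 intronic bp), start
   lost, stop gained/lost, frameshift (CDS indel with length change not
   divisible by 3), missense, synonymous — strand-aware. Genes with at least
   one large-effect call form per-mutant gene sets, compared with Venn
   logic.
4. **Structural-variant screen** — per 100-kb window,
   `log10((mut+ε)/(WT+ε))` of the depth of coverage, optionally smoothed;
   sustained runs beyond a threshold (default −0.8, ≥5 windows) flag large
   deletions. 5-Mb variant-density tracks summarise the genomic
   distribution.
5. **Element enrichment** — observed/expected ratios per element class,
   where "expected" is the mean class count of an equal number of uniformly
   drawn control sites over many resamples; plus a hypergeometric term
   over-representation test with BH correction.
6. **Differential expression** — median-of-ratios size factors, FPKM
   filtering (genes with FPKM < 0.1 in all samples removed) and abundance
   categories, then a per-gene negative-binomial likelihood-ratio test
   (gene-wise method-of-moments dispersion, χ², 1 df) with
   Benjamini–Hochberg FDR. DEGs are called at FDR < 0.05 and fold change
   ≥ 2 (or ≤ 0.5).
7. **Integration** — candidate genes = (shared, direction-concordant DEGs of
   both mutants) ∩ (genes with large-effect variants in both mutants),
   reported with full variant and expression evidence. Companion utilities:
   2^−ΔΔCt relative expression and a Mann–Whitney U test (exact by
   enumeration for n₁+n₂ ≤ 12).

Because the real study's numbers derive from deposited resequencing data,
the package ships a first-class **synthetic-data generator** that emulates
the study design with planted ground truth — engineered consequence
variants, planted deletions, and NB-distributed counts (3 replicates/line)
with planted fold changes — so every stage is testable without downloads.

## Worked example

```bash
mutcand run-all --seed 1 --out results/
```

prints the per-stage record counts of a default synthetic run (two 2.5-Mb
chromosomes, 80 genes, 5 planted candidate genes, 5 variant-only and 5
expression-only decoys):

```
variants_raw: {"WT": {"SNP": 259, "INDEL": 41}, "mut1": {"SNP": 393, "INDEL": 67}, ...}
variants_filtered: {"WT": {"SNP": 233, "INDEL": 36}, ...}
private: {"mut1": {"SNP": 119, "INDEL": 24}, "mut2": {"SNP": 120, "INDEL": 22}}
shared_private: {"SNP": 8, "INDEL": 2}
large_effect_genes: {"mut1": {"SNP": 8, "INDEL": 2, "ALL": 10}, ...}
degs: {"mut1": {"up": 5, "down": 5}, "mut2": {"up": 5, "down": 5}}
shared_degs: {"up": 5, "down": 5, "discordant": 0}
sv_flags: {"mut1": 0, "mut2": 0}
candidates: 5
```

Reading it: each mutant carries ~140 private variants surviving the hard
filter; the ten genes with planted large-effect variants are recovered in
both mutants (8 SNP-derived, 2 indel-derived); ten genes are differentially
expressed in both mutants with concordant direction; no spurious deletion is
flagged; and the final report (`results/candidates.tsv`) contains exactly
the five genes satisfying both criteria, e.g.

```
Gene_ID  Chromosome  Physical_Position  Reference  Variation  Effect        log2FC_mut1  Direction_mut1  ...
g0025    A01         1671699            A          G          splice_donor  -3.24        down
g0033    A01         1972599            T          G          missense      -2.96        down
g0046    B01          368875            C          A          stop_gained    3.05        up
```

The same stages are available individually (`mutcand simulate`,
`filter-variants`, `private`, `annotate`, `enrich`, `sv-screen`, `dge`,
`mwu`, `ddct`) and as library functions (`mutcand.build_scenario`,
`mutcand.run_pipeline`, and the per-stage modules).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a synthetic scenario from the given seed, executes the complete
pipeline from scratch — filtering, subtraction, annotation, the coverage
screen, enrichment, differential expression and integration — prints the
per-stage counts together with the reported-vs-planted candidate lists, and
writes the results JSON. The quantitative guarantees (oracle equivalence of
the consequence caller, filter and private-set exactness, screen
sensitivity/specificity, enrichment and DE calibration, end-to-end
planted-truth recovery, exact small-sample statistics) are asserted by
`tests/test_acceptance.py`.

See `docs/methods.md` for the statistical model, parameter defaults, and
known limitations.
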