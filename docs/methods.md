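# Methods

This note documents the models and procedures implemented in `mutcand`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the underlying
workflow left them open.

## Study design being emulated

A wild-type line and two mutagenised derivatives are resequenced against a
shared reference; variants present in a mutant but absent from the wild type
are attributed to mutagenesis ("private" variants). Candidate genes for the
mutant phenotype must satisfy two independent criteria in **both** mutants:
a predicted-deleterious variant in the gene, and a differential expression
change of concordant direction versus the wild type. The two criteria come
from different assays (DNA resequencing and RNA-seq), which is what gives
the intersection its filtering power.

Genotypes are deliberately ignored: planted variants are emitted homozygous
(`1/1`) and set membership is presence/absence of a PASS record, because no
downstream statistic here uses genotype state. The allotetraploid A/B
subgenome structure appears only in chromosome naming ("A01", "B01", ...);
no homoeologous duplication is simulated because nothing downstream depends
on it.

## Variant sets

**Hard filter.** A record is FILTERED iff any *present* INFO metric violates
its strict bound: QD < 2.0, FS > 200.0, SOR > 10.0, MQRankSum < −12.5,
ReadPosRankSum < −8.0. Values exactly at a bound pass. Missing metrics are
not evaluated (real callers omit rank-sum annotations for homozygous
sites). Non-numeric values are a parse error naming the record, never a
silent pass.

**Normalization.** Multi-allelic rows are split and MNPs decomposed to SNPs
before anything else, so set keys are atomic. Each record is then trimmed
(shared suffix, then shared prefix down to a single anchor base) and indels
are left-aligned against the reference until no further shift is possible —
the vt/bcftools-norm algorithm. The test suite checks this against an
independent oracle that derives the leftmost minimal representation directly
from the reference/haplotype string pair.

**Private and shared sets.** Subtraction and intersection operate on
`(chrom, pos, ref, alt)` keys after filtering both sides: a mutant variant
masked only by a *filtered* WT record still counts as private (filtering
precedes subtraction; a config flag can subtract the unfiltered WT set
instead). Position-only keying is available nowhere — the allele is part of
the identity.

## Consequence annotation

Element classes tile the genome: for any base exactly one summary label is
produced, with precedence coding exon > 5′ UTR > 3′ UTR > intron >
promoter > terminator > intergenic when features overlap. Defaults:
promoter = 2000 bp upstream of the TSS, terminator = 2000 bp downstream of
the transcript end (strand-aware, config-exposed; the common convention —
the source workflow never defines the span). Splice sites are the 2 bp of
intron at each boundary (the GT/AG dinucleotides), matching SnpEff's
donor/acceptor definitions. A batch classifier paints a per-base uint8
label array (1 byte/bp; fine at megabase scale) in ascending precedence;
tests assert it agrees with the per-variant classifier everywhere.

Consequences for CDS SNPs are called by codon arithmetic on the annotated
reading frame (reverse-complemented on minus-strand genes): start lost
(initiator codon altered), stop gained (new in-frame stop before the last
codon), stop lost (terminal stop destroyed; a stop-to-stop change counts as
synonymous), else missense/synonymous by translation. CDS indels are
frameshift when the length change is not divisible by 3; in-frame indels
report `none` unless they disrupt the start or stop codon. Indels spanning
an exon–intron junction are classified by their anchored start position and
flagged — full junction-spanning semantics are beyond the resolution of
this analysis. The whole caller is validated against an independent
mutate-and-retranslate oracle (apply the edit to the chromosome, re-extract
and re-translate the CDS) on ≥10⁴ random variants per run, plus a
strand-symmetry property (mirroring the genome changes no call).

The **large-effect** category set defaults to {splice acceptor, splice
donor, start lost, stop gained, stop lost, frameshift}. The integration
stage *additionally* admits missense, because validated candidates in this
kind of study carry plain amino-acid changes; the stricter prose definition
remains the annotation-stage default. Gene-level aggregation takes the most
severe call per gene and reports SNP-derived and indel-derived gene sets
separately.

## Windowed screens

The deletion screen computes `log10((mut + ε)/(WT + ε))` per 100-kb window
with ε = 0.1 (absolute; keeps the log finite on zero-depth windows and
makes a homozygous deletion at 8× depth read ≈ log10(0.1/8.1) ≈ −1.9),
followed by a k = 5 centered moving average (k = 1 disables smoothing; the
original description is ambiguous between a moving average and plain
windows, so both are provided). Flagging takes maximal runs of ≥ `min_run`
consecutive windows beyond the threshold; defaults threshold = −0.8
(≈ copy ratio 0.16, i.e. homozygous loss with margin) and `min_run` = 5
(≥ 500 kb, half the ≥ 1 Mb scale of concern). A positive threshold flags
duplications symmetrically. Heterozygous losses (log10 0.5 ≈ −0.30) are
invisible at the default threshold by design. Variant-density tracks count
private SNPs/indels per 5-Mb window.

## Enrichment

Observed/expected ratios per element class use `n` control positions drawn
uniformly over the assembled genome, classified with the same element
index; "expected" is the mean class count over `n_resamples` draws (default
100 — a single draw gives a noisy denominator; the mean ± sd makes the
ratio's stability visible). Classes with expected 0 report an undefined
ratio, never infinity. Control sites are single points even for indels (no
length-matched null is attempted). The term over-representation test is the
standard hypergeometric upper tail per term on a flat gene→terms map (no
DAG propagation), BH-adjusted, significant at q < 0.05.

## Differential expression

Size factors are DESeq2's median-of-ratios (genes positive in all samples;
factors have geometric mean 1). FPKM = count · 10⁹ / (length · library
size), with gene length = union of exon intervals; genes with FPKM < 0.1 in
*all* samples are removed, and per-sample abundance categories use
left-closed bounds (≥50 very high, 10–50 high, 2–10 moderate, 0.1–2 low).
DE testing runs on the FPKM-filtered universe (config flag to test all).

The NB test per gene: gene-wise method-of-moments dispersion from
within-condition residuals of normalized counts (df = n − 2, floored at
10⁻⁸), then a likelihood-ratio test of separate vs common group means on
the raw counts with size factors as offsets, χ² with 1 df.
log2FC = log2((mean_mut + c)/(mean_WT + c)) with pseudo-mean
c = 0.5/median size factor. DEGs: FDR < 0.05 (strict) and fold change ≥ 2
or ≤ 0.5. Dispersion shrinkage, Cook's-distance filtering and independent
filtering are deliberately **not** reproduced — the analysis depends on
thresholds, not on DESeq2's exact numerics, and acceptance is via
simulation properties.

**Known limitation.** With 3 + 3 replicates the plug-in of a noisy
gene-wise dispersion into the χ² LRT inflates raw p-values (measured
fraction p < 0.05 ≈ 0.11 under the null) — the well-known small-sample
effect that motivates dispersion shrinkage in DESeq2/edgeR. After BH
correction the error rate is controlled (mean fraction of null genes at
FDR < 0.05 ≈ 0.03 ≤ 0.05 over 200 simulations), which is the level at
which DEGs are actually called; power at |log2FC| = 2, baseMean ≥ 500 is
≈ 99% with correct sign. Treat raw p-values from this test as scores, not
calibrated tail probabilities.

BH adjustment is the standard step-up (`min` over larger p of
`p·m/rank`, capped at 1), monotone in the raw p-values; NaNs (untested
genes) pass through and do not count toward m.

## Integration

Candidates = (shared up ∪ shared down DEGs, direction-concordant in both
mutants — discordant genes are excluded, a config flag relaxes to the
union) ∩ (genes with a large-effect variant in *both* mutants' private
sets, missense included). The report lists each qualifying variant with
chromosome, 1-based position, reference/variant alleles and consequence,
plus per-mutant log2FC and direction, ordered by position. DEGs absent from
the annotation are dropped with a warning. 2^−ΔΔCt and the Mann–Whitney U
test (midrank ties; exact two-sided p by enumeration of all C(n₁+n₂, n₁)
rank assignments when n₁+n₂ ≤ 12, else normal approximation with tie and
continuity correction) support the downstream validation workflow.

## Synthetic data: what it does and does not emulate

The generator states the world the tests run in: a WT + two-mutant trio,
~8× depth, 3 replicates per line, NB dispersion 0.05, shared background
variants plus per-sample private ones (10% of background records planted
with a filter-failing INFO value, drawn from guaranteed-failing ranges;
passing records from guaranteed-passing ranges), engineered consequence
variants placed to *guarantee* their category (e.g. an in-frame stop by a
single substitution, a 1-bp CDS insertion that cannot left-shift), and
planted log-normal expression baselines with planted fold changes on
well-expressed genes (baseline 500–1500).

Two generator properties keep the planted truth exactly recoverable, and
are properties of the stated world rather than tuning: background variants
avoid CDS and splice dinucleotides (otherwise a uniform background variant
occasionally creates an unplanned large-effect call and no exact-recovery
test could be written), and all emitted records are pre-normalized so
planted keys survive pipeline normalization unchanged. Gene models are
simple but complete: ≥2 exons, ATG...stop CDS without internal stops,
GT/AG introns, UTRs, both strands, non-overlapping.

The end-to-end scenario plants its expression changes at |log2FC| = 3
(8-fold) rather than the marginal 2 used in the power simulations: the
end-to-end check is a *wiring* test (set algebra, thresholds, report
assembly) and its planted signals are positive controls that must not fail
by sampling accident; per-gene power at |log2FC| = 2 is ≈ 99.5%, which
across 20 seeds × 5 genes × 2 mutants would miss stochastically.

Not emulated: read-level data (FASTQ/BAM), sequencing error, mapping bias,
GC/coverage trends, homoeologous cross-mapping, genotype uncertainty,
dosage–response of the mutation rate (private-variant counts are a free
config parameter, not calibrated to radiation dose), indel length spectra
beyond 1–3 bp, and real annotation databases. A green test therefore
establishes that the *computational* pipeline is correct on its stated
inputs, not that the upstream calling/counting steps of a real experiment
are.

## Reproducibility

Every stochastic component takes an explicit seed and is a pure function of
(config, seed); scenario construction derives per-stage seeds by fixed
offsets. `mutcand run-all` writes a JSON manifest with the config, seed,
package version and per-stage record counts alongside the candidate table
and the planted truth.
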