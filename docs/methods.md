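# Methods

This note documents the models and procedures implemented in `lncreg`, the
parameters that matter, what the synthetic data emulate (and do not), and the
numerical choices made where the design was genuinely open.

## Coordinate and sequence conventions

All genomic coordinates are GTF-style 1-based inclusive; any future BED
export must convert to 0-based half-open at the boundary. Sequences are DNA
over {A,C,G,T,N}; `N` never base-pairs and counts toward lengths. Spliced
transcript sequences are the exon-ordered concatenation, reverse-complemented
on the minus strand. FPKM uses the per-sample total count over all matrix
features as the library size (no external mapped-fragment total exists at
this level): FPKM = count / ((L/10³)(lib/10⁶)).

## Filtering cascade

Known lncRNAs are annotated by sequence similarity to a reference lncRNA
FASTA: exact 11-mer seeds pre-select candidate references, the best
candidate is aligned with an optimal local alignment (match +2, mismatch −3,
gap open 5, gap extend 2), and the E-value follows Karlin–Altschul
E = K·m·n·e^(−λS) with λ = 0.625, K = 0.41 (the ungapped parameters for this
scoring scheme) and n = total reference length. "Known" requires identity
> 90% *and* E < 10⁻¹⁰; a perfect 20-nt match therefore stays a candidate
(S = 40 gives E ≈ 10⁻⁶ at desk-scale database sizes).

Structural filters retain a transcript iff it is not annotated
protein-coding, Σ raw counts over all 18 samples > 10, spliced length
> 200 nt, and ≥ 2 exons. Boundaries are strict (exactly 200 nt or exactly
10 counts is removed); "summarized expression" is the global raw-count sum,
not FPKM and not per-tissue. The retained set is order-independent; only
the recorded removal reason follows the cascade order (protein-coding →
expression → length → exons).

## Coding-potential consensus

Seven scorers, each oriented so higher = more coding-like:

| scorer | feature | notes |
|---|---|---|
| `orf_length` | longest-ORF length (nt) | ORF = ATG..stop inclusive, forward frames only; no stop → runs to the last full codon, flagged incomplete |
| `orf_coverage` | longest ORF / transcript length | |
| `fickett` | TESTCODE statistic | published position/content lookup tables bundled in `_tables.py` |
| `hexamer` | mean ln(coding/noncoding) over in-frame hexamers of the longest-ORF frame | tables estimated at calibration |
| `kmer_spectrum` | logistic over k = 1..5 k-mer frequencies (1364 dims) | weights fit at calibration |
| `triplet_frame` | max-over-frames mean adjacent codon-pair log-odds | matrix estimated at calibration |
| `stop_density` | −(min per-frame stop rate) + 0.3·GC | deliberately crude seventh voter |

Transcripts are scanned in forward frames only because assembled transcripts
are already stranded. Each scorer votes *coding* at or above its threshold;
thresholds sit at the equal-error-rate point of a calibration set of
2000 + 2000 generator transcripts (fixed seed 2022), so individual votes are
a-priori class-symmetric. All estimated artifacts (hexamer tables, k-mer
weights, codon-pair matrix, thresholds) are pure functions of that fixed
seed, recomputed at first use (~15 s) and memoized per process; shipping
them as data files would add ~150 kB of numbers with no reproducibility
gain.

The consensus declares *noncoding* iff ≥ 5 of 7 votes are noncoding
(29 of the 128 possible vote vectors). Consensus-noncoding transcripts then
pass a protein-domain filter: every ORF ≥ 90 nt is translated and scanned
against a bundled PSSM motif library (`data/motifs.tsv`, ~12 domain-flavored
consensus matrices with per-motif thresholds; the file format is documented
and any library can be substituted — the bundled set is a desk-scale
synthetic stand-in for a full domain database, not a copy of one). Any hit
reverts the transcript to coding. The filter applies to *all*
consensus-noncoding candidates. An empty motif library is a configuration
error, never a silent pass.

## Differential expression

Dual confirmation per comparison (E_vs_T, DD_vs_T, E_vs_DD), gene level:

- **Primary, NB Wald.** Median-of-ratios size factors (total-count fallback
  when no feature is everywhere-positive); per-feature method-of-moments
  dispersion pooled within groups, smoothed by a least-squares α(m) = a + b/m
  trend, floored at 10⁻⁸; log2FC on normalized means with pseudo-count 0.5
  (finite for zero groups: log2(100.5/0.5) ≈ 7.65); Wald z from the
  delta-method SE with Var(m̂) = (m + αm²)/n. All-zero features: p = 1,
  log2FC = 0.
- **Secondary, exact Wilcoxon rank-sum** on FPKM (exact null for n ≤ 10
  per group without ties; midranks/normal approximation with ties). With
  6 vs 6 replicates the smallest two-sided p is 2/924 ≈ 0.00216.
- **Calling.** BH adjustment within each comparison (features with non-zero
  total count only), separately per method; DE iff q < 0.01 in both *and*
  |log2FC| > 1.

The conjunction is deliberately conservative: on pure-null simulations the
false-call rate is ~0. Its sensitivity at |log2FC| = 2, base mean ≥ 100,
dispersion 0.1 is ≈ 0.90 (mean over seeds) and is bounded by the exact-test
floor — q < 0.01 after BH is only reachable for features at or near complete
group separation, so dual confirmation at these settings operates at the
edge of what 6 + 6 replicates can certify. At the planted-pair effect sizes
(|log2FC| ≥ 3) sensitivity is ≈ 0.99.

Profile groups: a feature joins X/(rest) iff DE in both comparisons
involving tissue X with consistent sign relative to X. The definitions can
doubly qualify a feature that separates all three tissues; such a feature is
assigned to the group with the larger mean |log2FC| (tie-break T, E, DD), so
groups partition the grouped features. Z-scores are per-feature
(x − mean)/sd with ddof = 1; constant rows map to zeros.

## Relation tiers

Tiers never gate each other; each is tagged with the comparison whose DELs
and DEGs it relates (a DEL and DEG must be significant in the *same*
comparison to be paired).

- **CIS.** Genomic distance between gene spans (not TSSs): 0 on overlap,
  else the base gap; undefined across chromosomes; strict < 100,000 bp
  (exactly 100 kbp is excluded). The sorted-start interval index is
  verified against the all-pairs scan.
- **TRANS.** Pearson r with the two-sided t-test p (df = n−2) across all 18
  samples, |r| > 0.9 and p < 0.05, sign preserved (negative correlations
  count — down-regulated partners are reported). The pipeline correlates
  log2(FPKM+1) because raw-scale Pearson is dominated by the highest-
  expression samples. P-values are not multiplicity-adjusted (the rule is a
  raw p < 0.05); zero-variance profiles are skipped with a warning record.
- **RNA–RNA.** The shorter sequence slides over the reverse of the longer;
  at each antiparallel offset the best contiguous run of paired bases
  (Watson–Crick + G·U) is scored by summing nearest-neighbor stack free
  energies (bundled 37 °C table: 10 unique Watson–Crick stacks expanded by
  symmetry, flat −1.0 / −0.5 kcal/mol terms for single/double wobble
  stacks). No loop or bulge penalties — a deliberate LncTar-style
  simplification that keeps the optimum exactly checkable by exhaustive
  enumeration. Arithmetic is integer centi-kcal so the DP optimum equals the
  brute-force oracle bit for bit. ΔG is the most negative run over all
  offsets; **ndG = ΔG / aligned-overlap length** at the winning offset
  (kcal/mol/nt), threshold strictly < −0.1. Normalizing by the overlap
  rather than the run length is what makes the −0.1 cutoff discriminative:
  any random 2-stack hit would pass a run-normalized threshold, while
  overlap normalization passes planted 60-nt complement windows
  (ndG ≈ −0.15 to −0.25 for 300–900-nt transcripts) and rejects shuffled
  controls (best random runs reach only ndG ≈ −0.05). Minimum overlap
  10 nt; both sequences must be ≥ 10 nt.
- **RNA–protein.** The RNA is encoded as sliding-window (20 nt, step 5)
  composition profiles plus a pairing-propensity proxy (G+C+0.5·T); the
  protein as per-residue hydrogen-bonding, Van der Waals (side-chain
  volume) and helix-propensity profiles (scales in `_tables.py`; unknown
  residue X imputes the scale mean, other letters are rejected). Each
  channel is reduced to its first 8 cosine coefficients; the score is
  σ(rᵀWp + b). W comes from a logistic fit on 250 + 250 fixed-seed
  synthetic pairs (positives drawn from a hydrogen-bond-enriched amino-acid
  composition), followed by a Platt recalibration of the 1-D bilinear score
  — the margin-limited bilinear fit alone leaves clearly-positive pairs
  under-confident relative to the 0.90 probability cutoff. The held-out 40%
  provides the reported AUC and class means. The discriminative signal is
  protein-side composition; the RNA features carry little class information
  in the synthetic design (a known limitation, see below).

Relation accounting collapses duplicate (DEL, DEG, kind, tag) records with
a warning count, reports per-tag × per-kind totals both overall and
restricted to an optional gene-subset list, and classifies each DEG by the
set of relation kinds it appears in. Networks export as SIF
(`del kind deg`) and GraphML with typed nodes and score-attributed edges.

## ΔΔCt validation

Ct is a cycle threshold (one cycle = one doubling), so the geometric mean of
reference *expression levels* equals the arithmetic mean of reference *Ct*
values: ΔCt = Ct_target − mean(reference Cts); ΔΔCt subtracts the
calibrator tissue's mean ΔCt; RQ = 2^(−ΔΔCt). One or many reference assays
are accepted. NGS concordance reports, per lncRNA, the sign agreement of
tissue contrasts and the Pearson r of log2 RQ vs log2 FPKM tissue means.

## The synthetic study

The generator is first-class, tested code; its defaults define the study
conditions and every output is a pure function of (config, seed).

- **Design**: 3 tissues × 6 replicates; 110 coding genes, 30 known + 60
  novel lncRNAs, 9 baits on 3 × 1.6 Mbp chromosomes. Counts are
  gamma-Poisson (NB) with variance m + αm², α = 0.1 (typical bulk RNA-seq
  biological replication; α → 0 recovers Poisson).
- **Classes**: coding transcripts carry a codon-usage-biased ORF of 100–300
  codons between UTRs; lncRNAs are 300–900 nt (typical of assembled lncRNA
  transcripts) with every ORF ≥ 100 nt destroyed by in-frame stop
  insertion; known lncRNAs also appear in the reference FASTA at ~98%
  identity; each bait violates exactly one structural filter (1 exon, or
  ≤ 200 nt, or ≈ 2 total counts).
- **Planted structure**: CIS pairs at an exact 50 kbp span gap; TRANS pairs
  with |log2FC| 5–7 in a designated tissue plus a shared per-sample
  log-normal factor (sd 0.8) — the tissue effect, not the factor, must carry
  most of the correlation, because a factor strong enough to correlate pairs
  on its own would destroy their per-gene DE detectability; duplex pairs
  share an exact 60-nt reverse-complement window (lncRNA window vs mRNA
  3′ UTR), mismatches appearing only in shuffled negative controls;
  protein partners (6 positive, 6 negative) are translated from their
  planted ORFs, positives with hydrogen-bond-enriched composition. All
  planted pair members get |log2FC| 3 (or 5–7 for TRANS) at base mean
  300–2000 so they are callable as DELs/DEGs; ~30% of the remaining genes
  are DE at |log2FC| 2–3.
- **What it does not emulate**: read-level noise (no FASTQ), splice-isoform
  complexity (one transcript per gene, so gene-level DE is exact),
  batch/GC biases, sequencing-depth heterogeneity beyond NB dispersion, and
  realistic intergenic spacing — the genome is gene-dense, so sub-100-kbp
  CIS neighbors and co-tissue TRANS correlations are far more frequent than
  in a real 1 Gbp genome. Passing tests therefore certify the machinery
  (rules applied exactly, planted structure recovered, oracles matched),
  not classifier performance on real transcriptomes.

## Problem sizes and determinism

The default study (209 genes) runs end-to-end in a few minutes on one CPU;
the dominant cost is the all-pairs DEL × DEG duplex scan. Scorer calibration
(one-time per process) adds ~15 s. Identical config + seed reproduce every
TSV/FASTA output byte for byte; the acceptance script derives all its
randomness from `--seed`.

## Known limitations

- The seven scorers are documented stand-ins for the feature families of
  published coding-potential tools, calibrated on generator output; their
  absolute accuracies do not transfer to real transcriptomes without
  recalibration on a real training set (the interfaces accept external
  tables/libraries for exactly that purpose).
- The duplex model ignores loops, bulges and terminal effects; ndG is
  comparable only within this model.
- The RNA–protein scorer's synthetic calibration separates classes by
  protein composition; on real data both sides of the bilinear form would
  need re-estimation from experimentally validated pairs.
- CIS relations use gene-span distance with no promoter orientation logic.
- The dual-confirmation DE rule saturates near sensitivity 0.90 at
  |log2FC| = 2 with 6 + 6 replicates (exact-test floor); stronger effects
  are needed for near-certain detection.
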