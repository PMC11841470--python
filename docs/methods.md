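# Methods

## Scope and data model

`spliceatlas` operates downstream of read alignment, transcript assembly
and quantification. Its inputs are (a) transcript annotations (reference
and assembled) as GFF3/GTF, parsed into exon-chain `TranscriptModel`
objects; (b) a transcripts × samples TPM matrix with a sample→tissue map;
(c) a VCF of candidate SNPs carrying FS/QD INFO annotations; (d) an intron
split-read count matrix with ids `chrom:start:end[:cluster]`. All
coordinates are 1-based closed intervals.

## Transcript cataloging

Assembled transcripts are classified against reference gene spans.
"Overlap" means ≥ 1 bp of genomic-span intersection on the same
chromosome; the label precedence is: ≥ 2 same-strand genes → `fusion`;
exactly one same-strand gene → `reference_match` when the intron chain is
identical to a reference isoform of that gene (single-exon transcripts
require an exact span match, a deliberate proxy for an exact-match
comparison class without reimplementing a full class-code taxonomy),
otherwise `novel_in_gene`; no same-strand but ≥ 1 opposite-strand gene →
`antisense`; no gene → `intergenic`. Opposite-strand genes never
contribute to fusion calls: the antisense rule is applied before fusion
logic becomes meaningful. This ordering is a design choice of the package;
nothing in the classification depends on the order in which reference
genes are supplied. Only `reference_match` and `novel_in_gene`
transcripts flow into expression analyses.

Transcript "length" in the structural summaries is the genomic span
(introns included), which is the scale on which multi-tens-of-kb
transcripts arise; the expressed-transcript threshold defaults to
1 TPM and is configurable.

## Tau tissue specificity

Per-tissue median TPM is computed per transcript (after an optional tissue
merge map for tissues known to be near-identical, e.g. pooling leaf
sub-tissues). Medians below 0.1 TPM are floored to 0 ("not expressed"),
then transformed as log2(TPM + 1). Transcripts whose transformed profile
sums to ≤ 0.1 are not scored (τ undefined); the remainder get

    τ = Σᵢ (1 − xᵢ / max xᵢ) / (n − 1)

on the transformed profile of n tissues, so τ ∈ [0, 1] with 0 for uniform
and 1 for single-tissue expression. Classes are assigned on the *raw*
floored medians, because the thresholds are stated in TPM units: `null`
if the maximum median is < 1 TPM, else `weak` if < 5 TPM, else
`tissue_specific` if τ ≥ 0.85, else `broad`. Both thresholds are
inclusive (≥) and configurable. The TPM gates precede the τ gate, so a
sharply restricted but weakly expressed transcript is `weak`, not
specific. The "maximum expression" gate uses the tissue median (the same
statistic τ is built from), not the single-sample maximum. Unscored
transcripts are reported as `null` with τ = NaN rather than dropped, so
the four classes partition the input; the argmax tissue is tie-broken
lexicographically for deterministic output.

## Transcript–host-gene correlation

Pearson r with a two-sided p-value (t transform, n − 2 df) over aligned
sample vectors; `positive`/`negative` require both p < 0.05 and
|r| > 0.3. No multiple-testing correction is applied by default, matching
the stated per-pair rule; BH-adjusted gating is available as an option.
Zero-variance vectors leave r undefined and are reported `uncorrelated`
with a `degenerate` flag so that catalog-scale runs never abort. When no
independently quantified gene matrix is provided, gene expression is
computed as the sum of the gene's transcript TPM and the output is flagged
(`gene_expr_source='tx_sum'`); note that this fallback induces a positive
bias for genes dominated by one isoform.

## Splicing events and PSI

Events are enumerated per gene from isoform exon structures, following the
event-centric convention of transcript-based AS tools. Splice sites are
compared genomically; A3/A5/AF/AL types are assigned strand-relatively.
The discriminating rules are:

* **SE** — internal exon of one isoform whose two flanking splice sites
  are joined directly by another isoform's intron.
* **RI** — one isoform's exon exactly spans another's intron including
  both flanking exon boundaries.
* **A3/A5** — two introns sharing one splice site with *overlapping*
  alternative exons on the other side (shared donor/alternative acceptor →
  A3; shared acceptor/alternative donor → A5, both in transcription
  orientation).
* **AF/AL** — *non-overlapping* terminal (first/last in transcription
  order) exons splicing into a shared site.
* **AL/AF vs A3/A5 disambiguation** — the overlap and terminal-exon
  requirements make the assignment unambiguous: non-overlapping
  alternative exons that are not terminal produce no event of these types.
* **MX** — two non-overlapping internal exons with both outer flanking
  splice sites shared; no isoform can carry both (a transcript has at most
  one junction per donor site).

Events are deduplicated by a serialized event id
(`gene;TYPE:chrom:coordinate-pairs:strand`), and the inclusion/total
transcript sets collect *every* isoform whose structure is compatible with
a form, not just the pair that defined the event. The inclusion polarity
is a fixed convention — SE: exon-included form; RI: intron-retained; A3/A5:
shorter intron; AF/AL: alternative exon more distal from the shared site;
MX: genomically upstream exon. Any fixed polarity preserves the
complementarity invariant PSI_incl + PSI_excl = 1.

PSI of an event in a sample is Σ TPM(inclusion) / Σ TPM(total), missing
when the denominator is zero; it is invariant under per-sample rescaling
of the TPM column. The retention filter keeps events with PSI strictly
greater than 0.1 in at least ⌈0.05 · N⌉ samples (missing counts as
failing); the 5 % fraction, not any fixed sample count, is the parameter.
Per-type summaries compute PSI variance over non-missing samples only
(imputation would manufacture variance) and rank top-K variable events
deterministically with an event-id tie-break.

## cis-sQTL mapping

Variant sites pass iff they are biallelic, FS < 30, QD > 2, have at least
90 % called genotypes, and minor allele frequency ≥ 0.05 among non-missing
calls; the missingness rule follows the convention of keeping a site whose
called fraction meets the 0.9 bound. The filter is idempotent.

Introns are clustered as connected components of the graph joining introns
that share a donor or acceptor coordinate (per chromosome); singleton
clusters are dropped. Within a cluster, each intron's phenotype is its
excision ratio (count / cluster total, missing where the total is zero);
introns are kept when non-missing and nonzero in ≥ 40 % of samples with
ratio SD > ε (ε = 0.005 by default — "minimal variation" is not
quantified anywhere authoritative, so it is an explicit, configurable
parameter). Kept rows are transformed by a rank-based inverse normal
transform, Φ⁻¹((rank − 0.5)/n) with ties averaged, computed over
non-missing entries.

Covariates are the top principal components of the transformed phenotype
matrix — a deterministic stand-in for Bayesian latent-factor correction,
standard practice when a factor model is not warranted — concatenated with
top genotype PCs for population structure (defaults k = 10 + 10,
configurable, each block truncated at matrix rank with a deterministic
sign convention). Either block can be disabled with k = 0. For each
phenotype row, every SNP within 100 kb of the intron interval (distance to
the nearest edge, 0 inside, symmetric upstream/downstream) is tested by
regressing the phenotype on dosage plus covariates; missing dosages are
mean-imputed per SNP. The implementation residualizes phenotype and
dosage against the covariates once per row and tests the partial
regression slope, which is algebraically identical to the full multiple
regression with n − k − 2 degrees of freedom. Benjamini–Hochberg
q-values are computed over all tested pairs, significance at q < 0.05.

## Enrichment

One-sided hypergeometric overrepresentation: p = P(X ≥ k) for overlap k
between foreground (n of N background genes) and a term annotating K
background genes, BH across terms. The background defaults to whatever
universe the caller supplies (typically all catalog genes or all expressed
genes; both are legitimate and neither is asserted as canonical).

## Synthetic study conditions

The generator's defaults define the conditions under which the pipeline is
validated; none of the published distributions are known, so all
distributional choices are explicit artifact choices:

* **Annotation** — 30 genes on one 2-Mb chromosome, 20 kb apart. The
  first seven genes are fixed designs instantiating exactly one event type
  each (SE, RI, A3, A5, AF, AL, MX), with the A3 and AL designs on the
  minus strand to exercise strand-relative typing; remaining genes carry
  1–3 isoforms built by skipping internal exons. The assembled catalog
  mirrors every reference isoform under new ids and plants one novel
  isoform (a 30-bp splice-site shift), one intergenic, one antisense and
  one two-gene fusion transcript.
* **Expression** — per-transcript log-normal baseline (meanlog 1,
  sdlog 1, heavy-tailed like real TPM), shared across tissues;
  multiplicative log-normal sample noise (sdlog 0.25). Planted
  tissue-restricted transcripts (10 by default) are set to 50 TPM in
  their target tissue and 1000× lower elsewhere — i.e. below the 0.1-TPM
  detection floor, modelling transcripts genuinely silent outside their
  tissue. This contrast is what "tissue-restricted" means here; with the
  0.85 τ threshold, off-target medians must fall below ≈ 0.15 of the
  transformed maximum for recovery, which holds by construction for
  off-silent transcripts but not for mildly enriched ones.
* **Genotypes/introns** — Hardy–Weinberg genotypes at MAF uniform in
  (0.05, 0.5]; causal SNPs fixed at MAF 0.3 within 50 kb of their intron
  cluster. Intron clusters are two introns sharing a donor; the latent
  excision ratio follows logit(p) = logit(p₀) + β·dosage + N(0, σ) with
  σ = 1 and β in units of σ, realized as a binomial draw at 200
  reads/cluster/sample, preserving the compositional structure of
  split-read phenotypes.

Everything is driven by one `numpy` generator seeded from
`SimulationConfig.seed` via separate named substreams, so identical
configs give byte-identical output files.

**What the synthetic data does not emulate:** read-level artifacts,
mapping bias, assembly fragmentation and redundant isoforms, linkage
disequilibrium between SNPs, correlated library-depth effects, batch
structure across studies, and realistic per-type event abundances (the
relative frequency of A3 vs RI etc. is a property of the genome and
annotation quality, and is deliberately not a target). Passing tests
therefore demonstrate algorithmic correctness and statistical calibration
under clean conditions, not robustness to real-data pathologies.

## Validation problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run at desk scale: the default
atlas (30 genes, 8 tissues × 10 samples), sQTL power over replicates of
n = 200 samples with one planted 1-SD effect at MAF 0.3, and null
calibration over replicates of 500 SNP–intron tests with no planted
effect, pooling 10,000–25,000 p-values. In those runs the
latent-factor-style phenotype-PC block is disabled (k_pheno = 0, genotype
PCs k = 2): with only ~20 phenotype rows, the top phenotype PCs align
with individual clusters and would absorb the very signal being planted —
a small-dimension regime that does not arise at the scale such covariates
are designed for.

Other numerical conventions: the Tau sum filter boundary is ≤ 0.1
(strictly greater passes); PSI filtering uses strict > 0.1 and a ceiling
on the sample count; BH q-values come from the standard step-up; PCA signs
are fixed by making the largest-magnitude loading positive; all argmax
tie-breaks are lexicographic.

## Known limitations

* Event enumeration is pairwise-complete but not exhaustive over complex
  nested structures (e.g. a three-way alternative acceptor yields the
  three pairwise A3 events, not one ternary event) — consistent with
  event-centric AS tools.
* `reference_match` requires exact intron-chain identity; near-matches
  with one shifted splice site are `novel_in_gene`.
* FDR control is BH over nominal p-values; a permutation-based per-
  phenotype scheme (as in beta-approximation QTL mappers) is out of scope.
* The transcript-sum gene-expression fallback biases correlations upward
  for genes with few isoforms; supply an independently quantified gene
  matrix where available.
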