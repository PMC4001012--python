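# Methods

## Scope and data model

`epidiff` quantifies between-population variation of a curated gene panel
from diploid SNP genotypes. Genotypes are allele-A dosages (0/1/2 copies,
or missing) in a samples × variants matrix with a population label per
sample; transcripts are 1-based inclusive spans with sorted non-overlapping
exons and optional UTR intervals. Allele A is the VCF REF allele by
default — chip manifests rarely document how their A/B alleles map to the
reference, so the package fixes a convention rather than guessing one; for
PLINK-style text tables the file's own A-allele column is taken as allele
A. Every statistic here is invariant to (abs differences, IBS, the gene
metric) or equivariant under (pA → 1 − pA) swapping the allele labels, so
the convention never changes a ranking or a p-value.

## SNP-to-transcript annotation

Each SNP is paired with at most one transcript: the one minimising the
distance (0 inside the span, otherwise the gap to the nearer span edge),
accepted when that minimum is ≤ 3000 bp ("within 3 kb" read as inclusive,
so distance 3000 qualifies and 3001 does not). Ties are broken by smaller
span, then lexicographic transcript id — a deterministic rule that keeps
SNP–transcript pairs unique even for overlapping transcripts. Positional
classes:

* **CAT1** — in an exon or UTR, or in the splice-region window;
* **CAT2** — intronic, outside the splice-region window;
* **CAT3** — outside the span within the flank, labelled up-/downstream by
  strand.

The splice-region window follows the Ensembl consequence convention
(1–8 bp into the intron from an exon junction; last 3 exonic bases at a
junction); transcript ends are not junctions. Intron-side splice-region
SNPs are counted as transcribed (CAT1) because a splice-region variant is
part of the processed transcript's functional context. UTR classification
requires UTR intervals in the GTF; without them such SNPs report the
`exon` detail, which does not affect the category.

Category summaries count, per gene-category letter a–i, the distinct
transcripts carrying ≥ 1 assigned SNP and the SNPs per CAT. The packaged
reference table (`epidiff/data/epigenetic_category_counts.tsv`) is a
nine-category screen of epigenetic-machinery genes on a bovine
high-density chip (193 transcripts; 113/2738/240 SNPs in CAT1/2/3);
`expand_category_counts` inverts it into a concrete annotation set so the
aggregation path can be exercised end-to-end.

## Frequencies and enrichment

Per population and variant, p0/p1/p2 are the fractions of
homozygous-A/heterozygous/homozygous-B among non-missing calls and
pA = p0 + p1/2; a variant with zero calls in a population is undefined
there and excluded (with a log entry) from differences and densities.
Differences use strict `>` against the divergence threshold (default 0.3).
Density summaries are unit-area histograms (default 20 bins); no kernel
smoothing is applied — smoothing is cosmetic and would add a bandwidth
parameter with no inferential content.

Enrichment uses the one-sided hypergeometric upper tail
P(X ≥ k), X ~ Hypergeom(N, K, n), including the observed k — the standard
over-representation convention; a lower-tail variant covers
"conservation" questions. N is all variants with defined differences.
Raw p-values are reported (flagged at p < 0.05); a Benjamini–Hochberg
helper is available but off by default, matching the single-hypothesis
framing of each labelled test. Chromosome-level tests treat the decile as
the drawn sample: N ranked genes, K on the chromosome, n in the decile,
k both.

## Gene-differentiation metric

For each transcript (optionally collapsed to gene level by pooling SNPs)
the genotypic frequencies of its assigned SNPs — all CATs pooled, since
intronic and flanking variation is equally informative about local
differentiation — are averaged per population, and

    d = (Δmean p0)² + (Δmean p1)² + (Δmean p2)²

is the squared Euclidean distance between the two mean profiles, bounded
by [0, 2] with the maximum at opposite fixed homozygotes. The squared form
is the primary definition; a `rooted` switch returns the Euclidean root.
Rankings and decile membership are invariant under this monotone
transform, which the test suite asserts. Deciles take ⌊decile · n⌋ genes
(minimum 1) from each end of the descending ranking, ties broken by gene
id for reproducibility.

## IBS distances and classical MDS

The pairwise distance is 1 minus mean allele sharing,
(2 − |dᵢ − dⱼ|)/2 per SNP, over the pairwise-complete SNP set (a pair with
no shared called SNP is an error). Classical (Torgerson) MDS
double-centres the squared-distance matrix, B = −½ J D² J, and returns the
top-k eigenvectors scaled by √eigenvalue; negative eigenvalues — possible
because IBS distances need not be Euclidean — are clamped to zero with a
warning. Since an MDS axis has arbitrary sign, embeddings are compared by
the squared Pearson correlation of their first components. The
random-subset null draws its subsets from the entire variant panel
(reference subset included), matching a "random markers from the whole
chip" design, and reports per-run r², their mean and minimum, and the r²
against the sign-aligned run-average component (the two readings of
"average over runs").

## The simulator

The generator emulates a two-breed chip study: two populations of
`n_per_population` diploids at `n_snps` unlinked biallelic SNPs on
`n_chromosomes` chromosomes. Per SNP, an ancestral frequency
p ~ U(0.05, 0.95) and independent per-population frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F), so F is the expected FST; dosages are
Binomial(2, p_pop). Target genes (2–5 exons, 4–15 kb, spaced ≥ 8 kb apart
so nearest-transcript assignment is unambiguous) carry `snps_per_gene`
SNPs inside the span and `flank_snps_per_gene` within 3 kb; background
SNPs avoid gene ± 3.5 kb so the planted truth stays clean. Categories a–i
are assigned round-robin.

Divergence is planted per gene, not per SNP: SNPs in or near a divergent
gene use `fst_divergent`, and — because independent Balding–Nichols draws
have random Δp signs that cancel under gene-level averaging — each
divergent gene picks a favoured population and its per-SNP frequency pairs
are oriented toward it. This is a deliberately cheap surrogate for
directional selection on a linked haplotype; the swap is symmetric in the
two frequencies, so per-SNP FST is untouched. When
`fst_divergent == fst_background` no orientation is applied and nothing is
planted. Defaults (250/population, 20,000 SNPs, background FST 0.15,
40 target genes of which 4 divergent at FST 0.4) are the study conditions
the test suite runs under; 0.15 is a realistic between-breed FST for
diverged cattle populations and 0.4 makes planted-gene recovery a sharp,
non-trivial target.

What the simulator does **not** model: linkage disequilibrium and
haplotype structure, ascertainment bias of chip SNPs, genotyping or
imputation error, and family structure within populations. Passing tests
therefore demonstrate correctness of the statistical machinery under an
idealised exchangeable-individuals model, not robustness to those
real-data features; in particular the MDS r² null band would widen under
strong LD (fewer effective markers per subset).

`realized_fst` is the Hudson ratio-of-averages estimator on sample allele
frequencies, Σ(p₁−p₂)² / Σ[p₁(1−p₂)+p₂(1−p₁)], without a finite-sample
correction term: the uncorrected form returns exactly 0 for identical
frequency vectors and exactly 1 for fixed opposite homozygotes, and its
bias at the default sizes (~+0.002 at n = 250, F = 0.15) is an order of
magnitude below the ±0.02 calibration band the generator is held to.

## Numerical and reproducibility choices

* One top-level seed per simulation/pipeline run; per-stage generators are
  spawned deterministically (`numpy` `SeedSequence`), and the pipeline
  manifest records the seed, parameter values and input SHA-256 checksums.
  Identical config + seed ⇒ byte-identical output bundles.
* Genotypic frequency triples sum to 1 to 1e-12 by construction; profile
  means inherit this exactly (unweighted arithmetic means).
* Hypergeometric tails are delegated to `scipy.stats.hypergeom` (log-space
  internals); the suite pins them to an exact combinatorial enumeration to
  1e-12 for all N ≤ 20.
* Eigendecomposition uses `numpy.linalg.eigh` on the symmetrised
  double-centred matrix; eigenvalue order is enforced explicitly.
* Degenerate inputs are contracts, not silent fallbacks: empty subsets,
  all-missing populations, k ≥ n MDS requests, constant components and
  unlabelled samples raise with specific messages.

## Problem sizes in the test suite

The suite exercises the study conditions directly: the MDS null check runs
the full 2 × 250 × 20,000 design; planted-gene recovery runs ten replicate
seeds of the 40-gene design at 1,000 SNPs (the gene-linked SNPs plus
background); oracle checks (annotation brute force, hypergeometric
enumeration, MDS Procrustes recovery) run on small exhaustively checkable
instances. The whole suite completes in well under a minute on one CPU.

## Known limitations

* Transcript-level versus gene-level reporting is a flag, not an
  inference; with transcript-level gene lists, transcripts of one gene are
  ranked independently (their metrics can differ sharply, which is a real
  feature of redundant gene families, not an artefact).
* The MDS null is a resampling comparison, not a formal test; no p-value
  is attached to r².
* BCF and binary PLINK (bed/bim/fam) are out of scope; inputs are VCF or
  the package's text dosage table.
* Multi-allelic sites are rejected rather than decomposed.
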