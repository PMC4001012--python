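# epidiff

Population-genetic differentiation of a target gene panel between two
populations, from SNP-chip genotypes.

`epidiff` is built for the common study design in which two labelled
populations (e.g. two livestock breeds) are genotyped on a dense SNP panel
and the question is whether a curated panel of genes — here, genes of the
epigenetic machinery (DNA methyltransferases, histone modifiers, chromatin
remodellers, …) — carries more between-population variation than the genome
at large. It provides, as a tested library plus a thin CLI:

* **SNP-to-transcript annotation** — each SNP is paired with its single
  nearest target transcript, provided it falls inside the transcript or
  within a 3 kb flank, and classified as **CAT1** (transcribed: exon,
  splice region, UTR), **CAT2** (intronic) or **CAT3** (up/downstream
  flanking), with per-category summary tables.
* **Per-population frequencies** — genotypic frequencies (p0, p1, p2) =
  (homozygous A, heterozygous, homozygous B) fractions, the allele-A
  frequency pA = p0 + p1/2, between-population differences
  Δ = pA⁽¹⁾ − pA⁽²⁾, and binned density summaries.
* **Gene-differentiation metric** — per gene, the genotypic frequencies of
  its SNPs are averaged within each population and compared by the squared
  Euclidean distance

  d(g) = (Δp̄0)² + (Δp̄1)² + (Δp̄2)²  ∈ [0, 2],

  with descending ranking and top/bottom-decile flags.
* **Hypergeometric enrichment** — one-sided over-representation tests:
  are SNPs with |Δ| > 0.3 over-represented in the target SNP set (overall,
  per CAT, per gene category), and are top-decile genes concentrated on
  particular chromosomes?
* **Population structure** — identity-by-state distances, classical
  (Torgerson) MDS, and a random-subset null: the leading MDS axis of a
  designated SNP subset is compared (squared Pearson r² of component 1)
  against 10 runs of equally many randomly drawn SNPs.
* **A two-population simulator** — Balding–Nichols allele frequencies with
  configurable background FST, planted strongly divergent genes, a
  multi-chromosome genome with multi-exon transcripts and a
  category-labelled gene list, so the whole pipeline is exercisable and
  testable without any external data.

## Worked example

```python
import epidiff as ed
from epidiff.simulate import SimulationConfig, simulate_dataset, realized_fst

cfg = SimulationConfig(
    n_per_population=250, n_snps=2000, n_chromosomes=5,
    n_target_genes=40, n_divergent_genes=4,
    fst_background=0.05, fst_divergent=0.4, seed=7,
)
dataset, transcripts, gene_list, truth = simulate_dataset(cfg)
print("realized FST:", round(realized_fst(dataset), 3))

annotations = ed.assign_snps(dataset.variants, transcripts)
freqs = ed.compute_frequencies(dataset)
diffs = ed.frequency_differences(freqs)
res = ed.divergent_snp_enrichment(diffs, {a.variant_id for a in annotations})
print(f"divergent-SNP enrichment: k={res.k}/{res.n} vs K={res.K}/{res.N}, "
      f"ratio={res.enrichment_ratio:.2f}, p={res.p_value:.3g}")

ranked = ed.rank_genes(ed.diff_records(ed.gene_profiles(annotations, freqs)))
print("top decile:", [(r.gene_id, round(r.metric, 3))
                      for r in ranked if r.top_decile])
print("planted   :", sorted(truth.divergent_gene_ids))
```

prints

```
realized FST: 0.063
divergent-SNP enrichment: k=35/480 vs K=94/2000, ratio=1.55, p=0.00227
top decile: [('gene007.t1', 0.211), ('gene026.t1', 0.176), ('gene034.t1', 0.169), ('gene004.t1', 0.137)]
planted   : ['gene004', 'gene007', 'gene026', 'gene034']
```

The simulated genome-wide Hudson FST is close to the configured background
(slightly above 0.05 because of the four planted genes). Gene-linked SNPs
are enriched for strong frequency differences (35 of 480 exceed |Δ| > 0.3
versus 94 of 2000 genome-wide, a 1.55-fold excess, hypergeometric
p ≈ 0.002), and the four genes planted at FST 0.4 are exactly the four
genes in the top decile of the gene-differentiation ranking.

The same analysis runs from the shell against VCF/GTF/TSV inputs:

```sh
epidiff simulate --seed 7 --out data/
epidiff run-all --config pipeline.yaml     # simulate/load → annotate →
                                           # freqs → genediff → enrich → mds
```

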