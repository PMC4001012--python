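"""Two-population diploid genotype simulator with planted divergent genes.

The generator emulates the design of a two-breed SNP-chip study: two diverged
populations genotyped at many unlinked biallelic SNPs on a multi-chromosome
genome carrying a panel of category-labelled target genes.  Per-SNP allele
frequencies follow the Balding-Nichols model: an ancestral frequency
``p ~ Uniform(0.05, 0.95)`` and, independently in each population,

    p_pop ~ Beta(p (1 - F) / F,  (1 - p) (1 - F) / F)

so that E[p_pop] = p and Var[p_pop] = F p (1 - p), i.e. ``F`` is the
expected FST between the populations.  SNPs inside or within 3 kb of a
planted "divergent" gene use ``fst_divergent``; all other SNPs use
``fst_background``.  Diploid dosages are drawn Binomial(2, p_pop) per
sample — no linkage disequilibrium is simulated.

Everything is reproducible from a single seed; per-stage generators are
spawned deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset, TranscriptModel, VariantRecord
from . import io as eio

#: flank width (bp) within which a SNP is attributable to a gene
GENE_FLANK = 3000

_NUCS = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Simulation configuration is infeasible."""


@dataclass
class SimulationConfig:
    """Parameters of the two-population simulation.

    Defaults follow the study design the package is exercised against:
    two populations of 250 diploids at 20,000 SNPs with background
    FST 0.15, a 40-gene target panel of which 4 genes are strongly
    divergent (FST 0.4) with 10 SNPs inside each gene plus 2 in its 3-kb
    flanks.
    """

    n_per_population: int = 250
    n_chromosomes: int = 10
    chromosome_length: int = 2_000_000
    n_snps: int = 20_000
    fst_background: float = 0.15
    fst_divergent: float = 0.4
    n_target_genes: int = 40
    n_divergent_genes: int = 4
    snps_per_gene: int = 10
    flank_snps_per_gene: int = 2
    missing_rate: float = 0.0
    population_labels: tuple[str, str] = ("pop1", "pop2")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fst_background", "fst_divergent"):
            f = getattr(self, name)
            if not 0.0 < f < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {f}")
        if self.fst_divergent < self.fst_background:
            raise ConfigError("fst_divergent must be >= fst_background")
        if self.n_divergent_genes > self.n_target_genes:
            raise ConfigError("n_divergent_genes exceeds n_target_genes")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        gene_snps = self.n_target_genes * (self.snps_per_gene + self.flank_snps_per_gene)
        if self.n_snps < gene_snps:
            raise ConfigError(
                f"n_snps={self.n_snps} too small to cover {self.n_target_genes} genes "
                f"({gene_snps} gene-linked SNPs requested)"
            )
        if len(set(self.population_labels)) != 2:
            raise ConfigError("population_labels must be two distinct labels")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset.

    ``per_snp_population_freqs`` has one row per variant with the true
    allele-A frequency in each population, the FST used at that SNP and the
    gene it was planted in (empty string for background SNPs).
    """

    divergent_gene_ids: set[str]
    per_snp_population_freqs: pd.DataFrame


@dataclass
class _PlannedSnp:
    chrom: int
    position: int
    gene: TranscriptModel | None
    divergent: bool


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeDataset, list[TranscriptModel], dict[str, str], SimulationTruth]:
    """Simulate genotypes, a toy annotation and a target-gene list.

    Returns
    -------
    dataset : GenotypeDataset
    transcripts : list of TranscriptModel
        One transcript per target gene, 2-5 exons, non-overlapping, spaced
        far enough apart that nearest-transcript assignment is unambiguous.
    gene_list : dict
        transcript_id -> epigenetic category letter (a-i, round-robin).
    truth : SimulationTruth
    """
    ss = np.random.SeedSequence(config.seed)
    rng_layout, rng_freq, rng_geno, rng_missing = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    transcripts, divergent_ids = _plan_genome(config, rng_layout)
    snps = _plan_snps(config, transcripts, divergent_ids, rng_layout)

    m = len(snps)
    fst = np.where(
        [s.divergent for s in snps], config.fst_divergent, config.fst_background
    )
    p_anc = rng_freq.uniform(0.05, 0.95, size=m)
    shape = (1.0 - fst) / fst
    p_pop = np.stack(
        [rng_freq.beta(p_anc * shape, (1.0 - p_anc) * shape) for _ in range(2)]
    )  # 2 x m true allele-A frequencies
    if config.fst_divergent > config.fst_background:
        # degenerate configs (equal F) plant nothing, by design
        _orient_divergent_genes(snps, p_pop, divergent_ids, rng_freq)

    lab1, lab2 = config.population_labels
    n = config.n_per_population
    calls = np.concatenate(
        [
            rng_geno.binomial(2, p_pop[0], size=(n, m)),
            rng_geno.binomial(2, p_pop[1], size=(n, m)),
        ]
    ).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng_missing.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    width = len(str(m))
    variants = []
    for j, s in enumerate(snps):
        a, b = rng_freq.choice(4, size=2, replace=False)
        variants.append(
            VariantRecord(
                variant_id=f"snp{j + 1:0{width}d}",
                chromosome=f"chr{s.chrom + 1}",
                position=int(s.position),
                allele_A=str(_NUCS[a]),
                allele_B=str(_NUCS[b]),
            )
        )

    sample_ids = [f"{lab1}_{i + 1:04d}" for i in range(n)] + [
        f"{lab2}_{i + 1:04d}" for i in range(n)
    ]
    population_of = {s: (lab1 if i < n else lab2) for i, s in enumerate(sample_ids)}
    dataset = GenotypeDataset(variants, sample_ids, population_of, calls)

    gene_list = {
        t.transcript_id: eio.CATEGORY_LETTERS[i % len(eio.CATEGORY_LETTERS)]
        for i, t in enumerate(transcripts)
    }
    truth = SimulationTruth(
        divergent_gene_ids=divergent_ids,
        per_snp_population_freqs=pd.DataFrame(
            {
                "variant_id": [v.variant_id for v in variants],
                "chromosome": [v.chromosome for v in variants],
                "position": [v.position for v in variants],
                "gene_id": [s.gene.gene_id if s.gene else "" for s in snps],
                "fst": fst,
                lab1: p_pop[0],
                lab2: p_pop[1],
            }
        ),
    )
    return dataset, transcripts, gene_list, truth


def _orient_divergent_genes(
    snps: list["_PlannedSnp"],
    p_pop: np.ndarray,
    divergent_ids: set[str],
    rng: np.random.Generator,
) -> None:
    """Make each divergent gene's SNPs diverge coherently.

    Independent per-SNP Balding-Nichols draws have random Delta-p signs, so
    averaging over a gene's SNPs would cancel the planted divergence.  Each
    divergent gene therefore picks a favoured population and its SNPs'
    frequency pairs are swapped to point the allele-A excess that way — a
    cheap surrogate for directional selection on a linked haplotype.  The
    swap is symmetric in the two frequencies, so per-SNP FST is unchanged.
    """
    cols: dict[str, list[int]] = {}
    for j, s in enumerate(snps):
        if s.divergent and s.gene is not None:
            cols.setdefault(s.gene.gene_id, []).append(j)
    for gid in sorted(divergent_ids):
        favoured = int(rng.integers(0, 2))
        idx = np.array(cols.get(gid, []), dtype=np.intp)
        if idx.size == 0:
            continue
        wrong = p_pop[favoured, idx] < p_pop[1 - favoured, idx]
        flip = idx[wrong]
        p_pop[0, flip], p_pop[1, flip] = (
            p_pop[1, flip].copy(), p_pop[0, flip].copy()
        )


def _plan_genome(config: SimulationConfig, rng: np.random.Generator):
    """Place non-overlapping multi-exon transcripts round-robin on chromosomes."""
    per_chrom = [[] for _ in range(config.n_chromosomes)]
    for g in range(config.n_target_genes):
        per_chrom[g % config.n_chromosomes].append(g)

    margin = GENE_FLANK + 1000
    transcripts: list[TranscriptModel] = []
    for c, gene_indices in enumerate(per_chrom):
        if not gene_indices:
            continue
        segment = (config.chromosome_length - 2 * margin) // len(gene_indices)
        for slot, g in enumerate(gene_indices):
            length = int(rng.integers(4000, 15001))
            slack = segment - length - 2 * margin
            if slack < 1:
                raise ConfigError(
                    "chromosome_length too small for the requested gene panel"
                )
            start = margin + slot * segment + margin + int(rng.integers(0, slack))
            end = start + length - 1
            exons = _split_exons(start, end, int(rng.integers(2, 6)), rng)
            strand = "+" if rng.random() < 0.5 else "-"
            first, last = exons[0], exons[-1]
            head = (first[0], min(first[0] + 99, first[1]))
            tail = (max(last[1] - 99, last[0]), last[1])
            utr5, utr3 = (head, tail) if strand == "+" else (tail, head)
            gid = f"gene{g + 1:03d}"
            transcripts.append(
                TranscriptModel(
                    gene_id=gid, transcript_id=f"{gid}.t1",
                    chromosome=f"chr{c + 1}", strand=strand,
                    start=start, end=end, exons=exons,
                    utr5=[utr5], utr3=[utr3],
                )
            )
    transcripts.sort(key=lambda t: (t.chromosome, t.start))
    order = rng.permutation(config.n_target_genes)[: config.n_divergent_genes]
    all_gids = sorted(t.gene_id for t in transcripts)
    divergent = {all_gids[i] for i in order}
    return transcripts, divergent


def _split_exons(start: int, end: int, n_exons: int, rng: np.random.Generator):
    """Cut [start, end] into alternating exon/intron segments (min 50 bp each)."""
    n_seg = 2 * n_exons - 1
    total = end - start + 1
    extra = rng.multinomial(total - 50 * n_seg, np.full(n_seg, 1.0 / n_seg))
    lengths = 50 + extra
    exons, pos = [], start
    for i, ln in enumerate(lengths):
        if i % 2 == 0:
            exons.append((pos, pos + int(ln) - 1))
        pos += int(ln)
    return exons


def _plan_snps(config, transcripts, divergent_ids, rng):
    """SNP positions: inside genes, in gene flanks, and genome background."""
    snps: list[_PlannedSnp] = []
    exclusion = [[] for _ in range(config.n_chromosomes)]
    for t in transcripts:
        c = int(t.chromosome[3:]) - 1
        div = t.gene_id in divergent_ids
        inside = rng.choice(
            np.arange(t.start, t.end + 1), size=config.snps_per_gene, replace=False
        )
        lo = np.arange(max(1, t.start - GENE_FLANK), t.start)
        hi = np.arange(t.end + 1, min(config.chromosome_length, t.end + GENE_FLANK) + 1)
        flank = rng.choice(
            np.concatenate([lo, hi]), size=config.flank_snps_per_gene, replace=False
        )
        for pos in np.concatenate([inside, flank]):
            snps.append(_PlannedSnp(c, int(pos), t, div))
        # keep background SNPs clear of the flank so annotation truth is clean
        exclusion[c].append((t.start - GENE_FLANK - 500, t.end + GENE_FLANK + 500))

    n_background = config.n_snps - len(snps)
    counts = np.full(config.n_chromosomes, n_background // config.n_chromosomes)
    counts[: n_background % config.n_chromosomes] += 1
    for c in range(config.n_chromosomes):
        allowed = _complement(exclusion[c], config.chromosome_length)
        pool = np.concatenate([np.arange(a, b + 1) for a, b in allowed])
        if counts[c] > pool.size:
            raise ConfigError("chromosome too dense for requested background SNPs")
        for pos in rng.choice(pool, size=counts[c], replace=False):
            snps.append(_PlannedSnp(c, int(pos), None, False))

    snps.sort(key=lambda s: (s.chrom, s.position))
    return snps


def _complement(blocks: list[tuple[int, int]], length: int):
    out, cursor = [], 1
    for a, b in sorted(blocks):
        if a > cursor:
            out.append((cursor, min(a - 1, length)))
        cursor = max(cursor, b + 1)
    if cursor <= length:
        out.append((cursor, length))
    return out


# ---------------------------------------------------------------------------
# generator validation statistic
# ---------------------------------------------------------------------------

def realized_fst(dataset: GenotypeDataset) -> float:
    """Hudson FST between the dataset's two populations.

    Ratio-of-averages form: with sample allele-A frequencies ``p1, p2``
    (computed from non-missing calls),

        FST = sum_j (p1 - p2)^2  /  sum_j [p1 (1 - p2) + p2 (1 - p1)]

    over all variants with at least one call in each population.  Identical
    frequency vectors give exactly 0; fixed opposite homozygotes give 1.
    """
    pops = dataset.populations
    if len(pops) != 2:
        raise ValueError(f"realized_fst needs exactly two populations, got {pops}")
    freqs = []
    for pop in pops:
        sub = dataset.calls[dataset.sample_rows(pop)]
        called = sub != MISSING
        n_called = called.sum(axis=0)
        if not n_called.any():
            raise ValueError(f"population {pop!r} has no called genotypes")
        with np.errstate(invalid="ignore"):
            p = np.where(called, sub, 0).sum(axis=0) / (2.0 * n_called)
        p[n_called == 0] = np.nan
        freqs.append(p)
    p1, p2 = freqs
    ok = ~(np.isnan(p1) | np.isnan(p2))
    if not ok.any():
        raise ValueError("no variant has defined frequencies in both populations")
    num = ((p1 - p2) ** 2)[ok].sum()
    den = (p1 * (1 - p2) + p2 * (1 - p1))[ok].sum()
    if den == 0.0:
        return 0.0
    return float(num / den)


def write_simulation(
    outdir: str | Path,
    dataset: GenotypeDataset,
    transcripts: list[TranscriptModel],
    gene_list: dict[str, str],
    truth: SimulationTruth,
) -> dict[str, Path]:
    """Write the simulated inputs (VCF/GTF/TSVs) plus the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "gtf": outdir / "transcripts.gtf",
        "genes": outdir / "gene_list.tsv",
        "labels": outdir / "labels.tsv",
        "truth": outdir / "truth.tsv",
    }
    eio.write_vcf(dataset, paths["vcf"])
    eio.write_gtf(transcripts, paths["gtf"])
    eio.write_gene_list(gene_list, paths["genes"])
    eio.write_labels(dataset.population_of, paths["labels"])
    truth_frame = truth.per_snp_population_freqs.copy()
    truth_frame["divergent_gene"] = truth_frame["gene_id"].isin(
        truth.divergent_gene_ids
    )
    eio.write_table(truth_frame, paths["truth"])
    return paths


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["population_labels"] = list(config.population_labels)
    return d
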