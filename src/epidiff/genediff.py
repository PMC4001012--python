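"""Gene-level population differentiation: averaged genotypic profiles,
the squared-Euclidean gene-differentiation metric, ranking and deciles.

For each gene (or transcript) the genotypic frequencies (p0, p1, p2) of
its assigned SNPs are averaged per population, and the two populations'
mean profiles are compared with

    metric = (dp0)^2 + (dp1)^2 + (dp2)^2

the squared Euclidean distance between the two profiles.  It ranges from 0
(identical profiles) to 2 (opposite fixed homozygotes).  An optional
rooted form takes the square root; rankings and decile membership are
identical under this monotone transform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .annotation import SnpAnnotation
from .frequencies import PopulationFrequencies

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneGenotypeProfile:
    """Mean genotypic frequencies over a gene's SNPs in one population."""

    gene_id: str
    chromosome: str
    population: str
    mean_p0: float
    mean_p1: float
    mean_p2: float
    n_snps: int

    def vector(self) -> np.ndarray:
        return np.array([self.mean_p0, self.mean_p1, self.mean_p2])


@dataclass(frozen=True)
class GeneDiffRecord:
    """A gene's differentiation metric with rank and decile flags."""

    gene_id: str
    chromosome: str
    metric: float
    rank: int = 0
    top_decile: bool = False
    bottom_decile: bool = False


def gene_profiles(
    annotations: list[SnpAnnotation],
    freqs: PopulationFrequencies,
    collapse_to_gene: bool = False,
) -> list[GeneGenotypeProfile]:
    """Average genotypic frequencies over each gene's SNPs per population.

    SNPs of all positional categories are pooled.  By default one profile
    per *transcript* and population (the unit of the SNP-transcript
    pairing); ``collapse_to_gene`` averages transcripts of a gene together
    by pooling their SNPs.  Variants lacking defined frequencies in any
    population are dropped (logged); a unit left without usable SNPs is
    excluded.
    """
    usable = set(freqs.defined_in_all())
    unit_of: dict[str, tuple[str, str]] = {}
    members: dict[str, list[str]] = {}
    n_dropped = 0
    for a in annotations:
        if a.variant_id not in usable:
            n_dropped += 1
            continue
        unit = a.gene_id if collapse_to_gene else a.transcript_id
        unit_of[unit] = (unit, a.chromosome)
        members.setdefault(unit, []).append(a.variant_id)
    if n_dropped:
        logger.info("%d annotated SNPs dropped (undefined frequencies)", n_dropped)

    profiles: list[GeneGenotypeProfile] = []
    for pop in freqs.populations:
        table = freqs.for_population(pop)
        for unit, vids in sorted(members.items()):
            sub = table.loc[vids, ["p0", "p1", "p2"]]
            mean = sub.mean(axis=0)
            profiles.append(
                GeneGenotypeProfile(
                    gene_id=unit, chromosome=unit_of[unit][1], population=pop,
                    mean_p0=float(mean["p0"]), mean_p1=float(mean["p1"]),
                    mean_p2=float(mean["p2"]), n_snps=len(vids),
                )
            )
    return profiles


def gene_diff_metric(
    profile_pop1: GeneGenotypeProfile,
    profile_pop2: GeneGenotypeProfile,
    rooted: bool = False,
) -> float:
    """Squared Euclidean distance between two populations' gene profiles."""
    if profile_pop1.gene_id != profile_pop2.gene_id:
        raise ValueError(
            f"profiles are for different genes: {profile_pop1.gene_id} "
            f"vs {profile_pop2.gene_id}"
        )
    if profile_pop1.population == profile_pop2.population:
        raise ValueError("profiles are for the same population")
    d = profile_pop1.vector() - profile_pop2.vector()
    metric = float(np.dot(d, d))
    return math.sqrt(metric) if rooted else metric


def diff_records(
    profiles: list[GeneGenotypeProfile],
    pop1: str | None = None,
    pop2: str | None = None,
    rooted: bool = False,
) -> list[GeneDiffRecord]:
    """Pair each gene's two population profiles and compute the metric."""
    pops = sorted({p.population for p in profiles})
    if pop1 is None or pop2 is None:
        if len(pops) != 2:
            raise ValueError(f"expected two populations in profiles, got {pops}")
        pop1, pop2 = pops
    by_gene: dict[str, dict[str, GeneGenotypeProfile]] = {}
    for p in profiles:
        by_gene.setdefault(p.gene_id, {})[p.population] = p
    records = []
    for gene_id, per_pop in sorted(by_gene.items()):
        if pop1 not in per_pop or pop2 not in per_pop:
            logger.info("gene %s lacks a profile in one population; skipped", gene_id)
            continue
        a = per_pop[pop1]
        records.append(
            GeneDiffRecord(
                gene_id=gene_id, chromosome=a.chromosome,
                metric=gene_diff_metric(a, per_pop[pop2], rooted=rooted),
            )
        )
    return records


def rank_genes(
    records: list[GeneDiffRecord], decile: float = 0.10
) -> list[GeneDiffRecord]:
    """Rank genes by descending metric and flag top/bottom deciles.

    Rank 1 is the most differentiated gene.  The decile size is
    ``floor(decile * n)`` with a minimum of 1; ties at a boundary are
    resolved by the deterministic (metric desc, gene_id asc) sort order.
    """
    if not records:
        raise ValueError("no gene records to rank")
    if not 0.0 < decile <= 0.5:
        raise ValueError("decile must be in (0, 0.5]")
    ordered = sorted(records, key=lambda r: (-r.metric, r.gene_id))
    n = len(ordered)
    k = max(1, int(math.floor(decile * n)))
    return [
        replace(
            r,
            rank=i + 1,
            top_decile=i < k,
            bottom_decile=i >= n - k,
        )
        for i, r in enumerate(ordered)
    ]


def records_to_frame(records: list[GeneDiffRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
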