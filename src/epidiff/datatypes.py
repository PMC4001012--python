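"""Core in-memory containers for two-population SNP genotype analyses.

Genotypes are stored as allele-A dosages: each call is the number of copies
(0, 1 or 2) of allele A carried by a diploid sample, or :data:`MISSING`.
Coordinates are 1-based inclusive throughout (VCF/GTF native convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel dosage value for a missing diploid call.
MISSING: int = -1

_VALID_CALLS = frozenset({-1, 0, 1, 2})


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP.

    Parameters
    ----------
    variant_id : str
        Unique marker name within a dataset.
    chromosome : str
        Chromosome name; must match the annotation's naming.
    position : int
        1-based position.
    allele_A : str
        The allele whose copies the dosage matrix counts (reference allele
        by default when read from VCF).
    allele_B : str
        The other allele.
    """

    variant_id: str
    chromosome: str
    position: int
    allele_A: str
    allele_B: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"variant {self.variant_id}: position must be >= 1, got {self.position}"
            )
        for name in ("allele_A", "allele_B"):
            allele = getattr(self, name)
            if len(allele) != 1 or allele.upper() not in "ACGT":
                raise ValueError(
                    f"variant {self.variant_id}: {name} must be a single nucleotide, got {allele!r}"
                )
        if self.allele_A == self.allele_B:
            raise ValueError(f"variant {self.variant_id}: alleles must differ")


@dataclass
class GenotypeDataset:
    """Samples x variants matrix of diploid allele-A dosages with labels.

    ``calls[i, j]`` is the dosage of ``variants[j].allele_A`` in sample
    ``sample_ids[i]`` (0, 1, 2 or :data:`MISSING`). Every sample carries a
    population label; the set of labels present defines the populations.
    """

    variants: list[VariantRecord]
    sample_ids: list[str]
    population_of: dict[str, str]
    calls: np.ndarray

    _variant_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D matrix")
        n_samples, n_variants = self.calls.shape
        if n_samples != len(self.sample_ids):
            raise ValueError(
                f"calls has {n_samples} rows but {len(self.sample_ids)} sample ids"
            )
        if n_variants != len(self.variants):
            raise ValueError(
                f"calls has {n_variants} columns but {len(self.variants)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        unlabelled = [s for s in self.sample_ids if s not in self.population_of]
        if unlabelled:
            raise ValueError(f"samples without a population label: {unlabelled[:5]}")
        bad = set(np.unique(self.calls)) - _VALID_CALLS
        if bad:
            raise ValueError(f"invalid call values {sorted(bad)}; expected 0/1/2/{MISSING}")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids")
        self._variant_index = {vid: j for j, vid in enumerate(ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def populations(self) -> tuple[str, ...]:
        """Population labels in order of first appearance in sample order."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.population_of[s], None)
        return tuple(seen)

    def variant_index(self, variant_id: str) -> int:
        return self._variant_index[variant_id]

    def sample_rows(self, population: str) -> np.ndarray:
        """Row indices of all samples belonging to ``population``."""
        rows = np.array(
            [i for i, s in enumerate(self.sample_ids) if self.population_of[s] == population],
            dtype=np.intp,
        )
        if rows.size == 0:
            raise ValueError(f"no samples in population {population!r}")
        return rows


@dataclass
class TranscriptModel:
    """One transcript: span, exon structure, optional epigenetic category.

    ``start``/``end`` are 1-based inclusive, exons are sorted non-overlapping
    inclusive intervals inside the span, UTR intervals lie inside exons.
    ``category`` is one of the nine epigenetic-machinery group letters a-i
    when the transcript belongs to the target list.
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    category: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ValueError(f"{self.transcript_id}: start > end")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in self.exons:
            if a > b:
                raise ValueError(f"{self.transcript_id}: exon interval ({a},{b}) inverted")
            if a < self.start or b > self.end:
                raise ValueError(
                    f"{self.transcript_id}: exon ({a},{b}) outside span "
                    f"({self.start},{self.end})"
                )
            if prev_end is not None and a <= prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = b
        for name, intervals in (("utr5", self.utr5), ("utr3", self.utr3)):
            for a, b in intervals:
                if not any(ea <= a and b <= eb for ea, eb in self.exons):
                    raise ValueError(
                        f"{self.transcript_id}: {name} interval ({a},{b}) not inside an exon"
                    )
        if self.category is not None and self.category not in "abcdefghi":
            raise ValueError(
                f"{self.transcript_id}: category must be a letter a-i, got {self.category!r}"
            )

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1

    def introns(self) -> list[tuple[int, int]]:
        """Inclusive intervals between consecutive exons (may be empty)."""
        out = []
        for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]):
            if a2 > b1 + 1:
                out.append((b1 + 1, a2 - 1))
        return out

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def distance_to(self, position: int) -> int:
        """0 inside the span, otherwise the gap to the nearest span edge."""
        if position < self.start:
            return self.start - position
        if position > self.end:
            return position - self.end
        return 0
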