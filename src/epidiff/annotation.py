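"""Positional SNP-to-transcript annotation and category summaries.

Each SNP is paired with at most one target transcript — the nearest one,
provided it lies inside the transcript span or within a 3-kb flank — and
classified positionally:

* **CAT1** (transcribed): in an exon, a UTR, or a splice region;
* **CAT2** (intronic): in an intron, outside the splice-region window;
* **CAT3** (flanking): up- or downstream of the span, within the flank.

The splice-region window follows the Ensembl consequence convention:
1-8 bp into the intron from an exon junction, or the last 3 exonic bases
adjacent to a junction.  Intron-side splice-region SNPs count as CAT1.

Distance ties between transcripts are broken by smaller span, then
lexicographic transcript id, which keeps the SNP-transcript pairing unique
and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .datatypes import TranscriptModel, VariantRecord

CAT1, CAT2, CAT3 = "CAT1", "CAT2", "CAT3"
CATEGORIES = (CAT1, CAT2, CAT3)

DEFAULT_FLANK = 3000
SPLICE_INTRON_BP = 8   # intron-side window, bases 1..8 from the junction
SPLICE_EXON_BP = 3     # exon-side window, last 3 exonic bases at a junction


@dataclass(frozen=True)
class SnpAnnotation:
    """A unique SNP-transcript pair with positional class."""

    variant_id: str
    transcript_id: str
    gene_id: str
    chromosome: str
    category: str
    distance: int
    consequence_detail: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        inside = self.distance == 0
        if inside != (self.category in (CAT1, CAT2)):
            raise ValueError(
                f"{self.variant_id}: distance {self.distance} inconsistent with "
                f"{self.category}"
            )
        if self.category == CAT3 and not 1 <= self.distance:
            raise ValueError(f"{self.variant_id}: CAT3 requires distance >= 1")


def assign_snps(
    variants: list[VariantRecord],
    transcripts: list[TranscriptModel],
    flank: int = DEFAULT_FLANK,
) -> list[SnpAnnotation]:
    """Assign each SNP to its closest transcript within ``flank`` bp.

    The distance is 0 inside the transcript span, otherwise the gap to the
    nearest span edge; a SNP farther than ``flank`` from every transcript is
    left unassigned (absent from the output).  Ties go to the transcript
    with the smaller span, then the lexicographically smaller id.
    """
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chromosome, []).append(t)

    annotations: list[SnpAnnotation] = []
    for chrom, txs in by_chrom.items():
        txs = sorted(txs, key=lambda t: (t.span_length, t.transcript_id))
        starts = np.array([t.start for t in txs])
        ends = np.array([t.end for t in txs])
        chrom_variants = [v for v in variants if v.chromosome == chrom]
        if not chrom_variants:
            continue
        pos = np.array([v.position for v in chrom_variants])[:, None]
        dist = np.maximum.reduce([starts[None, :] - pos, pos - ends[None, :],
                                  np.zeros_like(pos - ends[None, :])])
        best = np.argmin(dist, axis=1)  # first minimum = preferred tie-break order
        best_dist = dist[np.arange(len(chrom_variants)), best]
        for v, b, d in zip(chrom_variants, best, best_dist):
            if d > flank:
                continue
            t = txs[b]
            category, detail = classify_position(v, t)
            annotations.append(
                SnpAnnotation(
                    variant_id=v.variant_id, transcript_id=t.transcript_id,
                    gene_id=t.gene_id, chromosome=t.chromosome,
                    category=category, distance=int(d),
                    consequence_detail=detail,
                )
            )
    annotations.sort(key=lambda a: a.variant_id)
    return annotations


def classify_position(
    variant: VariantRecord, transcript: TranscriptModel
) -> tuple[str, str]:
    """Positional class of an assigned SNP relative to its transcript.

    Returns ``(category, consequence_detail)`` where the detail is one of
    exon, utr5, utr3, splice_region, intron, upstream, downstream.
    """
    pos = variant.position
    t = transcript
    if not t.contains(pos):
        d = t.distance_to(pos)
        before = pos < t.start
        upstream = before if t.strand == "+" else not before
        return CAT3, ("upstream" if upstream else "downstream")

    junction_starts = {a for a, _ in t.exons if a != t.start}
    junction_ends = {b for _, b in t.exons if b != t.end}
    for a, b in t.exons:
        if a <= pos <= b:
            for lo, hi in t.utr5:
                if lo <= pos <= hi:
                    return CAT1, "utr5"
            for lo, hi in t.utr3:
                if lo <= pos <= hi:
                    return CAT1, "utr3"
            near_junction = (
                (b in junction_ends and b - pos < SPLICE_EXON_BP)
                or (a in junction_starts and pos - a < SPLICE_EXON_BP)
            )
            return CAT1, ("splice_region" if near_junction else "exon")
    # intronic: distance to the flanking exon junctions
    prev_end = max(b for _, b in t.exons if b < pos)
    next_start = min(a for a, _ in t.exons if a > pos)
    into_intron = min(pos - prev_end, next_start - pos)
    if into_intron <= SPLICE_INTRON_BP:
        return CAT1, "splice_region"
    return CAT2, "intron"


# ---------------------------------------------------------------------------
# category summaries
# ---------------------------------------------------------------------------

@dataclass
class CategorySummary:
    """Per-category transcript and SNP counts with a TOTAL row.

    ``rows`` is indexed by category letter with columns
    ``n_transcripts, CAT1, CAT2, CAT3``; ``total_row`` is the column sum.
    """

    rows: pd.DataFrame
    total_row: pd.Series

    @property
    def total_snps(self) -> int:
        return int(self.total_row[list(CATEGORIES)].sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.rows.copy()
        out.loc["TOTAL"] = self.total_row
        return out.reset_index(names="category")


def summarize_by_category(
    annotations: list[SnpAnnotation], gene_list: dict[str, str]
) -> CategorySummary:
    """Tally transcripts tagged and SNPs per CAT within each category.

    A transcript counts as tagged if it carries at least one assigned SNP.
    The category of an annotation is looked up by transcript id first, then
    gene id; annotated transcripts absent from the gene list are an error.
    """
    letters = sorted(set(gene_list.values()))
    rows = pd.DataFrame(
        0, index=letters, columns=["n_transcripts", *CATEGORIES], dtype=int
    )
    tagged: dict[str, set[str]] = {c: set() for c in letters}
    unknown = []
    for a in annotations:
        cat_letter = gene_list.get(a.transcript_id, gene_list.get(a.gene_id))
        if cat_letter is None:
            unknown.append(a.transcript_id)
            continue
        rows.loc[cat_letter, a.category] += 1
        tagged[cat_letter].add(a.transcript_id)
    if unknown:
        raise ValueError(
            f"annotated transcripts missing from the gene list: {sorted(set(unknown))[:10]}"
        )
    for c in letters:
        rows.loc[c, "n_transcripts"] = len(tagged[c])
    return CategorySummary(rows=rows, total_row=rows.sum(axis=0))


def annotations_to_frame(annotations: list[SnpAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in annotations])


# ---------------------------------------------------------------------------
# packaged reference fixture
# ---------------------------------------------------------------------------

def load_reference_category_counts() -> pd.DataFrame:
    """Packaged per-category counts from a published bovine HD-chip screen
    of epigenetic-machinery genes (9 categories, 193 transcripts, 3091 SNPs).

    Columns: category, gene_function, n_transcripts, CAT1, CAT2, CAT3.
    """
    with resources.files("epidiff.data").joinpath(
        "epigenetic_category_counts.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def expand_category_counts(
    counts: pd.DataFrame,
) -> tuple[list[SnpAnnotation], dict[str, str]]:
    """Expand a per-category count table into a concrete annotation set.

    Builds synthetic transcripts and SNP annotations whose per-category
    tallies reproduce ``counts`` exactly: each category gets its stated
    number of transcripts, every transcript carries at least one SNP, and
    the CAT1/CAT2/CAT3 SNP totals match.  The inverse of
    :func:`summarize_by_category` up to the arbitrary within-category
    distribution of SNPs over transcripts.
    """
    annotations: list[SnpAnnotation] = []
    gene_list: dict[str, str] = {}
    snp_no = 0
    detail_of = {CAT1: "exon", CAT2: "intron", CAT3: "upstream"}
    for row in counts.itertuples(index=False):
        letter = row.category
        n_tx = int(row.n_transcripts)
        snp_cats = (
            [CAT1] * int(getattr(row, CAT1))
            + [CAT2] * int(getattr(row, CAT2))
            + [CAT3] * int(getattr(row, CAT3))
        )
        if n_tx > len(snp_cats):
            raise ValueError(
                f"category {letter}: {n_tx} transcripts but only "
                f"{len(snp_cats)} SNPs — every tagged transcript needs a SNP"
            )
        tx_ids = [f"{letter}_tx{i + 1:03d}" for i in range(n_tx)]
        gene_list.update({tid: letter for tid in tx_ids})
        for i, cat in enumerate(snp_cats):
            snp_no += 1
            tid = tx_ids[i % n_tx]
            annotations.append(
                SnpAnnotation(
                    variant_id=f"fix{snp_no:05d}", transcript_id=tid,
                    gene_id=tid.rsplit(".", 1)[0], chromosome="chrF",
                    category=cat, distance=0 if cat != CAT3 else 100,
                    consequence_detail=detail_of[cat],
                )
            )
    return annotations, gene_list


def bed6_rows(
    annotations: list[SnpAnnotation],
    variants: list[VariantRecord],
    category: str,
) -> list[tuple[str, int, str, str]]:
    """BED6 rows (chrom, pos, name, strand) for one annotation category."""
    pos_of = {v.variant_id: (v.chromosome, v.position) for v in variants}
    rows = []
    for a in annotations:
        if a.category != category:
            continue
        chrom, pos = pos_of[a.variant_id]
        rows.append((chrom, pos, a.variant_id, "."))
    return rows
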