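import numpy as np
import pytest

from epidiff.annotation import (
    CAT1,
    CAT2,
    CAT3,
    SnpAnnotation,
    assign_snps,
    classify_position,
    expand_category_counts,
    load_reference_category_counts,
    summarize_by_category,
)
from epidiff.datatypes import TranscriptModel, VariantRecord


def snp(pos, vid="v1", chrom="chr1"):
    return VariantRecord(vid, chrom, pos, "A", "G")


def transcript(start, end, tid="t1", gene="g1", chrom="chr1", strand="+",
               exons=None, **kw):
    return TranscriptModel(
        gene_id=gene, transcript_id=tid, chromosome=chrom, strand=strand,
        start=start, end=end, exons=exons or [(start, end)], **kw
    )


def brute_force_assign(variants, transcripts, flank=3000):
    """All-pairs distance enumeration with the documented tie-break."""
    out = {}
    for v in variants:
        candidates = []
        for t in transcripts:
            if t.chromosome != v.chromosome:
                continue
            d = t.distance_to(v.position)
            candidates.append((d, t.span_length, t.transcript_id))
        if not candidates:
            continue
        d, _, tid = min(candidates)
        if d <= flank:
            out[v.variant_id] = (tid, d)
    return out


class TestAssignSnps:
    def test_containment_distance_zero(self):
        (a,) = assign_snps([snp(1500)], [transcript(1000, 2000)])
        assert (a.transcript_id, a.distance) == ("t1", 0)

    def test_flank_boundary_is_inclusive_at_3000(self):
        assert assign_snps([snp(5001)], [transcript(1000, 2000)]) == []
        (a,) = assign_snps([snp(5000)], [transcript(1000, 2000)])
        assert a.distance == 3000 and a.category == CAT3

    def test_nearest_transcript_wins(self):
        txs = [transcript(1000, 2000, tid="t1"),
               transcript(5200, 6000, tid="t2", gene="g2")]
        (a,) = assign_snps([snp(4999)], txs)
        assert a.transcript_id == "t2" and a.distance == 201

    def test_tie_breaks_by_span_then_id(self):
        # equidistant overlapping spans: smaller span wins, then lexicographic
        txs = [transcript(1000, 3000, tid="tBig"),
               transcript(1400, 1600, tid="tSmall", gene="g2")]
        (a,) = assign_snps([snp(1500)], txs)
        assert a.transcript_id == "tSmall"
        txs = [transcript(1000, 2000, tid="tB"),
               transcript(1000, 2000, tid="tA", gene="g2")]
        (a,) = assign_snps([snp(1500)], txs)
        assert a.transcript_id == "tA"

    def test_each_variant_annotated_at_most_once(self, small_simulation):
        _, (dataset, transcripts, _, _) = small_simulation
        annotations = assign_snps(dataset.variants, transcripts)
        ids = [a.variant_id for a in annotations]
        assert len(ids) == len(set(ids))

    def test_matches_brute_force_on_random_toy_genomes(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            n_tx = rng.integers(2, 20)
            transcripts = []
            for i in range(n_tx):
                start = int(rng.integers(1, 80_000))
                end = start + int(rng.integers(100, 8000))
                transcripts.append(
                    transcript(start, end, tid=f"t{i:02d}", gene=f"g{i:02d}",
                               chrom=f"chr{rng.integers(1, 3)}")
                )
            variants = [
                snp(int(rng.integers(1, 95_000)), vid=f"v{j:03d}",
                    chrom=f"chr{rng.integers(1, 3)}")
                for j in range(200)
            ]
            got = {a.variant_id: (a.transcript_id, a.distance)
                   for a in assign_snps(variants, transcripts)}
            assert got == brute_force_assign(variants, transcripts)

    def test_enlarging_flank_only_adds_assignments(self):
        rng = np.random.default_rng(23)
        transcripts = [
            transcript(int(s), int(s) + 500, tid=f"t{i}", gene=f"g{i}")
            for i, s in enumerate(rng.integers(1, 50_000, size=8))
        ]
        variants = [snp(int(p), vid=f"v{j}") for j, p in
                    enumerate(rng.integers(1, 60_000, size=150))]
        small = {a.variant_id: a.transcript_id
                 for a in assign_snps(variants, transcripts, flank=1000)}
        large = {a.variant_id: a.transcript_id
                 for a in assign_snps(variants, transcripts, flank=5000)}
        assert set(small) <= set(large)
        assert all(large[v] == t for v, t in small.items())


class TestClassifyPosition:
    TX = TranscriptModel(
        gene_id="g1", transcript_id="t1", chromosome="chr1", strand="+",
        start=1000, end=2000, exons=[(1000, 1200), (1500, 2000)],
        utr5=[(1000, 1050)], utr3=[(1900, 2000)],
    )

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (1100, (CAT1, "exon")),          # mid-exon
            (1020, (CAT1, "utr5")),
            (1950, (CAT1, "utr3")),
            (1199, (CAT1, "splice_region")),  # exon side, 3 bp window
            (1205, (CAT1, "splice_region")),  # intron side, bases 1-8
            (1208, (CAT1, "splice_region")),
            (1250, (CAT2, "intron")),         # deep intron
            (1495, (CAT1, "splice_region")),  # intron side of next exon
            (900, (CAT3, "upstream")),
            (2500, (CAT3, "downstream")),
        ],
    )
    def test_positional_classes(self, pos, expected):
        assert classify_position(snp(pos), self.TX) == expected

    def test_strand_flips_flank_labels(self):
        minus = TranscriptModel(
            gene_id="g1", transcript_id="t1", chromosome="chr1", strand="-",
            start=1000, end=2000, exons=[(1000, 2000)],
        )
        assert classify_position(snp(900), minus)[1] == "downstream"
        assert classify_position(snp(2500), minus)[1] == "upstream"

    def test_splice_window_boundary(self):
        # 5 bp into the intron -> splice region; deeper -> intron
        assert classify_position(snp(1205), self.TX) == (CAT1, "splice_region")
        assert classify_position(snp(1209), self.TX) == (CAT2, "intron")

    def test_transcript_ends_are_not_splice_junctions(self):
        assert classify_position(snp(1000), self.TX)[1] == "utr5"
        assert classify_position(snp(2000), self.TX)[1] == "utr3"
        bare = transcript(1000, 2000, exons=[(1000, 2000)])
        assert classify_position(snp(1001), bare) == (CAT1, "exon")

    def test_partition_on_simulated_data(self, small_simulation):
        _, (dataset, transcripts, _, _) = small_simulation
        annotations = assign_snps(dataset.variants, transcripts)
        assert annotations, "expected gene-linked SNPs"
        by_tx = {t.transcript_id: t for t in transcripts}
        for a in annotations:
            assert a.category in (CAT1, CAT2, CAT3)
            inside = by_tx[a.transcript_id].contains(
                next(v for v in dataset.variants
                     if v.variant_id == a.variant_id).position
            )
            assert inside == (a.category in (CAT1, CAT2))

    def test_exonic_snps_lie_in_exon_intervals(self, small_simulation):
        _, (dataset, transcripts, _, _) = small_simulation
        by_tx = {t.transcript_id: t for t in transcripts}
        pos_of = {v.variant_id: v.position for v in dataset.variants}
        for a in assign_snps(dataset.variants, transcripts):
            if a.consequence_detail in ("exon", "utr5", "utr3"):
                t = by_tx[a.transcript_id]
                p = pos_of[a.variant_id]
                assert any(lo <= p <= hi for lo, hi in t.exons)


class TestSummarize:
    def test_manual_tally(self):
        annotations = [
            SnpAnnotation("v1", "tx1", "tx1", "chr1", CAT1, 0, "exon"),
            SnpAnnotation("v2", "tx1", "tx1", "chr1", CAT2, 0, "intron"),
            SnpAnnotation("v3", "tx2", "tx2", "chr1", CAT3, 10, "upstream"),
        ]
        summary = summarize_by_category(annotations, {"tx1": "a", "tx2": "c"})
        assert summary.rows.loc["a"].tolist() == [1, 1, 1, 0]
        assert summary.rows.loc["c"].tolist() == [1, 0, 0, 1]
        assert summary.total_row.tolist() == [2, 1, 1, 1]

    def test_empty_annotations_all_zero(self):
        summary = summarize_by_category([], {"tx1": "a"})
        assert (summary.rows.to_numpy() == 0).all()

    def test_unknown_transcript_errors(self):
        annotations = [SnpAnnotation("v1", "txX", "txX", "chr1", CAT1, 0, "exon")]
        with pytest.raises(ValueError, match="txX"):
            summarize_by_category(annotations, {"tx1": "a"})

    def test_reference_counts_round_trip(self):
        """Expanding the packaged category counts and re-summarizing
        reproduces the printed per-category table exactly."""
        counts = load_reference_category_counts()
        annotations, gene_list = expand_category_counts(counts)
        assert len(set(gene_list.values())) == 9
        summary = summarize_by_category(annotations, gene_list)
        for row in counts.itertuples(index=False):
            got = summary.rows.loc[row.category]
            assert got["n_transcripts"] == row.n_transcripts
            assert (got[CAT1], got[CAT2], got[CAT3]) == (row.CAT1, row.CAT2, row.CAT3)
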