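import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epidiff.annotation import CAT1, CAT2, SnpAnnotation
from epidiff.frequencies import compute_frequencies
from epidiff.genediff import (
    GeneDiffRecord,
    GeneGenotypeProfile,
    diff_records,
    gene_diff_metric,
    gene_profiles,
    rank_genes,
)

from conftest import make_dataset


def profile(p0, p1, p2, gene="g1", pop="A"):
    return GeneGenotypeProfile(
        gene_id=gene, chromosome="chr1", population=pop,
        mean_p0=p0, mean_p1=p1, mean_p2=p2, n_snps=1,
    )


simplex = st.tuples(
    st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
).map(lambda ab: (min(ab), max(ab))).map(lambda ab: (ab[0], ab[1] - ab[0], 1 - ab[1]))


class TestMetric:
    def test_identical_profiles_zero(self):
        a = profile(0.2, 0.5, 0.3)
        b = profile(0.2, 0.5, 0.3, pop="B")
        assert gene_diff_metric(a, b) == 0.0

    def test_opposite_fixed_homozygotes_reach_two(self):
        assert gene_diff_metric(
            profile(1, 0, 0), profile(0, 0, 1, pop="B")
        ) == pytest.approx(2.0)

    def test_direct_formula_evaluation(self):
        got = gene_diff_metric(
            profile(0.5, 0.3, 0.2), profile(0.4, 0.4, 0.2, pop="B")
        )
        assert got == pytest.approx(0.02)

    def test_mismatched_gene_rejected(self):
        with pytest.raises(ValueError, match="different genes"):
            gene_diff_metric(profile(1, 0, 0), profile(1, 0, 0, gene="g2", pop="B"))

    def test_rooted_form_is_square_root(self):
        a, b = profile(0.5, 0.3, 0.2), profile(0.4, 0.4, 0.2, pop="B")
        assert gene_diff_metric(a, b, rooted=True) == pytest.approx(
            math.sqrt(gene_diff_metric(a, b))
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(simplex, simplex)
    def test_symmetry_and_bounds(self, v, w):
        a = profile(*v)
        b = profile(*w, pop="B")
        m = gene_diff_metric(a, b)
        assert m == gene_diff_metric(b, a)
        assert 0.0 <= m <= 2.0 + 1e-12
        if m < 1e-15:
            assert np.allclose(v, w, atol=1e-7)


class TestProfiles:
    def _annotations(self):
        return [
            SnpAnnotation("v1", "t1", "g1", "chr1", CAT1, 0, "exon"),
            SnpAnnotation("v2", "t1", "g1", "chr1", CAT2, 0, "intron"),
            SnpAnnotation("v3", "t2", "g2", "chr1", CAT1, 0, "exon"),
        ]

    def test_single_snp_profile_equals_snp_frequencies(self):
        calls = np.array([[2], [2], [1], [0]])
        ds = make_dataset(calls, ["A", "A", "B", "B"])
        freqs = compute_frequencies(ds)
        annotations = [SnpAnnotation("v1", "t1", "g1", "chr1", CAT1, 0, "exon")]
        profs = {p.population: p for p in gene_profiles(annotations, freqs)}
        assert (profs["A"].mean_p0, profs["A"].mean_p1, profs["A"].mean_p2) == (1, 0, 0)
        assert (profs["B"].mean_p0, profs["B"].mean_p1, profs["B"].mean_p2) == (
            0, 0.5, 0.5,
        )

    def test_two_snp_midpoint(self):
        # SNP profiles (1,0,0) and (0,1,0) in pop A -> mean (0.5, 0.5, 0)
        calls = np.array([[2, 1], [2, 1], [0, 0], [0, 0]])
        ds = make_dataset(calls, ["A", "A", "B", "B"])
        freqs = compute_frequencies(ds)
        annotations = [
            SnpAnnotation("v1", "t1", "g1", "chr1", CAT1, 0, "exon"),
            SnpAnnotation("v2", "t1", "g1", "chr1", CAT2, 0, "intron"),
        ]
        profs = {p.population: p for p in gene_profiles(annotations, freqs)}
        assert (profs["A"].mean_p0, profs["A"].mean_p1, profs["A"].mean_p2) == (
            0.5, 0.5, 0.0,
        )
        assert profs["A"].n_snps == 2

    def test_three_snp_hand_mean(self):
        calls = np.array(
            [[2, 1, 0], [2, 1, 2], [1, 1, 1], [1, 1, 1]]
        )
        ds = make_dataset(calls, ["A", "A", "B", "B"])
        annotations = [
            SnpAnnotation(f"v{j}", "t1", "g1", "chr1", CAT1, 0, "exon")
            for j in (1, 2, 3)
        ]
        profs = {p.population: p for p in
                 gene_profiles(annotations, compute_frequencies(ds))}
        # pop A per-SNP p0: (1, 0, 0.5) -> mean 0.5; p1: (0, 1, 0) -> 1/3
        assert profs["A"].mean_p0 == pytest.approx(0.5)
        assert profs["A"].mean_p1 == pytest.approx(1 / 3)
        assert profs["A"].mean_p2 == pytest.approx(1 / 6)

    def test_collapse_to_gene_pools_transcripts(self):
        calls = np.array([[2, 0], [2, 0], [0, 2], [0, 2]])
        ds = make_dataset(calls, ["A", "A", "B", "B"])
        annotations = [
            SnpAnnotation("v1", "t1", "g1", "chr1", CAT1, 0, "exon"),
            SnpAnnotation("v2", "t2", "g1", "chr1", CAT1, 0, "exon"),
        ]
        freqs = compute_frequencies(ds)
        assert len(gene_profiles(annotations, freqs)) == 4  # 2 tx x 2 pops
        collapsed = gene_profiles(annotations, freqs, collapse_to_gene=True)
        assert {p.gene_id for p in collapsed} == {"g1"}
        byp = {p.population: p for p in collapsed}
        assert byp["A"].mean_p0 == 0.5 and byp["A"].n_snps == 2


class TestRanking:
    def _records(self, metrics):
        return [
            GeneDiffRecord(gene_id=f"g{i:02d}", chromosome="chr1", metric=m)
            for i, m in enumerate(metrics)
        ]

    def test_ten_genes_one_per_decile(self):
        ranked = rank_genes(self._records(np.linspace(0, 1, 10)))
        assert sum(r.top_decile for r in ranked) == 1
        assert sum(r.bottom_decile for r in ranked) == 1
        assert ranked[0].metric == 1.0 and ranked[0].rank == 1

    def test_boundary_tie_is_lexicographic_and_stable(self):
        records = self._records([0.5, 0.5, 0.1, 0.5])  # g00, g01, g03 tied
        out1 = rank_genes(records, decile=0.25)
        out2 = rank_genes(list(reversed(records)), decile=0.25)
        assert [r.gene_id for r in out1] == [r.gene_id for r in out2]
        assert [r.gene_id for r in out1 if r.top_decile] == ["g00"]

    def test_against_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(5)
        metrics = rng.uniform(0, 2, size=25)
        ranked = rank_genes(self._records(metrics))
        top = {r.gene_id for r in ranked if r.top_decile}
        oracle = sorted(
            self._records(metrics), key=lambda r: -r.metric
        )[:2]
        assert top == {r.gene_id for r in oracle}
        assert [r.rank for r in ranked] == list(range(1, 26))

    def test_minimum_decile_size_is_one(self):
        ranked = rank_genes(self._records([0.3, 0.1]))
        assert sum(r.top_decile for r in ranked) == 1

    def test_ranking_invariant_under_square_root(self):
        rng = np.random.default_rng(9)
        metrics = rng.uniform(0, 2, size=30)
        plain = rank_genes(self._records(metrics))
        rooted = rank_genes(
            [
                GeneDiffRecord(r.gene_id, r.chromosome, math.sqrt(r.metric))
                for r in self._records(metrics)
            ]
        )
        assert [r.gene_id for r in plain] == [r.gene_id for r in rooted]
        assert [(r.top_decile, r.bottom_decile) for r in plain] == [
            (r.top_decile, r.bottom_decile) for r in rooted
        ]

    def test_planted_genes_reach_top_decile(self, small_simulation):
        from epidiff.annotation import assign_snps

        _, (dataset, transcripts, _, truth) = small_simulation
        annotations = assign_snps(dataset.variants, transcripts)
        freqs = compute_frequencies(dataset)
        ranked = rank_genes(diff_records(gene_profiles(annotations, freqs)))
        top = {r.gene_id.split(".")[0] for r in ranked if r.top_decile}
        assert truth.divergent_gene_ids <= top
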