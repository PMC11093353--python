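"""Tests for region-to-gene assignment, context classification and HRE scanning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hifseek import DataError
from hifseek.targets import (
    GeneModel,
    assign_region,
    classify_context,
    cross_reference,
    gene_distance,
    scan_hre,
)


def plain_gene(gene_id="g1", chrom="chr1", start=10_000, end=13_000,
               strand="+", with_features=True):
    """Gene with 100 bp 5'UTR, two CDS exons around one intron, 150 bp 3'UTR."""
    if not with_features:
        return GeneModel(gene_id, chrom, start, end, strand)
    if strand == "+":
        five = [(start, start + 100)]
        three = [(end - 150, end)]
        inner = (start + 100, end - 150)
    else:
        five = [(end - 100, end)]
        three = [(start, start + 150)]
        inner = (start + 150, end - 100)
    if inner[1] - inner[0] > 2000:
        cds = [(inner[0], inner[0] + 900), (inner[1] - 900, inner[1])]
    else:
        cds = [inner]
    exons = sorted(five + cds + three)
    return GeneModel(gene_id, chrom, start, end, strand,
                     exons=exons, five_utr=five, three_utr=three, cds=cds)


class Region:
    def __init__(self, chrom, start, end):
        self.chrom, self.start, self.end = chrom, start, end


class TestGeneDistance:
    @pytest.mark.parametrize(
        "region,gene,expected",
        [
            # published promoter-distance conventions (1-based inclusive prints)
            ((6169999, 6170399), (6164905, 6168547), 1453),
            ((14217999, 14218599), (14219870, 14224440), 1272),
            ((20164399, 20164999), (20162614, 20164165), 235),
        ],
    )
    def test_printed_upstream_distances(self, region, gene, expected):
        assert gene_distance(region, gene) == expected

    def test_overlap_gives_zero(self):
        assert gene_distance((100, 300), (200, 500)) == 0
        assert gene_distance((100, 300), (0, 1000)) == 0

    @given(
        st.tuples(st.integers(0, 10_000), st.integers(1, 500)),
        st.tuples(st.integers(0, 10_000), st.integers(1, 500)),
    )
    def test_symmetric_and_zero_iff_overlap(self, a, b):
        ia = (a[0], a[0] + a[1])
        ib = (b[0], b[0] + b[1])
        d1, d2 = gene_distance(ia, ib), gene_distance(ib, ia)
        assert d1 == d2
        overlaps = max(ia[0], ib[0]) < min(ia[1], ib[1])
        assert (d1 == 0) == overlaps


class TestAssignRegion:
    def test_de_gene_beats_closer_non_de_gene(self):
        de_gene = plain_gene("de", start=20_000, end=23_000)
        near = plain_gene("near", start=17_500, end=18_300)
        region = Region("chr1", 18_400, 18_800)  # 101 bp from near, 1201 from de
        ann = assign_region(region, [de_gene, near], de_genes={"de"})
        assert ann.assigned_genes == ["de"]
        assert ann.assignments[0].basis == "de_priority"

    def test_all_de_candidates_assigned(self):
        g1 = plain_gene("a", start=20_000, end=22_000)
        g2 = plain_gene("b", start=14_000, end=16_000)
        region = Region("chr1", 17_000, 17_600)
        ann = assign_region(region, [g1, g2], de_genes={"a", "b"})
        assert sorted(ann.assigned_genes) == ["a", "b"]

    def test_nearest_wins_without_de(self):
        g1 = plain_gene("far", start=22_000, end=24_000)
        g2 = plain_gene("close", start=18_200, end=19_000)
        region = Region("chr1", 17_000, 18_000)
        ann = assign_region(region, [g1, g2], de_genes=set())
        assert ann.assigned_genes == ["close"]
        assert ann.assignments[0].basis == "nearest"

    def test_beyond_6kb_unassigned(self):
        g = plain_gene("g", start=100_000, end=102_000)
        region = Region("chr1", 93_000, 93_600)  # distance 6401
        ann = assign_region(region, [g])
        assert ann.assignments == []
        region2 = Region("chr1", 93_400, 94_000)  # distance 6001
        ann2 = assign_region(region2, [g])
        assert ann2.assignments == []
        region3 = Region("chr1", 93_401, 94_001)  # distance 6000
        assert assign_region(region3, [g]).assigned_genes == ["g"]

    def test_every_assignment_within_bound_and_tie_break(self):
        left = plain_gene("left", start=0, end=2_000)
        right = plain_gene("right", start=8_000, end=10_000)
        region = Region("chr1", 4_500, 5_500)  # equidistant: 2501 bp each
        assert gene_distance((4_500, 5_500), left.span) == gene_distance(
            (4_500, 5_500), right.span
        )
        ann = assign_region(region, [right, left])
        assert ann.assigned_genes == ["left"]  # smaller start coordinate


class TestClassifyContext:
    def test_upstream_downstream_strand_aware(self):
        plus = plain_gene("p", strand="+")
        minus = plain_gene("m", strand="-")
        before, after = (9_000, 9_400), (13_500, 13_900)
        assert classify_context(before, plus) == "upstream"
        assert classify_context(after, plus) == "downstream"
        assert classify_context(before, minus) == "downstream"
        assert classify_context(after, minus) == "upstream"

    def test_five_utr_overlap_extending_upstream(self):
        g = plain_gene("g")
        region = (9_800, 10_050)  # spans the + gene's start and its 5'UTR
        assert classify_context(region, g) == "upstream_5utr_overlap"
        gm = plain_gene("m", strand="-")
        region_m = (12_950, 13_200)
        assert classify_context(region_m, gm) == "upstream_5utr_overlap"

    def test_interior_feature_by_maximal_overlap(self):
        g = plain_gene("g")  # intron spans (11_000, 12_000)
        assert classify_context((11_100, 11_500), g) == "intron"
        assert classify_context((10_200, 10_600), g) == "coding"
        assert classify_context((12_900, 12_990), g) == "three_prime_utr"

    def test_fully_inside_long_gene_is_intragenic(self):
        # a region wholly inside the gene body must land in an interior class
        g = plain_gene("g", start=5_000, end=17_000)
        cat = classify_context((10_000, 10_600), g)
        assert cat in {"intron", "coding", "three_prime_utr"}

    def test_tiled_regions_are_exhaustively_classified(self):
        """Sliding a window across gene +/- flanks always yields a category."""
        for strand in "+-":
            g = plain_gene("g", strand=strand)
            for start in range(8_000, 15_000, 137):
                cat = classify_context((start, start + 400), g)
                assert cat in {
                    "upstream", "upstream_5utr_overlap", "intron",
                    "coding", "three_prime_utr", "downstream",
                }


class TestScanHre:
    def test_full_mode_single_hit(self):
        assert scan_hre("TTACGTGTT", mode="full") == [(2, "+")]

    def test_core_mode_tandem(self):
        assert scan_hre("CGTGCGTG", mode="core") == [(0, "+"), (4, "+")]

    def test_overlapping_matches_reported(self):
        # CGTG at 0 and also at 4 via overlap with ACGTG
        hits = scan_hre("CGTGACGTG", mode="core")
        assert (5, "+") in hits and (0, "+") in hits

    def test_both_strands_reports_reverse_complement_hits(self):
        # CACGT on + strand means ACGTG on - strand
        hits = scan_hre("TTCACGTTT", mode="full", strands="both")
        assert hits == [(2, "-")]

    def test_empty_sequence(self):
        assert scan_hre("", mode="core") == []

    def test_full_hits_contain_core(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), p=[0.32, 0.18, 0.18, 0.32], size=2000))
        full = {pos for pos, _ in scan_hre(seq, mode="full")}
        core = {pos for pos, _ in scan_hre(seq, mode="core")}
        assert {p + 1 for p in full} <= core

    def test_matches_naive_substring_oracle(self):
        rng = np.random.default_rng(42)
        p = [0.32, 0.18, 0.18, 0.32]
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), p=p, size=600))
            for mode, motifs in (("full", ("ACGTG", "GCGTG")), ("core", ("CGTG",))):
                oracle = sorted(
                    (i, "+")
                    for m in motifs
                    for i in range(len(seq))
                    if seq[i : i + len(m)] == m
                )
                assert scan_hre(seq, mode=mode) == oracle

    def test_bad_alphabet_rejected(self):
        with pytest.raises(DataError):
            scan_hre("ACGU")


class TestCrossReference:
    @staticmethod
    def _labels(rows):
        df = pd.DataFrame(rows).set_index("gene")
        return df.astype(bool)

    def _ann(self, gene_ids):
        from hifseek.targets import Assignment, PeakAnnotation

        ann = PeakAnnotation("r1", "chr1", 0, 600)
        ann.assignments = [
            Assignment(g, 100, "de_priority", "upstream") for g in gene_ids
        ]
        return [ann]

    def test_planted_positive_target_lands_in_first_row(self):
        labels = self._labels(
            [{"gene": "g1", "hif1_positive": True, "hif1_negative": False,
              "mutant_up:vhl-1": False, "mutant_down:vhl-1": False}]
        )
        out = cross_reference(self._ann(["g1"]), labels)
        assert out["hif1_positive"] == ["g1"]

    def test_gene_may_appear_in_multiple_rows(self):
        labels = self._labels(
            [{"gene": "g1", "hif1_positive": False, "hif1_negative": False,
              "mutant_up:vhl-1": True, "mutant_down:egl-9": True}]
        )
        out = cross_reference(self._ann(["g1"]), labels)
        assert out["mutant_up"] == ["g1"] and out["mutant_down"] == ["g1"]

    def test_unlabeled_gene_falls_through(self):
        labels = self._labels(
            [{"gene": "g1", "hif1_positive": False, "hif1_negative": False}]
        )
        out = cross_reference(self._ann(["g1"]), labels)
        assert out["unlabeled"] == ["g1"]

    def test_empty_region_list_gives_empty_rows(self):
        labels = self._labels([{"gene": "g1", "hif1_positive": True}])
        out = cross_reference([], labels)
        assert all(v == [] for v in out.values())
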