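import pysam
import pytest
from Bio.Seq import reverse_complement

from guidescout import variants as vs
from guidescout.mapping import (MapCounts, ReferenceGenome, build_index,
                                count_hits, map_variants, write_sam)
from guidescout.synthetic import PlantSpec, make_synthetic_genome
from guidescout.variants import VariantRecord

from conftest import naive_hits, random_guide


def _center(guide, pam, parent="f1"):
    return VariantRecord(parent, vs.SUBSTITUTION, guide, (), pam=pam,
                         hamming_distance=0)


class TestIndex:
    def test_overlapping_occurrences_all_reported(self):
        idx = build_index(ReferenceGenome({"c": "ACGT" * 10}))
        hits = [h for h in idx.search(["ACGTACGT"]) if h[3] == "+"]
        assert sorted(h[2] for h in hits) == [4 * i for i in range(9)]

    def test_absent_pattern_yields_nothing(self):
        idx = build_index(ReferenceGenome({"c": "A" * 100}))
        assert idx.search(["ACGTACGTAC"]) == []

    def test_palindromic_pattern_hits_both_strands(self):
        pat = "ACGCGT"  # its own reverse complement
        assert reverse_complement(pat) == pat
        idx = build_index(ReferenceGenome({"c": "TTTT" + pat + "TTTT"}))
        assert sorted(idx.search([pat])) == [(pat, "c", 4, "+"),
                                             (pat, "c", 4, "-")]

    def test_n_in_genome_never_matches(self):
        idx = build_index(ReferenceGenome({"c": "ACGTNACGT"}))
        assert idx.search(["GTNAC"]) == []

    def test_empty_genome_is_an_error(self):
        with pytest.raises(ValueError):
            ReferenceGenome({})


class TestMapVariants:
    def test_planted_substitution_site_recovered(self):
        guide = "ATGCGTCATCAGACGTAGTC"
        plant = PlantSpec(guide, "substitution",
                          (("S", 2, "A"), ("S", 15, "T")), "TAG", "chr1", 400)
        genome, truth = make_synthetic_genome(3, 1200, [plant])
        idx = build_index(ReferenceGenome(genome))
        variants = vs.expand_pams(vs.enumerate_substitutions(guide, 2))
        hits = map_variants(variants, idx)
        assert len(hits) == 1
        h = hits[0]
        assert (h.contig, h.pos, h.strand) == ("chr1", 400, "+")
        assert h.variant.scheme == vs.SUBSTITUTION and not h.is_on_target

    def test_no_planted_sites_means_no_hits(self):
        guide = "ATGCGTCATCAGACGTAGTC"
        genome, _ = make_synthetic_genome(4, 1000, [])
        idx = build_index(ReferenceGenome(genome))
        hits = map_variants(
            vs.expand_pams(vs.enumerate_deletions(guide, 1)), idx)
        oracle = [loc for v in vs.expand_pams(vs.enumerate_deletions(guide, 1))
                  for loc in naive_hits(genome, v.full_site)]
        assert [(h.contig, h.pos, h.strand) for h in hits] == sorted(oracle)

    def test_design_locus_is_flagged_on_target(self):
        guide = "ATGCGTCATCAGACGTAGTC"
        plant = PlantSpec(guide, "substitution", (), "AGG", "chr1", 300)
        genome, _ = make_synthetic_genome(5, 900, [plant])
        idx = build_index(ReferenceGenome(genome))
        hits = map_variants(vs.expand_pams([_center(guide, "")]), idx)
        assert len(hits) == 1 and hits[0].is_on_target

    def test_distance_zero_with_nag_pam_is_not_on_target(self):
        guide = "ATGCGTCATCAGACGTAGTC"
        plant = PlantSpec(guide, "substitution", (), "TAG", "chr1", 300)
        genome, _ = make_synthetic_genome(6, 900, [plant])
        idx = build_index(ReferenceGenome(genome))
        hits = map_variants(vs.expand_pams([_center(guide, "")]), idx)
        assert len(hits) == 1 and not hits[0].is_on_target

    def test_reverse_plant_reported_on_minus_strand(self):
        guide = "ATGCGTCATCAGACGTAGTC"
        plant = PlantSpec(guide, "deletion", (("D", 7, ""),), "CGG",
                          "chr1", 500, "-")
        genome, _ = make_synthetic_genome(7, 1500, [plant])
        idx = build_index(ReferenceGenome(genome))
        hits = map_variants(
            vs.expand_pams(vs.enumerate_deletions(guide, 1)), idx)
        assert [(h.contig, h.pos, h.strand) for h in hits] == [("chr1", 500, "-")]

    def test_strand_involution(self, rng):
        """Mapping against the reverse-complemented genome swaps strands
        and mirrors coordinates."""
        guide = random_guide(rng)
        plant = PlantSpec(guide, "substitution", (("S", 5, "A"),), "AGG",
                          "chr1", 200)
        genome, _ = make_synthetic_genome(8, 800, [plant])
        flipped = {"chr1": reverse_complement(genome["chr1"])}
        variants = list(vs.expand_pams(vs.enumerate_substitutions(guide, 1)))
        fwd = map_variants(variants, build_index(ReferenceGenome(genome)))
        rev = map_variants(variants, build_index(ReferenceGenome(flipped)))
        L = len(genome["chr1"])
        mirrored = sorted(
            ("chr1", L - h.pos - len(h.variant.full_site),
             "+" if h.strand == "-" else "-") for h in fwd)
        assert sorted((h.contig, h.pos, h.strand) for h in rev) == mirrored

    def test_oracle_equivalence_on_random_fixture(self, rng):
        guide = random_guide(rng)
        genome, _ = make_synthetic_genome(9, 4000, [])
        variants = list(vs.expand_pams(vs.enumerate_insertions(guide, 1)))
        hits = map_variants(variants, build_index(ReferenceGenome(genome)))
        got = sorted((h.variant.full_site, h.contig, h.pos, h.strand)
                     for h in hits)
        want = sorted((v.full_site, c, p, s) for v in variants
                      for c, p, s in naive_hits(genome, v.full_site))
        assert got == want


class TestCountHits:
    def test_empty(self):
        assert count_hits([]) == MapCounts(0, 0, 0, 0)

    def test_fixture_truth_table(self):
        guide = "ATGCGTCATCAGACGTAGTC"
        plants = [
            PlantSpec(guide, "substitution", (), "AGG", "chr1", 100),
            PlantSpec(guide, "substitution", (("S", 1, "G"),), "TGG", "chr1", 300),
            PlantSpec(guide, "substitution", (("S", 2, "T"),), "AAG", "chr1", 500),
            PlantSpec(guide, "substitution", (("S", 3, "A"), ("S", 8, "G")),
                      "CAG", "chr1", 700),
            PlantSpec(guide, "deletion", (("D", 10, ""),), "GGG", "chr1", 900),
        ]
        genome, _ = make_synthetic_genome(10, 1400, plants)
        idx = build_index(ReferenceGenome(genome))
        stream = list(vs.expand_pams(vs.enumerate_substitutions(guide, 2))) + \
            list(vs.expand_pams(vs.enumerate_deletions(guide, 1)))
        counts = count_hits(map_variants(stream, idx))
        # 3 planted substitution off-targets + >=1 deletion locus + design locus
        assert counts.subs == 3
        assert counts.on_target == 1
        assert counts.dels >= 1
        assert counts.ins == 0

    def test_one_variant_at_two_loci_contributes_two(self):
        guide = "ATGCGTCATCAGACGTAGTC"
        v = VariantRecord("f1", vs.DELETION, guide[:5] + guide[6:],
                          (("D", 5, ""),), pam="AGG")
        plants = [PlantSpec(guide, "deletion", (("D", 5, ""),), "AGG", "chr1", p)
                  for p in (100, 400)]
        genome, _ = make_synthetic_genome(11, 800, plants)
        hits = map_variants([v], build_index(ReferenceGenome(genome)))
        assert count_hits(hits).dels == 2


class TestWriteSam:
    def test_header_only_for_zero_hits(self, tmp_path):
        genome = ReferenceGenome({"chr1": "ACGT" * 50})
        path = tmp_path / "empty.sam"
        write_sam([], genome, path)
        with pysam.AlignmentFile(str(path), "r") as sam:
            assert sam.header.lengths == (200,)
            assert list(sam) == []

    def test_coordinates_flags_and_seq_roundtrip(self, tmp_path):
        guide = "ATGCGTCATCAGACGTAGTC"
        fwd = PlantSpec(guide, "substitution", (), "AGG", "chr1", 7)
        rev = PlantSpec(guide, "substitution", (("S", 4, "A"),), "TGG",
                        "chr1", 60, "-")
        genome, _ = make_synthetic_genome(12, 120, [fwd, rev])
        ref = ReferenceGenome(genome)
        hits = map_variants(
            vs.expand_pams(vs.enumerate_substitutions(guide, 1)),
            build_index(ref))
        path = tmp_path / "hits.sam"
        write_sam(hits, ref, path)
        with pysam.AlignmentFile(str(path), "r") as sam:
            reads = list(sam)
        assert len(reads) == 2
        by_flag = {r.flag: r for r in reads}
        assert by_flag[0].reference_start == 7          # 0-based back-translation
        assert by_flag[0].pos + 1 == 8                  # POS written 1-based
        assert by_flag[16].reference_start == 60
        for r in reads:
            # SEQ equals the forward reference slice at the reported locus
            assert r.query_sequence == \
                genome["chr1"][r.reference_start:r.reference_start + 23]
            assert r.cigarstring == "23M"
            assert r.get_tag("NM") == 0
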