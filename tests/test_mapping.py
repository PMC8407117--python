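"""K-mer localization and CDS/regulatory/intergenic classification."""

import numpy as np
import pandas as pd
import pytest

from rhizokmer.annotation import Gene, GenomeAnnotation, Replicon
from rhizokmer.kmers import canonicalize
from rhizokmer.mapping import (KmerOccurrence, carrier_exclusive_region,
                               classify_hit, classify_hits, locate_kmers,
                               revcomp, summarize_hits)

KMER = "ACGGATTACCAGT"  # no internal repeat, not palindromic


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def annotation_one_gene(replicon="rep", length=20_000, start=10_000,
                        end=10_900, strand="+", **kw):
    gene = Gene(replicon=replicon, start=start, end=end, strand=strand,
                locus_tag=kw.pop("locus_tag", "g1"), **kw)
    return GenomeAnnotation(
        strain="S", replicons={replicon: Replicon(replicon, length, "other")},
        genes=[gene])


class TestLocate:
    def test_planted_position(self, rng):
        seq = random_seq(rng, 500)
        seq = seq[:100] + KMER + seq[100:]
        occ = locate_kmers([KMER], {"S": {"rep": seq}})
        canon = canonicalize(KMER)
        forward = KMER == canon
        hits = [o for o in occ if o.position == 101]
        assert len(hits) == 1
        assert hits[0].strand == ("+" if forward else "-")

    def test_reverse_complement_found(self, rng):
        seq = random_seq(rng, 300) + revcomp(KMER) + random_seq(rng, 300)
        occ = locate_kmers([KMER], {"S": {"rep": seq}})
        assert len(occ) == 1
        assert occ[0].position == 301

    def test_overlapping_occurrences_all_reported(self):
        homopolymer = "A" * 20
        occ = locate_kmers(["A" * 13], {"S": {"rep": homopolymer}})
        assert [o.position for o in occ] == list(range(1, 9))

    def test_matches_brute_force(self, rng):
        genomes = {f"S{i}": {"rep": random_seq(rng, 5000)}
                   for i in range(4)}
        kmers = {canonicalize(random_seq(rng, 13)) for _ in range(50)}
        got = {(o.strain, o.replicon, o.position, o.kmer, o.strand)
               for o in locate_kmers(kmers, genomes)}
        want = set()
        for s, reps in genomes.items():
            for rid, seq in reps.items():
                for km in kmers:
                    rc = revcomp(km)
                    for i in range(len(seq) - 12):
                        if seq[i:i + 13] == km:
                            want.add((s, rid, i + 1, km, "+"))
                        elif seq[i:i + 13] == rc:
                            want.add((s, rid, i + 1, km, "-"))
        assert got == want


class TestClassify:
    def occurrence(self, pos):
        return KmerOccurrence(kmer=KMER, strain="S", replicon="rep",
                              position=pos, strand="+")

    def test_match_inside_gene_is_cds(self):
        ann = annotation_one_gene()
        rows = classify_hit(self.occurrence(10_400), ann)
        assert [r.context for r in rows] == ["CDS"]
        assert rows[0].locus_tag == "g1"

    def test_upstream_588_is_regulatory(self):
        ann = annotation_one_gene()
        rows = classify_hit(self.occurrence(9_400), ann)
        assert [r.context for r in rows] == ["regulatory"]
        assert rows[0].distance_to_start == 588

    def test_beyond_600_is_intergenic(self):
        ann = annotation_one_gene()
        rows = classify_hit(self.occurrence(9_387), ann)
        assert [r.context for r in rows] == ["intergenic"]
        assert rows[0].locus_tag is None

    def test_window_boundary_distance_600(self):
        ann = annotation_one_gene()
        # match ends exactly at start - 600 = 9400
        rows = classify_hit(self.occurrence(9_388), ann)
        assert rows[0].context == "regulatory"
        assert rows[0].distance_to_start == 600

    def test_minus_strand_window_is_downstream_in_coordinates(self):
        ann = annotation_one_gene(strand="-")
        rows = classify_hit(self.occurrence(11_000), ann)
        assert rows[0].context == "regulatory"
        assert rows[0].distance_to_start == 100

    def test_cds_precedence_over_regulatory(self):
        # match overlaps the gene start: CDS wins, no regulatory row
        ann = annotation_one_gene()
        rows = classify_hit(self.occurrence(9_995), ann)
        assert [r.context for r in rows] == ["CDS"]

    def test_one_kmer_tags_two_genes(self):
        genes = [Gene("rep", 100, 205, "+", "g1"),
                 Gene("rep", 206, 300, "+", "g2")]
        ann = GenomeAnnotation(
            strain="S", replicons={"rep": Replicon("rep", 1000, "other")},
            genes=genes)
        rows = classify_hit(
            KmerOccurrence(KMER, "S", "rep", 200, "+"), ann)
        assert sorted(r.locus_tag for r in rows) == ["g1", "g2"]

    def test_window_truncated_at_replicon_start(self):
        ann = annotation_one_gene(start=50, end=400)
        rows = classify_hit(self.occurrence(10), ann)
        assert rows[0].context == "regulatory"
        assert 1 <= rows[0].distance_to_start <= 600

    def test_strand_symmetry_of_classification(self, rng):
        length = 3000
        seq = random_seq(rng, length)
        seq = seq[:1500] + KMER + seq[1500 + 13:]
        gene = Gene("rep", 1700, 2200, "+", "g1")
        ann = GenomeAnnotation(
            strain="S", replicons={"rep": Replicon("rep", length, "other")},
            genes=[gene])
        flipped_seq = revcomp(seq)
        flipped_gene = Gene("rep", length - 2200 + 1, length - 1700 + 1,
                            "-", "g1")
        flipped = GenomeAnnotation(
            strain="S", replicons={"rep": Replicon("rep", length, "other")},
            genes=[flipped_gene])
        def signatures(genome, ann):
            occ = locate_kmers([KMER], {"S": {"rep": genome}})
            return sorted((r.kmer, r.locus_tag, r.context)
                          for o in occ for r in classify_hit(o, ann))
        assert signatures(seq, ann) == signatures(flipped_seq, flipped)


class TestSummarize:
    def make_hits(self):
        anns = {
            "S1": GenomeAnnotation(
                strain="S1",
                replicons={"S1_pSymA": Replicon("S1_pSymA", 10_000,
                                                "pSymA-like")},
                genes=[Gene("S1_pSymA", 100, 400, "+", "g1",
                            cog_id="COG1529", ortholog_group="OG1"),
                       Gene("S1_pSymA", 500, 900, "+", "g2")]),
        }
        hits = classify_hits(
            [KmerOccurrence(KMER, "S1", "S1_pSymA", 150, "+"),
             KmerOccurrence(KMER, "S1", "S1_pSymA", 600, "+")], anns)
        return hits, anns

    def test_counts_and_unannotated_bucket(self):
        hits, anns = self.make_hits()
        s = summarize_hits(hits, anns)
        assert s.cds_by_cog.loc["S1", "COG1529"] == 1
        assert s.unannotated_cds["S1"] == 1
        assert s.replicon_fractions.loc["S1", "pSymA-like"] == 1.0

    def test_ortholog_fraction_only_counts_ortholog_hits(self):
        hits, anns = self.make_hits()
        s = summarize_hits(hits, anns)
        assert s.ortholog_replicon_fractions.loc["S1", "pSymA-like"] == 1.0

    def test_empty_hits_rejected(self):
        _, anns = self.make_hits()
        with pytest.raises(ValueError, match="empty"):
            summarize_hits(pd.DataFrame(), anns)

    def test_core_flags_from_presence_table(self):
        hits, anns = self.make_hits()
        presence = pd.DataFrame({"S1": [1, 1], "S2": [1, 0]},
                                index=["OGcore", "OG1"])
        s = summarize_hits(hits, anns, gene_presence=presence)
        assert bool(s.core_flags["OGcore"]) is True
        assert bool(s.core_flags["OG1"]) is False


class TestExclusiveRegions:
    def make(self, positions, strains=("S1", "S2")):
        anns = {}
        rows = []
        for s in ("S1", "S2", "S3"):
            genes = []
            if s in strains:
                genes = [Gene(f"{s}_rep", 1, 100, "+", f"{s}_g",
                              ortholog_group="OGx")]
            anns[s] = GenomeAnnotation(
                strain=s,
                replicons={f"{s}_rep": Replicon(f"{s}_rep", 100_000,
                                                "other")},
                genes=genes)
        for s in strains:
            for p in positions:
                rows.append({"kmer": KMER, "strain": s,
                             "replicon": f"{s}_rep", "position": p,
                             "strand": "+", "context": "CDS",
                             "locus_tag": f"{s}_g", "cog_id": None,
                             "ortholog_group": "OGx",
                             "distance_to_start": None})
        return pd.DataFrame(rows), anns

    def test_exclusive_region_reported_per_carrier(self):
        hits, anns = self.make([10, 500, 900])
        regions = carrier_exclusive_region(hits, anns, {"S1", "S2"})
        assert len(regions) == 2
        assert {r["strain"] for r in regions} == {"S1", "S2"}
        assert regions[0]["ortholog_groups"] == ["OGx"]

    def test_gap_rule_splits_regions(self):
        hits, anns = self.make([10, 20_000])
        regions = carrier_exclusive_region(hits, anns, {"S1", "S2"},
                                           gap=5_000)
        assert len(regions) == 4  # two clusters per carrier

    def test_full_panel_carrier_set_yields_nothing(self):
        hits, anns = self.make([10], strains=("S1", "S2", "S3"))
        assert carrier_exclusive_region(hits, anns,
                                        {"S1", "S2", "S3"}) == []

    def test_wrong_carrier_set_yields_nothing(self):
        hits, anns = self.make([10])
        assert carrier_exclusive_region(hits, anns, {"S1", "S3"}) == []
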