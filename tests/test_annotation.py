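"""Feature/landscape classification, TSS profiles, gene mapping, parsers."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_sitemap
from hydroxyscan.annotate import (
    GeneModelError,
    GeneModels,
    Transcript,
    classify_feature,
    classify_landscape,
    map_sites_to_genes,
    nearest_tss_distance,
    tss_profile,
)


class TestClassifyFeature:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (501, "promoter"),    # 500 bp upstream of the TSS at 1001
            (1050, "utr5"),       # exonic, left of CDS start on + strand
            (1200, "exon"),       # CDS exon
            (1600, "intron"),
            (2950, "utr3"),       # exonic, right of CDS end
            (5000, "intergenic"),
            (1000, "promoter"),   # last base before the TSS
            (1, "promoter"),      # exactly promoter_span upstream
        ],
    )
    def test_forward_strand(self, forward_transcript, pos, expected):
        models = GeneModels([forward_transcript])
        sm = make_sitemap([("chr1", pos)])
        assert classify_feature(sm, models).iloc[0] == expected

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (3500, "promoter"),   # upstream on the - strand is to the right
            (2950, "utr5"),
            (1050, "utr3"),
            (1500, "exon"),
            (2200, "intron"),
            (4001, "intergenic"),  # just beyond the 1 kb promoter span
        ],
    )
    def test_reverse_strand(self, reverse_transcript, pos, expected):
        models = GeneModels([reverse_transcript])
        sm = make_sitemap([("chr2", pos)])
        assert classify_feature(sm, models).iloc[0] == expected

    def test_utr_precedence_over_exon(self, forward_transcript):
        # the 3' UTR interval is also exonic; precedence keeps utr3
        models = GeneModels([forward_transcript])
        assert classify_feature(make_sitemap([("chr1", 2990)]), models).iloc[0] == "utr3"

    def test_genic_context_beats_other_genes_promoter(self, forward_transcript):
        other = Transcript("T9.1", "G9", "chr1", "-", 100, 500, [(100, 500)], None)
        # promoter of the - strand gene covers 501-1500, overlapping T1's utr5
        models = GeneModels([forward_transcript, other])
        assert classify_feature(make_sitemap([("chr1", 1050)]), models).iloc[0] == "utr5"

    def test_invalid_transcript_rejected(self):
        with pytest.raises(GeneModelError):
            Transcript("T", "G", "chr1", "+", 100, 50)

    def test_feature_classes_partition_sites(self, small_sitemap, small_genome):
        _, _, tx = small_genome
        feat = classify_feature(small_sitemap, GeneModels(tx))
        assert feat.value_counts().sum() == len(small_sitemap)


class TestClassifyLandscape:
    cgi = {"chr1": [(10_000, 12_000)]}

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (11_000, "island"),
            (10_000, "island"),
            (13_500, "shore"),    # 1,500 bp from the island edge
            (8_000, "shore"),     # 2,000 bp exactly
            (15_000, "shelf"),    # 3,000 bp
            (16_000, "shelf"),    # 4,000 bp exactly
            (17_000, "open_sea"), # 5,000 bp
        ],
    )
    def test_distance_classes(self, pos, expected):
        sm = make_sitemap([("chr1", pos)])
        assert classify_landscape(sm, self.cgi).iloc[0] == expected

    def test_no_cgi_chromosome_is_open_sea(self):
        sm = make_sitemap([("chr9", 100)])
        assert classify_landscape(sm, self.cgi).iloc[0] == "open_sea"

    def test_invalid_spans_rejected(self):
        with pytest.raises(ValueError):
            classify_landscape(make_sitemap([("chr1", 1)]), self.cgi, 4000, 2000)

    def test_landscape_classes_partition_sites(self, small_sitemap, small_genome):
        _, cgis, _ = small_genome
        ls = classify_landscape(small_sitemap, cgis)
        assert ls.value_counts().sum() == len(small_sitemap)


class TestTssProfile:
    def test_forward_site_bin(self, forward_transcript):
        # TSS at 1001; site at 981 -> signed distance -20 -> bin [-50, 0)
        models = GeneModels([forward_transcript])
        prof = tss_profile(make_sitemap([("chr1", 981)]), models)
        assert len(prof) == 40
        hit = prof[prof["n_sites"] > 0]
        assert list(hit["bin_start"]) == [-50]

    def test_reverse_site_bin(self, reverse_transcript):
        # TSS at 3000 on -; site at 3020 -> distance -20 -> bin [-50, 0)
        models = GeneModels([reverse_transcript])
        prof = tss_profile(make_sitemap([("chr2", 3020)]), models)
        assert list(prof[prof["n_sites"] > 0]["bin_start"]) == [-50]

    def test_site_outside_window_contributes_nothing(self, forward_transcript):
        models = GeneModels([forward_transcript])
        prof = tss_profile(make_sitemap([("chr1", 2201)]), models)  # 1200 bp away
        assert prof["n_sites"].sum() == 0

    def test_bin_must_divide_window(self, forward_transcript):
        with pytest.raises(ValueError):
            tss_profile(make_sitemap([("chr1", 981)]), GeneModels([forward_transcript]), bin_size=30)

    def test_brute_force_pair_count(self, small_sitemap, small_genome):
        _, _, tx = small_genome
        prof = tss_profile(small_sitemap, GeneModels(tx))
        pairs = 0
        for t in tx:
            for _, pos in small_sitemap.entries[
                small_sitemap.entries["chrom"] == t.chrom
            ].itertuples(index=False):
                d = (pos - t.tss) * (1 if t.strand == "+" else -1)
                if -1000 <= d < 1000:
                    pairs += 1
        assert prof["n_sites"].sum() == pairs

    def test_summed_counts_track(self, forward_transcript):
        models = GeneModels([forward_transcript])
        sm = make_sitemap([("chr1", 981), ("chr1", 1101)])
        counts = pd.DataFrame(
            {"s1": [3.0, 5.0], "s2": [1.0, 2.0]}, index=sm.keys
        )
        prof = tss_profile(sm, models, counts=counts)
        assert prof.loc[prof["bin_start"] == -50, "summed_counts"].iloc[0] == 4.0
        assert prof.loc[prof["bin_start"] == 100, "summed_counts"].iloc[0] == 7.0


class TestMapSitesToGenes:
    def test_hand_drawn_overlaps(self):
        t1 = Transcript("A.1", "A", "chr1", "+", 1000, 2000, [(1000, 2000)], None)
        t2 = Transcript("B.1", "B", "chr1", "+", 1500, 2500, [(1500, 2500)], None)
        t3 = Transcript("C.1", "C", "chr1", "-", 4000, 5000, [(4000, 5000)], None)
        models = GeneModels([t1, t2, t3])
        sm = make_sitemap(
            [("chr1", p) for p in (1100, 1600, 1700, 1800, 2400, 4500, 5500, 9000, 300, 250)]
        )
        res = map_sites_to_genes(sm, models)
        counts = dict(zip(res["genes"]["gene_id"], res["genes"]["n_sites"]))
        # A body+promoter covers 1-2000 (6 sites); B covers 500-2500 (5 sites
        # incl. 1100 in its promoter); C (- strand) covers 4000-6000 (2 sites)
        assert counts == {"A": 6, "B": 5, "C": 2}
        assert res["site_genes"].loc["chr1:1600"] == "A,B"

    def test_three_sites_one_gene(self):
        t = Transcript("A.1", "A", "chr1", "+", 1000, 2000, [(1000, 2000)], None)
        sm = make_sitemap([("chr1", p) for p in (1100, 1200, 1300)])
        res = map_sites_to_genes(sm, GeneModels([t]))
        assert res["genes"].iloc[0].tolist() == ["A", 3]

    def test_risk_gene_intersection(self):
        t = Transcript("A.1", "A", "chr1", "+", 1000, 2000, [(1000, 2000)], None)
        res = map_sites_to_genes(
            make_sitemap([("chr1", 1100)]), GeneModels([t]), gene_list=["A", "Z"]
        )
        assert list(res["intersection"]["gene_id"]) == ["A"]


class TestParsers:
    GTF = """\
chr1\tsrc\ttranscript\t1001\t3000\t.\t+\t.\tgene_id "G1"; transcript_id "T1.1";
chr1\tsrc\texon\t1001\t1500\t.\t+\t.\tgene_id "G1"; transcript_id "T1.1";
chr1\tsrc\texon\t2001\t3000\t.\t+\t.\tgene_id "G1"; transcript_id "T1.1";
chr1\tsrc\tCDS\t1101\t1500\t.\t+\t.\tgene_id "G1"; transcript_id "T1.1";
chr1\tsrc\tCDS\t2001\t2900\t.\t+\t.\tgene_id "G1"; transcript_id "T1.1";
"""

    def test_gtf_parse(self, tmp_path, forward_transcript):
        p = tmp_path / "g.gtf"
        p.write_text(self.GTF)
        models = GeneModels.from_gtf(p)
        t = models.transcripts[0]
        ref = forward_transcript
        assert (t.chrom, t.strand, t.start, t.end, t.exons, t.cds) == (
            ref.chrom, ref.strand, ref.start, ref.end, ref.exons, ref.cds
        )

    def test_bed12_parse_matches_gtf(self, tmp_path, forward_transcript):
        # same transcript as BED12 (0-based half-open, thick = CDS span)
        line = "chr1\t1000\t3000\tT1.1\t0\t+\t1100\t2900\t0\t2\t500,1000\t0,1000\n"
        p = tmp_path / "g.bed"
        p.write_text(line)
        t = GeneModels.from_bed12(p).transcripts[0]
        ref = forward_transcript
        assert (t.start, t.end, t.exons, t.cds, t.strand) == (
            ref.start, ref.end, ref.exons, ref.cds, ref.strand
        )


def test_nearest_tss_signed_distance(forward_transcript, reverse_transcript):
    models = GeneModels([forward_transcript])
    d = nearest_tss_distance(make_sitemap([("chr1", 981), ("chr1", 1101)]), models)
    assert list(d) == [-20, 100]
    d2 = nearest_tss_distance(make_sitemap([("chr2", 3020)]), GeneModels([reverse_transcript]))
    assert list(d2) == [-20]
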