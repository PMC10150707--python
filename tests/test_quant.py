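"""Read filtering, trimming, exact placement, counting and SAM/BED import."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydroxyscan.digest import SiteMap, find_ccgg_sites
from hydroxyscan.quant import (
    FastqRead,
    ReadFilterParams,
    SiteIndexError,
    count_sites,
    filter_and_trim,
    import_alignments,
    place_reads,
    revcomp,
)

HIQ = "I"  # Phred 40
LOQ = "#"  # Phred 2


def read(seq, qual=None, name="r"):
    return FastqRead(name, seq, qual or HIQ * len(seq))


class TestFilterAndTrim:
    def test_boundary_length_kept(self):
        r = read("CCGG" + "A" * 31)  # 35 nt, no trailing CG
        kept, rep = filter_and_trim([r])
        assert rep.kept == 1 and kept[0].seq == r.seq

    def test_no_p5_motif_dropped(self):
        _, rep = filter_and_trim([read("ACGG" + "A" * 40)])
        assert rep.dropped_no_p5 == 1 and rep.kept == 0

    def test_adapter_trim_below_min_length_dropped(self):
        r = read("CCGG" + "A" * 30 + "CG")  # 36 nt -> 34 after CG removal
        kept, rep = filter_and_trim([r])
        assert rep.dropped_too_short == 1 and not kept

    def test_low_quality_tail_trimmed(self):
        seq = "CCGG" + "A" * 40
        qual = HIQ * 38 + LOQ * 6
        kept, rep = filter_and_trim([read(seq, qual)])
        assert rep.kept == 1
        assert kept[0].seq == seq[:38]

    def test_quality_trim_can_drop_read(self):
        seq = "CCGG" + "A" * 40
        qual = HIQ * 20 + LOQ * 24
        _, rep = filter_and_trim([read(seq, qual)])
        assert rep.dropped_too_short == 1

    @given(
        st.lists(
            st.tuples(st.text("ACGT", min_size=1, max_size=60), st.booleans()),
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_kept_plus_dropped_equals_total(self, specs):
        reads = [
            read(("CCGG" if prefix else "AAAA") + seq, name=f"r{i}")
            for i, (seq, prefix) in enumerate(specs)
        ]
        kept, rep = filter_and_trim(reads)
        assert rep.kept + rep.dropped_no_p5 + rep.dropped_too_short == rep.total == len(reads)
        assert len(kept) == rep.kept

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            FastqRead("r", "CCGGA", "II")


class TestPlaceReads:
    genome = {"c": "A" * 40 + "CCGG" + "TTACGTTACGATCCATTGACGTACCTGAGGTT" + "A" * 40}
    # single site at 1-based position 41

    def sitemap(self):
        return find_ccgg_sites(self.genome)

    def test_forward_exact_match_assigned(self):
        sm = self.sitemap()
        r = read(self.genome["c"][40:76])
        res = place_reads([r], sm, self.genome)
        assert res.counts[0] == 1 and res.n_assigned == 1

    def test_internal_mismatch_unassigned(self):
        sm = self.sitemap()
        seq = self.genome["c"][40:76]
        seq = seq[:20] + ("A" if seq[20] != "A" else "C") + seq[21:]
        res = place_reads([read(seq)], sm, self.genome)
        assert res.counts[0] == 0 and res.n_unassigned == 1

    def test_reverse_fragment_assigned_to_same_site(self):
        sm = self.sitemap()
        seq = revcomp(self.genome["c"][8:44])  # ends at motif end (pos 44)
        assert seq.startswith("CCGG")
        res = place_reads([read(seq)], sm, self.genome)
        assert res.counts[0] == 1

    def test_repeated_fragment_counted_ambiguous(self):
        frag = "CCGG" + "TTACGTTACGATCCATTGACGTACCTGAGGTTCCAA"
        genome = {"c": "A" * 20 + frag + "T" * 30 + frag + "A" * 20}
        sm = find_ccgg_sites(genome)
        res = place_reads([read(frag[:36])], sm, genome)
        assert res.n_ambiguous == 1 and res.counts.sum() == 0

    def test_read_order_invariance(self, small_genome, small_sitemap):
        seqs, _, _ = small_genome
        from hydroxyscan.simulate import simulate_reads

        lv = np.full((len(small_sitemap), 1), 0.4)
        reads, _ = simulate_reads(seqs, small_sitemap, lv, ["A"], depth=3.0, seed=5)
        kept, _ = filter_and_trim(reads["A"])
        fwd = place_reads(kept, small_sitemap, seqs)
        rev = place_reads(kept[::-1], small_sitemap, seqs)
        assert np.array_equal(fwd.counts, rev.counts)

    def test_inconsistent_sitemap_raises(self):
        sm = SiteMap(entries=pd.DataFrame({"chrom": ["c"], "pos": [3]}))
        with pytest.raises(SiteIndexError):
            place_reads([read("CCGG" + "A" * 31)], sm, self.genome)


class TestCountSites:
    def test_counts_and_zero_sites_retained(self):
        sm = SiteMap(entries=pd.DataFrame({"chrom": ["c", "c"], "pos": [1, 50]}))
        scm = count_sites({"s1": np.array([3, 0])}, sm)
        assert scm.counts.loc["c:1", "s1"] == 3
        assert scm.counts.loc["c:50", "s1"] == 0
        assert scm.library_sizes["s1"] == 3

    def test_disjoint_sites_block_matrix(self):
        sm = SiteMap(entries=pd.DataFrame({"chrom": ["c", "c"], "pos": [1, 50]}))
        scm = count_sites({"a": np.array([2, 0]), "b": np.array([0, 5])}, sm)
        assert scm.counts.to_numpy().tolist() == [[2, 0], [0, 5]]

    def test_simulator_bookkeeping_recovered_exactly(self, small_genome, small_sitemap):
        seqs, _, _ = small_genome
        from hydroxyscan.simulate import simulate_reads

        lv = np.tile(np.linspace(0, 1, len(small_sitemap))[:, None], (1, 2))
        reads, log = simulate_reads(seqs, small_sitemap, lv, ["A", "B"], depth=5.0, seed=7)
        placements = {
            s: place_reads(filter_and_trim(reads[s])[0], small_sitemap, seqs)
            for s in ("A", "B")
        }
        scm = count_sites(placements, small_sitemap)
        for s in ("A", "B"):
            assert np.array_equal(scm.counts[s].to_numpy(), log["site_counts"][s])


SAM_TEMPLATE = """\
@HD\tVN:1.6\tSO:unknown
@SQ\tSN:{chrom}\tLN:{length}
"""


def write_sam(path, chrom, length, records):
    with open(path, "w") as fh:
        fh.write(SAM_TEMPLATE.format(chrom=chrom, length=length))
        for name, flag, pos, seq in records:
            fh.write(
                f"{name}\t{flag}\t{chrom}\t{pos}\t60\t{len(seq)}M\t*\t0\t0\t{seq}\t{'I' * len(seq)}\n"
            )


class TestImportAlignments:
    genome = {"c": "A" * 40 + "CCGG" + "T" * 60 + "CCGG" + "G" * 40}
    # sites at 41 and 105

    def test_sam_forward_reverse_and_offsite(self, tmp_path):
        sm = find_ccgg_sites(self.genome)
        seq20 = "C" * 20
        records = [("f%d" % i, 0, 41, seq20) for i in range(4)]          # on site 41
        records += [("r%d" % i, 16, 89, seq20) for i in range(3)]        # end 108 -> site 105
        records += [("x%d" % i, 0, 10, seq20) for i in range(3)]         # off-site
        sam = tmp_path / "aln.sam"
        write_sam(sam, "c", len(self.genome["c"]), records)
        scm = import_alignments(sam, sm, sample="s1")
        assert scm.counts.loc["c:41", "s1"] == 4
        assert scm.counts.loc["c:105", "s1"] == 3
        assert scm.library_sizes["s1"] == 7

    def test_unknown_chromosome_skipped_with_warning(self, tmp_path):
        sm = find_ccgg_sites(self.genome)
        sam = tmp_path / "aln.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:c\tLN:148\n@SQ\tSN:other\tLN:100\n")
            fh.write("a\t0\tother\t5\t60\t10M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII\n")
            fh.write("b\t0\tc\t41\t60\t10M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII\n")
        with pytest.warns(UserWarning, match="unknown chromosome"):
            scm = import_alignments(sam, sm, sample="s1")
        assert scm.library_sizes["s1"] == 1

    def test_bed_import_strand_resolution(self, tmp_path):
        sm = find_ccgg_sites(self.genome)
        bed = tmp_path / "aln.bed"
        # forward record starting at site 41; reverse record ending at motif end 108
        bed.write_text("c\t40\t60\tr1\t0\t+\nc\t88\t108\tr2\t0\t-\nc\t0\t20\tr3\t0\t+\n")
        scm = import_alignments(bed, sm, sample="s1")
        assert scm.counts.loc["c:41", "s1"] == 1
        assert scm.counts.loc["c:105", "s1"] == 1
        assert scm.library_sizes["s1"] == 2
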