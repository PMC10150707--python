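"""RRHP read filtering, trimming, placement and site counting.

An RRHP read that begins with the protected CCGG junction reports one 5hmC
site.  The quantification contract here is deliberately exact: a kept read is
assigned to a site only when its sequence matches the reference verbatim from
that site's motif (either fragment orientation); real-data users with an
external aligner go through :func:`import_alignments` instead.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .digest import SiteMap, _as_sequences

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class FastqParseError(ValueError):
    pass


@dataclass
class ReadFilterParams:
    """Protected-site filter and 3' trimming parameters.

    min_length is enforced after adapter and quality trimming; the default 35
    matches the library's minimum informative fragment length.
    """

    p5_motif: str = "CCGG"
    p7_adapter: str = "CG"
    min_length: int = 35
    quality_floor: int = 20

    def __post_init__(self) -> None:
        for name in ("p5_motif", "p7_adapter"):
            v = getattr(self, name)
            if not v or set(v) - set("ACGT"):
                raise ValueError(f"{name} must be a non-empty uppercase ACGT string")
        if self.min_length <= len(self.p5_motif):
            raise ValueError("min_length must exceed the P5 motif length")


@dataclass
class FilterReport:
    total: int = 0
    kept: int = 0
    dropped_no_p5: int = 0
    dropped_too_short: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "kept": self.kept,
            "dropped_no_p5": self.dropped_no_p5,
            "dropped_too_short": self.dropped_too_short,
        }


@dataclass
class FastqRead:
    name: str
    seq: str
    qual: str  # Phred+33

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise FastqParseError(f"read {self.name!r}: sequence/quality length mismatch")


def read_fastq(path) -> Iterable[FastqRead]:
    """Parse a (possibly gzipped) FASTQ file into FastqRead records."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise FastqParseError(f"malformed FASTQ record at index {idx}")
            try:
                yield FastqRead(header[1:].split()[0], seq, qual)
            except FastqParseError as exc:
                raise FastqParseError(f"record {idx}: {exc}") from exc
            idx += 1


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")


def filter_and_trim(
    reads: Iterable[FastqRead], params: ReadFilterParams | None = None
) -> tuple[list[FastqRead], FilterReport]:
    """Keep reads with the 5' protected-site motif; trim 3' adapter/low quality.

    A read survives iff it begins with ``p5_motif`` and, after removing one
    terminal ``p7_adapter`` occurrence and then stripping 3' bases below
    ``quality_floor``, its length is at least ``min_length``.
    """
    params = params or ReadFilterParams()
    report = FilterReport()
    kept: list[FastqRead] = []
    floor = params.quality_floor
    for r in reads:
        report.total += 1
        if not r.seq.startswith(params.p5_motif):
            report.dropped_no_p5 += 1
            continue
        seq, qual = r.seq, r.qual
        if seq.endswith(params.p7_adapter):
            n = len(params.p7_adapter)
            seq, qual = seq[:-n], qual[:-n]
        end = len(seq)
        while end > 0 and (ord(qual[end - 1]) - 33) < floor:
            end -= 1
        seq, qual = seq[:end], qual[:end]
        if len(seq) < params.min_length:
            report.dropped_too_short += 1
            continue
        report.kept += 1
        kept.append(FastqRead(r.name, seq, qual))
    return kept, report


@dataclass
class PlacementResult:
    """Per-site read tallies for one sample plus assignment bookkeeping."""

    counts: np.ndarray  # aligned to the SiteMap
    n_assigned: int = 0
    n_unassigned: int = 0
    n_ambiguous: int = 0


class SiteIndexError(ValueError):
    """SiteMap inconsistent with the genome it claims to describe."""


def place_reads(
    reads: Sequence[FastqRead], sitemap: SiteMap, genome, anchor: int = 20
) -> PlacementResult:
    """Assign filtered reads to sites by exact reference match.

    A read belongs to site s when its sequence equals the reference starting
    at s's motif (forward), or the reverse complement of the reference ending
    at s's motif end (the palindromic other fragment end).  Reads matching
    more than one site are counted as ambiguous and assigned to none.
    """
    seqs = _as_sequences(genome)
    n = len(sitemap)
    counts = np.zeros(n, dtype=np.int64)
    result = PlacementResult(counts=counts)
    if not reads or n == 0:
        result.n_unassigned = len(reads)
        return result

    k = min(anchor, min(len(r.seq) for r in reads))
    index: dict[str, list[tuple[int, int]]] = {}
    chroms = sitemap.entries["chrom"].to_numpy()
    positions = sitemap.entries["pos"].to_numpy()
    for i in range(n):
        chrom, pos = chroms[i], int(positions[i])
        seq = seqs.get(chrom)
        if seq is None or seq[pos - 1 : pos + 3] != "CCGG":
            raise SiteIndexError(f"site {chrom}:{pos} does not sit on a CCGG motif in the genome")
        fwd = seq[pos - 1 : pos - 1 + k]
        if len(fwd) == k:
            index.setdefault(fwd, []).append((i, +1))
        rev = revcomp(seq[max(0, pos + 3 - k) : pos + 3])
        if len(rev) == k:
            index.setdefault(rev, []).append((i, -1))

    for r in reads:
        hits: set[int] = set()
        for i, orient in index.get(r.seq[:k], ()):  # verify full-length match
            chrom, pos = chroms[i], int(positions[i])
            seq = seqs[chrom]
            L = len(r.seq)
            if orient == +1:
                if seq[pos - 1 : pos - 1 + L] == r.seq:
                    hits.add(i)
            else:
                start = pos + 3 - L
                if start >= 0 and revcomp(seq[start : pos + 3]) == r.seq:
                    hits.add(i)
        if len(hits) == 1:
            counts[hits.pop()] += 1
            result.n_assigned += 1
        elif len(hits) > 1:
            result.n_ambiguous += 1
        else:
            result.n_unassigned += 1
    return result


@dataclass
class SiteCountMatrix:
    """Integer read counts, sites x samples, with per-sample library sizes.

    ``counts`` is indexed by ``chrom:pos`` site keys; ``library_sizes``
    defaults to column sums.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None
    sitemap: SiteMap | None = None

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("site").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SiteCountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df)


def count_sites(
    placements: dict[str, PlacementResult | np.ndarray], sitemap: SiteMap
) -> SiteCountMatrix:
    """Assemble per-sample placements into a SiteCountMatrix.

    Sites with zero counts in every sample are retained.
    """
    if not placements:
        raise ValueError("at least one sample required")
    cols = {}
    for sample, pl in placements.items():
        vec = pl.counts if isinstance(pl, PlacementResult) else np.asarray(pl)
        if len(vec) != len(sitemap):
            raise ValueError(f"sample {sample!r}: placement length mismatch with site map")
        cols[str(sample)] = vec
    if len(cols) != len(placements):
        raise ValueError("duplicate sample identifiers")
    counts = pd.DataFrame(cols, index=sitemap.keys)
    return SiteCountMatrix(counts=counts, sitemap=sitemap)


def import_alignments(path, sitemap: SiteMap, sample: str | None = None) -> SiteCountMatrix:
    """Count pre-aligned reads (SAM or 6-column BED) onto the site map.

    A record increments site s iff its 5' motif start coincides with s's
    coordinate: leftmost position for forward-strand records, rightmost
    aligned base minus 3 for reverse-strand records.  Records on unknown
    chromosomes are skipped with a warning; unmapped records are skipped.
    """
    import warnings

    site_lookup = {
        (c, int(p)): i
        for i, (c, p) in enumerate(zip(sitemap.entries["chrom"], sitemap.entries["pos"]))
    }
    known_chroms = set(sitemap.chrom_order)
    counts = np.zeros(len(sitemap), dtype=np.int64)
    name = sample or Path(str(path)).stem

    if str(path).endswith((".sam", ".bam")):
        import pysam

        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                chrom = rec.reference_name
                if chrom not in known_chroms:
                    warnings.warn(f"skipping alignment on unknown chromosome {chrom!r}")
                    continue
                pos = rec.reference_end - 3 if rec.is_reverse else rec.reference_start + 1
                i = site_lookup.get((chrom, pos))
                if i is not None:
                    counts[i] += 1
    else:  # BED: chrom start end [name score strand]
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
        for row in bed.itertuples(index=False):
            chrom = str(row[0])
            if chrom not in known_chroms:
                warnings.warn(f"skipping alignment on unknown chromosome {chrom!r}")
                continue
            strand = row[5] if len(row) > 5 else "+"
            pos = int(row[2]) - 3 if strand == "-" else int(row[1]) + 1
            i = site_lookup.get((chrom, pos))
            if i is not None:
                counts[i] += 1
    return count_sites({name: counts}, sitemap)
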