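"""In-silico MspI digestion of a reference genome.

RRHP libraries interrogate 5hmC at MspI restriction sites (C^CGG): every
CCGG occurrence on the forward strand is one assayable site, and because the
motif is palindromic a single strand-collapsed entry covers both fragment
ends.  This module enumerates that site universe and the fragment tiling the
enzyme produces.

Coordinates are 1-based inclusive internally; BED output converts to 0-based
half-open at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

MOTIF = "CCGG"
_VALID_RE = re.compile(r"^[ACGTN]*$")


class GenomeInputError(ValueError):
    """Raised for empty genomes or non-nucleotide characters."""


def _as_sequences(genome) -> dict[str, str]:
    """Coerce a genome argument to an ordered {name: uppercase sequence} dict.

    Accepts a mapping, a FASTA path, or a pyfaidx.Fasta object.
    """
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(genome), as_raw=True, sequence_always_upper=True, rebuild=True)
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
    elif isinstance(genome, Mapping):
        seqs = {str(k): str(v).upper() for k, v in genome.items()}
    else:  # pyfaidx.Fasta or similar keyed container
        seqs = {name: str(genome[name][:]).upper() for name in genome.keys()}
    if not seqs or all(len(s) == 0 for s in seqs.values()):
        raise GenomeInputError("genome is empty")
    for name, seq in seqs.items():
        if not _VALID_RE.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise GenomeInputError(f"sequence {name!r} contains non-nucleotide characters: {bad}")
    return seqs


@dataclass
class SiteMap:
    """Ordered catalogue of assayable CCGG sites.

    ``entries`` has columns ``chrom`` and ``pos`` (1-based position of the
    first C of the motif on the forward strand), sorted by chromosome (input
    order) then position, without duplicates.
    """

    entries: pd.DataFrame
    genome_id: str = ""
    chrom_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = self.entries.reset_index(drop=True)
        if not self.chrom_order:
            self.chrom_order = list(dict.fromkeys(self.entries["chrom"]))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def keys(self) -> pd.Index:
        """Site identifiers of the form ``chrom:pos``."""
        return pd.Index(
            self.entries["chrom"].astype(str) + ":" + self.entries["pos"].astype(str)
        )

    def positions(self, chrom: str):
        return self.entries.loc[self.entries["chrom"] == chrom, "pos"].to_numpy()

    def to_bed(self, path) -> None:
        """Write 4-bp motif intervals as BED (0-based half-open)."""
        bed = pd.DataFrame(
            {
                "chrom": self.entries["chrom"],
                "start": self.entries["pos"] - 1,
                "end": self.entries["pos"] + 3,
                "name": self.keys,
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_bed(cls, path, genome_id: str = "") -> "SiteMap":
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
        entries = pd.DataFrame({"chrom": bed[0].astype(str), "pos": bed[1].astype(int) + 1})
        order = list(dict.fromkeys(entries["chrom"]))
        entries["_c"] = pd.Categorical(entries["chrom"], categories=order, ordered=True)
        entries = (
            entries.sort_values(["_c", "pos"]).drop(columns="_c").drop_duplicates().reset_index(drop=True)
        )
        return cls(entries=entries, genome_id=genome_id, chrom_order=order)


def _scan_motif(seq: str) -> list[int]:
    """1-based start positions of every CCGG occurrence (overlap-safe)."""
    out = []
    i = seq.find(MOTIF)
    while i != -1:
        out.append(i + 1)
        i = seq.find(MOTIF, i + 1)
    return out


def find_ccgg_sites(genome, genome_id: str = "") -> SiteMap:
    """Enumerate CCGG motifs on the forward strand of ``genome``.

    The reverse strand is implicitly covered (CCGG is its own reverse
    complement); motifs overlapping N cannot match and are thereby skipped.
    """
    seqs = _as_sequences(genome)
    rows = []
    for name, seq in seqs.items():
        for pos in _scan_motif(seq):
            rows.append((name, pos))
    entries = pd.DataFrame(rows, columns=["chrom", "pos"]) if rows else pd.DataFrame(
        {"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=int)}
    )
    return SiteMap(entries=entries, genome_id=genome_id, chrom_order=list(seqs))


def digest_fragments(genome) -> dict[str, list[tuple[int, int]]]:
    """Fragment intervals produced by MspI (cut between C and CGG).

    Returns, per sequence, 1-based inclusive intervals that tile the sequence
    exactly: a motif at position p contributes a cut between p and p+1.
    """
    seqs = _as_sequences(genome)
    out: dict[str, list[tuple[int, int]]] = {}
    for name, seq in seqs.items():
        cuts = [pos for pos in _scan_motif(seq)]  # cut after this coordinate
        frags = []
        start = 1
        for c in cuts:
            frags.append((start, c))
            start = c + 1
        if start <= len(seq):
            frags.append((start, len(seq)))
        out[name] = frags
    return out


def fragment_sequences(genome) -> dict[str, list[str]]:
    """Fragment strings per sequence (convenience over :func:`digest_fragments`)."""
    seqs = _as_sequences(genome)
    out = {}
    for name, intervals in digest_fragments(seqs).items():
        seq = seqs[name]
        out[name] = [seq[s - 1 : e] for s, e in intervals]
    return out
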