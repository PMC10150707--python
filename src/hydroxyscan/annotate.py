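"""Genomic-feature and CpG-landscape annotation of 5hmC sites.

Each site receives exactly one mutually exclusive gene-context feature
(utr5 > utr3 > exon > intron > promoter > intergenic, precedence
configurable) and one CpG-landscape class (island, shore within 2 kb, shelf
within 2-4 kb, open sea), plus signed TSS distances and gene memberships.

All coordinates are 1-based inclusive internally; BED input/output converts
at the boundary.  Sites are classified by the position of the first C of
their CCGG motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import SiteMap

FEATURES = ["utr5", "utr3", "exon", "intron", "promoter", "intergenic"]
LANDSCAPES = ["island", "shore", "shelf", "open_sea"]
DEFAULT_PRECEDENCE = ["utr5", "utr3", "exon", "intron", "promoter"]

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


class GeneModelError(ValueError):
    pass


@dataclass
class Transcript:
    tx_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise GeneModelError(f"transcript {self.tx_id!r}: end < start")
        self.exons = sorted(self.exons)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class GeneModels:
    transcripts: list[Transcript]

    @classmethod
    def from_gtf(cls, path) -> "GeneModels":
        """Read GENCODE-dialect GTF (gene/transcript/exon/CDS rows)."""
        tx: dict[str, Transcript] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9:
                    continue
                chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
                if feature not in ("transcript", "exon", "CDS"):
                    continue
                a = dict(_ATTR_RE.findall(attrs))
                tid = a.get("transcript_id")
                if tid is None:
                    continue
                start, end = int(start), int(end)
                if tid not in tx:
                    tx[tid] = Transcript(
                        tx_id=tid, gene_id=a.get("gene_id", tid), chrom=chrom,
                        strand=strand, start=start, end=end,
                    )
                t = tx[tid]
                t.start, t.end = min(t.start, start), max(t.end, end)
                if feature == "exon":
                    t.exons.append((start, end))
                elif feature == "CDS":
                    t.cds = (
                        (start, end) if t.cds is None
                        else (min(t.cds[0], start), max(t.cds[1], end))
                    )
        for t in tx.values():
            t.exons = sorted(t.exons)
            if not t.exons:
                t.exons = [(t.start, t.end)]
        return cls(list(tx.values()))

    @classmethod
    def from_bed12(cls, path) -> "GeneModels":
        out = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
                thick_s, thick_e = int(f[6]), int(f[7])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + o + 1, start + o + s) for o, s in zip(offsets, sizes)]
                cds = (thick_s + 1, thick_e) if thick_e > thick_s else None
                out.append(
                    Transcript(name, name, chrom, strand, start + 1, end, exons, cds)
                )
        return cls(out)


def _merge(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Merge 1-based inclusive intervals; return (starts, ends) arrays."""
    if not intervals:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    intervals = sorted(intervals)
    starts, ends = [intervals[0][0]], [intervals[0][1]]
    for s, e in intervals[1:]:
        if s <= ends[-1] + 1:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _contains(merged: tuple[np.ndarray, np.ndarray], pos: np.ndarray) -> np.ndarray:
    starts, ends = merged
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] <= ends[idx[ok]]
    return out


def _class_intervals(models: GeneModels, promoter_span: int) -> dict[str, dict[str, list]]:
    """Per-chromosome raw interval lists for every feature class."""
    per: dict[str, dict[str, list]] = {c: {} for c in ("utr5", "utr3", "exon", "intron", "promoter")}

    def add(cls_name: str, chrom: str, s: int, e: int) -> None:
        if e >= s:
            per[cls_name].setdefault(chrom, []).append((s, e))

    for t in models.transcripts:
        for s, e in t.exons:
            add("exon", t.chrom, s, e)
        for (ps, pe), (ns, ne) in zip(t.exons, t.exons[1:]):  # gaps = introns
            add("intron", t.chrom, pe + 1, ns - 1)
        if t.cds is not None:
            cs, ce = t.cds
            for s, e in t.exons:
                if s < cs:  # exonic part left of the CDS
                    left = (s, min(e, cs - 1))
                    add("utr5" if t.strand == "+" else "utr3", t.chrom, *left)
                if e > ce:
                    right = (max(s, ce + 1), e)
                    add("utr3" if t.strand == "+" else "utr5", t.chrom, *right)
        if t.strand == "+":
            add("promoter", t.chrom, max(1, t.tss - promoter_span), t.tss - 1)
        else:
            add("promoter", t.chrom, t.tss + 1, t.tss + promoter_span)
    return per


def classify_feature(
    sitemap: SiteMap,
    models: GeneModels,
    promoter_span: int = 1000,
    precedence: list[str] | None = None,
) -> pd.Series:
    """Mutually exclusive gene-context class per site (union over transcripts)."""
    precedence = precedence or DEFAULT_PRECEDENCE
    raw = _class_intervals(models, promoter_span)
    merged = {
        cls_name: {chrom: _merge(iv) for chrom, iv in chrom_map.items()}
        for cls_name, chrom_map in raw.items()
    }
    out = np.full(len(sitemap), "intergenic", dtype=object)
    chroms = sitemap.entries["chrom"].to_numpy()
    pos = sitemap.entries["pos"].to_numpy()
    unresolved = np.ones(len(sitemap), dtype=bool)
    for cls_name in precedence:
        for chrom in np.unique(chroms):
            mask = unresolved & (chroms == chrom)
            if not mask.any() or chrom not in merged[cls_name]:
                continue
            hit = _contains(merged[cls_name][chrom], pos[mask])
            sel = np.flatnonzero(mask)[hit]
            out[sel] = cls_name
            unresolved[sel] = False
    return pd.Series(out, index=sitemap.keys, name="feature")


def read_cgi_bed(path) -> dict[str, list[tuple[int, int]]]:
    """CpG-island BED to 1-based inclusive intervals per chromosome."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    out: dict[str, list[tuple[int, int]]] = {}
    for row in bed.itertuples(index=False):
        out.setdefault(str(row[0]), []).append((int(row[1]) + 1, int(row[2])))
    return out


def classify_landscape(
    sitemap: SiteMap,
    cgi: dict[str, list[tuple[int, int]]],
    shore_span: int = 2000,
    shelf_span: int = 4000,
) -> pd.Series:
    """Island / shore / shelf / open-sea class by distance to the nearest CGI."""
    if shelf_span <= shore_span or shore_span <= 0:
        raise ValueError("require shelf_span > shore_span > 0")
    merged = {chrom: _merge(iv) for chrom, iv in cgi.items()}
    chroms = sitemap.entries["chrom"].to_numpy()
    pos = sitemap.entries["pos"].to_numpy()
    out = np.full(len(sitemap), "open_sea", dtype=object)
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        if chrom not in merged or len(merged[chrom][0]) == 0:
            continue
        starts, ends = merged[chrom]
        p = pos[mask]
        idx = np.searchsorted(starts, p, side="right") - 1
        inside = (idx >= 0) & (p <= ends[np.clip(idx, 0, None)])
        # gap distance to the nearest island boundary on either side
        dist_left = np.where(idx >= 0, p - ends[np.clip(idx, 0, None)], np.iinfo(np.int64).max)
        nxt = idx + 1
        dist_right = np.where(
            nxt < len(starts), starts[np.clip(nxt, 0, len(starts) - 1)] - p, np.iinfo(np.int64).max
        )
        dist = np.minimum(dist_left, dist_right)
        cls_vec = np.full(len(p), "open_sea", dtype=object)
        cls_vec[dist <= shelf_span] = "shelf"
        cls_vec[dist <= shore_span] = "shore"
        cls_vec[inside] = "island"
        out[mask] = cls_vec
    return pd.Series(out, index=sitemap.keys, name="landscape")


def tss_profile(
    sitemap: SiteMap,
    models: GeneModels,
    counts: pd.DataFrame | None = None,
    half_window: int = 1000,
    bin_size: int = 50,
) -> pd.DataFrame:
    """Site tallies (and optionally summed counts) in 50-bp bins around TSSs.

    Bins span [-half_window, +half_window); a site within the window of
    several TSSs contributes once per TSS.  Distances are strand-aware and
    signed (negative = upstream of the TSS).
    """
    if half_window % bin_size != 0:
        raise ValueError("bin_size must divide half_window")
    n_bins = 2 * half_window // bin_size
    tallies = np.zeros(n_bins, dtype=np.int64)
    signal = np.zeros(n_bins, dtype=float)
    site_signal = None
    if counts is not None:
        site_signal = counts.reindex(sitemap.keys).fillna(0.0).sum(axis=1).to_numpy()

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in models.transcripts:
        by_chrom.setdefault(t.chrom, []).append((t.tss, +1 if t.strand == "+" else -1))

    chroms = sitemap.entries["chrom"].to_numpy()
    pos = sitemap.entries["pos"].to_numpy()
    order = np.argsort(pos, kind="stable")
    for chrom, tss_list in by_chrom.items():
        sel = order[chroms[order] == chrom]
        if len(sel) == 0:
            continue
        p_sorted = pos[sel]
        for tss, sign in tss_list:
            lo = np.searchsorted(p_sorted, tss - half_window)
            hi = np.searchsorted(p_sorted, tss + half_window + 1)
            d = (p_sorted[lo:hi] - tss) * sign
            keep = (d >= -half_window) & (d < half_window)
            binned = (d[keep] + half_window) // bin_size
            np.add.at(tallies, binned.astype(int), 1)
            if site_signal is not None:
                np.add.at(signal, binned.astype(int), site_signal[sel[lo:hi][keep]])
    edges = np.arange(-half_window, half_window + 1, bin_size)
    out = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:], "n_sites": tallies})
    if site_signal is not None:
        out["summed_counts"] = signal
    return out


def nearest_tss_distance(sitemap: SiteMap, models: GeneModels) -> pd.Series:
    """Signed distance to the nearest TSS over all transcripts (negative = upstream)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in models.transcripts:
        by_chrom.setdefault(t.chrom, []).append((t.tss, +1 if t.strand == "+" else -1))
    chroms = sitemap.entries["chrom"].to_numpy()
    pos = sitemap.entries["pos"].to_numpy()
    out = np.full(len(sitemap), np.nan)
    for chrom, tss_list in by_chrom.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        tss_arr = np.array([t for t, _ in tss_list])
        sign_arr = np.array([s for _, s in tss_list])
        p = pos[mask][:, None]
        absd = np.abs(p - tss_arr[None, :])
        j = np.argmin(absd, axis=1)
        out[mask] = (p[:, 0] - tss_arr[j]) * sign_arr[j]
    return pd.Series(out, index=sitemap.keys, name="tss_distance")


def map_sites_to_genes(
    sitemap: SiteMap,
    models: GeneModels,
    promoter_span: int = 1000,
    gene_list: list[str] | None = None,
) -> dict:
    """Map sites to genes whose body or promoter contains them.

    Returns {"genes": DataFrame(gene_id, n_sites), "site_genes": per-site gene
    lists, "intersection": genes shared with ``gene_list`` (when given)}.
    """
    gene_iv: dict[str, dict[str, list]] = {}
    for t in models.transcripts:
        lo, hi = t.start, t.end
        if t.strand == "+":
            lo = max(1, lo - promoter_span)
        else:
            hi = hi + promoter_span
        gene_iv.setdefault(t.gene_id, {}).setdefault(t.chrom, []).append((lo, hi))

    chroms = sitemap.entries["chrom"].to_numpy()
    pos = sitemap.entries["pos"].to_numpy()
    site_genes: list[list[str]] = [[] for _ in range(len(sitemap))]
    gene_counts: dict[str, int] = {}
    for gene, chrom_map in gene_iv.items():
        for chrom, iv in chrom_map.items():
            mask = chroms == chrom
            if not mask.any():
                continue
            hit = _contains(_merge(iv), pos[mask])
            hits = np.flatnonzero(mask)[hit]
            if len(hits):
                gene_counts[gene] = gene_counts.get(gene, 0) + len(hits)
                for i in hits:
                    site_genes[i].append(gene)
    genes = (
        pd.DataFrame(sorted(gene_counts.items()), columns=["gene_id", "n_sites"])
        if gene_counts
        else pd.DataFrame(columns=["gene_id", "n_sites"])
    )
    out = {
        "genes": genes,
        "site_genes": pd.Series(
            [",".join(sorted(g)) for g in site_genes], index=sitemap.keys, name="gene_ids"
        ),
    }
    if gene_list is not None:
        listed = set(gene_list)
        out["intersection"] = genes[genes["gene_id"].isin(listed)].reset_index(drop=True)
    return out


def annotate_sites(
    sitemap: SiteMap,
    models: GeneModels,
    cgi: dict[str, list[tuple[int, int]]],
    promoter_span: int = 1000,
    shore_span: int = 2000,
    shelf_span: int = 4000,
) -> pd.DataFrame:
    """Full per-site annotation table (feature, landscape, TSS distance, genes)."""
    feature = classify_feature(sitemap, models, promoter_span)
    landscape = classify_landscape(sitemap, cgi, shore_span, shelf_span)
    tssd = nearest_tss_distance(sitemap, models)
    genes = map_sites_to_genes(sitemap, models, promoter_span)["site_genes"]
    out = pd.concat([feature, landscape, tssd, genes], axis=1)
    out.insert(0, "chrom", sitemap.entries["chrom"].to_numpy())
    out.insert(1, "pos", sitemap.entries["pos"].to_numpy())
    return out
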