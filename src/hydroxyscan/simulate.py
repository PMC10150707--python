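"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a paired reduced-representation 5hmC experiment:

* a small genome with planted CCGG motifs (and only those), disjoint CpG
  islands and strand-aware gene models;
* a paired design (each subject contributes one iPSC and one NSC library;
  subjects form case/sibling disease pairs);
* negative-binomial site counts with log-normal per-site baselines, a
  subject random effect inducing within-pair correlation, an optional
  global log2 shift in the second cell type (NSC hypo-hydroxymethylation),
  sparse per-site effects, and planted k-site DhMR runs;
* RRHP-style reads: CCGG-prefixed fragments from either motif orientation
  with a terminal CG adapter, plus a controlled fraction of decoy reads
  lacking the protected-site prefix.

Everything is deterministic under a fixed seed, and every non-null site is
listed in the ground-truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import MOTIF, SiteMap, find_ccgg_sites
from .quant import FastqRead, revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class SimDesign:
    """Paired two-cell-type, two-disease-group design (default: 4 subjects,
    two case/sibling pairs, 8 libraries)."""

    n_subjects: int = 4
    cell_types: tuple[str, str] = ("iPSC", "NSC")
    n_sites: int = 20_000
    seed: int = 0

    def sample_sheet(self) -> pd.DataFrame:
        if self.n_subjects % 2 != 0:
            raise ValueError("n_subjects must be even (case/sibling pairs)")
        rows = []
        sexes = ["M", "F"]
        rng = np.random.default_rng(self.seed)
        base_ages = rng.integers(9, 17, size=self.n_subjects // 2)
        for s in range(self.n_subjects):
            pair = s // 2 + 1
            group = "case" if s % 2 == 0 else "sibling"
            subject = f"S{s + 1}"
            age = int(base_ages[pair - 1]) + (0 if group == "case" else 1)
            sex = sexes[(pair - 1) % 2]
            for ct in self.cell_types:
                rows.append(
                    {
                        "sample": f"{subject}_{ct}",
                        "subject": subject,
                        "cell_type": ct,
                        "group": group,
                        "pair": f"P{pair}",
                        "age": age,
                        "sex": sex,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class SimEffects:
    """Effect structure for the count simulation (log2 scale)."""

    global_shift: float = -0.3
    frac_affected_sites: float = 0.02
    site_effect_mean: float = 0.0
    site_effect_sd: float = 1.0
    planted_dhmrs: list[tuple[str, int, int, float]] = field(default_factory=list)
    # (chromosome, start site index within that chromosome, run length, per-site log2 effect)
    dispersion: float = 0.05
    libsize_range: tuple[float, float] = (0.8, 1.2)
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.2
    subject_sd: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_affected_sites <= 1.0:
            raise ValueError("frac_affected_sites must be in [0, 1]")
        for d in self.planted_dhmrs:
            if d[2] < 2:
                raise ValueError("planted DhMR run length must be >= 2")


def _random_seq_without_motif(rng: np.random.Generator, length: int) -> np.ndarray:
    seq = rng.choice(_BASES, size=length)
    return seq


def _scrub_unplanted_motifs(seq: np.ndarray, planted: set[int], rng: np.random.Generator) -> None:
    """Mutate bases so CCGG occurs exactly at the planted 0-based offsets."""
    protected = np.zeros(len(seq), dtype=bool)
    for p in planted:
        protected[p : p + 4] = True
    s = "".join(seq)
    for _ in range(100):
        dirty = []
        i = s.find(MOTIF)
        while i != -1:
            if i not in planted:
                dirty.append(i)
            i = s.find(MOTIF, i + 1)
        if not dirty:
            return
        for i in dirty:
            for off in range(4):
                if not protected[i + off]:
                    seq[i + off] = "A" if seq[i + off] != "A" else "T"
                    break
        s = "".join(seq)
    raise RuntimeError("failed to scrub unintended CCGG motifs")


def simulate_genome(
    n_chrom: int = 2,
    length: int = 100_000,
    ccgg_rate: float = 0.002,
    cgi_density: float = 5e-5,
    gene_density: float = 2e-5,
    seed: int = 0,
    n_motifs: int | None = None,
):
    """Generate a genome with planted CCGG motifs, CGIs and gene models.

    Returns (sequences dict, cgi intervals dict (1-based inclusive),
    transcripts list).  Motif count per chromosome is Poisson(rate*length)
    unless ``n_motifs`` fixes it exactly; positions are uniform with >= 4 bp
    separation, and the background is scrubbed so the in-silico digest finds
    exactly the planted motifs.
    """
    if min(n_chrom, length) <= 0 or ccgg_rate < 0:
        raise ValueError("parameters must be positive")
    from .annotate import Transcript

    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    cgis: dict[str, list[tuple[int, int]]] = {}
    transcripts: list = []
    for c in range(1, n_chrom + 1):
        chrom = f"chr{c}"
        seq = _random_seq_without_motif(rng, length)
        n_mot = n_motifs if n_motifs is not None else rng.poisson(ccgg_rate * length)
        planted: set[int] = set()
        tries = 0
        while len(planted) < n_mot and tries < 50 * n_mot + 100:
            p = int(rng.integers(0, length - 4))
            if all(abs(p - q) >= 4 for q in planted):
                planted.add(p)
            tries += 1
        for p in planted:
            seq[p : p + 4] = list(MOTIF)
        _scrub_unplanted_motifs(seq, planted, rng)
        seqs[chrom] = "".join(seq)

        n_cgi = rng.poisson(cgi_density * length)
        iv: list[tuple[int, int]] = []
        for _ in range(n_cgi * 5):
            if len(iv) >= n_cgi:
                break
            w = int(rng.integers(400, 1500))
            s0 = int(rng.integers(1, max(2, length - w)))
            if all(s0 + w < a - 4000 or s0 > b + 4000 for a, b in iv):
                iv.append((s0, s0 + w - 1))
        cgis[chrom] = sorted(iv)

        n_genes = rng.poisson(gene_density * length)
        occupied: list[tuple[int, int]] = []
        for g in range(n_genes * 5):
            if len(occupied) >= n_genes:
                break
            glen = int(rng.integers(3000, 8000))
            s0 = int(rng.integers(1500, max(1501, length - glen - 1500)))
            e0 = s0 + glen - 1
            if any(not (e0 < a - 2500 or s0 > b + 2500) for a, b in occupied):
                continue
            occupied.append((s0, e0))
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 5))
            cuts = np.sort(rng.choice(np.arange(s0 + 200, e0 - 200), size=2 * (n_ex - 1), replace=False))
            bounds = [s0, *cuts.tolist(), e0]
            exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_ex)]
            margin5 = int(rng.integers(50, 150))
            margin3 = int(rng.integers(50, 150))
            cds = (exons[0][0] + margin5, exons[-1][1] - margin3)
            gid = f"{chrom}_G{len(occupied)}"
            transcripts.append(
                Transcript(
                    tx_id=gid + ".1", gene_id=gid, chrom=chrom, strand=strand,
                    start=s0, end=e0, exons=exons, cds=cds,
                )
            )
    return seqs, cgis, transcripts


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_cgi_bed(cgis: dict[str, list[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for chrom, iv in cgis.items():
            for s, e in iv:
                fh.write(f"{chrom}\t{s - 1}\t{e}\tCGI\n")


def write_gtf(transcripts, path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.tx_id}";'
            fh.write(
                f"{t.chrom}\tsim\ttranscript\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(f"{t.chrom}\tsim\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n")
            if t.cds is not None:
                cs, ce = t.cds
                for s, e in t.exons:
                    os_, oe = max(s, cs), min(e, ce)
                    if os_ <= oe:
                        fh.write(
                            f"{t.chrom}\tsim\tCDS\t{os_}\t{oe}\t.\t{t.strand}\t.\t{attrs}\n"
                        )


def simulate_counts(
    sitemap: SiteMap | int,
    design: SimDesign,
    effects: SimEffects,
    seed: int | None = None,
):
    """Negative-binomial site counts for the paired design plus ground truth.

    Sample means: m = 2^(mu_site + b_subject + shift) * libfactor, where
    shift applies in the second cell type and equals global_shift plus any
    site-specific or planted-DhMR effect; counts ~ NB(mean m, dispersion
    phi) via gamma-Poisson mixing (phi = 0 gives Poisson).

    Returns (SiteCountMatrix, sample sheet, ground-truth DataFrame,
    library factors Series).
    """
    from .quant import SiteCountMatrix

    rng = np.random.default_rng(design.seed if seed is None else seed)
    if isinstance(sitemap, SiteMap):
        keys = list(sitemap.keys)
        chroms = sitemap.entries["chrom"].to_numpy()
        n_sites = len(keys)
    else:
        n_sites = int(sitemap)
        chroms = np.array(["chr1"] * n_sites)
        keys = [f"chr1:{10 * i + 1}" for i in range(n_sites)]
    sheet = design.sample_sheet()
    samples = list(sheet["sample"])
    subjects = sheet["subject"].to_numpy()
    is_b = (sheet["cell_type"] == design.cell_types[1]).to_numpy()

    mu = rng.normal(effects.baseline_log2_mean, effects.baseline_log2_sd, size=n_sites)
    b_subj = {
        s: rng.normal(0.0, effects.subject_sd) for s in dict.fromkeys(subjects)
    }
    site_effect = np.zeros(n_sites)
    affected = np.zeros(n_sites, dtype=bool)
    n_aff = int(round(effects.frac_affected_sites * n_sites))
    if n_aff:
        idx = rng.choice(n_sites, size=n_aff, replace=False)
        site_effect[idx] = rng.normal(
            effects.site_effect_mean, effects.site_effect_sd, size=n_aff
        )
        affected[idx] = True
    dhmr_id = np.full(n_sites, "", dtype=object)
    for j, (chrom, start_idx, run, eff) in enumerate(effects.planted_dhmrs):
        chrom_idx = np.flatnonzero(chroms == chrom)
        if start_idx + run > len(chrom_idx):
            raise ValueError(f"planted DhMR {j} exceeds chromosome {chrom!r} site count")
        sel = chrom_idx[start_idx : start_idx + run]
        site_effect[sel] += eff
        affected[sel] = True
        dhmr_id[sel] = f"dhmr{j}"

    lib_factors = pd.Series(
        rng.uniform(*effects.libsize_range, size=len(samples)), index=samples
    )
    counts = np.empty((n_sites, len(samples)), dtype=np.int64)
    for j, row in enumerate(sheet.itertuples()):
        shift = (effects.global_shift + site_effect) if is_b[j] else 0.0
        log2_mean = mu + b_subj[row.subject] + shift
        m = np.exp2(log2_mean) * lib_factors.iloc[j]
        if effects.dispersion > 0:
            lam = rng.gamma(1.0 / effects.dispersion, m * effects.dispersion)
        else:
            lam = m
        counts[:, j] = rng.poisson(lam)

    truth = pd.DataFrame(
        {
            "site": keys,
            "baseline_log2_mean": mu,
            "affected": affected,
            "site_effect": site_effect,
            "dhmr_id": dhmr_id,
        }
    ).set_index("site")
    scm = SiteCountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(keys, name="site"), columns=samples),
        sitemap=sitemap if isinstance(sitemap, SiteMap) else None,
    )
    return scm, sheet, truth, lib_factors


def simulate_reads(
    genome: dict[str, str],
    sitemap: SiteMap,
    levels: np.ndarray,
    samples: list[str],
    depth: float = 10.0,
    read_length: int = 50,
    decoy_fraction: float = 0.0,
    quality_char: str = "I",
    seed: int = 0,
):
    """RRHP-style FASTQ reads per sample with exact bookkeeping.

    ``levels`` is (n_sites, n_samples) in [0, 1]; reads per site are
    Poisson(depth * level).  Each read is the reference fragment starting at
    the motif (forward, or reverse-complemented from the motif end) of
    ``read_length - 2`` bases plus the terminal CG adapter.  Sites without
    room for either orientation emit nothing (recorded as level 0 in the
    log).  Decoy reads lacking the CCGG prefix are appended at the stated
    fraction of each sample's total.

    Returns (reads dict sample -> list[FastqRead], log dict with per-site
    emitted counts and decoy counts).
    """
    levels = np.atleast_2d(np.asarray(levels, dtype=float))
    if levels.shape != (len(sitemap), len(samples)):
        raise ValueError("levels must be (n_sites, n_samples)")
    if np.any((levels < 0) | (levels > 1)):
        raise ValueError("levels must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    frag_len = read_length - 2
    chroms = sitemap.entries["chrom"].to_numpy()
    positions = sitemap.entries["pos"].to_numpy()

    feasible: list[list[str]] = []
    for i in range(len(sitemap)):
        chrom, pos = chroms[i], int(positions[i])
        L = len(genome[chrom])
        ok = []
        if pos - 1 + frag_len <= L:
            ok.append("fwd")
        if pos + 3 - frag_len >= 1:
            ok.append("rev")
        feasible.append(ok)

    reads: dict[str, list[FastqRead]] = {}
    log = {"site_counts": {}, "decoys": {}}
    qual = quality_char * read_length
    for j, sample in enumerate(samples):
        out: list[FastqRead] = []
        emitted = np.zeros(len(sitemap), dtype=np.int64)
        for i in range(len(sitemap)):
            if not feasible[i] or levels[i, j] == 0:
                continue
            n_reads = rng.poisson(depth * levels[i, j])
            if n_reads == 0:
                continue
            chrom, pos = chroms[i], int(positions[i])
            seq = genome[chrom]
            for r in range(n_reads):
                orient = feasible[i][int(rng.integers(len(feasible[i])))]
                if orient == "fwd":
                    frag = seq[pos - 1 : pos - 1 + frag_len]
                else:
                    frag = revcomp(seq[pos + 3 - frag_len : pos + 3])
                out.append(
                    FastqRead(f"{sample}:{chrom}:{pos}:{orient}:{r}", frag + "CG", qual)
                )
            emitted[i] = n_reads
        n_real = len(out)
        n_decoy = int(round(n_real * decoy_fraction / (1.0 - decoy_fraction))) if decoy_fraction else 0
        for dnum in range(n_decoy):
            body = "".join(rng.choice(_BASES, size=read_length - 1))
            out.append(FastqRead(f"{sample}:decoy:{dnum}", "A" + body, qual))
        reads[sample] = out
        log["site_counts"][sample] = emitted
        log["decoys"][sample] = n_decoy
    return reads, log


def levels_from_counts(scm, depth_scale: float | None = None) -> np.ndarray:
    """Map a count matrix to per-site read-emission levels in [0, 1]."""
    mat = scm.counts.to_numpy(dtype=float)
    top = mat.max() or 1.0
    return mat / (depth_scale or top)
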