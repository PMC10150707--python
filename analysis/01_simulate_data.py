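"""Generate the synthetic study dataset every downstream analysis consumes.

Emulates the study design: four subjects (two case/sibling disease pairs),
one iPSC and one NSC library each, a global NSC hypo-hydroxymethylation
shift of -0.3 log2 units, 2% sparse site effects, and two planted nine-site
DhMR runs.  Bulky artefacts (FASTA/GTF/FASTQ/counts) go to scratch/sim/;
small summary tables go to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hydroxyscan.digest import find_ccgg_sites
from hydroxyscan.simulate import (
    SimDesign,
    SimEffects,
    levels_from_counts,
    simulate_counts,
    simulate_genome,
    simulate_reads,
    write_cgi_bed,
    write_fasta,
    write_gtf,
)
from hydroxyscan.quant import write_fastq

SEED = 20_240_901
ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    seqs, cgis, tx = simulate_genome(
        n_chrom=4, length=250_000, ccgg_rate=0.002, cgi_density=6e-5,
        gene_density=3e-5, seed=SEED,
    )
    write_fasta(seqs, DATA / "genome.fa")
    write_cgi_bed(cgis, DATA / "cgi.bed")
    write_gtf(tx, DATA / "genes.gtf")
    sitemap = find_ccgg_sites(seqs, genome_id="sim")
    sitemap.to_bed(DATA / "sites.bed")
    print(f"genome: {len(seqs)} chromosomes, {len(sitemap)} CCGG sites, "
          f"{sum(len(v) for v in cgis.values())} CGIs, {len(tx)} transcripts")

    design = SimDesign(n_subjects=4, n_sites=len(sitemap), seed=SEED)
    # sparse hypo-biased site effects on top of the global shift, so the
    # hypo-hydroxymethylation signature survives within-sample CPM scaling
    effects = SimEffects(
        global_shift=-0.3,
        frac_affected_sites=0.10,
        site_effect_mean=-0.8,
        site_effect_sd=0.6,
        dispersion=0.05,
        planted_dhmrs=[("chr1", 40, 9, -2.0), ("chr2", 120, 9, -1.5)],
    )
    scm, sheet, truth, libf = simulate_counts(sitemap, design, effects, seed=SEED + 1)
    scm.to_tsv(DATA / "counts.tsv")
    sheet.to_csv(DATA / "samples.tsv", sep="\t", index=False)
    truth.to_csv(DATA / "truth.tsv", sep="\t")
    print(f"counts: {scm.counts.shape[0]} sites x {scm.counts.shape[1]} samples; "
          f"{int(truth['affected'].sum())} affected sites, "
          f"{truth['dhmr_id'].str.len().gt(0).sum()} in planted DhMRs")

    # small FASTQ demonstration for two samples (the count matrix above is
    # what downstream stages consume; reads exercise the quant path)
    lv = levels_from_counts(scm)[:, :2]
    reads, log = simulate_reads(
        seqs, sitemap, lv, scm.samples[:2], depth=4.0, decoy_fraction=0.1,
        seed=SEED + 2,
    )
    for s in scm.samples[:2]:
        write_fastq(reads[s], DATA / f"{s}.fastq.gz")
    pd.DataFrame(
        {s: log["site_counts"][s] for s in scm.samples[:2]}, index=scm.counts.index
    ).rename_axis("site").to_csv(DATA / "read_truth.tsv", sep="\t")
    print(f"reads: {[len(reads[s]) for s in scm.samples[:2]]} for {scm.samples[:2]} "
          f"(decoys {[log['decoys'][s] for s in scm.samples[:2]]})")

    sheet.to_csv(RESULTS / "sample_sheet.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
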