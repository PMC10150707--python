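"""Annotate the site universe: gene features, CpG landscape, TSS profile.

Produces the feature and landscape composition tables (pie-chart analogues)
and the signed TSS-distance profile in 50-bp bins.
"""

from pathlib import Path

import pandas as pd

from hydroxyscan.annotate import GeneModels, annotate_sites, read_cgi_bed, tss_profile
from hydroxyscan.digest import find_ccgg_sites
from hydroxyscan.quant import SiteCountMatrix

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main() -> None:
    from hydroxyscan.digest import _as_sequences

    seqs = _as_sequences(DATA / "genome.fa")
    sitemap = find_ccgg_sites(seqs)
    models = GeneModels.from_gtf(DATA / "genes.gtf")
    cgi = read_cgi_bed(DATA / "cgi.bed")
    counts = SiteCountMatrix.from_tsv(DATA / "counts.tsv")

    ann = annotate_sites(sitemap, models, cgi)
    ann.rename_axis("site").to_csv(DATA / "annotation.tsv", sep="\t")

    feat = ann["feature"].value_counts(normalize=True).rename("fraction")
    land = ann["landscape"].value_counts(normalize=True).rename("fraction")
    feat.rename_axis("feature").to_csv(RESULTS / "feature_fractions.tsv", sep="\t")
    land.rename_axis("landscape").to_csv(RESULTS / "landscape_fractions.tsv", sep="\t")
    print("feature composition:\n" + feat.round(3).to_string())
    print("CpG landscape composition:\n" + land.round(3).to_string())

    prof = tss_profile(sitemap, models, counts=counts.counts)
    prof.to_csv(RESULTS / "tss_profile.tsv", sep="\t", index=False)
    near = prof.loc[prof["bin_start"].abs() <= 200, "n_sites"].sum()
    print(f"TSS profile: {prof['n_sites'].sum()} site-TSS pairs within 1 kb "
          f"({near} within 200 bp)")


if __name__ == "__main__":
    main()
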