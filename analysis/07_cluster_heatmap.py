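"""Two-way UPGMA clustering of the top differentiated sites.

Clusters samples and sites on 1-r Pearson dissimilarity of the normalized
values (sites at p < 0.01), writes the Z-score matrix and dendrogram merge
tables, and renders a static heatmap.  With a global NSC shift planted, the
sample dendrogram should split iPSC from NSC libraries.
"""

from pathlib import Path

import pandas as pd

from hydroxyscan.cluster import select_top_sites, two_way_cluster

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main() -> None:
    norm = pd.read_csv(DATA / "normalized.tsv", sep="\t", index_col=0)
    res = pd.read_csv(DATA / "diff.tsv", sep="\t", index_col=0)

    top = select_top_sites(res, p_thresh=0.01)
    print(f"clustering {len(top)} sites with p < 0.01")
    cl = two_way_cluster(norm.loc[top.index], heatmap_path=ROOT / "scratch" / "heatmap.png")

    cl["sample_tree"].to_merge_table().to_csv(
        RESULTS / "cluster_sample_merges.tsv", sep="\t", index=False
    )
    cl["z"].rename_axis("site").head(200).to_csv(DATA / "zscores.tsv", sep="\t")
    order = cl["sample_order"]
    print("sample dendrogram order:", " ".join(order))
    split = [s.split("_")[1] for s in order]
    clean = split in (sorted(split), sorted(split, reverse=True)) or (
        len(set(split[:4])) == 1 and len(set(split[4:])) == 1
    )
    print(f"cell types separate cleanly: {clean}")


if __name__ == "__main__":
    main()
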