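"""Two-way hierarchical clustering of differentiated 5hmC sites.

Dissimilarity is 1 - r (Pearson correlation); clustering is UPGMA with the
unweighted arithmetic-mean update and deterministic tie-breaking by lowest
leaf index.  Join heights use the d/2 convention by default (recorded in the
dendrogram metadata) so that two leaves at distance d meet at height d/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def pearson_dissimilarity(matrix, axis: int = 0) -> pd.DataFrame:
    """Square 1 - r matrix over rows (axis=0) or columns (axis=1)."""
    df = pd.DataFrame(matrix)
    mat = df.to_numpy(dtype=float)
    labels = list(df.index) if axis == 0 else list(df.columns)
    vecs = mat if axis == 0 else mat.T
    if vecs.shape[0] < 2:
        raise ValueError("need at least two vectors")
    sd = vecs.std(axis=1)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance vectors: {bad}")
    r = np.corrcoef(vecs)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=labels, columns=labels)


@dataclass
class Dendrogram:
    """UPGMA merge history in linkage form.

    ``merges`` rows are (id_a, id_b, height, size): leaves are 0..n-1,
    internal nodes n, n+1, ... in merge order.  ``height_convention`` records
    whether heights are d/2 ("half") or the raw average distance ("full").
    """

    merges: np.ndarray
    labels: list[str]
    height_convention: str = "half"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order from the final merge."""
        n = self.n_leaves
        children: dict[int, tuple[int, int]] = {
            n + i: (int(a), int(b)) for i, (a, b, _, _) in enumerate(self.merges)
        }
        order: list[str] = []

        def walk(node: int) -> None:
            if node < n:
                order.append(self.labels[node])
            else:
                a, b = children[node]
                walk(a)
                walk(b)

        walk(n + len(self.merges) - 1)
        return order

    def cophenetic(self) -> pd.DataFrame:
        """Pairwise cophenetic distances (on the input-distance scale)."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        scale = 2.0 if self.height_convention == "half" else 1.0
        out = np.zeros((n, n))
        for i, (a, b, h, _) in enumerate(self.merges):
            la, lb = members[int(a)], members[int(b)]
            for x in la:
                for y in lb:
                    out[x, y] = out[y, x] = h * scale
            members[n + i] = la + lb
        return pd.DataFrame(out, index=self.labels, columns=self.labels)

    def to_merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["id_a", "id_b", "height", "size"])


def upgma(dissimilarity: pd.DataFrame, height_convention: str = "half") -> Dendrogram:
    """UPGMA clustering with lowest-leaf-index tie-breaking.

    Inter-cluster distance is the unweighted average over member pairs
    (size-weighted Lance-Williams update); at each step the closest pair is
    merged, ties resolved by the smallest (min leaf index of A, min leaf
    index of B) lexicographically.
    """
    d = pd.DataFrame(dissimilarity).to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    labels = [str(x) for x in dissimilarity.index]
    n = d.shape[0]
    active: dict[int, dict] = {
        i: {"size": 1, "min_leaf": i} for i in range(n)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges = []
    next_id = n
    denom = 2.0 if height_convention == "half" else 1.0
    while len(active) > 1:
        best = None
        for (i, j), dij in dist.items():
            key = (
                dij,
                min(active[i]["min_leaf"], active[j]["min_leaf"]),
                max(active[i]["min_leaf"], active[j]["min_leaf"]),
            )
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        dij = dist[(i, j)]
        a, b = (i, j) if active[i]["min_leaf"] < active[j]["min_leaf"] else (j, i)
        size = active[i]["size"] + active[j]["size"]
        merges.append((a, b, dij / denom, size))
        new = {"size": size, "min_leaf": min(active[i]["min_leaf"], active[j]["min_leaf"])}
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            dnew = (active[i]["size"] * dik + active[j]["size"] * djk) / size
            dist[tuple(sorted((next_id, k)))] = dnew
        for key in [key for key in dist if i in key or j in key]:
            del dist[key]
        del active[i], active[j]
        active[next_id] = new
        next_id += 1
    return Dendrogram(
        merges=np.array(merges, dtype=float),
        labels=labels,
        height_convention=height_convention,
    )


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0, sample sd 1 (heatmap Z-scores)."""
    df = pd.DataFrame(matrix).astype(float)
    sd = df.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = list(df.index[sd == 0])
        raise ValueError(f"constant rows cannot be standardized: {bad}")
    return df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)


def select_top_sites(diff_result: pd.DataFrame, p_thresh: float = 0.01) -> pd.DataFrame:
    """Non-degenerate sites with p < p_thresh, sorted by p ascending."""
    res = diff_result
    mask = res["p_value"] < p_thresh
    if "degenerate" in res:
        mask &= ~res["degenerate"].astype(bool)
    return res.loc[mask].sort_values("p_value", kind="stable")


def two_way_cluster(
    values: pd.DataFrame, heatmap_path=None
) -> dict:
    """Cluster samples (columns) and sites (rows) of a Z-scored value matrix.

    Returns the two dendrograms, ordered labels and the row-standardized
    matrix; optionally renders a static heatmap.
    """
    z = zscore_rows(values)
    sample_tree = upgma(pearson_dissimilarity(values, axis=1))
    site_tree = upgma(pearson_dissimilarity(values, axis=0))
    out = {
        "z": z,
        "sample_tree": sample_tree,
        "site_tree": site_tree,
        "sample_order": sample_tree.leaf_order(),
        "site_order": site_tree.leaf_order(),
    }
    if heatmap_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        zo = z.loc[out["site_order"], out["sample_order"]]
        fig, ax = plt.subplots(figsize=(6, 8))
        im = ax.imshow(zo.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
        ax.set_xticks(range(len(zo.columns)), zo.columns, rotation=90, fontsize=7)
        ax.set_yticks([])
        fig.colorbar(im, ax=ax, label="Z-score")
        fig.tight_layout()
        fig.savefig(heatmap_path, dpi=150)
        plt.close(fig)
    return out
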