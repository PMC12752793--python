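"""Count-free clustering of unique protein pools by Grantham distance.

Agglomerative clustering on the all-pairs summed Grantham distance of the
unique sequences in a pool (read counts never enter), flattened at a
distance cutoff or to a requested cluster count; per-cluster consensus
calling by Grantham-distance minimization; an average-linkage dendrogram
over the consensuses; greedy max-min representative picking; and the
position frequency (logo) and per-sequence distance (heatmap) matrices.

All tie-breaks are deterministic: sequences are processed in lexicographic
order, consensus ties fall back to residue frequency then alphabet, and
representative ties to larger cluster size then lexicographic consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .grantham import (
    AMINO_ACIDS,
    GranthamMatrix,
    default_matrix,
    encode,
    pairwise_distance_matrix,
    sequence_distance,
)
from .read_processing import RoundPool

__all__ = [
    "Cluster",
    "ClusterSet",
    "cluster_pool",
    "consensus_of",
    "build_dendrogram",
    "select_representatives",
    "logo_matrix",
    "heatmap_matrix",
    "linkage_to_newick",
]


@dataclass
class Cluster:
    members: tuple[str, ...]
    consensus: str
    diversity: float = 0.0

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """A partition of a pool plus a dendrogram over cluster consensuses."""

    clusters: list[Cluster]
    assignment: dict[str, int]
    linkage: np.ndarray | None = None  # scipy linkage over consensuses
    labels: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def consensuses(self) -> list[str]:
        return [c.consensus for c in self.clusters]


def consensus_of(
    members: Sequence[str] | Cluster, matrix: GranthamMatrix | None = None
) -> str:
    """Grantham-coherent consensus of a set of equal-length sequences.

    Per position, the residue (among those observed at that position)
    minimizing the summed Grantham distance to all members' residues; ties
    broken by higher observed frequency, then alphabetical order.
    """
    if isinstance(members, Cluster):
        members = members.members
    seqs = list(members)
    if not seqs:
        raise ValueError("empty cluster")
    m = matrix if matrix is not None else default_matrix()
    codes = np.stack([encode(s) for s in seqs])  # n x L
    out = []
    for j in range(codes.shape[1]):
        col = codes[:, j]
        observed, counts = np.unique(col, return_counts=True)
        cost = m.distance[np.ix_(observed, col)].sum(axis=1)
        # minimal cost, then maximal count, then alphabetical (lowest code)
        order = sorted(
            range(len(observed)),
            key=lambda k: (cost[k], -counts[k], observed[k]),
        )
        out.append(AMINO_ACIDS[observed[order[0]]])
    return "".join(out)


def _diversity(dist_block: np.ndarray) -> float:
    n = dist_block.shape[0]
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, 1)
    return float(dist_block[iu].mean())


def cluster_pool(
    pool: RoundPool | Sequence[str],
    linkage: str = "average",
    cutoff: float | None = 100.0,
    n_clusters: int | None = None,
    positions="all",
    matrix: GranthamMatrix | None = None,
    consensus_mode: str = "grantham",
) -> ClusterSet:
    """Agglomerative clustering of a pool's unique sequences.

    The tree is flattened at distance ``cutoff`` (or to ``n_clusters`` when
    given, which takes precedence).  Deterministic under input reordering:
    sequences are sorted lexicographically before the distance matrix is
    built.  Clusters are returned largest-first (ties lexicographic by
    consensus).
    """
    seqs = sorted(pool.sequences if isinstance(pool, RoundPool) else set(pool))
    if not seqs:
        raise ValueError("empty pool")
    if n_clusters is None and (cutoff is None or cutoff <= 0):
        raise ValueError("cutoff must be positive")
    m = matrix if matrix is not None else default_matrix()
    if len(seqs) == 1:
        clusters = [Cluster(members=(seqs[0],), consensus=seqs[0], diversity=0.0)]
        return ClusterSet(clusters=clusters, assignment={seqs[0]: 0})

    dist = pairwise_distance_matrix(seqs, positions=positions, matrix=m)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    if n_clusters is not None:
        flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        flat = hierarchy.fcluster(Z, t=cutoff, criterion="distance")

    clusters: list[Cluster] = []
    for cid in np.unique(flat):
        idx = np.flatnonzero(flat == cid)
        members = tuple(seqs[i] for i in idx)
        if consensus_mode == "majority":
            cons = _majority_consensus(members)
        else:
            cons = consensus_of(members, m)
        clusters.append(
            Cluster(members=members, consensus=cons, diversity=_diversity(dist[np.ix_(idx, idx)]))
        )
    clusters.sort(key=lambda c: (-c.size, c.consensus))
    assignment = {s: i for i, c in enumerate(clusters) for s in c.members}
    return ClusterSet(clusters=clusters, assignment=assignment)


def _majority_consensus(members: Sequence[str]) -> str:
    codes = np.stack([encode(s) for s in members])
    out = []
    for j in range(codes.shape[1]):
        observed, counts = np.unique(codes[:, j], return_counts=True)
        order = sorted(range(len(observed)), key=lambda k: (-counts[k], observed[k]))
        out.append(AMINO_ACIDS[observed[order[0]]])
    return "".join(out)


def build_dendrogram(
    consensuses: Sequence[str],
    positions="all",
    matrix: GranthamMatrix | None = None,
) -> np.ndarray:
    """Average-linkage scipy linkage matrix over consensus sequences."""
    seqs = list(consensuses)
    if len(seqs) < 2:
        raise ValueError("need at least 2 consensuses")
    dist = pairwise_distance_matrix(seqs, positions=positions, matrix=matrix)
    return hierarchy.linkage(squareform(dist, checks=False), method="average")


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a newick string with branch lengths."""
    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, list(labels))
    # skbio stores merge heights as lengths already; serialize compactly
    return str(tree).strip()


def select_representatives(clusters: ClusterSet, n: int) -> list[str]:
    """Greedy max-min pick of ``n`` consensus sequences covering diversity.

    Seeded with the largest cluster's consensus; each step adds the
    consensus whose minimum distance to the chosen set is largest, breaking
    ties by larger cluster size then lexicographic order.
    """
    k = len(clusters.clusters)
    if not 1 <= n <= k:
        raise ValueError(f"n must be in [1, {k}]")
    cons = clusters.consensuses
    sizes = [c.size for c in clusters.clusters]
    dist = pairwise_distance_matrix(cons)
    # seed: largest cluster (clusters are sorted largest-first already)
    chosen = [0]
    while len(chosen) < n:
        remaining = [i for i in range(k) if i not in chosen]
        best = max(
            remaining,
            key=lambda i: (dist[i, chosen].min(), sizes[i], _neg_lex(cons[i])),
        )
        chosen.append(best)
    return [cons[i] for i in chosen]


class _neg_lex(str):
    """Orders strings so that max() prefers the lexicographically smaller."""

    def __lt__(self, other):  # inverted comparison
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def logo_matrix(pool: RoundPool | Sequence[str]) -> pd.DataFrame:
    """Position x residue frequency table over *unique* sequences.

    Rows are 0-based positions, columns the 20 residues; each row sums to 1.
    Computed on the deduplicated sequence set, never on read counts.
    """
    seqs = sorted(set(pool.sequences if isinstance(pool, RoundPool) else pool))
    if not seqs:
        raise ValueError("empty pool")
    codes = np.stack([encode(s) for s in seqs])
    n, L = codes.shape
    freq = np.zeros((L, 20))
    for j in range(L):
        observed, counts = np.unique(codes[:, j], return_counts=True)
        freq[j, observed] = counts / n
    return pd.DataFrame(freq, index=range(L), columns=list(AMINO_ACIDS))


def heatmap_matrix(
    clusters: ClusterSet, matrix: GranthamMatrix | None = None
) -> pd.DataFrame:
    """Per-sequence distance-to-consensus profiles, rows grouped by cluster.

    Row index is (cluster id, sequence); entry (i, j) is the Grantham
    distance of sequence i's residue j to its cluster consensus residue j.
    """
    from .grantham import distance_profile

    rows, index = [], []
    for cid, cluster in enumerate(clusters.clusters):
        for seq in sorted(cluster.members):
            rows.append(distance_profile(seq, cluster.consensus, matrix))
            index.append((cid, seq))
    return pd.DataFrame(
        np.stack(rows),
        index=pd.MultiIndex.from_tuples(index, names=["cluster", "sequence"]),
    )


def render_logo_png(freq: pd.DataFrame, path: str) -> None:
    """Minimal logo-style render: stacked per-position frequency bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.25 * len(freq)), 3))
    bottom = np.zeros(len(freq))
    cmap = plt.get_cmap("tab20")
    for k, aa in enumerate(freq.columns):
        vals = freq[aa].to_numpy()
        ax.bar(freq.index, vals, bottom=bottom, color=cmap(k % 20), label=aa, width=0.9)
        bottom += vals
    ax.set_xlabel("position")
    ax.set_ylabel("residue frequency")
    ax.legend(ncols=10, fontsize=6, loc="upper center", bbox_to_anchor=(0.5, -0.25))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_heatmap_png(hm: pd.DataFrame, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.15 * hm.shape[1]), max(3, 0.02 * hm.shape[0])))
    im = ax.imshow(hm.to_numpy(), aspect="auto", cmap="viridis", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="Grantham distance to consensus")
    ax.set_xlabel("position")
    ax.set_ylabel("sequence (grouped by cluster)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
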