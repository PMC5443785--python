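"""Population genetics over high-quality polymorphic SSR genotypes.

Between-individual distance is the fraction of shared called loci whose
unordered allele pairs differ: ``1 - identical / (identical + distinct)``,
with loci missing in either sample excluded from both counts.  Trees are
built by neighbour joining (Saitou-Nei agglomeration on the Q criterion),
which recovers any additive distance matrix exactly.  Per-breed diversity
is summarised by homozygous/heterozygous genotype counts, windowed
heterozygous ratios and per-locus per-group heterozygosity and PIC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedDistanceError
from .scan import SSRLocus


@dataclass(frozen=True)
class PairwiseComparison:
    sample_a: str
    sample_b: str
    identical: int
    distinct: int

    @property
    def distance(self) -> float:
        return 1.0 - self.identical / (self.identical + self.distinct)


def _genotype_arrays(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """locus x sample matrices of the sorted allele pair (NaN = missing)."""
    lo = calls[["locus", "sample"]].copy()
    lo["a"] = np.minimum(calls["allele_a"], calls["allele_b"])
    lo["b"] = np.maximum(calls["allele_a"], calls["allele_b"])
    return (lo.pivot(index="locus", columns="sample", values="a"),
            lo.pivot(index="locus", columns="sample", values="b"))


def pairwise_distance(sample_a: str, sample_b: str,
                      calls: pd.DataFrame) -> PairwiseComparison:
    """Compare two samples' genotypes as unordered allele pairs."""
    a_mat, b_mat = _genotype_arrays(
        calls[calls["sample"].isin([sample_a, sample_b])])
    for s in (sample_a, sample_b):
        if s not in a_mat.columns:
            a_mat[s] = np.nan
            b_mat[s] = np.nan
    both = a_mat[sample_a].notna() & a_mat[sample_b].notna()
    if not both.any():
        raise UndefinedDistanceError(
            f"no locus called in both {sample_a!r} and {sample_b!r}")
    same = ((a_mat.loc[both, sample_a] == a_mat.loc[both, sample_b])
            & (b_mat.loc[both, sample_a] == b_mat.loc[both, sample_b]))
    identical = int(same.sum())
    return PairwiseComparison(sample_a, sample_b, identical, int(both.sum()) - identical)


def distance_matrix(calls: pd.DataFrame,
                    samples: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Symmetric matrix of pairwise distances over all sample pairs."""
    a_mat, b_mat = _genotype_arrays(calls)
    if samples is None:
        samples = sorted(a_mat.columns)
    a = a_mat.reindex(columns=samples).to_numpy(float)
    b = b_mat.reindex(columns=samples).to_numpy(float)
    n = len(samples)
    dist = np.zeros((n, n))
    called = ~np.isnan(a)
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            total = int(both.sum())
            if total == 0:
                raise UndefinedDistanceError(
                    f"no locus called in both {samples[i]!r} and {samples[j]!r}")
            same = int(((a[both, i] == a[both, j]) & (b[both, i] == b[both, j])).sum())
            dist[i, j] = dist[j, i] = 1.0 - same / total
    return pd.DataFrame(dist, index=list(samples), columns=list(samples))


class NJTree:
    """Unrooted tree from neighbour joining.

    Nodes 0..n-1 are the input taxa in order; internal nodes are appended.
    ``edges`` holds (u, v, raw_length); serialisation clamps negative branch
    lengths to zero while ``path_distances`` uses the raw values.
    """

    def __init__(self, labels: Sequence[str]):
        self.labels = list(labels)
        self.edges: list[tuple[int, int, float]] = []
        self._next = len(labels)

    def _new_node(self) -> int:
        node = self._next
        self._next += 1
        return node

    def _adjacency(self, clamp: bool) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {}
        for u, v, w in self.edges:
            wl = max(0.0, w) if clamp else w
            adj.setdefault(u, []).append((v, wl))
            adj.setdefault(v, []).append((u, wl))
        return adj

    def path_distances(self) -> pd.DataFrame:
        """Leaf-to-leaf path lengths using raw (unclamped) branch lengths."""
        adj = self._adjacency(clamp=False)
        n = len(self.labels)
        out = np.zeros((n, n))
        for leaf in range(n):
            dist = {leaf: 0.0}
            stack = [leaf]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for other in range(n):
                out[leaf, other] = dist[other]
        return pd.DataFrame(out, index=self.labels, columns=self.labels)

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions (as the smaller-side leaf set is not
        canonical, both sides are represented by the side not containing
        leaf 0)."""
        adj = self._adjacency(clamp=True)
        result: set[frozenset[str]] = set()
        for u, v, _ in self.edges:
            # leaves on v's side of the (u, v) edge
            seen = {u, v}
            stack = [v]
            side = set()
            while stack:
                x = stack.pop()
                if x < len(self.labels):
                    side.add(self.labels[x])
                for y, _w in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            if 1 < len(side) < len(self.labels) - 1:
                if self.labels[0] in side:
                    side = set(self.labels) - side
                result.add(frozenset(side))
        return result

    def to_newick(self) -> str:
        adj = self._adjacency(clamp=True)
        root = self._next - 1  # last internal node created
        if root < len(self.labels):  # degenerate: no internal nodes
            root = 0

        def render(node: int, parent: Optional[int]) -> str:
            children = [(v, w) for v, w in adj[node] if v != parent]
            name = self.labels[node] if node < len(self.labels) else ""
            if not children:
                return name
            inner = ",".join(f"{render(v, node)}:{w:.17g}" for v, w in children)
            return f"({inner}){name}"

        return render(root, None) + ";"


def nj_tree(matrix: pd.DataFrame) -> NJTree:
    """Neighbour joining on a symmetric distance matrix.

    Ties on the Q criterion break to the smallest (i, j) position pair in
    the current node order (original taxa first, joined nodes appended), so
    the result is deterministic.  Requires >= 3 taxa, zero diagonal, no NaN.
    """
    d = np.asarray(matrix, dtype=float)
    labels = [str(x) for x in matrix.index]
    n = d.shape[0]
    if d.shape[0] != d.shape[1] or list(matrix.columns.astype(str)) != labels:
        raise ValueError("distance matrix must be square with matching labels")
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    tree = NJTree(labels)
    active = list(range(n))  # node ids, in stable order
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]

    def get(u: int, v: int) -> float:
        return dist[(u, v) if u < v else (v, u)]

    while len(active) > 3:
        m = len(active)
        r = {u: sum(get(u, v) for v in active if v != u) for u in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                u, v = active[ii], active[jj]
                q = (m - 2) * get(u, v) - r[u] - r[v]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ii, jj)
        _, ii, jj = best
        u, v = active[ii], active[jj]
        duv = get(u, v)
        lu = 0.5 * duv + (r[u] - r[v]) / (2 * (m - 2))
        lv = duv - lu
        new = tree._new_node()
        tree.edges.append((new, u, lu))
        tree.edges.append((new, v, lv))
        for w in active:
            if w not in (u, v):
                dist[(min(new, w), max(new, w))] = 0.5 * (get(u, w) + get(v, w) - duv)
        active = [w for w in active if w not in (u, v)] + [new]

    # final star join of the last three nodes (closed-form limb lengths)
    a, b, c = active
    dab, dac, dbc = get(a, b), get(a, c), get(b, c)
    center = tree._new_node()
    tree.edges.append((center, a, 0.5 * (dab + dac - dbc)))
    tree.edges.append((center, b, 0.5 * (dab + dbc - dac)))
    tree.edges.append((center, c, 0.5 * (dac + dbc - dab)))
    return tree


def breed_het_counts(calls: pd.DataFrame, breed_map: Mapping[str, str]) -> pd.DataFrame:
    """Mean homozygous / heterozygous called-locus counts per breed."""
    unknown = set(calls["sample"]) - set(breed_map)
    if unknown:
        raise KeyError(f"samples with unknown breed: {sorted(unknown)[:5]}")
    per_sample = calls.assign(het=calls["allele_a"] != calls["allele_b"]).groupby("sample").agg(
        n_called=("het", "size"), n_het=("het", "sum"))
    per_sample["n_hom"] = per_sample["n_called"] - per_sample["n_het"]
    per_sample["breed"] = [breed_map[s] for s in per_sample.index]
    return (per_sample.groupby("breed")[["n_hom", "n_het", "n_called"]]
            .mean().rename(columns={"n_hom": "mean_hom", "n_het": "mean_het",
                                    "n_called": "mean_called"}))


def windowed_het_ratio(calls: pd.DataFrame, loci: Sequence[SSRLocus],
                       breed_map: Mapping[str, str],
                       chrom_lengths: Mapping[str, int],
                       window: int = 10_000_000) -> pd.DataFrame:
    """Heterozygous fraction per sample per non-overlapping genomic window,
    averaged over each breed's samples.

    Windows with no called locus for a sample are missing (NaN) and are
    excluded from breed averages.  Returns one row per (breed, chrom,
    window_start) with the breed-mean ratio and sample count.
    """
    coord = {l.locus_id: (l.chrom, l.start) for l in loci}
    frame = calls.copy()
    frame["chrom"] = [coord[l][0] for l in frame["locus"]]
    frame["wstart"] = [(coord[l][1] // window) * window for l in frame["locus"]]
    frame["het"] = frame["allele_a"] != frame["allele_b"]
    frame["breed"] = [breed_map[s] for s in frame["sample"]]
    per = (frame.groupby(["breed", "sample", "chrom", "wstart"])["het"]
           .agg(["sum", "size"]).reset_index())
    per["ratio"] = per["sum"] / per["size"]
    out = (per.groupby(["breed", "chrom", "wstart"])["ratio"]
           .agg(mean_ratio="mean", n_samples="size").reset_index())
    return out


def breed_median_het_ratio(windowed: pd.DataFrame) -> pd.Series:
    """Median over windows of each breed's mean heterozygous ratio."""
    return windowed.groupby("breed")["mean_ratio"].median()


def group_locus_stats(calls: pd.DataFrame, group_map: Mapping[str, str]) -> pd.DataFrame:
    """Per-locus, per-group heterozygous ratio and PIC.

    The heterozygous ratio divides heterozygous individuals by the group's
    called individuals at that locus; PIC = 1 - sum(p_i^2) over the group's
    called chromosomes.
    """
    frame = calls.copy()
    frame["group"] = [group_map[s] for s in frame["sample"]]
    frame["het"] = frame["allele_a"] != frame["allele_b"]
    rows = []
    for (locus, group), g in frame.groupby(["locus", "group"], sort=True):
        alleles = pd.concat([g["allele_a"], g["allele_b"]]).value_counts(normalize=True)
        rows.append({"locus_id": locus, "group": group,
                     "n_called": len(g),
                     "het_ratio": float(g["het"].mean()),
                     "pic": 1.0 - float((alleles ** 2).sum())})
    return pd.DataFrame(rows)
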