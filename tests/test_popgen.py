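"""Distances, neighbour joining, and diversity summaries."""

import numpy as np
import pandas as pd
import pytest

from ssr_popscan.errors import UndefinedDistanceError
from ssr_popscan.motifs import MotifClass
from ssr_popscan.popgen import (breed_het_counts, breed_median_het_ratio,
                                distance_matrix, group_locus_stats, nj_tree,
                                pairwise_distance, windowed_het_ratio)
from ssr_popscan.scan import SSRLocus


def calls_frame(rows):
    return pd.DataFrame(rows, columns=["sample", "locus", "allele_a", "allele_b",
                                       "q", "reads"])


# ---------------------------------------------------------------------------
# random additive trees for NJ recovery


def random_additive_tree(rng, n_taxa):
    """Random unrooted binary tree with positive branch lengths; returns
    (leaf labels, path-distance matrix, set of non-trivial splits)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = list(range(n_taxa))
    edges = []
    next_id = n_taxa
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        u, v = nodes[j], nodes[i]
        edges.append((next_id, u, float(rng.uniform(0.1, 2.0))))
        edges.append((next_id, v, float(rng.uniform(0.1, 2.0))))
        nodes = [x for x in nodes if x not in (u, v)] + [next_id]
        next_id += 1
    center = next_id
    for u in nodes:
        edges.append((center, u, float(rng.uniform(0.1, 2.0))))
    adj = {}
    for u, v, w in edges:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    dist = np.zeros((n_taxa, n_taxa))
    for leaf in range(n_taxa):
        seen = {leaf: 0.0}
        stack = [leaf]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in seen:
                    seen[y] = seen[x] + w
                    stack.append(y)
        for other in range(n_taxa):
            dist[leaf, other] = seen[other]
    splits = set()
    for u, v, _ in edges:
        comp, stack, seen = set(), [v], {u, v}
        while stack:
            x = stack.pop()
            if x < n_taxa:
                comp.add(labels[x])
            for y, _w in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 1 < len(comp) < n_taxa - 1:
            if labels[0] in comp:
                comp = set(labels) - comp
            splits.add(frozenset(comp))
    return labels, pd.DataFrame(dist, index=labels, columns=labels), splits


class TestPairwiseDistance:
    def test_nine_identical_one_distinct(self):
        rows = []
        for i in range(9):
            rows.append(["a", f"L{i}", 10, 12, 0.9, 5])
            rows.append(["b", f"L{i}", 10, 12, 0.9, 5])
        rows.append(["a", "L9", 10, 10, 0.9, 5])
        rows.append(["b", "L9", 10, 12, 0.9, 5])
        cmp = pairwise_distance("a", "b", calls_frame(rows))
        assert (cmp.identical, cmp.distinct) == (9, 1)
        assert cmp.distance == pytest.approx(0.1)

    def test_identical_samples_distance_zero(self):
        rows = [[s, f"L{i}", 10, 12, 0.9, 5] for s in "ab" for i in range(5)]
        assert pairwise_distance("a", "b", calls_frame(rows)).distance == 0.0

    def test_unordered_allele_pairs_compared(self):
        rows = [["a", "L0", 12, 10, 0.9, 5], ["b", "L0", 10, 12, 0.9, 5]]
        assert pairwise_distance("a", "b", calls_frame(rows)).identical == 1

    def test_loci_missing_in_either_sample_excluded(self):
        rows = [["a", "L0", 10, 10, 0.9, 5], ["b", "L0", 10, 10, 0.9, 5],
                ["a", "L1", 10, 10, 0.9, 5]]  # L1 uncalled in b
        cmp = pairwise_distance("a", "b", calls_frame(rows))
        assert cmp.identical + cmp.distinct == 1

    def test_no_shared_loci_is_an_error(self):
        rows = [["a", "L0", 10, 10, 0.9, 5], ["b", "L1", 10, 10, 0.9, 5]]
        with pytest.raises(UndefinedDistanceError):
            pairwise_distance("a", "b", calls_frame(rows))

    @pytest.mark.parametrize("seed", range(4))
    def test_matrix_matches_per_locus_comparison_oracle(self, seed):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(5)]
        rows = []
        genotypes = {}
        for locus in range(30):
            for s in samples:
                if rng.random() < 0.15:
                    continue
                a, b = sorted(rng.choice([10, 12, 14], size=2))
                rows.append([s, f"L{locus}", a, b, 0.9, 5])
                genotypes[(s, locus)] = (a, b)
        matrix = distance_matrix(calls_frame(rows), samples)
        for i, x in enumerate(samples):
            assert matrix.loc[x, x] == 0.0
            for y in samples[i + 1:]:
                same = diff = 0
                for locus in range(30):
                    gx, gy = genotypes.get((x, locus)), genotypes.get((y, locus))
                    if gx is None or gy is None:
                        continue
                    if gx == gy:
                        same += 1
                    else:
                        diff += 1
                expected = 1 - same / (same + diff)
                assert matrix.loc[x, y] == pytest.approx(expected)
                assert matrix.loc[y, x] == matrix.loc[x, y]


class TestNeighbourJoining:
    def test_three_taxa_closed_form(self):
        d = pd.DataFrame([[0, 5, 9], [5, 0, 10], [9, 10, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        tree = nj_tree(d)
        paths = tree.path_distances()
        assert np.allclose(paths.to_numpy(), d.to_numpy())
        # limb lengths solve the three-point formulas: a=2, b=3, c=7
        lengths = sorted(w for _u, _v, w in tree.edges)
        assert lengths == pytest.approx([2.0, 3.0, 7.0])

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((a:2,b:3):1,(c:4,d:5)) as an unrooted quartet
        d = pd.DataFrame([[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]],
                         index=list("abcd"), columns=list("abcd"), dtype=float)
        tree = nj_tree(d)
        assert np.allclose(tree.path_distances().loc[list("abcd"), list("abcd")],
                           d, atol=1e-9)
        assert tree.splits() == {frozenset({"c", "d"})}

    @pytest.mark.parametrize("seed", range(25))
    def test_random_additive_trees_recovered(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        labels, d, splits = random_additive_tree(rng, n)
        tree = nj_tree(d)
        assert tree.splits() == splits
        assert np.allclose(tree.path_distances().loc[labels, labels].to_numpy(),
                           d.to_numpy(), atol=1e-9)

    def test_newick_roundtrip_preserves_distances(self):
        import dendropy

        rng = np.random.default_rng(7)
        labels, d, _ = random_additive_tree(rng, 8)
        tree = nj_tree(d)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                    d.loc[a, b], abs=1e-9)

    def test_invalid_matrices_rejected(self):
        bad = pd.DataFrame([[0, 1], [1, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            nj_tree(bad)  # too few taxa
        asym = pd.DataFrame([[0, 1, 2], [9, 0, 3], [2, 3, 0]],
                            index=list("abc"), columns=list("abc"), dtype=float)
        with pytest.raises(ValueError):
            nj_tree(asym)
        nan = pd.DataFrame(np.full((3, 3), np.nan),
                           index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            nj_tree(nan)


def loc(start, end=None, chrom="chr1"):
    end = start + 20 if end is None else end
    return SSRLocus(chrom, start, end, MotifClass("AC", 2), (end - start) // 2)


class TestDiversity:
    def test_all_homozygous_sample_has_zero_het(self):
        rows = [["a", "L0", 10, 10, 0.9, 5], ["a", "L1", 12, 12, 0.9, 5]]
        counts = breed_het_counts(calls_frame(rows), {"a": "X"})
        assert counts.loc["X", "mean_het"] == 0
        assert counts.loc["X", "mean_hom"] == 2

    def test_hom_plus_het_equals_called(self):
        rng = np.random.default_rng(2)
        rows = [[f"s{i}", f"L{j}", *sorted(rng.choice([10, 12], size=2)), 0.9, 5]
                for i in range(4) for j in range(25)]
        counts = breed_het_counts(calls_frame(rows), {f"s{i}": "X" for i in range(4)})
        assert counts.loc["X", "mean_hom"] + counts.loc["X", "mean_het"] == \
            pytest.approx(counts.loc["X", "mean_called"])

    def test_unknown_breed_rejected(self):
        with pytest.raises(KeyError):
            breed_het_counts(calls_frame([["a", "L0", 10, 10, 0.9, 5]]), {})

    def test_window_ratio_worked_example(self):
        loci = [loc(i * 1000) for i in range(5)]
        rows = [["a", l.locus_id, 10, 12 if i < 2 else 10, 0.9, 5]
                for i, l in enumerate(loci)]
        out = windowed_het_ratio(calls_frame(rows), loci, {"a": "X"},
                                 {"chr1": 100_000}, window=10_000)
        assert len(out) == 1
        assert out["mean_ratio"].iloc[0] == pytest.approx(0.4)

    def test_empty_windows_absent_from_output(self):
        loci = [loc(1000), loc(95_000)]
        rows = [["a", loci[0].locus_id, 10, 12, 0.9, 5]]
        out = windowed_het_ratio(calls_frame(rows), loci, {"a": "X"},
                                 {"chr1": 100_000}, window=10_000)
        assert list(out["wstart"]) == [0]
        med = breed_median_het_ratio(out)
        assert med.loc["X"] == pytest.approx(1.0)

    def test_group_locus_stats_examples(self):
        # 8 homozygotes plus 2 heterozygotes: allele freqs 0.9/0.1 over 20
        # chromosomes give PIC 0.18
        rows = [[f"s{i}", "L0", 10, 10, 0.9, 5] for i in range(8)]
        rows.append(["s8", "L0", 10, 12, 0.9, 5])
        rows.append(["s9", "L0", 10, 12, 0.9, 5])
        frame = calls_frame(rows)
        out = group_locus_stats(frame, {f"s{i}": "G" for i in range(10)})
        assert out.loc[0, "pic"] == pytest.approx(1 - 0.9 ** 2 - 0.1 ** 2)
        rows4 = [["a", "L0", 10, 10, 0.9, 5], ["b", "L0", 10, 10, 0.9, 5],
                 ["c", "L0", 10, 10, 0.9, 5], ["d", "L0", 10, 12, 0.9, 5]]
        out4 = group_locus_stats(calls_frame(rows4), {s: "G" for s in "abcd"})
        assert out4.loc[0, "het_ratio"] == pytest.approx(0.25)
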