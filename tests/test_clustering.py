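"""Clustering, consensus calling, dendrogram, representatives, logo/heatmap."""

import itertools

import numpy as np
import pytest

from affiselect.clustering import (
    ClusterSet,
    build_dendrogram,
    cluster_pool,
    consensus_of,
    heatmap_matrix,
    linkage_to_newick,
    logo_matrix,
    select_representatives,
)
from affiselect.grantham import AMINO_ACIDS, sequence_distance


def brute_force_average_clusters(seqs, cutoff):
    """Independent agglomerative oracle: repeatedly merge the closest pair of
    clusters under mean-pairwise (average-linkage) distance until the minimum
    exceeds the cutoff.  Returns the partition as a set of frozensets.
    Raises on a distance tie between distinct candidate merges, where the
    merge order (and hence the flat partition) is not uniquely defined.
    """
    clusters = [frozenset([s]) for s in seqs]
    while len(clusters) > 1:
        cand = []
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = np.mean(
                [sequence_distance(a, b) for a in clusters[i] for b in clusters[j]]
            )
            cand.append((d, i, j))
        cand.sort()
        if len(cand) > 1 and abs(cand[0][0] - cand[1][0]) < 1e-9:
            raise ValueError("tied merge")
        d, i, j = cand[0]
        if d > cutoff:
            break
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return set(clusters)


def random_pool(rng, n, length=8):
    return list({"".join(rng.choice(list(AMINO_ACIDS), length)) for _ in range(n)})


class TestClusterPool:
    def test_single_sequence_single_cluster(self, toy_design):
        cs = cluster_pool(["MKVAGELT"], cutoff=100)
        assert len(cs) == 1 and cs.clusters[0].consensus == "MKVAGELT"

    def test_two_planted_families(self, rng):
        # within-family distance <= 40, between >= 400
        fam_a = ["MKVAGELT", "MKVAGELS", "MKIAGELT"]
        fam_b = ["WDDWWDWD", "WDDWWDWN", "WDDWWEWD"]
        for a in fam_a:
            for b in fam_b:
                assert sequence_distance(a, b) >= 400
        for fam in (fam_a, fam_b):
            for a, b in itertools.combinations(fam, 2):
                assert sequence_distance(a, b) <= 120
        cs = cluster_pool(fam_a + fam_b, cutoff=150)
        assert len(cs) == 2
        assert {frozenset(c.members) for c in cs.clusters} == {
            frozenset(fam_a),
            frozenset(fam_b),
        }

    def test_oracle_equivalence_small_pools(self, rng):
        """cluster_pool matches first-principles agglomeration on pools <= 12."""
        checked = 0
        for trial in range(20):
            seqs = random_pool(rng, int(rng.integers(3, 13)))
            cutoff = float(rng.uniform(50, 600))
            try:
                expected = brute_force_average_clusters(seqs, cutoff)
            except ValueError:
                continue  # tied merge: flat partition not uniquely defined
            cs = cluster_pool(seqs, cutoff=cutoff)
            got = {frozenset(c.members) for c in cs.clusters}
            assert got == expected, f"trial {trial}"
            checked += 1
        assert checked >= 10

    def test_partition_property(self, rng):
        seqs = random_pool(rng, 30)
        cs = cluster_pool(seqs, cutoff=300)
        assert sum(c.size for c in cs.clusters) == len(seqs)
        assert set(cs.assignment) == set(seqs)
        for s, cid in cs.assignment.items():
            assert s in cs.clusters[cid].members

    def test_deterministic_under_reordering(self, rng):
        seqs = random_pool(rng, 20)
        cs1 = cluster_pool(seqs, cutoff=250)
        cs2 = cluster_pool(list(reversed(seqs)), cutoff=250)
        assert [c.members for c in cs1.clusters] == [c.members for c in cs2.clusters]

    def test_n_clusters_override(self, rng):
        seqs = random_pool(rng, 15)
        cs = cluster_pool(seqs, n_clusters=4)
        assert len(cs) == 4

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            cluster_pool(["MK", "ML"], cutoff=0)


class TestConsensus:
    def test_singleton(self):
        assert consensus_of(["MKVL"]) == "MKVL"

    def test_majority_by_distance(self):
        # at each position, L beats I 2:1 and minimizes summed distance
        assert consensus_of(["LL", "LL", "II"]) == "LL"

    def test_identical_members(self):
        assert consensus_of(["MKVL"] * 4) == "MKVL"

    def test_brute_force_oracle(self, rng):
        """Per position the consensus residue minimizes the summed Grantham
        distance over observed candidates (frequency then alphabet on ties),
        checked by explicit enumeration."""
        for _ in range(10):
            members = ["".join(rng.choice(list(AMINO_ACIDS), 5)) for _ in range(6)]
            cons = consensus_of(members)
            for j in range(5):
                observed = sorted({m[j] for m in members})
                freq = {aa: sum(m[j] == aa for m in members) for aa in observed}
                best = min(
                    observed,
                    key=lambda aa: (
                        sum(sequence_distance(aa, m[j]) for m in members),
                        -freq[aa],
                        aa,
                    ),
                )
                assert cons[j] == best

    def test_diversity_zero_iff_identical(self):
        cs = cluster_pool(["MKVL"], cutoff=10)
        assert cs.clusters[0].diversity == 0.0
        cs2 = cluster_pool(["MKVL", "MKVI"], cutoff=100)
        assert cs2.clusters[0].diversity > 0


class TestDendrogram:
    def test_two_leaves_merge_at_pairwise_distance(self):
        Z = build_dendrogram(["MKVL", "MKVI"])
        assert Z.shape == (1, 4)
        assert Z[0, 2] == sequence_distance("MKVL", "MKVI")

    def test_closest_pair_merges_first(self):
        a, b, c = "LLLL", "LLLI", "WWWW"
        assert sequence_distance(a, b) < sequence_distance(a, c)
        Z = build_dendrogram([a, b, c])
        # first merge joins leaves 0 and 1 (a, b)
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_permutation_invariant_topology(self):
        seqs = ["LLLL", "LLLI", "WWWW", "WWWD"]
        nwk1 = linkage_to_newick(build_dendrogram(seqs), seqs)
        # same tree after permuting leaf order: compare sibling sets
        perm = [seqs[2], seqs[0], seqs[3], seqs[1]]
        nwk2 = linkage_to_newick(build_dendrogram(perm), perm)
        import re

        def sibling_pairs(nwk):
            return {
                frozenset(m.groups())
                for m in re.finditer(r"\(([A-Z]+):[0-9.]+,([A-Z]+):[0-9.]+\)", nwk)
            }

        assert sibling_pairs(nwk1) == sibling_pairs(nwk2)

    def test_fewer_than_two_raises(self):
        with pytest.raises(ValueError):
            build_dendrogram(["MKVL"])

    def test_merge_heights_non_decreasing(self, rng):
        seqs = random_pool(rng, 10)
        Z = build_dendrogram(seqs)
        assert np.all(np.diff(Z[:, 2]) >= 0)


class TestRepresentatives:
    def _clusterset(self, seqs, cutoff=10):
        return cluster_pool(seqs, cutoff=cutoff)

    def test_n_equals_cluster_count_returns_all(self):
        cs = self._clusterset(["LLLL", "WWWW", "DDDD"])
        reps = select_representatives(cs, 3)
        assert sorted(reps) == sorted(cs.consensuses)

    def test_n_one_returns_largest_cluster_consensus(self):
        cs = cluster_pool(["LLLL", "LLLI", "WWWW"], cutoff=50)
        assert cs.clusters[0].size == 2  # seeding rule: largest cluster first
        assert select_representatives(cs, 1) == [cs.clusters[0].consensus]

    def test_maxmin_picks_extremes_on_a_line(self):
        """Four singleton clusters on a Grantham line; n=2 must pick the two
        ends, verified against exhaustive max-min search over all pairs."""
        # G-A = 60ish scale; use residue strings with graded distances
        seqs = ["GGGG", "AGGG", "WGGG", "WWGG"]
        cs = cluster_pool(seqs, cutoff=1)
        assert len(cs) == 4
        reps = set(select_representatives(cs, 2))
        dist = {
            (a, b): sequence_distance(a, b) for a in seqs for b in seqs if a != b
        }
        # exhaustive: the pair containing the seed (largest cluster; here the
        # lexicographically-first consensus of equal-size clusters) with max
        # distance to it
        seed = cs.consensuses[0]
        best = max((s for s in seqs if s != seed), key=lambda s: dist[(seed, s)])
        assert reps == {seed, best}

    def test_out_of_range_raises(self):
        cs = self._clusterset(["LLLL", "WWWW"])
        with pytest.raises(ValueError):
            select_representatives(cs, 3)
        with pytest.raises(ValueError):
            select_representatives(cs, 0)


class TestLogoHeatmap:
    def test_single_sequence_one_hot(self):
        logo = logo_matrix(["MK"])
        assert logo.loc[0, "M"] == 1.0 and logo.loc[1, "K"] == 1.0
        assert np.allclose(logo.sum(axis=1), 1.0)

    def test_frequencies_over_unique_sequences(self):
        logo = logo_matrix(["AK", "AR", "AK"])  # duplicate collapses
        assert logo.loc[0, "A"] == 1.0
        assert logo.loc[1, "K"] == 0.5 and logo.loc[1, "R"] == 0.5

    def test_columns_sum_to_one(self, rng):
        seqs = random_pool(rng, 25, length=6)
        logo = logo_matrix(seqs)
        assert np.allclose(logo.sum(axis=1), 1.0)

    def test_heatmap_zero_column_implies_one_hot_logo(self):
        seqs = ["MKVL", "MKVI", "MKIL"]
        cs = cluster_pool(seqs, cutoff=500)
        hm = heatmap_matrix(cs)
        logo = logo_matrix(seqs)
        for j in range(4):
            if np.all(hm[j].to_numpy() == 0):
                assert logo.loc[j].max() == 1.0

    def test_heatmap_rows_are_profiles(self):
        seqs = ["MKVL", "MKVI"]
        cs = cluster_pool(seqs, cutoff=500)
        hm = heatmap_matrix(cs)
        cons = cs.clusters[0].consensus
        for (cid, seq), row in hm.iterrows():
            assert row.sum() == sequence_distance(seq, cons)
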