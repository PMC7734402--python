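"""Alignment, distances, neighbor joining and newick round-trips."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from thermosig.phylo import (
    AlignedPair,
    DistanceMatrix,
    bootstrap_support,
    distance_matrix,
    global_align,
    neighbor_joining,
    percent_identity,
    read_newick,
    tip_distance_matrix,
    write_newick,
)

# ---------------------------------------------------------------------------
# independent Gotoh affine-gap DP oracle (scores only)


def gotoh_score(a, b, match=1.0, mismatch=-1.0, gap_open=-5.0, gap_extend=-1.0):
    """Affine-gap global alignment score; gap of length k costs
    gap_open + (k-1)*gap_extend.  Plain O(nm) dynamic program."""
    n, m = len(a), len(b)
    neg = -math.inf
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def random_additive_tree(n_taxa, rng):
    """Random binary topology with positive branch lengths; returns the
    exact leaf-to-leaf path-length matrix (labels t0..t{n-1}, sorted)."""
    # each cluster: dict leaf -> distance to cluster root
    clusters = [{f"t{i}": 0.0} for i in range(n_taxa)]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        a, b = clusters[i], clusters[j]
        la, lb = rng.uniform(0.05, 1.0, size=2)
        merged = {k: v + la for k, v in a.items()}
        merged.update({k: v + lb for k, v in b.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        # record pairwise distances on merge
        for ka, va in a.items():
            for kb, vb in b.items():
                random_additive_tree.dists[(ka, kb)] = va + la + vb + lb
    labels = sorted(f"t{i}" for i in range(n_taxa))
    d = np.zeros((n_taxa, n_taxa))
    for x in range(n_taxa):
        for y in range(x + 1, n_taxa):
            key = (labels[x], labels[y])
            v = random_additive_tree.dists.get(key) or random_additive_tree.dists[
                (labels[y], labels[x])
            ]
            d[x, y] = d[y, x] = v
    random_additive_tree.dists = {}
    return labels, d


random_additive_tree.dists = {}


class TestAlignmentAndIdentity:
    def test_identical_sequences(self):
        pair = global_align("ACGT", "ACGT")
        assert percent_identity(pair) == 100.0

    def test_single_substitution(self):
        pair = global_align("ACGT", "ACGA")
        assert percent_identity(pair) == 75.0

    def test_identity_symmetric(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = "".join(rng.choice(list("ACGT"), size=80))
            b = "".join(rng.choice(list("ACGT"), size=75))
            assert percent_identity(global_align(a, b)) == pytest.approx(
                percent_identity(global_align(b, a))
            )

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_score_matches_independent_dp(self):
        rng = np.random.default_rng(99)
        for n, m in [(60, 60), (200, 180), (50, 90)]:
            a = "".join(rng.choice(list("ACGT"), size=n))
            b = "".join(rng.choice(list("ACGT"), size=m))
            pair = global_align(a, b)
            assert pair.score == pytest.approx(gotoh_score(a, b))

    def test_gap_columns_excluded_by_default(self):
        pair = AlignedPair("ACG-T", "ACGGT", score=0)
        assert percent_identity(pair) == 100.0
        assert percent_identity(pair, "include_gaps") == 80.0

    def test_no_compared_columns_error(self):
        pair = AlignedPair("A-", "-A", score=0)
        with pytest.raises(ValueError, match="compared"):
            percent_identity(pair)

    def test_both_gapped_column_rejected(self):
        with pytest.raises(ValueError):
            AlignedPair("A-C", "A-C", score=0)

    def test_one_substitution_in_thousand(self):
        a = "ACGT" * 250
        b = a[:500] + ("A" if a[500] != "A" else "C") + a[501:]
        assert percent_identity(global_align(a, b)) == pytest.approx(99.9)


class TestDistances:
    def test_identical_sequences_zero(self):
        dm = distance_matrix([("a", "ACGT"), ("b", "ACGT"), ("c", "ACGT")])
        assert np.all(dm.d == 0)

    def test_jc_closed_form(self):
        # p = 0.25 -> d = -(3/4) ln(2/3)
        seqs = [("a", "AAAA"), ("b", "AAAC"), ("c", "AAAA")]
        dm = distance_matrix(seqs, model="jukes_cantor")
        expected = -0.75 * math.log(2 / 3)
        assert dm.d[0, 1] == pytest.approx(expected)

    def test_jc_geq_p_distance(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            p = rng.uniform(0.01, 0.70)
            jc = -0.75 * math.log1p(-4 * p / 3)
            assert jc >= p

    def test_saturation_error_names_pair(self):
        seqs = [("a", "AAAA"), ("b", "CCCC"), ("c", "AAAA")]
        with pytest.raises(ValueError, match="a.*b"):
            distance_matrix(seqs, model="jukes_cantor")

    def test_pairwise_gap_deletion(self):
        seqs = [("a", "AC-T"), ("b", "ACGT"), ("c", "ACGA")]
        dm = distance_matrix(seqs)
        assert dm.d[0, 1] == 0.0  # gap column dropped for this pair
        assert dm.d[1, 2] == pytest.approx(0.25)

    def test_symmetry_and_zero_diagonal_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(2.0)
        assert lengths["b"] == pytest.approx(3.0)
        assert lengths["c"] == pytest.approx(7.0)

    def test_additive_four_taxon_exact(self):
        labels, d = random_additive_tree(4, np.random.default_rng(5))
        tree = neighbor_joining(DistanceMatrix(labels, d))
        dm = tip_distance_matrix(tree)
        assert np.allclose(dm.d, d, atol=1e-10)

    def test_additive_random_trees_reproduced(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            labels, d = random_additive_tree(n, rng)
            tree = neighbor_joining(DistanceMatrix(labels, d))
            dm = tip_distance_matrix(tree)
            assert dm.labels == labels
            assert np.allclose(dm.d, d, atol=1e-9)

    def test_star_matrix_completes_deterministically(self):
        n = 6
        d = np.ones((n, n)) - np.eye(n)
        labels = [f"t{i}" for i in range(n)]
        t1 = neighbor_joining(DistanceMatrix(labels, d))
        t2 = neighbor_joining(DistanceMatrix(labels, d))
        assert str(t1) == str(t2)

    def test_matches_skbio_nj_on_additive_matrix(self):
        labels, d = random_additive_tree(8, np.random.default_rng(77))
        ours = tip_distance_matrix(neighbor_joining(DistanceMatrix(labels, d)))
        ref = skbio_nj(SkbioDM(d, ids=labels))
        ref_dm = ref.tip_tip_distances()
        ref_sub = ref_dm.filter(sorted(ref_dm.ids))
        assert np.allclose(ours.d, ref_sub.data, atol=1e-9)

    def test_too_few_taxa_error(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestNewick:
    def test_three_taxon_round_trip(self, tmp_path):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        path = tmp_path / "t.nwk"
        text = write_newick(tree, path)
        assert text.strip().endswith(";")
        back = read_newick(path)
        assert {t.name for t in back.tips()} == {"a", "b", "c"}
        assert np.allclose(
            tip_distance_matrix(back).d, tip_distance_matrix(tree).d
        )

    def test_twenty_taxon_round_trip_path_lengths(self, tmp_path):
        labels, d = random_additive_tree(20, np.random.default_rng(13))
        tree = neighbor_joining(DistanceMatrix(labels, d))
        path = tmp_path / "big.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert np.allclose(tip_distance_matrix(back).d, d, atol=1e-8)


class TestBootstrap:
    def test_supports_in_range_and_high_for_clear_split(self):
        rng = np.random.default_rng(2)
        core = "".join(rng.choice(list("ACGT"), size=400))

        def mutate(s, k):
            s = list(s)
            for i in rng.choice(len(s), size=k, replace=False):
                s[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[i]]
            return "".join(s)

        groupA = mutate(core, 120)
        seqs = [
            ("a1", mutate(core, 3)), ("a2", mutate(core, 3)),
            ("b1", mutate(groupA, 3)), ("b2", mutate(groupA, 3)),
            ("out", mutate(core, 200)),
        ]
        tree = bootstrap_support(seqs, replicates=50, seed=0)
        supports = [int(n.name) for n in tree.non_tips(include_self=False)
                    if n.name is not None]
        assert supports, "internal nodes carry support values"
        assert all(0 <= s <= 100 for s in supports)
        assert max(supports) >= 90  # the a/b split is unambiguous
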