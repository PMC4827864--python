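import itertools

import dendropy
import numpy as np
import pytest
from scipy.optimize import nnls

from ompbarrel.seqio import ProteinRecord, SequenceSet
from ompbarrel.simulate import (
    BarrelSpec,
    FamilySpec,
    SuperfamilySpec,
    evolve_family,
    make_ancestor,
    make_superfamily,
)
from ompbarrel.trees import (
    DistanceMatrix,
    allvsall_scores,
    clade_support,
    consensus_tree,
    family_tree,
    is_monophyletic,
    msa_tree,
    nj_tree,
    read_newick,
    rf_distance,
    scores_to_distances,
    write_newick,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _rand_set(rng, n, length=80, prefix="s"):
    return SequenceSet(
        [ProteinRecord(f"{prefix}{i}", "".join(rng.choice(list(AA), size=length)))
         for i in range(n)]
    )


class TestScores:
    def test_identical_sequences_give_equal_offdiagonals(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(AA), size=80))
        sset = SequenceSet([ProteinRecord(f"x{i}", seq) for i in range(4)])
        sm = allvsall_scores(sset)
        off = sm.bits[~np.eye(4, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_matrix_is_symmetric_and_diagonal_dominant(self):
        rng = np.random.default_rng(1)
        sm = allvsall_scores(_rand_set(rng, 5))
        assert np.allclose(sm.bits, sm.bits.T)
        for i in range(5):
            for j in range(5):
                assert sm.bits[i, j] <= min(sm.bits[i, i], sm.bits[j, j]) + 1e-9

    def test_matches_pair_by_pair_recomputation(self):
        from ompbarrel.homology import bit_score
        from ompbarrel.pairwise import DEFAULT_PARAMS, align_score

        rng = np.random.default_rng(2)
        sset = _rand_set(rng, 4)
        sm = allvsall_scores(sset)
        for i, ra in enumerate(sset):
            for j, rb in enumerate(sset):
                s = align_score(ra.ungapped, rb.ungapped, mode="local")
                assert sm.bits[i, j] == pytest.approx(bit_score(s, DEFAULT_PARAMS))

    def test_fewer_than_three_sequences_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            allvsall_scores(_rand_set(rng, 2))


class TestDistances:
    def test_identical_sequences_have_zero_distance(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list(AA), size=80))
        sset = SequenceSet([ProteinRecord(f"x{i}", seq) for i in range(3)])
        dm = scores_to_distances(allvsall_scores(sset))
        assert np.allclose(dm.d, 0.0)

    def test_nonpositive_scores_saturate_at_one(self):
        from ompbarrel.trees import ScoreMatrix

        bits = np.array([[50.0, -1.0, 10.0],
                         [-1.0, 40.0, 5.0],
                         [10.0, 5.0, 45.0]])
        dm = scores_to_distances(ScoreMatrix(["a", "b", "c"], bits))
        assert dm.d[0, 1] == 1.0

    def test_raising_a_score_never_increases_its_distance(self):
        from ompbarrel.trees import ScoreMatrix

        rng = np.random.default_rng(5)
        for _ in range(20):
            self_b = rng.uniform(30, 80, size=4)
            bits = np.minimum.outer(self_b, self_b) * rng.uniform(0.1, 0.9, (4, 4))
            bits = (bits + bits.T) / 2
            np.fill_diagonal(bits, self_b)
            i, j = 0, 1
            d1 = scores_to_distances(ScoreMatrix(list("abcd"), bits)).d[i, j]
            bits2 = bits.copy()
            bits2[i, j] = bits2[j, i] = bits[i, j] + rng.uniform(0, 5)
            d2 = scores_to_distances(ScoreMatrix(list("abcd"), bits2)).d[i, j]
            assert d2 <= d1 + 1e-12


class TestNeighborJoining:
    def test_recovers_four_taxon_additive_tree_exactly(self):
        # ((A:1,B:2):1,(C:3,D:4)) pairwise path lengths
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        t = nj_tree(DistanceMatrix(list("ABCD"), d))
        truth = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        assert rf_distance(t, truth) == 0
        lengths = {
            l.taxon.label: l.edge.length for l in t.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_agrees_with_least_squares_search_on_five_taxa(self):
        rng = np.random.default_rng(6)
        labels = list("ABCDE")
        # random additive matrix from a random tree + tiny noise
        tns = dendropy.TaxonNamespace(labels)
        gen = dendropy.Tree.get(data="((A:2,B:3):1,(C:2,(D:1,E:2):2):1);",
                                schema="newick", taxon_namespace=tns)
        pdm = gen.phylogenetic_distance_matrix()
        d = np.zeros((5, 5))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    d[i, j] = pdm.distance(
                        tns.get_taxon(a), tns.get_taxon(b)
                    )
        d += rng.normal(0, 0.01, d.shape)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)

        def topology_sse(newick):
            t = dendropy.Tree.get(data=newick, schema="newick")
            t.encode_bipartitions()
            pairs = list(itertools.combinations(range(5), 2))
            edges = [e for e in t.edges() if e.bipartition.leafset_bitmask]
            tns2 = t.taxon_namespace
            rows = []
            for i, j in pairs:
                row = []
                mask_i = tns2.taxa_bitmask(labels=[labels[i]])
                mask_j = tns2.taxa_bitmask(labels=[labels[j]])
                for e in edges:
                    m = e.bipartition.leafset_bitmask
                    row.append(1.0 if bool(m & mask_i) != bool(m & mask_j) else 0.0)
                rows.append(row)
            A = np.array(rows)
            y = np.array([d[i, j] for i, j in pairs])
            x, _ = nnls(A, y)
            return float(((A @ x - y) ** 2).sum())

        # all 15 unrooted 5-taxon topologies
        topologies = []
        for others in itertools.permutations(labels[1:]):
            nwk = f"(({labels[0]},{others[0]}),({others[1]},({others[2]},{others[3]})));"
            topologies.append(nwk)
        best = min(topologies, key=topology_sse)
        t = nj_tree(DistanceMatrix(labels, d))
        assert rf_distance(
            t, dendropy.Tree.get(data=best, schema="newick")
        ) == 0

    def test_star_like_equal_distances_give_valid_tree(self):
        d = np.ones((5, 5)) - np.eye(5)
        t = nj_tree(DistanceMatrix(list("ABCDE"), d))
        assert {l.taxon.label for l in t.leaf_node_iter()} == set("ABCDE")

    def test_nonfinite_distances_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.inf
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(list("ABC"), d))


class TestConsensus:
    def test_zero_noise_replicates_reproduce_point_tree_at_full_support(self):
        rng = np.random.default_rng(7)
        sset = _rand_set(rng, 6)
        point = nj_tree(scores_to_distances(allvsall_scores(sset)))
        cons = consensus_tree(sset, n_replicates=10, seed=0, strategy="none")
        assert rf_distance(cons, point) == 0
        sups = [n.label for n in cons.internal_nodes() if n.label]
        assert sups and all(float(s) == 100 for s in sups)

    def test_leaf_input_order_does_not_change_consensus(self, small_family):
        fam, _ = small_family
        sub = SequenceSet(fam.records[:6])
        shuffled = SequenceSet(list(reversed(fam.records[:6])))
        t1 = consensus_tree(sub, n_replicates=20, seed=3)
        t2 = consensus_tree(shuffled, n_replicates=20, seed=3)
        assert rf_distance(t1, t2) == 0

    def test_planted_families_are_monophyletic_with_high_support(self):
        fams, _, _ = make_superfamily(SuperfamilySpec(
            guide_tree=(("A", "B"), "C"), branch_identity=0.45,
            family=FamilySpec(n_members=5, target_within_identity=0.55),
            seed=71,
        ))
        merged = SequenceSet([r for f in sorted(fams) for r in fams[f]])
        cons = consensus_tree(merged, n_replicates=50, seed=1)
        for f in fams:
            leaves = {r.id for r in fams[f]}
            assert is_monophyletic(cons, leaves)
            assert clade_support(cons, leaves) >= 90

    def test_consensus_stable_across_seeds(self):
        fams, _, _ = make_superfamily(SuperfamilySpec(
            guide_tree=(("A", "B"), "C"), branch_identity=0.5,
            family=FamilySpec(n_members=4, target_within_identity=0.6),
            seed=72,
        ))
        merged = SequenceSet([r for f in sorted(fams) for r in fams[f]])
        t1 = consensus_tree(merged, n_replicates=50, seed=10)
        t2 = consensus_tree(merged, n_replicates=50, seed=20)
        assert rf_distance(t1, t2) <= 2


class TestFamilyTree:
    def test_staggered_divergence_groups_closest_pair(self):
        fams, _, _ = make_superfamily(SuperfamilySpec(
            guide_tree=(("A", "B"), "C"), branch_identity=0.5,
            family=FamilySpec(n_members=4, target_within_identity=0.6),
            seed=73,
        ))
        ft = family_tree(fams, n_replicates=30, seed=0, min_members=3)
        assert is_monophyletic(ft, {"A", "B"})

    def test_duplicated_family_sits_at_zero_distance(self):
        fams, _, _ = make_superfamily(SuperfamilySpec(
            guide_tree=("A", "B"), branch_identity=0.5,
            family=FamilySpec(n_members=4, target_within_identity=0.6),
            seed=74,
        ))
        dup = {
            "A": fams["A"],
            "A2": SequenceSet(
                [ProteinRecord(r.id + "_dup", r.sequence) for r in fams["A"]]
            ),
            "B": fams["B"],
        }
        ft = family_tree(dup, n_replicates=10, seed=0, min_members=3)
        for leaf in ft.leaf_node_iter():
            if leaf.taxon.label in ("A", "A2"):
                assert leaf.edge.length == pytest.approx(0.0, abs=1e-6)

    def test_sparse_families_warn_but_proceed(self):
        fams, _, _ = make_superfamily(SuperfamilySpec(
            guide_tree=(("A", "B"), "C"), branch_identity=0.5,
            family=FamilySpec(n_members=2, target_within_identity=0.7),
            seed=75,
        ))
        with pytest.warns(UserWarning, match="members"):
            family_tree(fams, n_replicates=5, seed=0)

    def test_five_members_beat_single_members_on_divergent_data(self):
        wins = {"five": 0, "one": 0}
        truth = dendropy.Tree.get(data="(((A,B),C),(D,E));", schema="newick")
        for s in range(6):
            fams, _, _ = make_superfamily(SuperfamilySpec(
                guide_tree=((("A", "B"), "C"), ("D", "E")),
                branch_identity=0.35,
                family=FamilySpec(n_members=5, target_within_identity=0.5),
                seed=760 + s,
            ))
            singles = {f: SequenceSet(fams[f].records[:1]) for f in fams}
            t5 = family_tree(fams, n_replicates=10, seed=s, min_members=1)
            t1 = family_tree(singles, n_replicates=10, seed=s, min_members=1)
            wins["five"] += rf_distance(t5, truth) == 0
            wins["one"] += rf_distance(t1, truth) == 0
        assert wins["five"] >= wins["one"]


class TestMsaTree:
    def test_low_divergence_agrees_with_score_tree_at_family_level(self):
        fams, _, _ = make_superfamily(SuperfamilySpec(
            guide_tree=(("A", "B"), "C"), branch_identity=0.75,
            family=FamilySpec(n_members=4, target_within_identity=0.8),
            seed=77,
        ))
        merged = SequenceSet([r for f in sorted(fams) for r in fams[f]])
        mt = msa_tree(merged)
        st = nj_tree(scores_to_distances(allvsall_scores(merged)))
        ab = {r.id for f in ("A", "B") for r in fams[f]}
        for tree in (mt, st):
            for f in fams:
                assert is_monophyletic(tree, {r.id for r in fams[f]})
            assert is_monophyletic(tree, ab)


def test_newick_roundtrip_preserves_everything(tmp_path, small_family):
    fam, _ = small_family
    sub = SequenceSet(fam.records[:6])
    t = consensus_tree(sub, n_replicates=20, seed=4)
    path = tmp_path / "t.nwk"
    write_newick(t, path)
    back = read_newick(path)
    assert rf_distance(t, back) == 0
    orig = sorted(
        round(l.edge.length, 9) for l in t.leaf_node_iter() if l.edge.length
    )
    got = sorted(
        round(l.edge.length, 9) for l in back.leaf_node_iter() if l.edge.length
    )
    assert orig == got
    sups_a = sorted(n.label for n in t.internal_nodes() if n.label)
    sups_b = sorted(n.label for n in back.internal_nodes() if n.label)
    assert sups_a == sups_b
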