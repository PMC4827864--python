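import random

import numpy as np
import pytest

from ompbarrel.homology import (
    HomologyEdge,
    build_superfamilies,
    evalue,
    expand_family,
    karlin_altschul_params,
    tssearch,
    verify_chain,
)
from ompbarrel.pairwise import AlignmentParams, SegmentRule, align_score
from ompbarrel.seqio import ProteinRecord, SequenceSet
from ompbarrel.simulate import BarrelSpec, FamilySpec, evolve_family, make_ancestor
from ompbarrel.simulate import _calibrate_p_sub, _mutate_model
from oracles import dfs_components

AA = "ACDEFGHIKLMNPQRSTVWY"


def _rand_rec(rng, name, n=120):
    return ProteinRecord(name, "".join(rng.choice(list(AA), size=n)))


class TestEvalue:
    def test_known_gap_combination_available(self):
        lam, k = karlin_altschul_params(AlignmentParams())
        assert 0 < lam < 1 and 0 < k < 1

    def test_unknown_combination_is_instructive_error(self):
        with pytest.raises(KeyError, match="Karlin-Altschul"):
            karlin_altschul_params(AlignmentParams(gap_open=30, gap_extend=5))

    def test_evalue_decreases_with_score(self):
        p = AlignmentParams()
        assert evalue(100, 200, 10000, p) > evalue(200, 200, 10000, p)


@pytest.fixture(scope="module")
def two_hop_db():
    """Planted A -> I -> B reachability with unrelated decoys."""
    rng = np.random.default_rng(1)
    _, _, model = make_ancestor(BarrelSpec(n_hairpins=6), seed=31)
    p = _calibrate_p_sub(model, 0.45, 0.01, np.random.default_rng(2),
                         between_members=False)
    inter = _mutate_model(model, p, 0.01, np.random.default_rng(3))
    far = _mutate_model(inter, p, 0.01, np.random.default_rng(4))
    seed = ProteinRecord("A", model.sequence)
    db = SequenceSet([
        seed,
        ProteinRecord("I", inter.sequence),
        ProteinRecord("B", far.sequence),
        _rand_rec(rng, "decoy1", 250),
        _rand_rec(rng, "decoy2", 250),
    ])
    return seed, db


class TestExpandFamily:
    def test_database_of_only_seed_returns_seed(self):
        rng = np.random.default_rng(0)
        seed = _rand_rec(rng, "seed")
        out = expand_family(seed, SequenceSet([seed]))
        assert out.ids == ["seed"]

    def test_two_iterations_reach_through_intermediate(self, two_hop_db):
        seed, db = two_hop_db
        out = expand_family(seed, db, iterations=2, cutoffs=(1e-4, 1e-6))
        assert {"A", "I", "B"} <= set(out.ids)
        assert not {"decoy1", "decoy2"} & set(out.ids)

    def test_stringent_cutoff_stays_at_seed(self, two_hop_db):
        seed, db = two_hop_db
        out = expand_family(seed, db, iterations=1, cutoffs=(1e-60,))
        assert out.ids == ["A"]

    def test_second_pass_respects_its_cutoff(self, two_hop_db):
        seed, db = two_hop_db
        out = expand_family(seed, db, iterations=2, cutoffs=(1e-4, 1e-6))
        p = AlignmentParams()
        total = sum(len(r.ungapped) for r in db)
        for rec in out:
            if rec.id in ("A", "I"):
                continue
            best = min(
                evalue(align_score(q.ungapped, rec.ungapped, p, mode="local"),
                       len(q.ungapped), total, p)
                for q in out if q.id != rec.id
            )
            assert best <= 1e-6


class TestTssearch:
    def test_single_self_pair_ranks_first(self):
        rng = np.random.default_rng(5)
        rec = _rand_rec(rng, "only")
        hits = tssearch(SequenceSet([rec]), SequenceSet([rec]))
        assert hits[0][1].id == hits[0][2].id == "only"

    def test_planted_pair_outranks_decoys(self):
        rng = np.random.default_rng(6)
        shared = "".join(rng.choice(list(AA), size=80))
        a = ProteinRecord("hit_a", shared + "".join(rng.choice(list(AA), 40)))
        b = ProteinRecord("hit_b", "".join(rng.choice(list(AA), 40)) + shared)
        set_a = SequenceSet([a, _rand_rec(rng, "da1"), _rand_rec(rng, "da2")])
        set_b = SequenceSet([b, _rand_rec(rng, "db1"), _rand_rec(rng, "db2")])
        top = tssearch(set_a, set_b, top_k=1)[0]
        assert (top[1].id, top[2].id) == ("hit_a", "hit_b")

    def test_ranking_matches_exhaustive_score_table(self):
        rng = np.random.default_rng(7)
        set_a = SequenceSet([_rand_rec(rng, f"a{i}", 60) for i in range(5)])
        set_b = SequenceSet([_rand_rec(rng, f"b{i}", 60) for i in range(5)])
        hits = tssearch(set_a, set_b)
        table = {
            (ra.id, rb.id): align_score(ra.ungapped, rb.ungapped, mode="local")
            for ra in set_a for rb in set_b
        }
        expected = sorted(table, key=lambda k: (-table[k], k[0], k[1]))
        assert [(ra.id, rb.id) for _, ra, rb in hits] == expected


class TestVerifyChain:
    def test_self_chain_accepted(self):
        rng = np.random.default_rng(8)
        rec = _rand_rec(rng, "self", 120)
        chain = verify_chain(rec, rec, rec, rec, n_shuffles=100, seed=1)
        assert chain.accepted

    def test_short_sequence_rejected_with_reason(self):
        rng = np.random.default_rng(9)
        short = _rand_rec(rng, "tiny", 40)
        other = _rand_rec(rng, "big", 120)
        chain = verify_chain(short, other, other, other, n_shuffles=100, seed=1)
        assert not chain.accepted
        assert "below 60 aa" in chain.reason

    def test_calibrated_chain_accepts_while_direct_rejects(self):
        _, _, hub = make_ancestor(BarrelSpec(n_hairpins=8), seed=41)
        rng = np.random.default_rng(10)
        p = _calibrate_p_sub(hub, 0.25, 0.01, rng, between_members=False)
        end_a = _mutate_model(hub, p, 0.01, rng)
        end_c = _mutate_model(hub, p, 0.01, rng)
        fam_b, _ = evolve_family(hub, FamilySpec(2, 0.85, seed=51))
        a = ProteinRecord("a", end_a.sequence)
        d = ProteinRecord("d", end_c.sequence)
        chain = verify_chain(a, fam_b[0], fam_b[1], d, n_shuffles=300, seed=2)
        assert chain.accepted and chain.method == "chained"
        assert chain.z_ad_direct < 12
        assert min(chain.z_ab, chain.z_bc, chain.z_cd) > 12


class TestBuildSuperfamilies:
    def test_no_edges_gives_singletons_with_no_evidence_status(self):
        family_of = {"p1": "F1", "p2": "F2", "p3": "F3"}
        out = build_superfamilies([], family_of)
        assert len(out.members) == 3
        assert all(out.status(f) == "no evidence" for f in ("F1", "F2", "F3"))

    def test_transitive_merge(self):
        family_of = {"a": "A", "b": "B", "c": "C"}
        edges = [
            HomologyEdge("a", "b", 15.0, 80),
            HomologyEdge("b", "c", 14.0, 80),
        ]
        out = build_superfamilies(edges, family_of)
        assert out.members["SFI"] == ["A", "B", "C"]

    def test_largest_component_is_sfi(self):
        family_of = {f"p{i}": f"F{i}" for i in range(5)}
        edges = [
            HomologyEdge("p0", "p1", 13, 70),
            HomologyEdge("p1", "p2", 13, 70),
            HomologyEdge("p3", "p4", 13, 70),
        ]
        out = build_superfamilies(edges, family_of)
        assert out.members["SFI"] == ["F0", "F1", "F2"]
        assert out.members["SFII"] == ["F3", "F4"]

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_dfs_oracle_on_random_graphs(self, trial):
        rng = random.Random(trial)
        for rep in range(10):
            n = rng.randint(3, 12)
            fams = [f"F{i}" for i in range(n)]
            family_of = {f"p{i}": fams[i] for i in range(n)}
            edges = []
            for _ in range(rng.randint(0, 2 * n)):
                u, v = rng.sample(range(n), 2)
                edges.append(HomologyEdge(f"p{u}", f"p{v}", 13.0, 70))
            out = build_superfamilies(edges, family_of)
            expected = set(
                dfs_components(fams, [(family_of[e.id_a], family_of[e.id_b])
                                      for e in edges])
            )
            got = {frozenset(m) for m in out.members.values()}
            assert got == expected

    def test_partition_is_order_independent(self):
        rng = random.Random(99)
        family_of = {f"p{i}": f"F{i}" for i in range(8)}
        edges = [
            HomologyEdge(f"p{u}", f"p{v}", 13.0, 70)
            for u, v in [(0, 1), (1, 2), (3, 4), (5, 6), (6, 7)]
        ]
        base = build_superfamilies(edges, family_of).members
        for _ in range(5):
            rng.shuffle(edges)
            assert build_superfamilies(edges, family_of).members == base
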