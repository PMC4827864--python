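"""Seeded benchmark runs used for validation and reproducibility reports.

Each function generates its own synthetic inputs at the standard study
conditions, runs the relevant analysis end to end and returns summary
metrics.  Problem sizes are chosen so the full battery completes in minutes
on one CPU; docs/methods.md records the sizes and conditions.
"""

from __future__ import annotations

import numpy as np

from .homology import build_superfamilies, bridge_candidates, verify_chain
from .pairwise import SegmentRule, shuffle_z
from .repeats import hairpin_repeat_scan
from .seqio import SequenceSet
from .simulate import (
    BarrelSpec,
    FamilySpec,
    SuperfamilySpec,
    evolve_family,
    make_ancestor,
    make_superfamily,
)
from .topology import count_tms_by_family, predict_beta_tms
from .trees import (
    allvsall_scores,
    clade_support,
    family_tree,
    is_monophyletic,
    msa_tree,
    nj_tree,
    rf_distance,
    scores_to_distances,
)

# membrane-protein-like biased composition: 70% of the mass on I/L/V/F
BIASED_RESIDUES = list("ILVFACDEGHKMNPQRSTWY")
BIASED_WEIGHTS = np.array(
    [0.175] * 4 + [0.3 / 16] * 16
)


def _seed(master: int, k: int) -> int:
    return (master * 48271 + k * 2654435761 + 7) % (2**31 - 1)


def null_calibration(
    seed: int, n_pairs: int = 1000, length: int = 200, n_shuffles: int = 200
) -> dict:
    """Shuffle-Z calibration on unrelated composition-biased sequence pairs.

    A well-calibrated statistic should center near zero and never approach
    the 12 SD evidence threshold for unrelated sequences, however biased
    their composition.
    """
    rng = np.random.default_rng(_seed(seed, 1))
    zs = np.empty(n_pairs)
    for i in range(n_pairs):
        a = "".join(rng.choice(BIASED_RESIDUES, size=length, p=BIASED_WEIGHTS))
        b = "".join(rng.choice(BIASED_RESIDUES, size=length, p=BIASED_WEIGHTS))
        zs[i] = shuffle_z(a, b, n_shuffles=n_shuffles, seed=_seed(seed, 100 + i)).z_sd
    return {
        "mean_z": float(zs.mean()),
        "max_z": float(zs.max()),
        "n_z_above_threshold": int((zs > 12.0).sum()),
        "n_pairs": n_pairs,
    }


def chain_recovery(seed: int, n_seeds: int = 20, n_shuffles: int = 500) -> dict:
    """Transitive-chain benchmark: links at ~20 SD, ends below threshold.

    Three families A-B-C where A and C each diverged from hub family B to
    30% expected identity, just above the generator's divergence floor
    (link scores calibrate to ~20 SD), while the A-to-C divergence is
    beyond direct detectability.  Success means the A-B-B-C chain is
    accepted while the direct A-C comparison is rejected.
    """
    rule = SegmentRule()
    chain_ok = direct_reject = joint = 0
    link_zs = []
    for s in range(n_seeds):
        from .simulate import _calibrate_p_sub, _mutate_model

        _, _, hub = make_ancestor(BarrelSpec(n_hairpins=8), seed=_seed(seed, 10 + s))
        rng = np.random.default_rng(_seed(seed, 40 + s))
        p = _calibrate_p_sub(hub, 0.30, 0.01, rng, between_members=False)
        end_a = _mutate_model(hub, p, 0.01, rng)
        end_c = _mutate_model(hub, p, 0.01, rng)
        fam_a, _ = evolve_family(end_a, FamilySpec(3, 0.85, seed=_seed(seed, 70 + s)))
        fam_b, _ = evolve_family(hub, FamilySpec(3, 0.85, seed=_seed(seed, 80 + s)))
        fam_c, _ = evolve_family(end_c, FamilySpec(3, 0.85, seed=_seed(seed, 90 + s)))
        chain = verify_chain(
            fam_a[0], fam_b[0], fam_b[1], fam_c[0],
            rule=rule, n_shuffles=n_shuffles, seed=_seed(seed, 200 + s),
        )
        rejected_direct = chain.z_ad_direct is None or chain.z_ad_direct < rule.sd_threshold
        accepted_chain = chain.accepted and chain.method == "chained"
        chain_ok += chain.accepted
        direct_reject += rejected_direct
        joint += accepted_chain and rejected_direct
        if chain.z_ab is not None:
            link_zs.append(chain.z_ab)
    return {
        "chain_accept_rate": chain_ok / n_seeds,
        "direct_reject_rate": direct_reject / n_seeds,
        "joint_success_rate": joint / n_seeds,
        "mean_link_z": float(np.mean(link_zs)) if link_zs else float("nan"),
        "n_seeds": n_seeds,
    }


def _pair_partition(families: dict) -> dict[str, str]:
    return {rec.id: label for label, sset in families.items() for rec in sset}


def partition_recovery(seed: int, n_seeds: int = 20, n_shuffles: int = 500) -> dict:
    """Two planted 3-family superfamilies: recover the exact partition.

    Families within one superfamily are mutually detectable; the two
    superfamilies descend from independent ancestors, so any accepted
    chain across them is a false merge.
    """
    rule = SegmentRule()
    exact = 0
    false_merges = 0
    for s in range(n_seeds):
        sf1, _, _ = make_superfamily(SuperfamilySpec(
            guide_tree=(("A", "B"), "C"), branch_identity=0.65,
            family=FamilySpec(n_members=4, target_within_identity=0.7),
            seed=_seed(seed, 300 + s),
        ))
        sf2, _, _ = make_superfamily(SuperfamilySpec(
            guide_tree=(("D", "E"), "F"), branch_identity=0.65,
            family=FamilySpec(n_members=4, target_within_identity=0.7),
            seed=_seed(seed, 600 + s),
        ))
        families = {**sf1, **sf2}
        family_of = {rec.id: lab for lab, ss in families.items() for rec in ss}
        labels = sorted(families)
        chains = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                la, lb = labels[i], labels[j]
                pairs = bridge_candidates(families[la], families[lb], top_k=2)
                for k, (ra, rb) in enumerate(pairs):
                    ch = verify_chain(
                        families[la][0], ra, rb, families[lb][0],
                        rule=rule, n_shuffles=n_shuffles,
                        seed=_seed(seed, 900 + s * 37 + i * 7 + j),
                    )
                    chains.append(ch)
                    if ch.accepted:
                        break
        assignment = build_superfamilies(
            [c for c in chains if c.accepted], family_of
        )
        truth = {"A": 0, "B": 0, "C": 0, "D": 1, "E": 1, "F": 1}
        groups: dict[str, set] = {}
        for fam, comp in assignment.component_of.items():
            groups.setdefault(comp, set()).add(fam)
        exact += set(map(frozenset, groups.values())) == {
            frozenset("ABC"), frozenset("DEF")
        }
        for c in chains:
            if c.accepted and truth[family_of[c.a]] != truth[family_of[c.d]]:
                false_merges += 1
    return {
        "exact_partition_rate": exact / n_seeds,
        "false_merges": false_merges,
        "n_seeds": n_seeds,
    }


GUIDE5 = ((("A", "B"), "C"), ("D", "E"))
TRUE_BIPARTITIONS = [{"A", "B"}, {"A", "B", "C"}, {"D", "E"}]


def tree_recovery(seed: int, n_seeds: int = 10, n_replicates: int = 100) -> dict:
    """Family-tree recovery on a 5-family guide tree at moderate divergence.

    Success: Robinson-Foulds distance 0 to the guide topology with
    consensus support >= 90 on every true bipartition.
    """
    import dendropy

    truth = dendropy.Tree.get(
        data="(((A,B),C),(D,E));", schema="newick"
    )
    ok = 0
    for s in range(n_seeds):
        fams, _, _ = make_superfamily(SuperfamilySpec(
            guide_tree=GUIDE5, branch_identity=0.5,
            family=FamilySpec(n_members=5, target_within_identity=0.55),
            seed=_seed(seed, 1500 + s),
        ))
        ft = family_tree(fams, n_replicates=n_replicates, seed=_seed(seed, 1600 + s))
        if rf_distance(ft, truth) != 0:
            continue
        sups = [clade_support(ft, bp) for bp in TRUE_BIPARTITIONS]
        if all(sp is not None and sp >= 90 for sp in sups):
            ok += 1
    return {"rf0_high_support_rate": ok / n_seeds, "n_seeds": n_seeds}


def msa_contrast(seed: int, n_seeds: int = 10) -> dict:
    """Score-based vs MSA-based trees at high divergence with hairpin
    gain/loss.  Counts monophyletic families (of 5) for each route."""
    score_total = msa_total = 0
    for s in range(n_seeds):
        fams, _, _ = make_superfamily(SuperfamilySpec(
            guide_tree=GUIDE5, branch_identity=0.25,
            family=FamilySpec(
                n_members=5, target_within_identity=0.25,
                indel_rate=0.08, hairpin_turnover=3.0,
            ),
            seed=_seed(seed, 2000 + s),
        ))
        merged = SequenceSet([r for f in sorted(fams) for r in fams[f]])
        pt = nj_tree(scores_to_distances(allvsall_scores(merged)))
        mt = msa_tree(merged)
        for f in fams:
            leaves = {r.id for r in fams[f]}
            score_total += is_monophyletic(pt, leaves)
            msa_total += is_monophyletic(mt, leaves)
    return {
        "score_tree_monophyletic": score_total,
        "msa_tree_monophyletic": msa_total,
        "n_families": 5 * n_seeds,
    }


def strand_benchmark(seed: int, n_barrels: int = 50) -> dict:
    """Strand-caller accuracy across barrels of 8-28 strands.

    Residue-level recall on the ancestor plus family-modal strand count
    (5 members each) against the planted count.
    """
    recalls = []
    within2 = 0
    for k in range(n_barrels):
        nh = 4 + (k % 11)
        rec, truth, model = make_ancestor(
            BarrelSpec(n_hairpins=nh), seed=_seed(seed, 3000 + k)
        )
        called = predict_beta_tms(rec.ungapped)
        tm = np.zeros(len(rec.sequence), bool)
        cm = tm.copy()
        for s, e in truth.strands:
            tm[s - 1 : e] = True
        for s, e in called.strands:
            cm[s - 1 : e] = True
        recalls.append((tm & cm).sum() / tm.sum())
        fam, _ = evolve_family(
            model, FamilySpec(5, 0.6, seed=_seed(seed, 4000 + k))
        )
        modal = count_tms_by_family({"f": fam})["f"]["modal"]
        within2 += abs(modal - 2 * nh) <= 2
    return {
        "mean_strand_recall": float(np.mean(recalls)),
        "modal_within_2_rate": within2 / n_barrels,
        "n_barrels": n_barrels,
    }


def repeat_benchmark(
    seed: int, n_amplified: int = 20, n_null: int = 40, n_shuffles: int = 1000
) -> dict:
    """Hairpin-repeat scan on amplified vs independent-strand barrels.

    Amplified barrels carry four tandem copies of one hairpin at 30%
    divergence; success requires at least 4 of the 6 amplified-pair
    comparisons to outrank every background pair.  The null calibration
    uses i.i.d. barrel-like sequence (residues drawn independently from
    the generator's overall composition, nominal strand layout) and counts
    a run as clean when no pair reaches empirical p < 0.001.  Structured
    but unrelated barrels are deliberately *not* the null here: their
    shared amphipathic periodicity is real mutual signal under a
    composition-preserving shuffle (see docs/methods.md).
    """
    from .topology import BetaTopology

    amp_ok = 0
    for s in range(n_amplified):
        rec, truth, _ = make_ancestor(
            BarrelSpec(n_hairpins=8, amplified_unit=(2, 4),
                       amplification_divergence=0.3),
            seed=_seed(seed, 5000 + s),
        )
        hits = hairpin_repeat_scan(
            rec.ungapped, truth, n_shuffles=n_shuffles, seed=_seed(seed, 5100 + s)
        )
        amp_units = {2, 3, 4, 5}
        amp_pairs = {
            ((2 * u + 1, 2 * u + 2), (2 * v + 1, 2 * v + 2))
            for u in amp_units for v in amp_units if u < v
        }
        flags = [
            (h.unit_a.strand_pair, h.unit_b.strand_pair) in amp_pairs
            for h in hits
        ]
        first_bg = flags.index(False) if False in flags else len(flags)
        amp_ok += sum(flags[:first_bg]) >= 4
    null_clean = 0
    template, _, _ = make_ancestor(BarrelSpec(n_hairpins=8), seed=_seed(seed, 5999))
    composition = sorted(set(template.ungapped))
    freqs = np.array([template.ungapped.count(c) for c in composition], float)
    freqs /= freqs.sum()
    layout = BetaTopology(
        [(20 + 18 * k, 29 + 18 * k) for k in range(16)], caller="nominal"
    )
    for s in range(n_null):
        rng = np.random.default_rng(_seed(seed, 6000 + s))
        seq = "".join(rng.choice(composition, size=320, p=freqs))
        hits = hairpin_repeat_scan(
            seq, layout, n_shuffles=n_shuffles, seed=_seed(seed, 6100 + s)
        )
        null_clean += all(h.empirical_p >= 0.001 for h in hits)
    return {
        "amplified_rank_rate": amp_ok / n_amplified,
        "null_clean_rate": null_clean / n_null,
        "n_amplified": n_amplified,
        "n_null": n_null,
    }
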