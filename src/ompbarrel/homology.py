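"""Cross-family homology search and transitive superfamily assignment.

Two families A and D whose members are too divergent for a direct alignment
to reach significance can still be shown to be homologous through
intermediates: if A~B, B~C and C~D each exceed the evidence threshold
(>12 SD over >=60 residues), then A and D share ancestry by transitivity
(the Superfamily Principle).  Superfamilies are the connected components of
the family-level graph whose edges are accepted chains; the inability to
establish homology is never treated as evidence of non-membership.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .pairwise import (
    AlignmentParams,
    DEFAULT_PARAMS,
    SegmentRule,
    extract_comparable_segment,
    global_align,
    align_score,
    shuffle_z,
)
from .seqio import ProteinRecord, SequenceSet

# Gapped Karlin-Altschul parameters for BLOSUM62, keyed by this package's
# (gap_open, gap_extend) convention where a gap of length g costs
# open + (g-1)*extend.  Values from the NCBI BLAST statistics tables for the
# equivalent (open-extend, extend) combination.
KARLIN_ALTSCHUL: dict[tuple[str, int, int], tuple[float, float]] = {
    ("BLOSUM62", 8, 2): (0.201, 0.0120),
    ("BLOSUM62", 10, 2): (0.264, 0.0450),
    ("BLOSUM62", 12, 1): (0.267, 0.0410),
}
KARLIN_ALTSCHUL_UNGAPPED = {"BLOSUM62": (0.3176, 0.134)}


def karlin_altschul_params(params: AlignmentParams) -> tuple[float, float]:
    key = (params.matrix, params.gap_open, params.gap_extend)
    if key in KARLIN_ALTSCHUL:
        return KARLIN_ALTSCHUL[key]
    raise KeyError(
        f"no Karlin-Altschul parameters for {key}; use one of "
        f"{sorted(KARLIN_ALTSCHUL)} or provide score-rank cutoffs"
    )


def evalue(score: float, m: int, n: int, params: AlignmentParams) -> float:
    """Karlin-Altschul E-value for a local score over search space m*n."""
    lam, k = karlin_altschul_params(params)
    return k * m * n * math.exp(-lam * score)


def bit_score(score: float, params: AlignmentParams) -> float:
    lam, k = karlin_altschul_params(params)
    return (lam * score - math.log(k)) / math.log(2)


@dataclass
class HomologyEdge:
    """An accepted pairwise evidence link between two proteins."""

    id_a: str
    id_b: str
    z_sd: float
    segment_length: int
    method: str = "direct"  # direct | chained


@dataclass
class TransitiveChain:
    """An A-B-C-D homology chain with its three link comparison scores.

    ``accepted`` is true when all three links exceed the SD threshold on
    qualifying segments, or when the direct A-D comparison itself reaches
    the threshold (in which case B and C are omitted).
    """

    a: str
    b: str
    c: str
    d: str
    z_ab: Optional[float]
    z_bc: Optional[float]
    z_cd: Optional[float]
    z_ad_direct: Optional[float]
    accepted: bool
    method: str = "chained"  # chained | direct
    reason: str = ""


def expand_family(
    seed: ProteinRecord,
    database: SequenceSet,
    iterations: int = 2,
    cutoffs: Sequence[float] = (1e-4, 1e-6),
    params: Optional[AlignmentParams] = None,
) -> SequenceSet:
    """Iterative local-search family expansion (PSI-BLAST-style, run locally).

    Iteration 1 gathers database members whose local-alignment E-value
    against the seed passes the first cutoff; each later iteration
    re-searches with every gathered member as query under the next cutoff.
    The union (seed included) is returned.
    """
    if len(database) == 0:
        raise ValueError("database is empty")
    if len(cutoffs) != iterations:
        raise ValueError("need one E-value cutoff per iteration")
    params = params or DEFAULT_PARAMS
    karlin_altschul_params(params)  # fail early if matrix/gaps unknown
    total_db = sum(len(r.ungapped) for r in database)
    gathered: dict[str, ProteinRecord] = {seed.id: seed}
    queries = [seed]
    for cutoff in cutoffs:
        new: dict[str, ProteinRecord] = {}
        for q in queries:
            qlen = len(q.ungapped)
            for rec in database:
                if rec.id in gathered or rec.id in new:
                    continue
                s = align_score(q.ungapped, rec.ungapped, params, mode="local")
                if evalue(s, qlen, total_db, params) <= cutoff:
                    new[rec.id] = rec
        gathered.update(new)
        queries = list(new.values())
        if not queries:
            break
    order = [r.id for r in database if r.id in gathered]
    if seed.id not in order:
        order.insert(0, seed.id)
    return SequenceSet([gathered[i] for i in order], source_tag=f"expand:{seed.id}")


def tssearch(
    set_a: SequenceSet,
    set_b: SequenceSet,
    params: Optional[AlignmentParams] = None,
    top_k: Optional[int] = None,
) -> list[tuple[float, ProteinRecord, ProteinRecord]]:
    """All-vs-all Smith-Waterman screen between two FASTA sets.

    Returns candidate pairs ranked by raw local score (descending, with a
    deterministic id tie-break) for downstream shuffle-Z confirmation.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("both sets must be non-empty")
    params = params or DEFAULT_PARAMS
    hits = []
    for ra in set_a:
        for rb in set_b:
            s = align_score(ra.ungapped, rb.ungapped, params, mode="local")
            hits.append((float(s), ra, rb))
    hits.sort(key=lambda t: (-t[0], t[1].id, t[2].id))
    return hits[:top_k] if top_k else hits


def _link_z(
    x: ProteinRecord,
    y: ProteinRecord,
    params: AlignmentParams,
    rule: SegmentRule,
    n_shuffles: int,
    seed: int,
) -> tuple[Optional[float], int, str]:
    """Comparison score for one link on its best comparable segment."""
    aln = global_align(x.ungapped, y.ungapped, params)
    seg = extract_comparable_segment(aln, rule)
    if seg is None:
        return None, 0, f"no comparable segment of >= {rule.min_length} aa"
    res = shuffle_z(seg[0], seg[1], params, n_shuffles=n_shuffles, seed=seed)
    if res.degenerate:
        return None, min(len(seg[0]), len(seg[1])), "degenerate shuffle null"
    return res.z_sd, min(len(seg[0]), len(seg[1])), ""


def verify_chain(
    a: ProteinRecord,
    b: ProteinRecord,
    c: ProteinRecord,
    d: ProteinRecord,
    params: Optional[AlignmentParams] = None,
    rule: SegmentRule = SegmentRule(),
    n_shuffles: int = 2000,
    seed: int = 0,
) -> TransitiveChain:
    """Verify an A-B-C-D transitive homology chain with shuffle-Z scores.

    The direct A-D comparison short-circuits: if it reaches the threshold
    (>= threshold, as for direct comparisons) on a qualifying segment the
    chain is accepted without intermediates.  Otherwise all three links must
    strictly exceed the threshold.  Sequences shorter than the minimum
    segment length are rejected outright.
    """
    params = params or DEFAULT_PARAMS
    for rec in (a, b, c, d):
        if len(rec.ungapped) < rule.min_length:
            return TransitiveChain(
                a.id, b.id, c.id, d.id, None, None, None, None,
                accepted=False, reason=f"{rec.id}: below {rule.min_length} aa",
            )
    z_ad, _, _ = _link_z(a, d, params, rule, n_shuffles, _sub_seed(seed, 3))
    if z_ad is not None and z_ad >= rule.sd_threshold:
        return TransitiveChain(
            a.id, "", "", d.id, None, None, None, z_ad,
            accepted=True, method="direct",
        )
    zs = []
    reasons = []
    for k, (x, y) in enumerate(((a, b), (b, c), (c, d))):
        if x.id == y.id:
            zs.append(float("inf"))  # identical endpoints collapse the link
            continue
        z, _, why = _link_z(x, y, params, rule, n_shuffles, _sub_seed(seed, k))
        zs.append(z)
        if why:
            reasons.append(f"{x.id}-{y.id}: {why}")
    ok = all(z is not None and z > rule.sd_threshold for z in zs)
    zs = [None if z is None else (z if math.isfinite(z) else None) for z in zs]
    return TransitiveChain(
        a.id, b.id, c.id, d.id, zs[0], zs[1], zs[2], z_ad,
        accepted=ok, reason="; ".join(reasons),
    )


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1000003 + k) % (2**31 - 1)


@dataclass
class SuperfamilyAssignment:
    """Family -> superfamily component map from accepted evidence.

    Components are labelled in decreasing size order (``SFI`` is the
    largest).  Families without any accepted evidence carry status
    ``no evidence`` — absence of evidence never asserts non-membership.
    """

    component_of: dict[str, str]
    members: dict[str, list[str]]
    support: dict[tuple[str, str], int] = field(default_factory=dict)

    def status(self, family: str) -> str:
        label = self.component_of.get(family)
        if label is None:
            return "unknown family"
        if len(self.members[label]) == 1 and not any(
            family in pair for pair in self.support
        ):
            return "no evidence"
        return label


_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX"]


def _roman(n: int) -> str:
    return _ROMAN[n - 1] if n <= len(_ROMAN) else str(n)


def build_superfamilies(
    evidence: Sequence, family_of: dict[str, str]
) -> SuperfamilyAssignment:
    """Transitive closure of accepted evidence into superfamily components.

    ``evidence`` may mix :class:`HomologyEdge` and accepted
    :class:`TransitiveChain` items; every referenced protein id must map to
    a family.  The partition is independent of evidence order.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(set(family_of.values())))
    support: dict[tuple[str, str], int] = {}
    for ev in evidence:
        if isinstance(ev, TransitiveChain):
            if not ev.accepted:
                continue
            pa, pb = ev.a, ev.d
        else:
            pa, pb = ev.id_a, ev.id_b
        if pa not in family_of or pb not in family_of:
            raise KeyError(f"unmapped protein id in evidence: {pa!r}/{pb!r}")
        fa, fb = family_of[pa], family_of[pb]
        if fa == fb:
            continue
        key = tuple(sorted((fa, fb)))
        support[key] = support.get(key, 0) + 1
        g.add_edge(fa, fb)
    comps = sorted(
        (sorted(comp) for comp in nx.connected_components(g)),
        key=lambda c: (-len(c), c),
    )
    component_of = {}
    members = {}
    for i, comp in enumerate(comps, start=1):
        label = f"SF{_roman(i)}"
        members[label] = comp
        for fam in comp:
            component_of[fam] = label
    return SuperfamilyAssignment(component_of, members, support)


def bridge_candidates(
    set_a: SequenceSet,
    set_b: SequenceSet,
    params: Optional[AlignmentParams] = None,
    top_k: int = 10,
) -> list[tuple[ProteinRecord, ProteinRecord]]:
    """Top-k candidate (member-of-A, member-of-B) bridge pairs by local score.

    Automates the manual intermediate-picking step: chains are then verified
    as seed_A - bridge_A - bridge_B - seed_B.
    """
    hits = tssearch(set_a, set_b, params, top_k=top_k)
    return [(ra, rb) for _, ra, rb in hits]
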