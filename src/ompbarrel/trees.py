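"""Alignment-free score-based trees (protein-level and family-level).

Trees are built from all-vs-all Smith-Waterman bit scores, bypassing
multiple alignment entirely.  For highly divergent protein families a
multiple alignment degrades into noise and trees derived from it scatter
family members around the topology; pairwise optimal scores remain
informative much deeper, so the score->distance->neighbor-joining route
keeps families coherent.  Support is estimated as the majority-rule
consensus of replicate trees built from perturbed distance matrices.

The bit-score -> distance transform, the replicate-generation strategy and
the trimmed-mean family distance are this package's own (documented,
pluggable) choices; trees are returned as ``dendropy.Tree`` objects.
"""

from __future__ import annotations

import io
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
from scipy.stats import trim_mean

from .homology import bit_score
from .pairwise import AlignmentParams, DEFAULT_PARAMS, align_score
from .seqio import SequenceSet, write_fasta


@dataclass
class ScoreMatrix:
    """Symmetric all-vs-all pairwise bit scores with self-score diagonal."""

    ids: list[str]
    bits: np.ndarray

    @property
    def self_scores(self) -> np.ndarray:
        return np.diag(self.bits)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")


def allvsall_scores(sset: SequenceSet, params: Optional[AlignmentParams] = None) -> ScoreMatrix:
    """All-vs-all local alignment scores converted to bits.

    ``b = (lambda*S - ln K) / ln 2`` with gapped Karlin-Altschul parameters
    for the configured matrix/gap combination.
    """
    if len(sset) < 3:
        raise ValueError("need at least 3 sequences")
    params = params or DEFAULT_PARAMS
    seqs = [r.ungapped for r in sset]
    n = len(seqs)
    bits = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = align_score(seqs[i], seqs[j], params, mode="local")
            bits[i, j] = bits[j, i] = bit_score(s, params)
    return ScoreMatrix(ids=list(sset.ids), bits=bits)


def scores_to_distances(m: ScoreMatrix) -> DistanceMatrix:
    """Normalized score deficit: d(i,j) = 1 - b(i,j)/min(b(i,i), b(j,j)).

    Clipped to [0, 1]; pairs with non-positive bit scores saturate at 1.
    """
    b = m.bits
    self_b = np.diag(b)
    denom = np.minimum.outer(self_b, self_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - b / denom
    d[b <= 0] = 1.0
    d = np.clip(d, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(ids=list(m.ids), d=d)


def _pdm(dm: DistanceMatrix, taxon_namespace=None) -> dendropy.PhylogeneticDistanceMatrix:
    buf = io.StringIO()
    buf.write("," + ",".join(dm.ids) + "\n")
    for i, name in enumerate(dm.ids):
        buf.write(name + "," + ",".join(f"{x:.10g}" for x in dm.d[i]) + "\n")
    buf.seek(0)
    return dendropy.PhylogeneticDistanceMatrix.from_csv(
        buf, taxon_namespace=taxon_namespace, delimiter=","
    )


def nj_tree(dm: DistanceMatrix, taxon_namespace=None) -> dendropy.Tree:
    """Neighbor-joining tree; negative branch lengths are floored at zero
    with the deficit transferred to the sister branch."""
    if len(dm.ids) < 3:
        raise ValueError("need at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("non-finite distances")
    tree = _pdm(dm, taxon_namespace).nj_tree()
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        for child in children:
            if child.edge.length is not None and child.edge.length < 0:
                deficit = -child.edge.length
                child.edge.length = 0.0
                for sib in children:
                    if sib is not child and sib.edge.length is not None:
                        sib.edge.length += deficit
                        break
    tree.is_rooted = False
    return tree


def _replicate_distance(d: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Perturbed distance matrix from a bootstrap sample of reference taxa.

    Each taxon's score profile is its vector of distances to all taxa; a
    replicate resamples, with replacement, which taxa serve as profile
    coordinates and measures pairwise mean profile dissimilarity
    ``mean_r |d(i,r) - d(j,r)|``.  Relationships supported across the whole
    profile survive every resampling; those resting on few coordinates
    fluctuate and lose consensus support.
    """
    diff = np.abs(d[:, refs][:, None, :] - d[None, :, refs])
    rep = diff.mean(axis=2)
    np.fill_diagonal(rep, 0.0)
    return rep


def _consensus(
    replicates: list[dendropy.Tree],
    point_tree: dendropy.Tree,
) -> dendropy.Tree:
    """Majority-rule consensus with support (0-100) as internal node labels
    and branch lengths copied from the point-estimate tree where the
    bipartition matches."""
    tl = dendropy.TreeList(replicates, taxon_namespace=point_tree.taxon_namespace)
    cons = tl.consensus(min_freq=0.5, summarize_splits=True)
    point_tree.encode_bipartitions()
    lengths = {
        e.bipartition.split_bitmask: e.length for e in point_tree.edges()
    }
    cons.encode_bipartitions()
    for node in cons:
        sup = getattr(node, "support", None)
        if sup is not None and not node.is_leaf():
            node.label = f"{100.0 * float(sup):.0f}"
        key = node.edge.bipartition.split_bitmask
        if key in lengths and lengths[key] is not None:
            node.edge.length = lengths[key]
    cons.is_rooted = False
    return cons


def clade_support(tree: dendropy.Tree, leaves: set[str]) -> Optional[float]:
    """Consensus support (0-100) of the edge separating ``leaves`` from the
    rest, or ``None`` if the clade is not in the tree."""
    leaves = set(leaves)
    all_leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    for node in tree.internal_nodes():
        clade = {l.taxon.label for l in node.leaf_iter()}
        if (clade == leaves or (all_leaves - clade) == leaves) and node.label is not None:
            try:
                return float(node.label)
            except ValueError:
                return None
    return None


def is_monophyletic(tree: dendropy.Tree, leaves: set[str]) -> bool:
    """True if some edge of the (unrooted) tree splits ``leaves`` exactly."""
    leaves = set(leaves)
    all_leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    if not leaves <= all_leaves:
        raise ValueError("leaves not in tree")
    if len(leaves) in (1, len(all_leaves)):
        return True
    for node in tree:
        clade = {l.taxon.label for l in node.leaf_iter()}
        if clade == leaves or (all_leaves - clade) == leaves:
            return True
    return False


def consensus_tree(
    sset: SequenceSet,
    params: Optional[AlignmentParams] = None,
    n_replicates: int = 100,
    seed: int = 0,
    strategy: str = "resample",
) -> dendropy.Tree:
    """Protein-level NJ tree with majority-rule consensus support (0-100).

    Replicates perturb the distance matrix by resampling, with replacement,
    the proteins contributing to each id's score profile
    (``strategy="resample"``); ``strategy="none"`` makes every replicate
    identical (all supports 100), useful as a zero-noise control.
    """
    if len(sset) < 4:
        raise ValueError("need at least 4 sequences")
    # canonical leaf order: the consensus is invariant to input order
    ordered = SequenceSet(sorted(sset.records, key=lambda r: r.id))
    dm = scores_to_distances(allvsall_scores(ordered, params))
    tns = dendropy.TaxonNamespace(sorted(dm.ids))
    point = nj_tree(dm, tns)
    rng = np.random.default_rng(seed)
    n = len(dm.ids)
    reps = []
    for _ in range(n_replicates):
        if strategy == "none":
            rep_d = dm.d
        elif strategy == "resample":
            refs = rng.integers(0, n, size=n)
            rep_d = _replicate_distance(dm.d, refs)
        else:
            raise ValueError(f"unknown replicate strategy {strategy!r}")
        reps.append(nj_tree(DistanceMatrix(dm.ids, rep_d), tns))
    return _consensus(reps, point)


def family_tree(
    family_sets: dict[str, SequenceSet],
    params: Optional[AlignmentParams] = None,
    min_members: int = 5,
    n_replicates: int = 100,
    seed: int = 0,
    trim: float = 0.1,
) -> dendropy.Tree:
    """Family-level consensus tree from cross-family protein distances.

    The distance between two families is the net divergence: the trimmed
    mean (default 10% two-sided) of cross-family member distances minus
    the average of the two mean within-family distances, floored at zero —
    so two families with identical membership sit at distance zero.
    Replicates resample members within each family with replacement.
    Families with fewer than ``min_members`` members are flagged with a
    warning and retained.
    """
    families = sorted(family_sets)
    if len(families) < 3:
        raise ValueError("need at least 3 families")
    for fam in families:
        if len(family_sets[fam]) < min_members:
            warnings.warn(
                f"family {fam!r} has {len(family_sets[fam])} members "
                f"(< {min_members}); tree may be unreliable",
                stacklevel=2,
            )
    merged: list = []
    fam_idx: dict[str, list[int]] = {}
    for fam in families:
        fam_idx[fam] = []
        for rec in family_sets[fam]:
            fam_idx[fam].append(len(merged))
            merged.append(rec)
    union = SequenceSet(merged)
    dm = scores_to_distances(allvsall_scores(union, params))

    def _within(idx: list[int]) -> float:
        if len(idx) < 2:
            return 0.0
        block = dm.d[np.ix_(idx, idx)]
        vals = block[np.triu_indices(len(idx), k=1)]
        return float(trim_mean(vals, trim)) if len(vals) > 2 else float(vals.mean())

    def family_matrix(member_idx: dict[str, list[int]]) -> np.ndarray:
        k = len(families)
        fd = np.zeros((k, k))
        within = [_within(member_idx[f]) for f in families]
        for i in range(k):
            for j in range(i + 1, k):
                block = dm.d[np.ix_(member_idx[families[i]], member_idx[families[j]])]
                cross = trim_mean(block.ravel(), trim)
                net = max(0.0, cross - (within[i] + within[j]) / 2.0)
                fd[i, j] = fd[j, i] = net
        return fd

    tns = dendropy.TaxonNamespace(families)
    point_fd = family_matrix(fam_idx)
    point = nj_tree(DistanceMatrix(families, point_fd), tns)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_replicates):
        resampled = {
            fam: [idx[i] for i in rng.integers(0, len(idx), size=len(idx))]
            for fam, idx in fam_idx.items()
        }
        reps.append(nj_tree(DistanceMatrix(families, family_matrix(resampled)), tns))
    return _consensus(reps, point)


def _run_mafft(sset: SequenceSet) -> SequenceSet:
    from .seqio import read_fasta

    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH; msa_tree requires it")
    with tempfile.TemporaryDirectory() as td:
        inp = Path(td) / "in.fasta"
        out = Path(td) / "out.fasta"
        write_fasta(sset, inp)
        with open(out, "w") as fh:
            subprocess.run(
                ["mafft", "--auto", "--quiet", str(inp)],
                stdout=fh, check=True,
            )
        return read_fasta(out, aligned=True)


def msa_tree(sset: SequenceSet) -> dendropy.Tree:
    """Conventional tree: progressive multiple alignment, then NJ on
    alignment p-distances.  Provided as the comparison baseline — for very
    divergent families this route is expected to scatter family members.
    """
    if len(sset) < 3:
        raise ValueError("need at least 3 sequences")
    msa = _run_mafft(sset)
    rows = {r.id: r.sequence for r in msa}
    ids = list(sset.ids)
    n = len(ids)
    arr = np.array([list(rows[i]) for i in ids])
    gap = (arr == "-") | (arr == ".")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            m = both.sum()
            p = float((arr[i][both] != arr[j][both]).sum() / m) if m else 1.0
            d[i, j] = d[j, i] = p
    return nj_tree(DistanceMatrix(ids, d))


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds bipartition distance (topologies only)."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
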