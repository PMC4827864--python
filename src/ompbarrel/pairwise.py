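"""Pairwise alignment and the Monte-Carlo shuffle "comparison score".

The homology statistic implemented here expresses a Needleman-Wunsch global
alignment score as a number of standard deviations above the score expected
between *shuffled* versions of the same two sequences.  Because each shuffle
preserves residue composition exactly, the null distribution is conditioned
on composition — the statistic stays calibrated for proteins with the skewed
compositions typical of membrane proteins, where a raw alignment score (or a
database E-value computed under average-composition assumptions) does not.

A comparison score of at least 12 SD over comparable segments of at least 60
residues is the conventional evidence threshold for homology used throughout
the package (:class:`SegmentRule`).

Default alignment parameters are a gap-creation penalty of 8 and a
gap-extension penalty of 2 (a gap of length ``g`` costs ``8 + 2*(g-1)``)
with BLOSUM62 scores and 2000 shuffles per comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices


@dataclass(frozen=True)
class AlignmentParams:
    """Substitution matrix and affine gap penalties.

    ``gap_open`` is the cost of the first gapped position and ``gap_extend``
    the cost of each further position, so a gap of length g costs
    ``gap_open + gap_extend*(g-1)``.  ``penalize_end_gaps=True`` gives a true
    global alignment.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 8
    gap_extend: int = 2
    penalize_end_gaps: bool = True

    def __post_init__(self):
        if not self.gap_open >= self.gap_extend >= 1:
            raise ValueError("require gap_open >= gap_extend >= 1")


DEFAULT_PARAMS = AlignmentParams()


@lru_cache(maxsize=8)
def load_matrix(name: str):
    """Load a named substitution matrix with X scoring 0 against everything."""
    m = substitution_matrices.load(name)
    m = m.copy()
    if "X" in m.alphabet:
        for aa in m.alphabet:
            m["X", aa] = 0.0
            m[aa, "X"] = 0.0
    return m


@lru_cache(maxsize=32)
def _aligner(params: AlignmentParams, mode: str) -> PairwiseAligner:
    a = PairwiseAligner()
    a.substitution_matrix = load_matrix(params.matrix)
    a.open_gap_score = -float(params.gap_open)
    a.extend_gap_score = -float(params.gap_extend)
    a.mode = mode
    if mode == "global" and not params.penalize_end_gaps:
        a.target_end_gap_score = 0.0
        a.query_end_gap_score = 0.0
    return a


@dataclass
class PairwiseAlignment:
    """A scored pairwise alignment with percent identity and similarity.

    ``percent_identity`` is the percentage of alignment columns in which the
    two residues are identical; ``percent_similarity`` additionally counts
    columns whose substitution score is positive.  Spans are 1-based
    inclusive coordinates on the unaligned inputs.
    """

    aligned_a: str
    aligned_b: str
    score: int
    percent_identity: float
    percent_similarity: float
    aligned_span_a: Optional[tuple[int, int]]
    aligned_span_b: Optional[tuple[int, int]]
    params: AlignmentParams = field(default=DEFAULT_PARAMS, repr=False)

    def __len__(self) -> int:
        return len(self.aligned_a)


def _column_stats(aligned_a: str, aligned_b: str, matrix) -> tuple[int, int]:
    ident = simil = 0
    for x, y in zip(aligned_a, aligned_b):
        if x in "-." or y in "-.":
            continue
        if x == y:
            ident += 1
            simil += 1
        elif matrix[x, y] > 0:
            simil += 1
    return ident, simil


def _build(a: str, b: str, params: AlignmentParams, mode: str) -> PairwiseAlignment:
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    eng = _aligner(params, mode)
    score = eng.score(a, b)
    if mode == "local" and score <= 0:
        return PairwiseAlignment("", "", 0, 0.0, 0.0, None, None, params)
    aln = eng.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    coords = aln.coordinates
    span_a = (int(coords[0, 0]) + 1, int(coords[0, -1]))
    span_b = (int(coords[1, 0]) + 1, int(coords[1, -1]))
    matrix = load_matrix(params.matrix)
    ncols = len(ga)
    ident, simil = _column_stats(ga, gb, matrix)
    return PairwiseAlignment(
        aligned_a=ga,
        aligned_b=gb,
        score=int(round(score)),
        percent_identity=100.0 * ident / ncols,
        percent_similarity=100.0 * simil / ncols,
        aligned_span_a=span_a,
        aligned_span_b=span_b,
        params=params,
    )


def global_align(a: str, b: str, params: Optional[AlignmentParams] = None) -> PairwiseAlignment:
    """Optimal Needleman-Wunsch global alignment under affine gap costs."""
    return _build(a, b, params or DEFAULT_PARAMS, "global")


def local_align(a: str, b: str, params: Optional[AlignmentParams] = None) -> PairwiseAlignment:
    """Optimal Smith-Waterman local alignment; empty (score 0) when nothing
    scores positively."""
    return _build(a, b, params or DEFAULT_PARAMS, "local")


def align_score(a: str, b: str, params: Optional[AlignmentParams] = None, mode: str = "global") -> float:
    """Alignment score only (no traceback) — the fast path for the null."""
    return _aligner(params or DEFAULT_PARAMS, mode).score(a, b)


@dataclass
class ShuffleZResult:
    """The shuffle-null comparison score in standard-deviation units."""

    z_sd: float
    observed_score: int
    null_mean: float
    null_sd: float
    n_shuffles: int
    seed: int
    degenerate: bool = False  # null_sd == 0; z_sd is NaN
    null_scores: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def empirical_p(self) -> Optional[float]:
        """(1 + #{null >= observed}) / (n + 1); needs ``keep_null=True``."""
        if self.null_scores is None:
            return None
        ge = int((self.null_scores >= self.observed_score).sum())
        return (1 + ge) / (self.n_shuffles + 1)

    def __str__(self) -> str:
        if self.degenerate:
            return "comparison score undefined (degenerate null)"
        return f"{self.z_sd:.1f} SD (score {self.observed_score}, null {self.null_mean:.1f} ± {self.null_sd:.1f}, {self.n_shuffles} shuffles)"


def shuffle_z(
    a: str,
    b: str,
    params: Optional[AlignmentParams] = None,
    n_shuffles: int = 2000,
    seed: int = 0,
    *,
    mode: str = "global",
    shuffle_both: bool = True,
    keep_null: bool = False,
) -> ShuffleZResult:
    """Comparison score of ``a`` vs ``b`` in SD units of a shuffled null.

    The observed score is the optimal alignment score of the native
    sequences.  Each null replicate independently permutes the residues of
    each sequence (Fisher-Yates via the seeded generator; set
    ``shuffle_both=False`` to permute only ``b``) and re-scores the pair.
    ``z = (observed - null_mean) / null_sd`` with the sample (n-1) standard
    deviation.  A zero-variance null (e.g. homopolymers) yields a flagged
    result with ``z_sd = NaN`` rather than an exception.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("sequences must have at least 2 residues")
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    params = params or DEFAULT_PARAMS
    eng = _aligner(params, mode)
    observed = eng.score(a, b)
    rng = np.random.default_rng(seed)
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        sa = rng.permutation(arr_a).tobytes().decode() if shuffle_both else a
        sb = rng.permutation(arr_b).tobytes().decode()
        null[i] = eng.score(sa, sb)
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    kept = null if keep_null else None
    if sd == 0.0:
        return ShuffleZResult(float("nan"), int(round(observed)), mean, 0.0,
                              n_shuffles, seed, degenerate=True,
                              null_scores=kept)
    return ShuffleZResult(
        z_sd=(observed - mean) / sd,
        observed_score=int(round(observed)),
        null_mean=mean,
        null_sd=sd,
        n_shuffles=n_shuffles,
        seed=seed,
        null_scores=kept,
    )


@dataclass(frozen=True)
class SegmentRule:
    """Evidence rule: comparable segments of >= 60 residues at >= 12.0 SD."""

    min_length: int = 60
    sd_threshold: float = 12.0

    def __post_init__(self):
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def extract_comparable_segment(
    alignment: PairwiseAlignment, rule: SegmentRule = SegmentRule()
) -> Optional[tuple[str, str]]:
    """Trim alignment ends to the best comparable segment, or ``None``.

    Only end columns are removed (central regions are never cut).  Among all
    (left, right) trims keeping at least ``rule.min_length`` residues in each
    de-gapped segment, the trim maximizing ``identities - gap_columns`` over
    the kept window is chosen; ties prefer the wider, then the left-most
    window.  Returns the contiguous underlying substrings of both sequences.
    """
    ga, gb = alignment.aligned_a, alignment.aligned_b
    L = len(ga)
    if L == 0:
        return None
    xa = np.frombuffer(ga.encode(), dtype="S1")
    xb = np.frombuffer(gb.encode(), dtype="S1")
    gap_a = (xa == b"-") | (xa == b".")
    gap_b = (xb == b"-") | (xb == b".")
    ident = (~gap_a) & (~gap_b) & (xa == xb)
    gapcol = gap_a | gap_b
    res_a = (~gap_a).astype(np.int64)
    res_b = (~gap_b).astype(np.int64)
    # prefix sums; window [i, j) metrics in O(1)
    c_ident = np.concatenate([[0], np.cumsum(ident)])
    c_gap = np.concatenate([[0], np.cumsum(gapcol)])
    c_ra = np.concatenate([[0], np.cumsum(res_a)])
    c_rb = np.concatenate([[0], np.cumsum(res_b)])

    best = None  # (J, width, -left)
    best_window = None
    ends = np.arange(1, L + 1)
    for left in range(L):
        j = ends[left:]
        ra = c_ra[j] - c_ra[left]
        rb = c_rb[j] - c_rb[left]
        ok = (ra >= rule.min_length) & (rb >= rule.min_length)
        if not ok.any():
            continue
        J = (c_ident[j] - c_ident[left]) - (c_gap[j] - c_gap[left])
        J = np.where(ok, J, np.iinfo(np.int64).min)
        # widest window among equal objective values (last argmax)
        k = len(J) - 1 - int(np.argmax(J[::-1]))
        cand = (int(J[k]), int(j[k] - left), -left)
        if best is None or cand > best:
            best = cand
            best_window = (left, int(j[k]))
    if best_window is None:
        return None
    l, r = best_window
    seg_a = ga[l:r].replace("-", "").replace(".", "")
    seg_b = gb[l:r].replace("-", "").replace(".", "")
    return seg_a, seg_b


def format_alignment(
    alignment: PairwiseAlignment,
    id_a: str = "seq_a",
    id_b: str = "seq_b",
    width: int = 60,
) -> str:
    """Text alignment report in 60-column blocks.

    ``|`` marks an identity and ``:`` a similarity (positive substitution
    score); residue numbers on the unaligned sequences flank each line.
    """
    matrix = load_matrix(alignment.params.matrix)
    ga, gb = alignment.aligned_a, alignment.aligned_b
    marks = []
    for x, y in zip(ga, gb):
        if x in "-." or y in "-.":
            marks.append(" ")
        elif x == y:
            marks.append("|")
        elif matrix[x, y] > 0:
            marks.append(":")
        else:
            marks.append(" ")
    marks = "".join(marks)
    start_a = alignment.aligned_span_a[0] if alignment.aligned_span_a else 1
    start_b = alignment.aligned_span_b[0] if alignment.aligned_span_b else 1
    pos_a, pos_b = start_a, start_b
    out = []
    name_w = max(len(id_a), len(id_b))
    for off in range(0, len(ga), width):
        block_a = ga[off : off + width]
        block_b = gb[off : off + width]
        block_m = marks[off : off + width]
        na = sum(1 for c in block_a if c not in "-.")
        nb = sum(1 for c in block_b if c not in "-.")
        end_a = pos_a + na - 1 if na else pos_a
        end_b = pos_b + nb - 1 if nb else pos_b
        out.append(f"{id_a:<{name_w}} {pos_a:>5} {block_a} {end_a}")
        out.append(f"{'':<{name_w}} {'':>5} {block_m}")
        out.append(f"{id_b:<{name_w}} {pos_b:>5} {block_b} {end_b}")
        out.append("")
        pos_a += na
        pos_b += nb
    footer = (
        f"score = {alignment.score}, identity = {alignment.percent_identity:.0f}%, "
        f"similarity = {alignment.percent_similarity:.0f}%"
    )
    out.append(footer)
    return "\n".join(out)
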