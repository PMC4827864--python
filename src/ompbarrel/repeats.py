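"""Intra-protein β-hairpin repeat scanning with the shuffle-Z statistic.

Under the hairpin-amplification model of barrel evolution, adjacent
two-strand hairpin units within one protein descend from a duplicated
ancestral unit and retain detectable mutual similarity.  The scan compares
every pair of candidate hairpin units with the composition-conditioned
shuffle statistic.  Units are short (well under 60 residues), so hits are
reported with their z and an empirical shuffle p-value but are never
labelled as established homology — the 12 SD / 60 aa rule applies only to
full-length comparable segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .pairwise import AlignmentParams, ShuffleZResult, shuffle_z
from .topology import BetaTopology

# Local alignment with a softer gap opening is used inside unit
# comparisons because units are short.
UNIT_PARAMS = AlignmentParams(gap_open=4, gap_extend=2)


@dataclass
class HairpinUnit:
    """A candidate hairpin: strand k through strand k+1 plus the turn."""

    strand_pair: tuple[int, int]  # 1-based strand indices (k, k+1)
    start: int  # 1-based inclusive on the sequence
    end: int
    sequence: str

    def __post_init__(self):
        if self.strand_pair[1] != self.strand_pair[0] + 1:
            raise ValueError("hairpin units pair consecutive strands only")
        if len(self.sequence) < 12:
            raise ValueError("hairpin unit must span >= 12 residues")


@dataclass
class RepeatHit:
    unit_a: HairpinUnit
    unit_b: HairpinUnit
    z_sd: float
    empirical_p: float
    result: ShuffleZResult


def enumerate_hairpins(
    topology: BetaTopology, seq: str, *, disjoint: bool = True
) -> list[HairpinUnit]:
    """Hairpin units from consecutive strand pairs.

    ``disjoint=True`` (the default, matching the tandem-hairpin model)
    tiles strands as (1,2), (3,4), ...; otherwise every consecutive pair
    (1,2), (2,3), ... yields a unit.  Units shorter than 12 residues are
    dropped.
    """
    strands = topology.strands
    if len(strands) < 2:
        return []
    pairs = (
        [(k, k + 1) for k in range(0, len(strands) - 1, 2)]
        if disjoint
        else [(k, k + 1) for k in range(len(strands) - 1)]
    )
    units = []
    for k, k2 in pairs:
        start = strands[k][0]
        end = strands[k2][1]
        if end - start + 1 < 12:
            continue
        units.append(
            HairpinUnit(
                strand_pair=(k + 1, k2 + 1),
                start=start,
                end=end,
                sequence=seq[start - 1 : end],
            )
        )
    return units


def hairpin_repeat_scan(
    seq: str,
    topology: BetaTopology,
    params: Optional[AlignmentParams] = None,
    n_shuffles: int = 2000,
    seed: int = 0,
    *,
    disjoint: bool = True,
) -> list[RepeatHit]:
    """Compare all hairpin-unit pairs within one protein.

    Each pair is scored with the shuffle statistic on a local alignment of
    the two units; ``empirical_p = (1 + #{null >= observed}) / (n + 1)``.
    Hits are sorted by descending z (ties by unit positions); output is
    independent of enumeration order.
    """
    params = params or UNIT_PARAMS
    units = enumerate_hairpins(topology, seq, disjoint=disjoint)
    if len(units) < 2:
        return []
    out = []
    for i in range(len(units)):
        for j in range(i + 1, len(units)):
            ua, ub = units[i], units[j]
            pair_seed = (seed * 69069 + i * 131 + j) % (2**31 - 1)
            res = shuffle_z(
                ua.sequence, ub.sequence, params,
                n_shuffles=n_shuffles, seed=pair_seed, mode="local",
                keep_null=True,
            )
            out.append(RepeatHit(ua, ub, res.z_sd, res.empirical_p, res))
    out.sort(key=lambda h: (-(h.z_sd if h.z_sd == h.z_sd else -1e9),
                            h.unit_a.start, h.unit_b.start))
    return out


def write_repeat_report(hits: list[RepeatHit], path, protein_id: str = "") -> None:
    """TSV repeat report (id, unit spans, z, empirical p)."""
    with open(path, "w") as fh:
        fh.write("id\tunit_a_span\tunit_b_span\tz_sd\tempirical_p\n")
        for h in hits:
            fh.write(
                f"{protein_id}\t{h.unit_a.start}-{h.unit_a.end}\t"
                f"{h.unit_b.start}-{h.unit_b.end}\t"
                f"{h.z_sd:.1f}\t{h.empirical_p:.6f}\n"
            )
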