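"""Sequence I/O, TC-identifier parsing and redundancy reduction.

Sequences are plain upper-case amino-acid strings over the 20 canonical
residues plus ``X``.  Ambiguity codes (B, Z, U, O, J) are collapsed to ``X``
on input; ``X`` scores zero against everything downstream.  Identifiers may
follow the Transporter Classification convention
``class.subclass.family.subfamily.protein`` (e.g. ``1.B.4.2.4``), in which
case a family label (``1.B.4``) is derived automatically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED = set(AMINO_ACIDS) | {"X"}
_AMBIGUOUS = str.maketrans({c: "X" for c in "BZUOJ"})
_GAPS = re.compile(r"[-.*]")

_TC_RE = re.compile(r"^(\d+)\.([A-Za-z])\.(\d+)\.(\d+)\.(\d+)$")


class FastaFormatError(ValueError):
    """Raised when a FASTA file cannot be parsed into a valid sequence set."""


def parse_tc_id(identifier: str) -> Optional[tuple[int, int, int]]:
    """Decompose a TC-style identifier into (family, subfamily, protein).

    Returns ``None`` for identifiers that are not TC numbers (a total
    function; free-form ids like ``Req1`` are simply not TC-style).
    """
    m = _TC_RE.match(identifier.strip())
    if m is None:
        return None
    return int(m.group(3)), int(m.group(4)), int(m.group(5))


def tc_family_label(identifier: str) -> Optional[str]:
    """First three dotted components of a TC id (``1.B.4.2.4`` -> ``1.B.4``)."""
    m = _TC_RE.match(identifier.strip())
    if m is None:
        return None
    return f"{m.group(1)}.{m.group(2)}.{m.group(3)}"


def clean_sequence(seq: str, *, keep_gaps: bool = False) -> str:
    seq = seq.upper()
    if not keep_gaps:
        seq = _GAPS.sub("", seq)
    seq = seq.translate(_AMBIGUOUS)
    bad = set(seq) - ALLOWED - ({"-", "."} if keep_gaps else set())
    if bad:
        raise FastaFormatError(f"sequence contains disallowed letters: {sorted(bad)}")
    return seq


@dataclass
class ProteinRecord:
    """One protein sequence with an identifier and optional TC family label."""

    id: str
    sequence: str
    description: str = ""
    family_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = clean_sequence(self.sequence, keep_gaps=True)
        if len(self.sequence.replace("-", "").replace(".", "")) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.family_label is None:
            self.family_label = tc_family_label(self.id)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ungapped(self) -> str:
        return _GAPS.sub("", self.sequence)


@dataclass
class SequenceSet:
    """Ordered collection of :class:`ProteinRecord` with unique ids."""

    records: list[ProteinRecord] = field(default_factory=list)
    source_tag: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise FastaFormatError(f"duplicate id {rec.id!r} in sequence set")
            seen.add(rec.id)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key) -> ProteinRecord:
        if isinstance(key, str):
            for rec in self.records:
                if rec.id == key:
                    return rec
            raise KeyError(key)
        return self.records[key]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def add(self, rec: ProteinRecord) -> None:
        if rec.id in set(self.ids):
            raise FastaFormatError(f"duplicate id {rec.id!r} in sequence set")
        self.records.append(rec)

    def subset(self, ids: Iterable[str]) -> "SequenceSet":
        wanted = list(ids)
        by_id = {r.id: r for r in self.records}
        return SequenceSet([by_id[i] for i in wanted], source_tag=self.source_tag)


def read_fasta(path, *, aligned: bool = False, source_tag: str = "") -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Gap characters (``-``/``.``) are stripped unless ``aligned=True``.
    Malformed or empty input raises :class:`FastaFormatError`.
    """
    path = Path(path)
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - Bio raises rarely here
        raise FastaFormatError(f"{path}: {exc}") from exc
    if not parsed:
        raise FastaFormatError(f"{path}: no FASTA entries found (line 1)")
    for i, sr in enumerate(parsed, start=1):
        if not sr.id:
            raise FastaFormatError(f"{path}: entry {i} has an empty header")
        seq = clean_sequence(str(sr.seq), keep_gaps=aligned)
        if not seq.replace("-", "").replace(".", ""):
            raise FastaFormatError(f"{path}: entry {sr.id!r} has an empty sequence")
        desc = sr.description[len(sr.id):].strip() if sr.description else ""
        records.append(ProteinRecord(id=sr.id, sequence=seq, description=desc))
    return SequenceSet(records, source_tag=source_tag or str(path))


def write_fasta(sset: SequenceSet, path, *, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in sset:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def pairwise_identity(a: str, b: str, params=None) -> float:
    """Fractional identity between two unaligned sequences.

    Computed from the global alignment; the denominator is the length of the
    shorter unaligned sequence (CD-HIT convention).
    """
    from . import pairwise  # local import to avoid a cycle

    aln = pairwise.global_align(a, b, params)
    matches = sum(
        1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x == y and x not in "-."
    )
    return matches / min(len(a), len(b))


def reduce_redundancy(
    sset: SequenceSet,
    cutoff: float,
    params=None,
    *,
    report: Optional[list] = None,
) -> SequenceSet:
    """Greedy longest-first redundancy reduction at a fractional identity cutoff.

    No two retained sequences share pairwise identity strictly greater than
    ``cutoff``; every removed sequence exceeds ``cutoff`` against the
    representative it was assigned to.  Ties in length are broken
    lexicographically by id so output is deterministic.  If ``report`` is a
    list, tuples ``(representative_id, member_id, identity)`` are appended
    for every clustered record (representatives included with identity 1.0).
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    order = sorted(sset.records, key=lambda r: (-len(r.ungapped), r.id))
    representatives: list[ProteinRecord] = []
    for rec in order:
        placed = False
        for rep in representatives:
            ident = pairwise_identity(rec.ungapped, rep.ungapped, params)
            if ident > cutoff:
                if report is not None:
                    report.append((rep.id, rec.id, round(ident, 4)))
                placed = True
                break
        if not placed:
            representatives.append(rec)
            if report is not None:
                report.append((rec.id, rec.id, 1.0))
    keep = {r.id for r in representatives}
    return SequenceSet(
        [r for r in sset.records if r.id in keep], source_tag=sset.source_tag
    )


def write_cluster_report(report: list, path) -> None:
    """TSV cluster-membership report: representative_id, member_id, identity."""
    with open(path, "w") as fh:
        fh.write("representative_id\tmember_id\tidentity\n")
        for rep, mem, ident in report:
            fh.write(f"{rep}\t{mem}\t{ident}\n")
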