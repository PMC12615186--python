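"""Sequence primitives: IUPAC algebra, composition metrics and FASTA I/O.

Everything downstream (conservation profiling, clamp design, in-silico PCR)
speaks in terms of :class:`SequenceRecord` and :class:`Oligo` and relies on
the IUPAC set semantics implemented here.  Sequences are stored uppercase;
``U`` is accepted on input and mapped to ``T`` (reference databases mix
RNA/DNA conventions).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Role",
    "OligoKind",
    "SequenceRecord",
    "Oligo",
    "IUPAC_SETS",
    "iupac_match",
    "reverse_complement",
    "purine_fraction",
    "max_purine_run",
    "self_complementary_stretch",
    "parse_fasta",
    "write_fasta",
    "read_role_map",
    "expand_degenerate",
]

#: IUPAC nucleotide codes mapped to the set of concrete bases they stand for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}

GAP = "-"
_CONCRETE = frozenset("ACGT")
_PURINES = frozenset("AG")


class Role(str, Enum):
    """Whether a reference sequence belongs to the host or to the microbes
    whose amplification the clamp must spare."""

    HOST = "host"
    MICROBE = "microbe"
    UNKNOWN = "unknown"


class OligoKind(str, Enum):
    PCR_PRIMER = "pcr_primer"
    BLOCKING_PRIMER = "blocking_primer"
    PNA = "pna"


def _canonicalize(residues: str, *, where: str = "sequence", allow_gaps: bool = False) -> str:
    out = residues.upper().replace("U", "T")
    allowed = set(IUPAC_SETS)
    if allow_gaps:
        allowed.add(GAP)
    for pos, ch in enumerate(out):
        if ch not in allowed:
            raise ValueError(
                f"illegal character {ch!r} at position {pos} in {where}"
            )
    return out


@dataclass(frozen=True)
class SequenceRecord:
    """One IUPAC DNA sequence tagged with a host/microbe role.

    Gaps (``-``) are only meaningful in an aligned context; pass
    ``aligned=True`` at construction to allow them.
    """

    id: str
    residues: str
    role: Role = Role.UNKNOWN
    description: str = ""
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        canon = _canonicalize(
            self.residues, where=f"record {self.id!r}", allow_gaps=self.aligned
        )
        object.__setattr__(self, "residues", canon)
        if isinstance(self.role, str) and not isinstance(self.role, Role):
            object.__setattr__(self, "role", Role(self.role))

    def __len__(self) -> int:
        return len(self.residues)

    def degapped(self) -> "SequenceRecord":
        return SequenceRecord(
            id=self.id,
            residues=self.residues.replace(GAP, ""),
            role=self.role,
            description=self.description,
            aligned=False,
        )


@dataclass
class Oligo:
    """An oligomer as synthesized, written 5'->3'.

    ``three_prime_block`` records a C3 spacer on the 3' end.  Blocking
    primers must carry one; PNAs must not — a PNA is non-extendable by its
    peptide backbone, not by a spacer.
    """

    name: str
    sequence: str
    kind: OligoKind = OligoKind.PCR_PRIMER
    three_prime_block: bool = False
    tm_estimate: float | None = None

    def __post_init__(self) -> None:
        self.sequence = _canonicalize(self.sequence, where=f"oligo {self.name!r}")
        if isinstance(self.kind, str) and not isinstance(self.kind, OligoKind):
            self.kind = OligoKind(self.kind)
        if len(self.sequence) < 6:
            raise ValueError(f"oligo {self.name!r}: length must be >= 6")
        if self.kind is OligoKind.BLOCKING_PRIMER and not self.three_prime_block:
            raise ValueError(
                f"oligo {self.name!r}: a blocking primer requires a 3' C3 spacer"
            )
        if self.kind is OligoKind.PNA and self.three_prime_block:
            raise ValueError(
                f"oligo {self.name!r}: a PNA carries no C3 spacer"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def iupac_match(a: str, b: str) -> bool:
    """True iff the base sets represented by two IUPAC codes intersect."""
    try:
        sa, sb = IUPAC_SETS[a], IUPAC_SETS[b]
    except KeyError as exc:
        raise ValueError(f"not an ungapped IUPAC base: {exc.args[0]!r}") from None
    return not sa.isdisjoint(sb)


def reverse_complement(seq: str) -> str:
    """Reverse complement extended to the full IUPAC alphabet."""
    try:
        return "".join(_COMPLEMENT[ch] for ch in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"illegal character {exc.args[0]!r}") from None


def _require_concrete(seq: str, op: str) -> str:
    if not seq:
        raise ValueError(f"{op}: empty sequence")
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in _CONCRETE:
            raise ValueError(
                f"{op}: degenerate or illegal base {ch!r} at position {pos}; "
                "resolve degeneracies first"
            )
    return seq


def purine_fraction(seq: str) -> float:
    """Fraction of A/G residues on the oligomer as synthesized."""
    seq = _require_concrete(seq, "purine_fraction")
    return sum(ch in _PURINES for ch in seq) / len(seq)


def max_purine_run(seq: str) -> int:
    """Length of the longest contiguous A/G run (0 for purine-free input)."""
    seq = _require_concrete(seq, "max_purine_run")
    best = run = 0
    for ch in seq:
        run = run + 1 if ch in _PURINES else 0
        best = max(best, run)
    return best


def self_complementary_stretch(seq: str, k: int = 4) -> tuple[int, bool]:
    """Longest self-complementary stretch and whether it reaches ``k``.

    Returns ``(L, flagged)`` where ``L`` is the largest length such that some
    L-mer of ``seq`` equals the reverse complement of some (possibly the
    same, possibly overlapping) L-mer of ``seq``; ``flagged`` is ``L >= k``.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    seq = _require_concrete(seq, "self_complementary_stretch")
    n = len(seq)
    best = 0
    for length in range(1, n + 1):
        kmers = {seq[i:i + length] for i in range(n - length + 1)}
        if any(reverse_complement(km) in kmers for km in kmers):
            best = length
        else:
            break  # a hit at L implies hits at all shorter L
    return best, best >= k


def expand_degenerate(seq: str, limit: int = 4096) -> list[str]:
    """All concrete ACGT sequences represented by a degenerate IUPAC string."""
    seq = _canonicalize(seq, where="expand_degenerate input")
    total = 1
    for ch in seq:
        total *= len(IUPAC_SETS[ch])
        if total > limit:
            raise ValueError(
                f"degeneracy {total}+ exceeds expansion limit {limit}"
            )
    out = [""]
    for ch in seq:
        out = [pre + b for pre in out for b in sorted(IUPAC_SETS[ch])]
    return out


# ---------------------------------------------------------------------------
# FASTA and role-map I/O


def read_role_map(path: str | Path) -> dict[str, Role]:
    """Two-column TSV (id, role) mapping record ids to host/microbe roles."""
    roles: dict[str, Role] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0].strip().lower() == "id" and row[1].strip().lower() == "role":
                continue
            if len(row) < 2:
                raise ValueError(f"role map {path}: malformed row {row!r}")
            roles[row[0].strip()] = Role(row[1].strip().lower())
    return roles


def _split_role(raw_id: str, token: str) -> tuple[str, Role]:
    if token in raw_id:
        stem, _, tag = raw_id.rpartition(token)
        tag = tag.strip().lower()
        if tag in (Role.HOST.value, Role.MICROBE.value):
            return stem, Role(tag)
    return raw_id, Role.UNKNOWN


def parse_fasta(
    path: str | Path,
    *,
    role_token: str = "|",
    role_map: Mapping[str, Role] | None = None,
    aligned: bool = False,
) -> list[SequenceRecord]:
    """Read a multi-FASTA into :class:`SequenceRecord` objects.

    Roles come from a header suffix (default ``|host`` / ``|microbe``),
    overridden by an explicit ``role_map`` keyed by the stripped id.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id, role = _split_role(rec.id, role_token)
        if role_map and rec_id in role_map:
            role = Role(role_map[rec_id])
        if rec_id in seen:
            raise ValueError(f"duplicate record id {rec_id!r} in {path}")
        seen.add(rec_id)
        desc = rec.description[len(rec.id):].strip()
        records.append(
            SequenceRecord(
                id=rec_id, residues=str(rec.seq), role=role,
                description=desc, aligned=aligned,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                *, role_token: str = "|") -> None:
    """Write records, encoding non-unknown roles back into the header."""
    out = []
    for r in records:
        rid = r.id if r.role is Role.UNKNOWN else f"{r.id}{role_token}{r.role.value}"
        out.append(SeqRecord(Seq(r.residues), id=rid, description=r.description))
    SeqIO.write(out, str(path), "fasta")
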