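"""IUPAC sequence model, FASTA I/O, complement arithmetic and primer-site location.

Every other module consumes these primitives.  Coordinates are 0-based
half-open on the plus strand throughout the library; strand is recorded
explicitly.  Human-readable reports convert to 1-based inclusive at the
output boundary only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

from Bio import SeqIO

__all__ = [
    "DegenerateSequence",
    "PrimerSite",
    "IUPAC_EXPANSION",
    "IUPAC_COMPLEMENT",
    "CODE_FOR_BASES",
    "GAP",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "iupac_compatible",
    "count_mismatches",
    "find_primer_sites",
    "expand_degenerate",
    "SequenceAlphabetError",
    "FastaParseError",
    "AlignmentLengthError",
    "LengthMismatchError",
]

GAP = "-"

#: Expansion set of every IUPAC DNA code.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
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

#: Minimal IUPAC code covering each non-empty base set (inverse of the above).
CODE_FOR_BASES: dict[frozenset, str] = {v: k for k, v in IUPAC_EXPANSION.items()}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
    GAP: GAP,
}

CONCRETE_BASES = ("A", "C", "G", "T")


class SequenceAlphabetError(ValueError):
    """A residue outside the IUPAC DNA alphabet (or an unexpected gap)."""


class FastaParseError(ValueError):
    """Malformed FASTA input; the message names the offending record."""


class AlignmentLengthError(ValueError):
    """Aligned records do not share a common length."""


class LengthMismatchError(ValueError):
    """Two sequences that must be equally long are not."""


@dataclass(frozen=True)
class DegenerateSequence:
    """A DNA string over the IUPAC degenerate alphabet.

    Parameters
    ----------
    residues : str
        Sequence letters; lower case is normalised to upper case.
    id : str
        Free-text identifier (FASTA header token).
    is_aligned : bool
        When set, the gap character ``-`` is permitted.
    """

    residues: str
    id: str = ""
    is_aligned: bool = False

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        allowed = set(IUPAC_EXPANSION)
        if self.is_aligned:
            allowed.add(GAP)
        bad = set(residues) - allowed
        if bad:
            raise SequenceAlphabetError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def __getitem__(self, key) -> str:
        return self.residues[key]

    def ungapped(self) -> "DegenerateSequence":
        """Return the same record with alignment gaps stripped."""
        if GAP not in self.residues:
            return self
        return DegenerateSequence(self.residues.replace(GAP, ""), id=self.id)

    @property
    def degeneracy(self) -> int:
        """Number of positions carrying a non-concrete code."""
        return sum(1 for r in self.residues if r not in CONCRETE_BASES and r != GAP)


@dataclass(frozen=True)
class PrimerSite:
    """A located primer binding site, 0-based half-open on the plus strand.

    ``three_prime_pos`` is the plus-strand template index paired with the
    primer's 3' terminal base: ``end - 1`` for a plus-strand hit, ``start``
    for a minus-strand hit.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    three_prime_pos: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.mismatches < 0:
            raise ValueError("mismatches must be non-negative")
        if self.three_prime_pos == -1:
            tpp = self.end - 1 if self.strand == "+" else self.start
            object.__setattr__(self, "three_prime_pos", tpp)
        if not (self.start <= self.three_prime_pos < self.end):
            raise ValueError("three_prime_pos must lie within [start, end)")

    @property
    def length(self) -> int:
        return self.end - self.start


PathLike = Union[str, Path]


def read_fasta(path: PathLike, aligned: bool = False) -> list[DegenerateSequence]:
    """Read a FASTA file into :class:`DegenerateSequence` records.

    Residues are upper-cased.  With ``aligned=True`` the gap character is
    accepted and all records must share one length.
    """
    path = Path(path)
    records: list[DegenerateSequence] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            try:
                records.append(
                    DegenerateSequence(str(rec.seq), id=rec.id, is_aligned=aligned)
                )
            except SequenceAlphabetError as exc:
                raise FastaParseError(f"record {rec.id!r}: {exc}") from exc
    except ValueError as exc:
        if isinstance(exc, (FastaParseError, SequenceAlphabetError)):
            raise
        raise FastaParseError(f"malformed FASTA file {path}: {exc}") from exc
    if aligned and records:
        ref = len(records[0])
        for rec in records:
            if len(rec) != ref:
                raise AlignmentLengthError(
                    f"aligned record {rec.id!r} has length {len(rec)}, expected {ref}"
                )
    return records


def write_fasta(records: Iterable[DegenerateSequence], path: PathLike, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id or 'seq'}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def reverse_complement(s: DegenerateSequence | str) -> DegenerateSequence:
    """Antiparallel complement with degenerate codes mapped (involution)."""
    if isinstance(s, str):
        s = DegenerateSequence(s, is_aligned=GAP in s)
    try:
        rc = "".join(IUPAC_COMPLEMENT[r] for r in reversed(s.residues))
    except KeyError as exc:  # pragma: no cover - constructor already validates
        raise SequenceAlphabetError(f"non-IUPAC residue {exc}") from exc
    return DegenerateSequence(rc, id=s.id, is_aligned=s.is_aligned)


def iupac_compatible(a: str, b: str, gap_compatible: bool = False) -> bool:
    """True iff the expansion sets of two IUPAC codes intersect.

    Symmetric.  A gap paired with a base is incompatible by default.
    """
    if a == GAP or b == GAP:
        if a == b:
            return True
        return gap_compatible
    try:
        return bool(IUPAC_EXPANSION[a] & IUPAC_EXPANSION[b])
    except KeyError:
        bad = a if a not in IUPAC_EXPANSION else b
        raise SequenceAlphabetError(f"non-IUPAC residue {bad!r}")


def count_mismatches(query: DegenerateSequence | str, window: DegenerateSequence | str) -> int:
    """Number of positions where the two equal-length strings are incompatible."""
    q = str(query).upper()
    w = str(window).upper()
    if len(q) != len(w):
        raise LengthMismatchError(f"length {len(q)} vs {len(w)}")
    return sum(1 for a, b in zip(q, w) if not iupac_compatible(a, b))


def expand_degenerate(s: DegenerateSequence | str, limit: int = 512) -> list[str]:
    """All concrete sequences covered by a degenerate string (sorted).

    Raises ``ValueError`` when the expansion would exceed ``limit`` members.
    """
    text = str(s).upper()
    if GAP in text:
        raise SequenceAlphabetError("cannot expand a gapped sequence")
    n = 1
    for r in text:
        n *= len(IUPAC_EXPANSION[r])
        if n > limit:
            raise ValueError(f"degenerate expansion exceeds limit of {limit}")
    pools = [sorted(IUPAC_EXPANSION[r]) for r in text]
    return ["".join(p) for p in itertools.product(*pools)]


def find_primer_sites(
    seq: DegenerateSequence,
    primer: DegenerateSequence,
    max_mismatch: int = 0,
) -> list[PrimerSite]:
    """Locate all windows on both strands matching a primer.

    Matching uses IUPAC set-intersection compatibility; a minus-strand hit
    compares the reverse complement of the primer against the plus-strand
    window, which is equivalent to matching the primer against the reverse
    complement of the window.  Results are sorted by (start, strand) with
    plus before minus.  A primer longer than the sequence yields an empty
    list.
    """
    target = seq.ungapped()
    text = target.residues
    p = primer.ungapped().residues
    plen = len(p)
    if plen == 0:
        raise ValueError("primer is empty")
    if plen > len(text):
        return []
    p_rc = str(reverse_complement(p))
    sites: list[PrimerSite] = []
    for start in range(len(text) - plen + 1):
        window = text[start:start + plen]
        mm = sum(1 for a, b in zip(p, window) if not iupac_compatible(a, b))
        if mm <= max_mismatch:
            sites.append(PrimerSite(target.id, start, start + plen, "+", mm))
        mm_rc = sum(1 for a, b in zip(p_rc, window) if not iupac_compatible(a, b))
        if mm_rc <= max_mismatch:
            sites.append(PrimerSite(target.id, start, start + plen, "-", mm_rc))
    sites.sort(key=lambda s: (s.start, 0 if s.strand == "+" else 1))
    return sites
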