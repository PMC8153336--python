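"""Primer-flanking regions: extraction, haplotype collapsing, conservation profiles.

The clamp-design step needs two facts about the host family around a primer
binding site: how many distinct flanking haplotypes exist, and which columns
are conserved.  Collapsing identical flanks and profiling per-column base
sets deliver both without any phylogenetic-network machinery.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .seqcore import (
    CODE_FOR_BASES,
    GAP,
    IUPAC_EXPANSION,
    DegenerateSequence,
    LengthMismatchError,
    PrimerSite,
    reverse_complement,
)

__all__ = [
    "FlankRecord",
    "HaplotypeSummary",
    "ConservationProfile",
    "extract_flank",
    "collapse_haplotypes",
    "conservation_profile",
]

Side = Literal["inside", "outside"]


@dataclass(frozen=True)
class FlankRecord:
    """A flanking region reported 5'->3' on the primer's strand.

    ``partial`` flags flanks truncated at a sequence boundary.
    """

    seq: DegenerateSequence
    partial: bool = False


@dataclass(frozen=True)
class HaplotypeSummary:
    """Distinct flank strings with occurrence counts.

    Ordered by descending count, then lexicographically.
    """

    haplotypes: dict[str, int]
    n_sequences: int
    n_haplotypes: int
    source_group: str = ""

    def __post_init__(self) -> None:
        if sum(self.haplotypes.values()) != self.n_sequences:
            raise ValueError("haplotype counts must sum to n_sequences")
        if len(self.haplotypes) != self.n_haplotypes:
            raise ValueError("n_haplotypes must equal number of distinct haplotypes")


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column observed base sets with a minimal covering IUPAC consensus.

    ``degeneracy`` counts columns whose consensus code is non-concrete.
    Columns whose only variation came from N wildcards are flagged in
    ``wildcard_columns`` and do not contribute to ``degeneracy``.
    """

    columns: tuple[frozenset, ...]
    consensus: DegenerateSequence
    degeneracy: int
    wildcard_columns: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.columns)

    def slice(self, start: int, end: int) -> "ConservationProfile":
        cols = self.columns[start:end]
        cons = DegenerateSequence(self.consensus.residues[start:end])
        deg = sum(1 for c in cols if len(c) > 1)
        wc = tuple(i - start for i in self.wildcard_columns if start <= i < end)
        return ConservationProfile(cols, cons, deg, wc)


def extract_flank(
    seq: DegenerateSequence,
    site: PrimerSite,
    flank_len: int,
    side: Side,
) -> FlankRecord:
    """Residues adjacent to a primer site, 5'->3' on the primer's strand.

    ``outside`` is the extension side (3' of the primer footprint);
    ``inside`` is behind the primer 5' end.  A region reaching past the
    sequence boundary is truncated and the record flagged partial.
    """
    if side not in ("inside", "outside"):
        raise ValueError(f"side must be 'inside' or 'outside', got {side!r}")
    if flank_len < 0:
        raise ValueError("flank_len must be non-negative")
    target = seq.ungapped()
    n = len(target)
    if site.strand == "+":
        lo, hi = (site.end, site.end + flank_len) if side == "outside" else (
            site.start - flank_len, site.start)
    else:
        lo, hi = (site.start - flank_len, site.start) if side == "outside" else (
            site.end, site.end + flank_len)
    clo, chi = max(lo, 0), min(hi, n)
    partial = (clo, chi) != (lo, hi)
    text = target.residues[clo:chi]
    flank = DegenerateSequence(text, id=f"{target.id}|{side}")
    if site.strand == "-":
        flank = reverse_complement(flank)
    return FlankRecord(flank, partial)


def collapse_haplotypes(
    flanks: Sequence[DegenerateSequence | str],
    group: str = "",
) -> HaplotypeSummary:
    """Collapse equal-length flank strings into haplotypes with counts."""
    strings = [str(f).upper() for f in flanks]
    if strings:
        ref = len(strings[0])
        for s in strings:
            if len(s) != ref:
                raise LengthMismatchError("flanks must share one length")
    counts = Counter(strings)
    ordered = dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return HaplotypeSummary(
        haplotypes=ordered,
        n_sequences=len(strings),
        n_haplotypes=len(ordered),
        source_group=group,
    )


def conservation_profile(
    flanks: Sequence[DegenerateSequence | str],
) -> ConservationProfile:
    """Per-column base sets and the minimal IUPAC consensus covering them.

    Degenerate input residues contribute their whole expansion set.  N is
    treated as a wildcard: it does not widen a column (GenBank Ns would
    otherwise force full degeneracy) but flags it; an all-N column falls
    back to the full base set.
    """
    strings = [str(f).upper() for f in flanks]
    if not strings:
        raise ValueError("conservation_profile requires at least one sequence")
    ref = len(strings[0])
    for s in strings:
        if len(s) != ref:
            raise LengthMismatchError("sequences must share one length")
        if GAP in s:
            raise ValueError("strip alignment gaps before profiling")
    columns: list[frozenset] = []
    wildcard: list[int] = []
    all_n: set[int] = set()
    for i in range(ref):
        bases: set[str] = set()
        saw_n = False
        for s in strings:
            r = s[i]
            if r == "N":
                saw_n = True
                continue
            bases |= IUPAC_EXPANSION[r]
        if not bases:
            # variation here is wildcard-only; it does not count as polymorphism
            bases = set("ACGT")
            all_n.add(i)
            saw_n = True
        if saw_n:
            wildcard.append(i)
        columns.append(frozenset(bases))
    consensus = DegenerateSequence("".join(CODE_FOR_BASES[c] for c in columns))
    degeneracy = sum(1 for i, c in enumerate(columns) if len(c) > 1 and i not in all_n)
    return ConservationProfile(tuple(columns), consensus, degeneracy, tuple(wildcard))
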