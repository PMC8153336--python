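"""Clamp (blocker) design: scan candidate windows around a universal primer's
3' end and apply four selection criteria.

A blocking clamp must (1) match every host sequence perfectly, with limited
IUPAC degeneracy absorbing host polymorphism, (2) mismatch every sequence in
the exclusion set (the taxa it must spare) by at least a configured count,
(3) melt above a temperature threshold, and (4) show low self-complementarity.

Offset convention
-----------------
Candidate windows are anchored on the primer's 3'-end template position.
``offset_upstream`` counts bases strictly 5' of that position on the
primer's strand; ``offset_downstream`` counts bases from the 3'-end position
onward in the extension direction, so the 3'-end base itself is the first
downstream base and ``length = offset_upstream + offset_downstream``.
Reports additionally print the field idiom that counts the 3'-end base as
upstream ("11 bp upstream / 6 bp downstream" for a 10+6 window).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

from .flankhap import ConservationProfile, conservation_profile
from .seqcore import (
    CONCRETE_BASES,
    DegenerateSequence,
    PrimerSite,
    count_mismatches,
    find_primer_sites,
    read_fasta,
    reverse_complement,
)
from .thermo import ThermoParams, TmEstimate, estimate_tm, hairpin_score, self_complementarity

__all__ = [
    "DesignConfig",
    "CandidateWindow",
    "BlockerCandidate",
    "DesignError",
    "enumerate_windows",
    "apply_criteria",
    "rank_candidates",
    "design_blockers",
    "extract_search_region",
    "describe_candidate",
]


class DesignError(RuntimeError):
    """The design pipeline cannot proceed (e.g. no primer site in any host)."""


@dataclass(frozen=True)
class DesignConfig:
    """Tunable thresholds and search geometry for clamp design.

    ``upstream_flank``/``downstream_flank`` bound the region scanned around
    the primer 3' end (defaults 27 bases strictly upstream, 6 from the 3'-end
    base onward).  ``tm_estimate`` names which estimate the Tm threshold is
    applied to; the choice is recorded on every candidate.
    """

    window_length_range: tuple[int, int] = (14, 18)
    offset_downstream_range: tuple[int, int] = (0, 10)
    min_exclusion_mismatch: int = 3
    tm_min: float = 70.0
    max_degeneracy: int = 2
    selfcomp_max: int = 8
    hairpin_max: int = 4
    upstream_flank: int = 27
    downstream_flank: int = 6
    tm_estimate: str = "pna"
    degenerate_policy: str = "min"
    primer_max_mismatch: int = 2
    exclusion_primer_max_mismatch: Optional[int] = None

    def __post_init__(self) -> None:
        for lo, hi in (self.window_length_range, self.offset_downstream_range):
            if hi < lo:
                raise ValueError("ranges must be non-empty")
        if self.min_exclusion_mismatch < 1:
            raise ValueError("min_exclusion_mismatch must be >= 1")
        if self.tm_estimate not in ("dna", "pna", "lna"):
            raise ValueError("tm_estimate must be one of dna/pna/lna")

    @property
    def exclusion_site_tolerance(self) -> int:
        """Mismatch allowance when locating the primer in exclusion sequences.

        The clamp window overlaps the primer footprint, so exclusion taxa are
        expected to diverge there; allow the planted divergence on top of the
        ordinary tolerance unless overridden.
        """
        if self.exclusion_primer_max_mismatch is not None:
            return self.exclusion_primer_max_mismatch
        return self.primer_max_mismatch + self.min_exclusion_mismatch


@dataclass(frozen=True)
class CandidateWindow:
    """One (start, length) window of the anchored conservation profile."""

    offset_upstream: int
    offset_downstream: int
    start_col: int
    end_col: int
    consensus: str

    @property
    def length(self) -> int:
        return self.offset_upstream + self.offset_downstream


@dataclass(frozen=True)
class BlockerCandidate:
    """A scored clamp candidate with per-criterion flags.

    ``sequence`` is reported 5'->3' on the primer's strand (clamp
    orientation); ``template_plus_sequence`` is its reverse complement.
    """

    sequence: DegenerateSequence
    offset_upstream: int
    offset_downstream: int
    length: int
    host_max_mismatch: int
    exclusion_min_mismatch: Optional[int]
    tm: TmEstimate
    selfcomp: int
    hairpin: int
    degeneracy: int
    criteria_flags: dict[str, Optional[bool]]
    tm_margin: float
    rank_score: float = 0.0
    strand_convention: str = "primer-strand-5to3"
    template_plus_sequence: str = ""

    def __post_init__(self) -> None:
        if self.length != self.offset_upstream + self.offset_downstream:
            raise ValueError("length must equal offset_upstream + offset_downstream")
        if not self.template_plus_sequence:
            object.__setattr__(
                self, "template_plus_sequence", str(reverse_complement(self.sequence)))

    @property
    def passes(self) -> bool:
        return all(v is True for v in self.criteria_flags.values())

    @property
    def failure_reasons(self) -> list[str]:
        return [k for k, v in self.criteria_flags.items() if v is not True]


def extract_search_region(
    seq: DegenerateSequence,
    site: PrimerSite,
    upstream: int,
    downstream: int,
) -> Optional[str]:
    """Template region around the primer 3' end, 5'->3' on the primer strand.

    Index ``upstream`` of the returned string is the base paired with the
    primer's 3' terminal base.  Returns None when the region leaves the
    sequence bounds.
    """
    text = seq.ungapped().residues
    if site.strand == "+":
        p3 = site.end - 1
        lo, hi = p3 - upstream, p3 + downstream
        if lo < 0 or hi > len(text):
            return None
        return text[lo:hi]
    p3 = site.start
    lo, hi = p3 - downstream + 1, p3 + upstream + 1
    if lo < 0 or hi > len(text):
        return None
    return str(reverse_complement(text[lo:hi]))


def enumerate_windows(
    profile: ConservationProfile,
    config: DesignConfig,
    anchor: Optional[int] = None,
) -> list[CandidateWindow]:
    """Every admissible (length, downstream offset) window of the profile.

    ``anchor`` is the profile column holding the primer 3'-end base
    (defaults to ``config.upstream_flank`` for a profile built over the
    configured search region).  Windows are emitted in deterministic
    (length, offset_downstream) order.
    """
    if anchor is None:
        anchor = config.upstream_flank
    ncols = len(profile)
    if ncols < config.upstream_flank + config.downstream_flank:
        raise ValueError(
            f"profile has {ncols} columns; search region needs "
            f"{config.upstream_flank + config.downstream_flank}")
    windows: list[CandidateWindow] = []
    l_lo, l_hi = config.window_length_range
    d_lo, d_hi = config.offset_downstream_range
    for length in range(l_lo, l_hi + 1):
        for d in range(d_lo, d_hi + 1):
            u = length - d
            if u < 0 or u > anchor or anchor + d > ncols:
                continue
            start, end = anchor - u, anchor + d
            windows.append(CandidateWindow(
                offset_upstream=u,
                offset_downstream=d,
                start_col=start,
                end_col=end,
                consensus=profile.consensus.residues[start:end],
            ))
    return windows


def apply_criteria(
    window: CandidateWindow,
    host_regions: Sequence[str],
    exclusion_regions: Sequence[str],
    thermo: ThermoParams | None = None,
    config: DesignConfig | None = None,
) -> BlockerCandidate:
    """Evaluate the four selection criteria for one window.

    ``host_regions`` and ``exclusion_regions`` are search-region strings on
    the common anchored frame (see :func:`extract_search_region`).  All four
    flags are recorded even when failing; an empty exclusion set leaves
    criterion 2 not-evaluable (None).
    """
    thermo = thermo or ThermoParams()
    config = config or DesignConfig()
    consensus = DegenerateSequence(window.consensus)
    sl = slice(window.start_col, window.end_col)

    host_mm = max(count_mismatches(consensus, h[sl]) for h in host_regions)
    degeneracy = sum(1 for r in consensus.residues if r not in CONCRETE_BASES)
    flag_host = host_mm == 0 and degeneracy <= config.max_degeneracy

    if exclusion_regions:
        excl_mm: Optional[int] = min(
            count_mismatches(consensus, e[sl]) for e in exclusion_regions)
        flag_excl: Optional[bool] = excl_mm >= config.min_exclusion_mismatch
    else:
        excl_mm = None
        flag_excl = None

    tm = estimate_tm(consensus, thermo, degenerate_policy=config.degenerate_policy)
    tm_value = tm.selected(config.tm_estimate if config.tm_estimate != "lna" else "dna")
    tm = replace(tm, method=f"nn-unified/{config.tm_estimate}")
    flag_tm = tm_value > config.tm_min

    sc = self_complementarity(consensus)
    hp = hairpin_score(consensus)
    flag_sc = sc <= config.selfcomp_max and hp <= config.hairpin_max

    flags = {
        "host_conserved": flag_host,
        "exclusion_divergent": flag_excl,
        "tm": flag_tm,
        "selfcomp": flag_sc,
    }
    margin = tm_value - config.tm_min
    score = (excl_mm if excl_mm is not None else -1) * 100.0 + margin - 0.1 * sc - 0.1 * degeneracy
    return BlockerCandidate(
        sequence=consensus,
        offset_upstream=window.offset_upstream,
        offset_downstream=window.offset_downstream,
        length=window.length,
        host_max_mismatch=host_mm,
        exclusion_min_mismatch=excl_mm,
        tm=tm,
        selfcomp=sc,
        hairpin=hp,
        degeneracy=degeneracy,
        criteria_flags=flags,
        tm_margin=margin,
        rank_score=score,
    )


def rank_candidates(candidates: Sequence[BlockerCandidate]) -> list[BlockerCandidate]:
    """Passing candidates first, then failures, each deterministically sorted.

    Sort key: descending exclusion mismatch, descending Tm margin, ascending
    self-complementarity, ascending degeneracy, ascending window start (most
    upstream first).  Ties preserve input order (stable sort).
    """
    def key(c: BlockerCandidate):
        excl = c.exclusion_min_mismatch if c.exclusion_min_mismatch is not None else -1
        return (
            0 if c.passes else 1,
            -excl,
            -c.tm_margin,
            c.selfcomp,
            c.degeneracy,
            -c.offset_upstream,
        )
    return sorted(candidates, key=key)


def _best_site(
    seq: DegenerateSequence,
    primer: DegenerateSequence,
    max_mismatch: int,
) -> Optional[PrimerSite]:
    sites = find_primer_sites(seq, primer, max_mismatch)
    if not sites:
        return None
    return min(sites, key=lambda s: (s.mismatches, s.start, s.strand))


FastaOrSeqs = Union[str, Path, Sequence[DegenerateSequence]]


def _as_sequences(source: FastaOrSeqs) -> list[DegenerateSequence]:
    if isinstance(source, (str, Path)):
        return read_fasta(source)
    return list(source)


def design_blockers(
    host_fasta: FastaOrSeqs,
    exclusion_fasta: FastaOrSeqs,
    primer: DegenerateSequence,
    thermo: ThermoParams | None = None,
    config: DesignConfig | None = None,
) -> list[BlockerCandidate]:
    """End-to-end clamp design.

    Locates the primer in every host sequence, builds a conservation profile
    of the search region around the primer 3' end, enumerates candidate
    windows, applies the four criteria against hosts and exclusion taxa, and
    returns the ranked candidates.
    """
    thermo = thermo or ThermoParams()
    config = config or DesignConfig()
    hosts = [h.ungapped() for h in _as_sequences(host_fasta)]
    exclusions = [e.ungapped() for e in _as_sequences(exclusion_fasta)]
    if not hosts:
        raise DesignError("no host sequences supplied")

    host_regions: list[str] = []
    missing: list[str] = []
    for h in hosts:
        site = _best_site(h, primer, config.primer_max_mismatch)
        if site is None:
            best = _best_site(h, primer, len(primer))
            missing.append(f"{h.id or '<unnamed>'}: best {best.mismatches if best else 'n/a'} mismatches")
            continue
        region = extract_search_region(h, site, config.upstream_flank, config.downstream_flank)
        if region is None:
            missing.append(f"{h.id or '<unnamed>'}: search region out of bounds")
            continue
        host_regions.append(region)
    if not host_regions:
        raise DesignError(
            "primer not locatable in any host sequence within "
            f"{config.primer_max_mismatch} mismatches ({'; '.join(missing)})")

    exclusion_regions: list[str] = []
    for e in exclusions:
        site = _best_site(e, primer, config.exclusion_site_tolerance)
        if site is None:
            continue
        region = extract_search_region(e, site, config.upstream_flank, config.downstream_flank)
        if region is not None:
            exclusion_regions.append(region)

    profile = conservation_profile(host_regions)
    windows = enumerate_windows(profile, config)
    candidates = [
        apply_criteria(w, host_regions, exclusion_regions, thermo, config)
        for w in windows
    ]
    return rank_candidates(candidates)


def describe_candidate(c: BlockerCandidate) -> str:
    """Human-readable placement of a candidate in the field's offset idiom.

    The idiom counts the primer 3'-end base as upstream, so a window with
    10 bases strictly upstream plus 6 from the 3'-end base onward is
    described as "11 bp upstream / 6 bp downstream".
    """
    return (
        f"{c.offset_upstream + 1} bp upstream / {c.offset_downstream} bp downstream "
        f"of the primer 3' end (convention: {c.offset_upstream} bases strictly 5' of "
        f"the 3'-end position; the 3'-end base opens the {c.offset_downstream}-base "
        f"downstream run)"
    )
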