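"""In-silico PCR, nested amplification and clamp-blocking prediction.

Predicts which templates a primer pair amplifies, restricts second-round
primers to first-round amplicons (nested schemes), and flags amplicons whose
template carries a near-perfect clamp binding site as blocked.  Aggregation
over a labelled community yields per-taxon amplifiable/blocked/no-site
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

from .seqcore import (
    DegenerateSequence,
    PrimerSite,
    count_mismatches,
    find_primer_sites,
    reverse_complement,
)

__all__ = [
    "AmpliconPrediction",
    "insilico_pcr",
    "nested_pcr",
    "blocking_prediction",
    "community_coverage",
    "trim_primer_tail",
]

#: Primers longer than this almost certainly carry non-genomic adapter tail.
ADAPTER_LENGTH_WARNING = 25


@dataclass(frozen=True)
class AmpliconPrediction:
    """One predicted amplicon on the plus strand of a template.

    ``amplicon_span`` is 0-based half-open and includes both primer
    footprints.  ``template`` keeps a reference to the searched sequence so
    that blocking prediction can rescan the span.
    """

    seq_id: str
    taxon_label: str
    fwd_site: PrimerSite
    rev_site: PrimerSite
    amplicon_span: tuple[int, int]
    blocked: bool = False
    block_mismatches: Optional[int] = None
    template: Optional[DegenerateSequence] = field(
        default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.fwd_site.strand != "+" or self.rev_site.strand != "-":
            raise ValueError("fwd site must be plus strand, rev site minus strand")
        lo, hi = self.amplicon_span
        if not (lo <= self.fwd_site.start and self.rev_site.end <= hi):
            raise ValueError("amplicon span must contain both primer sites")

    @property
    def length(self) -> int:
        return self.amplicon_span[1] - self.amplicon_span[0]


def trim_primer_tail(primer: DegenerateSequence, keep_3prime: int) -> DegenerateSequence:
    """Keep only the 3' ``keep_3prime`` bases (drops a 5' adapter tail)."""
    if keep_3prime <= 0 or keep_3prime > len(primer):
        raise ValueError("keep_3prime must be in [1, primer length]")
    return DegenerateSequence(primer.residues[-keep_3prime:], id=primer.id)


def insilico_pcr(
    seq: DegenerateSequence,
    fwd: DegenerateSequence,
    rev: DegenerateSequence,
    max_mismatch: int = 2,
    max_len: int = 5000,
    taxon_label: str = "",
) -> list[AmpliconPrediction]:
    """All properly oriented forward/reverse site pairs within ``max_len``.

    The forward primer must sit on the plus strand and the reverse primer on
    the minus strand 3' of it; the amplicon spans both primer footprints.
    """
    target = seq.ungapped()
    fwd_sites = [s for s in find_primer_sites(target, fwd, max_mismatch) if s.strand == "+"]
    rev_sites = [s for s in find_primer_sites(target, rev, max_mismatch) if s.strand == "-"]
    preds: list[AmpliconPrediction] = []
    for f in fwd_sites:
        for r in rev_sites:
            if r.start < f.end:
                continue
            span = (f.start, r.end)
            if span[1] - span[0] > max_len:
                continue
            preds.append(AmpliconPrediction(
                seq_id=target.id,
                taxon_label=taxon_label,
                fwd_site=f,
                rev_site=r,
                amplicon_span=span,
                template=target,
            ))
    preds.sort(key=lambda p: p.amplicon_span)
    return preds


def _shift_site(site: PrimerSite, offset: int, seq_id: str) -> PrimerSite:
    return PrimerSite(
        seq_id=seq_id,
        start=site.start + offset,
        end=site.end + offset,
        strand=site.strand,
        mismatches=site.mismatches,
        three_prime_pos=site.three_prime_pos + offset,
    )


def nested_pcr(
    seq: DegenerateSequence,
    outer_fwd: DegenerateSequence,
    outer_rev: DegenerateSequence,
    inner_fwd: DegenerateSequence,
    inner_rev: DegenerateSequence,
    max_mismatch: int = 2,
    max_len: int = 5000,
    taxon_label: str = "",
) -> list[AmpliconPrediction]:
    """Second-round predictions restricted to first-round amplicon spans.

    Inner primers are matched only within outer amplicons; returned
    predictions reference the inner span in the original template's
    coordinates.  Nesting can only restrict the inner primer pair's
    unconstrained predictions.
    """
    target = seq.ungapped()
    outer = insilico_pcr(target, outer_fwd, outer_rev, max_mismatch, max_len, taxon_label)
    seen: set[tuple[int, int]] = set()
    preds: list[AmpliconPrediction] = []
    for op in outer:
        lo, hi = op.amplicon_span
        sub = DegenerateSequence(target.residues[lo:hi], id=target.id)
        for ip in insilico_pcr(sub, inner_fwd, inner_rev, max_mismatch, max_len, taxon_label):
            span = (ip.amplicon_span[0] + lo, ip.amplicon_span[1] + lo)
            if span in seen:
                continue
            seen.add(span)
            preds.append(AmpliconPrediction(
                seq_id=target.id,
                taxon_label=taxon_label,
                fwd_site=_shift_site(ip.fwd_site, lo, target.id),
                rev_site=_shift_site(ip.rev_site, lo, target.id),
                amplicon_span=span,
                template=target,
            ))
    preds.sort(key=lambda p: p.amplicon_span)
    return preds


def blocking_prediction(
    pred: AmpliconPrediction,
    blocker: DegenerateSequence,
    max_block_mismatch: int = 1,
) -> AmpliconPrediction:
    """Flag an amplicon as blocked when the clamp finds a near-perfect site.

    Both strands of the template within the amplicon span are scanned; the
    best (lowest-mismatch) window is recorded.  Raising the threshold never
    unblocks an amplicon.
    """
    if pred.template is None:
        raise ValueError("prediction carries no template reference")
    lo, hi = pred.amplicon_span
    region = pred.template.residues[lo:hi]
    b = blocker.ungapped().residues
    if len(b) > len(region):
        return replace(pred, blocked=False, block_mismatches=None)
    rc_region = str(reverse_complement(region))
    best = min(
        count_mismatches(b, text[i:i + len(b)])
        for text in (region, rc_region)
        for i in range(len(text) - len(b) + 1)
    )
    return replace(pred, blocked=best <= max_block_mismatch, block_mismatches=best)


def community_coverage(
    seqs: Sequence[tuple[DegenerateSequence, str]],
    fwd: DegenerateSequence,
    rev: DegenerateSequence,
    blocker: Optional[DegenerateSequence] = None,
    max_mismatch: int = 2,
    max_block_mismatch: int = 1,
    max_len: int = 5000,
) -> pd.DataFrame:
    """Partition each taxon's sequences into amplifiable / blocked / no_site.

    Returns a DataFrame indexed by taxon with class counts and per-taxon
    proportions summing to one.
    """
    if not seqs:
        raise ValueError("empty community")
    rows: dict[str, dict[str, int]] = {}
    for seq, taxon in seqs:
        if not taxon:
            raise ValueError(f"sequence {seq.id!r} lacks a taxon label")
        counts = rows.setdefault(taxon, {"amplifiable": 0, "blocked": 0, "no_site": 0})
        preds = insilico_pcr(seq, fwd, rev, max_mismatch, max_len, taxon)
        if not preds:
            counts["no_site"] += 1
            continue
        if blocker is not None:
            scored = [blocking_prediction(p, blocker, max_block_mismatch) for p in preds]
            if all(p.blocked for p in scored):
                counts["blocked"] += 1
                continue
        counts["amplifiable"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df["n"] = df[["amplifiable", "blocked", "no_site"]].sum(axis=1)
    for col in ("amplifiable", "blocked", "no_site"):
        df[f"p_{col}"] = df[col] / df["n"]
    return df
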