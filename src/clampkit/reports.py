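"""Tabular report writers.

All human-readable coordinates are 1-based inclusive; every coordinate-
bearing report starts with a ``# coord_system`` header line saying so.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .blockerdesign import BlockerCandidate, describe_candidate
from .flankhap import HaplotypeSummary
from .insilico import AmpliconPrediction

COORD_HEADER = "# coord_system: 1-based inclusive\n"


def write_candidates_tsv(candidates: Sequence[BlockerCandidate], path: str | Path) -> None:
    rows = []
    for c in candidates:
        flags = {f"crit_{k}": (1 if v else 0 if v is False else "NA")
                 for k, v in c.criteria_flags.items()}
        rows.append({
            "sequence": str(c.sequence),
            "template_plus_sequence": c.template_plus_sequence,
            "length": c.length,
            "offset_upstream": c.offset_upstream,
            "offset_downstream": c.offset_downstream,
            "placement": describe_candidate(c),
            "host_max_mismatch": c.host_max_mismatch,
            "exclusion_min_mismatch": (
                c.exclusion_min_mismatch if c.exclusion_min_mismatch is not None else "NA"),
            "tm_dna": round(c.tm.tm_dna, 2),
            "tm_pna": round(c.tm.tm_pna, 2) if c.tm.tm_pna is not None else "NA",
            "tm_lna": round(c.tm.tm_lna, 2) if c.tm.tm_lna is not None else "NA",
            "tm_thresholded": c.tm.method,
            "selfcomp": c.selfcomp,
            "hairpin": c.hairpin,
            "degeneracy": c.degeneracy,
            **flags,
            "passes": int(c.passes),
            "rank_score": round(c.rank_score, 3),
        })
    path = Path(path)
    with path.open("w") as fh:
        fh.write(COORD_HEADER)
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def write_haplotypes_tsv(summaries: Sequence[HaplotypeSummary], path: str | Path) -> None:
    rows = []
    for s in summaries:
        for hap, count in s.haplotypes.items():
            rows.append({
                "group": s.source_group,
                "haplotype": hap,
                "count": count,
                "frequency": count / s.n_sequences if s.n_sequences else float("nan"),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_predictions_tsv(preds: Sequence[AmpliconPrediction], path: str | Path) -> None:
    rows = []
    for p in preds:
        rows.append({
            "seq_id": p.seq_id,
            "taxon": p.taxon_label,
            "fwd_start": p.fwd_site.start + 1,
            "fwd_end": p.fwd_site.end,
            "rev_start": p.rev_site.start + 1,
            "rev_end": p.rev_site.end,
            "amplicon_start": p.amplicon_span[0] + 1,
            "amplicon_end": p.amplicon_span[1],
            "amplicon_length": p.length,
            "fwd_mismatches": p.fwd_site.mismatches,
            "rev_mismatches": p.rev_site.mismatches,
            "blocked": int(p.blocked),
            "block_mismatches": p.block_mismatches if p.block_mismatches is not None else "NA",
        })
    path = Path(path)
    with path.open("w") as fh:
        fh.write(COORD_HEADER)
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
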