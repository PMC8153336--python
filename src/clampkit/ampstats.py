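"""Downstream statistics on taxonomy-annotated amplicon count tables.

Covers the comparisons used to judge host-blocking performance: per-sample
non-host read proportions, enrichment relative to a matched no-blocker
control, pairwise proportion tests with Bonferroni correction, alpha
diversity (Shannon, observed variants, Faith's phylogenetic diversity),
blocking-assay fluorescence normalisation, detection-grid summaries and
top-taxa rankings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "CommunityCountTable",
    "EnrichmentResult",
    "DetectionTable",
    "APICOMPLEXA_CODE_BOOK",
    "CONTROL_METHOD",
    "nontick_proportion",
    "nonhost_proportion",
    "enrichment_value",
    "enrichment_table",
    "pairwise_prop_test",
    "shannon",
    "observed_asvs",
    "faith_pd",
    "relative_intensity",
    "detection_summary",
    "top_taxa",
    "alpha_diversity_table",
    "load_apicomplexa_detections",
]

CONTROL_METHOD = "control"


@dataclass
class CommunityCountTable:
    """Sample x taxon read counts with per-sample method metadata.

    ``counts`` is taxa (semicolon-delimited lineage strings) by samples;
    ``meta`` is indexed by sample with at least ``tick_id`` and ``method``
    columns.  Each non-control sample must link to a control-method sample
    of the same individual.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(counts.to_numpy().dtype, np.integer):
            if not np.allclose(counts.to_numpy(), counts.to_numpy().astype(int)):
                raise ValueError("counts must be integers")
            self.counts = counts.astype(int)
        missing = set(counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        for col in ("tick_id", "method"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        links = self.control_links()
        unresolved = [s for s, c in links.items() if c is None]
        if unresolved:
            raise ValueError(
                f"no control-method sample for individuals of: {unresolved}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    def control_links(self) -> dict[str, Optional[str]]:
        """Map each non-control sample to its individual's control sample."""
        meta = self.meta.loc[self.samples]
        controls = meta[meta["method"] == CONTROL_METHOD]
        by_tick = {row.tick_id: sample for sample, row in controls.iterrows()}
        out: dict[str, Optional[str]] = {}
        for sample, row in meta.iterrows():
            if row.method == CONTROL_METHOD:
                continue
            out[sample] = by_tick.get(row.tick_id)
        return out

    @classmethod
    def from_tsv(cls, counts_path: str | Path, meta_path: str | Path) -> "CommunityCountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(counts=counts, meta=meta)

    def to_tsv(self, counts_path: str | Path, meta_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="taxon")
        self.meta.to_csv(meta_path, sep="\t", index_label="sample")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-sample non-host enrichment relative to the matched control."""

    sample: str
    p_nonhost: float
    p_control: float
    enrichment: float
    excluded: bool = False
    reason: str = ""


def nonhost_proportion(counts: Mapping[str, int] | pd.Series, host_taxon_prefix: str) -> float:
    """Fraction of reads not assigned under the host lineage prefix.

    NaN when the sample holds no reads.
    """
    series = pd.Series(counts, dtype=float)
    total = series.sum()
    if total <= 0:
        return float("nan")
    host = series[[t for t in series.index if str(t).startswith(host_taxon_prefix)]].sum()
    return float((total - host) / total)


# the host of interest here is the tick whose DNA swamps the library
nontick_proportion = nonhost_proportion


def enrichment_value(p_method: float, p_control: float) -> float:
    """Ratio of a method's non-host proportion to its matched control's.

    NaN (flagged-undefined) when the control proportion is zero or
    undefined; such samples are excluded from summaries.
    """
    if not 0.0 <= p_method <= 1.0 or not 0.0 <= p_control <= 1.0:
        if math.isnan(p_method) or math.isnan(p_control):
            return float("nan")
        raise ValueError("proportions must lie in [0, 1]")
    if p_control == 0 or math.isnan(p_control) or math.isnan(p_method):
        return float("nan")
    return p_method / p_control


def enrichment_table(table: CommunityCountTable, host_taxon_prefix: str) -> pd.DataFrame:
    """Per-sample enrichment report with the zero-control exclusion rule.

    A method sample whose matched control yielded only host reads cannot be
    normalised; it is flagged ``excluded`` with a reason and carries a NaN
    enrichment, mirroring how such individuals are dropped from summary
    statistics.
    """
    p = {s: nonhost_proportion(table.counts[s], host_taxon_prefix) for s in table.samples}
    links = table.control_links()
    rows = []
    for sample, control in links.items():
        p_m, p_c = p[sample], p[control]
        value = enrichment_value(p_m if not math.isnan(p_m) else float("nan"), p_c)
        excluded = math.isnan(value)
        reason = ""
        if excluded:
            reason = ("control sample has no non-host reads"
                      if p_c == 0 else "proportion undefined")
        rows.append({
            "sample": sample,
            "tick_id": table.meta.loc[sample, "tick_id"],
            "method": table.meta.loc[sample, "method"],
            "control_sample": control,
            "p_nonhost": p_m,
            "p_control": p_c,
            "enrichment": value,
            "excluded": excluded,
            "reason": reason,
        })
    return pd.DataFrame(rows).set_index("sample")


def _prop_test_2x2(s1: int, t1: int, s2: int, t2: int, correction: bool = True) -> float:
    """Chi-square test of equal proportions on one 2x2 table (Yates by default)."""
    if t1 <= 0 or t2 <= 0:
        return float("nan")
    table = np.array([[s1, t1 - s1], [s2, t2 - s2]], dtype=float)
    # degenerate margins: identical proportions by construction
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 1.0
    _, p, _, _ = sstats.chi2_contingency(table, correction=correction)
    return float(p)


def pairwise_prop_test(
    successes: Mapping[str, int] | pd.Series,
    totals: Mapping[str, int] | pd.Series,
    correction: str = "bonferroni",
    continuity: bool = True,
) -> pd.DataFrame:
    """All pairwise 2x2 chi-square tests of equal proportions.

    Mirrors the R convention: Yates continuity correction on each 2x2 table
    and Bonferroni multiplication by the number of pairs.  Groups with zero
    total are flagged not-evaluable (NaN).  The matrix is symmetric with a
    NaN diagonal.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    succ = pd.Series(successes)
    tot = pd.Series(totals).loc[succ.index]
    if ((succ < 0) | (tot < succ)).any():
        raise ValueError("need totals >= successes >= 0")
    groups = list(succ.index)
    pairs = list(combinations(groups, 2))
    m = len(pairs)
    mat = pd.DataFrame(np.nan, index=groups, columns=groups, dtype=float)
    for a, b in pairs:
        p = _prop_test_2x2(int(succ[a]), int(tot[a]), int(succ[b]), int(tot[b]),
                           correction=continuity)
        if correction == "bonferroni" and not math.isnan(p):
            p = min(1.0, m * p)
        mat.loc[a, b] = p
        mat.loc[b, a] = p
    return mat


def shannon(counts: Mapping[str, int] | pd.Series | Sequence[float]) -> float:
    """Shannon diversity, natural log: -sum p_i ln p_i over nonzero taxa."""
    arr = np.asarray(pd.Series(counts, dtype=float))
    total = arr.sum()
    if total <= 0:
        return float("nan")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def observed_asvs(counts: Mapping[str, int] | pd.Series | Sequence[float]) -> int:
    """Number of taxa (sequence variants) with a nonzero count."""
    arr = np.asarray(pd.Series(counts, dtype=float))
    return int((arr > 0).sum())


def faith_pd(
    present_taxa: Iterable[str],
    tree: dendropy.Tree,
    include_root: bool = True,
) -> float:
    """Faith's phylogenetic diversity: branch length of the minimal subtree
    connecting the present tips to the root.

    With ``include_root`` the edge above the spanning subtree's MRCA up to
    the root is included (rooted PD).  An unknown tip label is an error; an
    empty set yields 0.
    """
    present = set(present_taxa)
    if not present:
        return 0.0
    leaves = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None:
            leaves[leaf.taxon.label] = leaf
    unknown = present - set(leaves)
    if unknown:
        raise ValueError(f"tips not in tree: {sorted(unknown)}")
    root = tree.seed_node
    marked: dict[int, dendropy.Node] = {}
    for label in sorted(present):
        node = leaves[label]
        while node is not None and id(node) not in marked:
            marked[id(node)] = node
            node = node.parent_node
    if not include_root:
        # drop the path from the spanning subtree's MRCA up to the root
        node = root
        while node is not None:
            children = [c for c in node.child_nodes() if id(c) in marked]
            marked.pop(id(node), None)
            if len(children) != 1:
                break
            node = children[0]
    total = 0.0
    for node in marked.values():
        if node is root:
            continue  # the root has no edge above it
        if node.edge is not None and node.edge.length is not None:
            total += node.edge.length
    return float(total)


def alpha_diversity_table(
    table: CommunityCountTable,
    tree: Optional[dendropy.Tree] = None,
) -> pd.DataFrame:
    """Per-sample Shannon, observed variants and (optionally) Faith's PD."""
    rows = []
    for sample in table.samples:
        counts = table.counts[sample]
        row = {
            "sample": sample,
            "shannon": shannon(counts),
            "observed_asvs": observed_asvs(counts),
        }
        if tree is not None:
            present = [t for t in counts.index if counts[t] > 0]
            row["faith_pd"] = faith_pd(present, tree)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


def relative_intensity(
    values: pd.DataFrame,
    control_dose: str,
) -> pd.DataFrame:
    """Normalise replicate fluorescence readings to each trial's no-blocker
    control (control = 1.0 by construction).

    ``values`` has one row per trial and one column per dose; returns per-dose
    mean, standard deviation and replicate count.  Trials whose control
    reading is zero or missing cannot be normalised; they are dropped and
    listed in ``result.attrs['flagged_trials']``.
    """
    if control_dose not in values.columns:
        raise ValueError(f"control dose {control_dose!r} not among doses")
    ctrl = values[control_dose]
    flagged = list(values.index[(ctrl <= 0) | ctrl.isna()])
    usable = values.drop(index=flagged)
    if usable.empty:
        raise ValueError("no trial has a positive control reading")
    ratios = usable.div(usable[control_dose], axis=0)
    out = pd.DataFrame({
        "mean": ratios.mean(axis=0),
        "sd": ratios.std(axis=0, ddof=1),
        "n": ratios.count(axis=0).astype(int),
    })
    out.index.name = "dose"
    out.attrs["flagged_trials"] = flagged
    return out


#: Code book for the apicomplexan detection grid.
APICOMPLEXA_CODE_BOOK: dict[str, str] = {
    "N": "unclassified Apicomplexa",
    "A": "Amoebogregarina",
    "G": "Gregarina",
    "Cr": "Cryptosporidium",
    "T": "Theileria",
    "EU": "unclassified Eugregarinorida",
    "Co": "unclassified Colpodellidae",
}


@dataclass(frozen=True)
class DetectionTable:
    """Sample x method grid of detected-taxon code sets."""

    grid: pd.DataFrame  # cells are frozensets of codes
    code_book: Mapping[str, str] = field(default_factory=lambda: dict(APICOMPLEXA_CODE_BOOK))

    def __post_init__(self) -> None:
        known = set(self.code_book)
        for sample, row in self.grid.iterrows():
            for method, cell in row.items():
                bad = set(cell) - known
                if bad:
                    raise ValueError(
                        f"unknown detection codes {sorted(bad)} at ({sample}, {method})")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        code_book: Mapping[str, str] | None = None,
    ) -> "DetectionTable":
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
        parsed = raw.apply(lambda col: col.map(_parse_codes))
        return cls(grid=parsed, code_book=code_book or APICOMPLEXA_CODE_BOOK)


def _parse_codes(cell) -> frozenset:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return frozenset()
    text = str(cell).strip()
    if text in ("", "-"):
        return frozenset()
    return frozenset(tok.strip() for tok in text.split(",") if tok.strip())


def detection_summary(table: DetectionTable) -> pd.Series:
    """Per-code count of samples with at least one detection in any method."""
    counts = {code: 0 for code in table.code_book}
    for _, row in table.grid.iterrows():
        seen: set[str] = set()
        for cell in row:
            seen |= set(cell)
        for code in seen:
            counts[code] += 1
    return pd.Series(counts, name="n_samples_detected")


def load_apicomplexa_detections() -> DetectionTable:
    """The packaged apicomplexan detection grid (17 tick DNA samples, six
    PCR/purification methods)."""
    ref = resources.files("clampkit").joinpath("data/apicomplexa_detections.tsv")
    with resources.as_file(ref) as path:
        return DetectionTable.from_tsv(path)


def top_taxa(
    abundances: Mapping[str, float] | pd.Series,
    n: int,
    exclude: Sequence[str] = (),
) -> pd.Series:
    """Top-``n`` taxa by abundance after dropping excluded lineage prefixes.

    Host and unclassified lineages are typically excluded so the ranking
    reflects the community of interest.  Ties break lexicographically.
    """
    series = pd.Series(abundances, dtype=float)
    if (series < 0).any():
        raise ValueError("abundances must be non-negative")
    keep = [t for t in series.index
            if not any(str(t).startswith(pref) for pref in exclude)]
    series = series.loc[keep]
    order = sorted(series.index, key=lambda t: (-series[t], str(t)))
    return series.loc[order[:n]]
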