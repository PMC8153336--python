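"""Deterministic synthetic-data generator with planted ground truth.

Emulates the input structure of a clamp-design study: a host 18S-like
sequence family sharing a backbone with a small number of haplotypes and
limited polymorphism around the reverse-primer 3' end, an exclusion
("spare me") sequence carrying a fixed number of planted mismatches inside
the clamp window, and sample x taxon count tables with per-method non-host
read proportions relative to matched controls.

All randomness flows from a single integer seed; the same spec yields
byte-identical outputs.  The planted clamp window is drawn so that it is
admissible under the default design thresholds — the fixture's contract is
that exactly one designed site exists, as in the study setting the generator
emulates.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import primers
from .ampstats import CommunityCountTable, CONTROL_METHOD
from .blockerdesign import DesignConfig
from .seqcore import (
    IUPAC_COMPLEMENT,
    IUPAC_EXPANSION,
    CODE_FOR_BASES,
    DegenerateSequence,
    find_primer_sites,
    iupac_compatible,
    reverse_complement,
)
from .thermo import ThermoParams, estimate_tm, hairpin_score, self_complementarity

__all__ = [
    "FixtureSpec",
    "CountTableSpec",
    "Backbone",
    "HOST_LINEAGE_PREFIX",
    "make_host_family",
    "make_exclusion_seq",
    "make_count_table",
    "make_design_fixture",
]

HOST_LINEAGE_PREFIX = "Eukaryota;Obazoa;Arthropoda;Acari"

_DEFAULT_HOST_TAXA = (
    "Eukaryota;Obazoa;Arthropoda;Acari;Ixodidae;Haemaphysalis",
    "Eukaryota;Obazoa;Arthropoda;Acari;Ixodidae;Ixodes",
)

_DEFAULT_NONHOST_TAXA = (
    "Eukaryota;Opisthokonta;Fungi;Ascomycota;Ascochyta",
    "Eukaryota;Opisthokonta;Fungi;Ascomycota;Cladosporium",
    "Eukaryota;Opisthokonta;Fungi;Basidiomycota;Papiliotrema",
    "Eukaryota;SAR;Alveolata;Apicomplexa;Gregarina",
    "Eukaryota;SAR;Alveolata;Ciliophora;Colpoda",
    "Eukaryota;SAR;Rhizaria;Cercozoa;Heteromita",
)

#: Per-method target non-host read proportions.  The control reflects a
#: host-swamped library (0.03 % non-host reads); clamped and nested methods
#: sit one to two orders of magnitude higher, spanning the enrichment range
#: such studies report.
_DEFAULT_METHOD_NONHOST: dict[str, float] = {
    CONTROL_METHOD: 0.0003,
    "PNA-AMPure": 0.006,
    "PNA-SizeSelect": 0.031,
    "LNA-AMPure": 0.006,
    "LNA-SizeSelect": 0.017,
    "UNM": 0.058,
}


@dataclass(frozen=True)
class CountTableSpec:
    """Targets for the synthetic count table."""

    n_ticks: int = 6
    total_reads: int = 10_000
    method_nonhost: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_METHOD_NONHOST))
    include_zero_control_tick: bool = True
    host_taxa: tuple[str, ...] = _DEFAULT_HOST_TAXA
    nonhost_taxa: tuple[str, ...] = _DEFAULT_NONHOST_TAXA

    def __post_init__(self) -> None:
        if CONTROL_METHOD not in self.method_nonhost:
            raise ValueError("method_nonhost must include the control method")
        for m, p in self.method_nonhost.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"target proportion for {m!r} outside [0, 1]")
        if self.n_ticks < 1 or self.total_reads < 1:
            raise ValueError("need n_ticks >= 1 and total_reads >= 1")


@dataclass(frozen=True)
class FixtureSpec:
    """Planted ground truth for the sequence-family generator.

    ``polymorphic_columns`` and ``exclusion_mismatch_positions`` are indices
    into the planted clamp window (0-based, 5'->3' on the primer strand; the
    window covers ``blocker_upstream`` bases strictly 5' of the reverse
    primer's 3'-end template position plus ``blocker_downstream`` bases from
    that position onward).
    """

    seed: int = 0
    n_host: int = 6
    n_haplotypes: int = 2
    polymorphic_columns: tuple[tuple[int, str], ...] = ((6, "AT"),)
    exclusion_mismatch_positions: tuple[int, ...] = (8, 9, 15)
    primer_pair: tuple[DegenerateSequence, DegenerateSequence] = (
        primers.TAREUK454FWD1, primers.TAREUKREV3)
    amplicon_length: int = 380
    flank_length: int = 60
    gc_content: float = 0.5
    blocker_upstream: int = 10
    blocker_downstream: int = 6
    allow_primer_collision: bool = False
    count_table: CountTableSpec = field(default_factory=CountTableSpec)

    def __post_init__(self) -> None:
        if not 1 <= self.n_haplotypes <= self.n_host:
            raise ValueError("need 1 <= n_haplotypes <= n_host")
        length = self.blocker_upstream + self.blocker_downstream
        combos = 1
        for pos, alleles in self.polymorphic_columns:
            if not 0 <= pos < length:
                raise ValueError(f"polymorphic column {pos} outside the clamp window")
            alleles = alleles.upper()
            if len(set(alleles)) < 2 or not set(alleles) <= set("ACGT"):
                raise ValueError(f"bad allele set {alleles!r} at column {pos}")
            combos *= len(set(alleles))
        if self.n_haplotypes > 1 and combos < self.n_haplotypes:
            raise ValueError("allele combinations cannot realise n_haplotypes")
        for pos in self.exclusion_mismatch_positions:
            if not 0 <= pos < length:
                raise ValueError(f"exclusion position {pos} outside the clamp window")
        insert = self.amplicon_length - len(self.primer_pair[0]) - len(self.primer_pair[1])
        if insert < self.blocker_downstream + 10:
            raise ValueError("amplicon too short for the clamp window")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie strictly in (0, 1)")


@dataclass(frozen=True)
class Backbone:
    """Internal: the deterministic template shared by hosts and exclusion."""

    plus: str              # haplotype-0 plus strand
    p3: int                # plus-strand coordinate paired with the rev primer 3' base
    fwd_start: int
    window_plus: tuple[int, int]   # plus-strand half-open span of the clamp window
    window_consensus: str          # degenerate consensus, primer strand 5'->3'
    haplotype_combos: tuple[tuple[str, ...], ...]


def _concretize(rng: np.random.Generator, primer: DegenerateSequence) -> str:
    out = []
    for r in primer.residues:
        opts = sorted(IUPAC_EXPANSION[r])
        out.append(opts[rng.integers(len(opts))] if len(opts) > 1 else opts[0])
    return "".join(out)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _window_relpos(spec: FixtureSpec, idx: int) -> int:
    # window index -> position relative to the primer 3'-end base
    return idx - spec.blocker_upstream


def _plus_coord(p3: int, relpos: int) -> int:
    # primer-strand relative position -> plus-strand coordinate (minus-strand site)
    return p3 - relpos


def _window_string(plus: str, spec: FixtureSpec, p3: int) -> str:
    lo = p3 - (spec.blocker_downstream - 1)
    hi = p3 + spec.blocker_upstream + 1
    return str(reverse_complement(plus[lo:hi]))


def _apply_window_base(plus: list[str], p3: int, relpos: int, base: str) -> None:
    plus[_plus_coord(p3, relpos)] = IUPAC_COMPLEMENT[base]


_MAX_ATTEMPTS = 5000


def _backbone(spec: FixtureSpec) -> Backbone:
    """Draw a template whose planted clamp window is admissible.

    Redraws (within the seeded stream) until the planted consensus passes
    the default design thresholds and every haplotype carries unique primer
    sites: the fixture's contract is one designed site with known truth.
    """
    rng = np.random.default_rng(spec.seed)
    fwd, rev = spec.primer_pair
    config = DesignConfig()
    thermo = ThermoParams()
    insert_len = spec.amplicon_length - len(fwd) - len(rev)

    allele_sets = [sorted(set(a.upper())) for _, a in spec.polymorphic_columns]
    combos = tuple(itertools.product(*allele_sets))[: spec.n_haplotypes] if allele_sets else ((),)
    combos = tuple(tuple(c) for c in combos)
    if spec.polymorphic_columns and len(combos) < spec.n_haplotypes:
        raise ValueError("not enough allele combinations for n_haplotypes")

    for _ in range(_MAX_ATTEMPTS):
        fwd_c = _concretize(rng, fwd)
        rev_c = _concretize(rng, rev)
        left = _random_bases(rng, spec.flank_length, spec.gc_content)
        insert = _random_bases(rng, insert_len, spec.gc_content)
        right = _random_bases(rng, spec.flank_length, spec.gc_content)
        plus = list(left + fwd_c + insert + str(reverse_complement(rev_c)) + right)
        p3 = spec.flank_length + len(fwd) + insert_len
        # haplotype 0 carries the first allele at every polymorphic column
        for (idx, _), alleles in zip(spec.polymorphic_columns, allele_sets):
            _apply_window_base(plus, p3, _window_relpos(spec, idx), alleles[0])
        plus_str = "".join(plus)

        window = list(_window_string(plus_str, spec, p3))
        for (idx, _), alleles in zip(spec.polymorphic_columns, allele_sets):
            window[idx] = CODE_FOR_BASES[frozenset(alleles)]
        consensus = "".join(window)

        if not _window_admissible(consensus, config, thermo):
            continue
        if not _sites_unique(plus_str, spec, combos, allele_sets, p3, config):
            continue
        lo = p3 - (spec.blocker_downstream - 1)
        hi = p3 + spec.blocker_upstream + 1
        return Backbone(
            plus=plus_str,
            p3=p3,
            fwd_start=spec.flank_length,
            window_plus=(lo, hi),
            window_consensus=consensus,
            haplotype_combos=combos,
        )
    raise RuntimeError("could not draw an admissible planted window")


def _window_admissible(consensus: str, config: DesignConfig, thermo: ThermoParams) -> bool:
    seq = DegenerateSequence(consensus)
    if seq.degeneracy > config.max_degeneracy:
        return False
    tm = estimate_tm(seq, thermo, degenerate_policy="min")
    if tm.selected(config.tm_estimate) <= config.tm_min:
        return False
    if self_complementarity(seq) > config.selfcomp_max:
        return False
    if hairpin_score(seq) > config.hairpin_max:
        return False
    return True


def _haplotype_plus(backbone_plus: str, spec: FixtureSpec, p3: int,
                    combo: Sequence[str]) -> str:
    plus = list(backbone_plus)
    for (idx, _), base in zip(spec.polymorphic_columns, combo):
        _apply_window_base(plus, p3, _window_relpos(spec, idx), base)
    return "".join(plus)


def _sites_unique(plus: str, spec: FixtureSpec, combos, allele_sets, p3: int,
                  config: DesignConfig) -> bool:
    fwd, rev = spec.primer_pair
    for combo in combos:
        hap = DegenerateSequence(_haplotype_plus(plus, spec, p3, combo))
        fsites = find_primer_sites(hap, fwd, config.primer_max_mismatch)
        rsites = find_primer_sites(hap, rev, config.primer_max_mismatch)
        if len([s for s in fsites if s.strand == "+"]) != 1 or len(fsites) != 1:
            return False
        if len([s for s in rsites if s.strand == "-"]) != 1 or len(rsites) != 1:
            return False
        if rsites[0].start != p3:
            return False
    return True


def make_host_family(spec: FixtureSpec) -> list[DegenerateSequence]:
    """Host sequences sharing the backbone, partitioned into haplotypes.

    Host ``i`` carries haplotype ``i % n_haplotypes``, so every haplotype is
    realised and counts are as balanced as possible.
    """
    bb = _backbone(spec)
    hosts = []
    for i in range(spec.n_host):
        hap = i % spec.n_haplotypes
        combo = bb.haplotype_combos[hap] if spec.polymorphic_columns else ()
        seq = _haplotype_plus(bb.plus, spec, bb.p3, combo)
        hosts.append(DegenerateSequence(seq, id=f"host_{i:02d}_hap{hap}"))
    return hosts


def make_exclusion_seq(spec: FixtureSpec) -> DegenerateSequence:
    """Host backbone with substitutions at exactly the planted positions.

    Each substitution is guaranteed incompatible with the host consensus at
    that column.  Inside the primer footprint a substitution must remain
    primer-compatible (the exclusion taxon is still an amplification target)
    unless ``allow_primer_collision`` is set.
    """
    bb = _backbone(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    _, rev = spec.primer_pair
    poly = {idx: sorted(set(a.upper())) for idx, a in spec.polymorphic_columns}
    plus = list(bb.plus)
    window = _window_string(bb.plus, spec, bb.p3)
    for idx in spec.exclusion_mismatch_positions:
        relpos = _window_relpos(spec, idx)
        host_bases = set(poly.get(idx, [window[idx]]))
        candidates = [b for b in "ACGT" if not any(iupac_compatible(b, h) for h in host_bases)]
        if relpos <= 0:  # inside the reverse-primer footprint
            primer_res = rev.residues[len(rev) - 1 + relpos]
            compatible = [b for b in candidates if iupac_compatible(b, primer_res)]
            if compatible:
                candidates = compatible
            elif not spec.allow_primer_collision:
                raise ValueError(
                    f"exclusion position {idx} collides with the primer site and no "
                    "primer-compatible substitution exists; set allow_primer_collision")
        if not candidates:
            raise ValueError(f"no admissible substitution at window position {idx}")
        base = candidates[int(rng.integers(len(candidates)))]
        _apply_window_base(plus, bb.p3, relpos, base)
    return DegenerateSequence("".join(plus), id="exclusion_00")


def make_design_fixture(spec: FixtureSpec):
    """Hosts, exclusion sequence and the planted-truth record in one call."""
    bb = _backbone(spec)
    hosts = make_host_family(spec)
    exclusion = make_exclusion_seq(spec)
    truth = {
        "window_consensus": bb.window_consensus,
        "window_plus_span": list(bb.window_plus),
        "rev_three_prime_pos": bb.p3,
        "offset_upstream": spec.blocker_upstream,
        "offset_downstream": spec.blocker_downstream,
        "n_haplotypes": spec.n_haplotypes,
        "polymorphic_columns": [list(pc) for pc in spec.polymorphic_columns],
        "exclusion_mismatch_positions": list(spec.exclusion_mismatch_positions),
        "n_exclusion_mismatches": len(set(spec.exclusion_mismatch_positions)),
    }
    return hosts, exclusion, truth


def make_count_table(spec: FixtureSpec):
    """Synthetic count table plus the true parameter record.

    Realised non-host proportions equal the targets to within 1/total_reads.
    One extra individual with a zero non-host control (when enabled)
    exercises the exclusion rule for enrichment summaries.
    """
    ct = spec.count_table
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    taxa = list(ct.host_taxa) + list(ct.nonhost_taxa)
    tick_ids = [f"tick{i + 1:02d}" for i in range(ct.n_ticks)]
    zero_tick = None
    if ct.include_zero_control_tick:
        zero_tick = f"tick{ct.n_ticks + 1:02d}"
        tick_ids.append(zero_tick)

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    truth_samples = {}
    n_non = len(ct.nonhost_taxa)
    for tick in tick_ids:
        for method, target in ct.method_nonhost.items():
            p = 0.0 if (tick == zero_tick and method == CONTROL_METHOD) else target
            nonhost = int(round(p * ct.total_reads))
            host = ct.total_reads - nonhost
            vec = np.zeros(len(taxa), dtype=int)
            host_split = rng.multinomial(host, np.full(len(ct.host_taxa), 1 / len(ct.host_taxa)))
            vec[: len(ct.host_taxa)] = host_split
            if nonhost:
                vec[len(ct.host_taxa):] = rng.multinomial(nonhost, np.full(n_non, 1 / n_non))
            sample = f"{tick}_{method}"
            columns[sample] = vec
            purification = method.split("-", 1)[1] if "-" in method else "-"
            meta_rows.append({
                "sample": sample,
                "tick_id": tick,
                "method": method,
                "purification": purification,
            })
            truth_samples[sample] = {"target_nonhost": p, "total": ct.total_reads}

    counts = pd.DataFrame(columns, index=taxa)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    table = CommunityCountTable(counts=counts, meta=meta)
    control_p = ct.method_nonhost[CONTROL_METHOD]
    truth = {
        "method_nonhost": dict(ct.method_nonhost),
        "expected_enrichment": {
            m: (p / control_p if control_p > 0 else None)
            for m, p in ct.method_nonhost.items() if m != CONTROL_METHOD
        },
        "zero_control_tick": zero_tick,
        "host_lineage_prefix": HOST_LINEAGE_PREFIX,
        "samples": truth_samples,
    }
    return table, truth


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write hosts.fasta, exclusion.fasta, counts.tsv, meta.tsv, truth.json."""
    from .seqcore import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hosts, exclusion, design_truth = make_design_fixture(spec)
    table, count_truth = make_count_table(spec)
    write_fasta(hosts, out / "hosts.fasta")
    write_fasta([exclusion], out / "exclusion.fasta")
    table.to_tsv(out / "counts.tsv", out / "meta.tsv")
    truth = {"design": design_truth, "counts": count_truth,
             "spec": {k: v for k, v in asdict(spec).items() if k != "primer_pair"}}
    (out / "truth.json").write_text(json.dumps(truth, indent=1, default=str))
    return truth
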