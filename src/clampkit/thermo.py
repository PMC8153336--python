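"""Melting-temperature estimation for DNA, PNA and LNA oligos, plus
self-complementarity and hairpin screening.

DNA duplex Tm uses the unified nearest-neighbor model (Allawi & SantaLucia
1997 parameter set) with the entropic monovalent-salt correction

    Tm = 1000*dH / (dS + 0.368*(N-1)*ln[Na+] + R*ln(C_T/x)) - 273.15

with dH in kcal/mol, dS in cal/(mol K), R = 1.9872 cal/(mol K), x = 4 for
non-self-complementary duplexes (x = 1 with a symmetry entropy term
otherwise).

PNA/DNA duplex Tm is the published linear regression on the NN DNA Tm,
pyrimidine fraction and length (Giesen et al. 1998):

    Tm_PNA = 20.79 + 0.83*Tm_NN - 26.13*f_pyr + 0.44*L

LNA-substituted oligos gain an additive per-substitution increment.  All
coefficients live in :class:`ThermoParams` and are user-overridable.

Degenerate sequences are expanded into their concrete variants and the
per-variant estimates aggregated; the default policy ``min`` is the
conservative bound (a threshold passes only if every variant passes).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional

from .seqcore import (
    IUPAC_COMPLEMENT,
    IUPAC_EXPANSION,
    DegenerateSequence,
    expand_degenerate,
    reverse_complement,
)

__all__ = [
    "ThermoParams",
    "TmEstimate",
    "DNA_NN_UNIFIED",
    "GIESEN_PNA_COEFFS",
    "DEFAULT_LNA_INCREMENTS",
    "tm_nearest_neighbor",
    "tm_pna_estimate",
    "tm_lna_estimate",
    "estimate_tm",
    "self_complementarity",
    "hairpin_score",
]

R_GAS = 1.9872  # cal / (mol K)
SALT_ENTROPY_COEFF = 0.368  # cal / (mol K) per phosphate, ln-molar salt

#: Unified NN parameters: dimer -> (dH kcal/mol, dS cal/(mol K)).
DNA_NN_UNIFIED: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}

#: (intercept, slope on NN DNA Tm, pyrimidine-fraction weight, length weight).
GIESEN_PNA_COEFFS: tuple[float, float, float, float] = (20.79, 0.83, -26.13, 0.44)

#: Per-substitution Tm gain (degC).  Published single-substitution gains span
#: roughly +2 to +8 degC with G/C locks at the upper end; these defaults sit
#: mid-range.
DEFAULT_LNA_INCREMENTS: dict[str, float] = {"A": 3.0, "T": 3.0, "C": 5.0, "G": 5.0}

DegeneratePolicy = Literal["min", "max", "mean"]


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic model parameters.

    ``monovalent_salt`` and ``oligo_conc`` are molar.  Defaults reflect the
    NN reference salt condition (1 M Na+) and a clamp working concentration
    of 2 uM (50 pmol in a 25 uL reaction).
    """

    nn_table: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DNA_NN_UNIFIED))
    init_at: tuple[float, float] = (2.3, 4.1)
    init_gc: tuple[float, float] = (0.1, -2.8)
    symmetry: tuple[float, float] = (0.0, -1.4)
    monovalent_salt: float = 1.0
    oligo_conc: float = 2e-6
    pna_coeffs: tuple[float, float, float, float] = GIESEN_PNA_COEFFS
    lna_increment_table: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LNA_INCREMENTS))

    def __post_init__(self) -> None:
        missing = set(DNA_NN_UNIFIED) - set(self.nn_table)
        if missing:
            raise ValueError(f"nn_table lacks dimers: {sorted(missing)}")
        if self.oligo_conc <= 0:
            raise ValueError("oligo_conc must be > 0")
        if self.monovalent_salt <= 0:
            raise ValueError("monovalent_salt must be > 0")

    def to_file(self, path: str | Path) -> None:
        data = {
            "nn_table": {k: list(v) for k, v in self.nn_table.items()},
            "init_at": list(self.init_at),
            "init_gc": list(self.init_gc),
            "symmetry": list(self.symmetry),
            "monovalent_salt": self.monovalent_salt,
            "oligo_conc": self.oligo_conc,
            "pna_coeffs": list(self.pna_coeffs),
            "lna_increment_table": dict(self.lna_increment_table),
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_file(cls, path: str | Path) -> "ThermoParams":
        data = json.loads(Path(path).read_text())
        return cls(
            nn_table={k: tuple(v) for k, v in data["nn_table"].items()},
            init_at=tuple(data["init_at"]),
            init_gc=tuple(data["init_gc"]),
            symmetry=tuple(data["symmetry"]),
            monovalent_salt=data["monovalent_salt"],
            oligo_conc=data["oligo_conc"],
            pna_coeffs=tuple(data["pna_coeffs"]),
            lna_increment_table=data["lna_increment_table"],
        )


@dataclass(frozen=True)
class TmEstimate:
    """Bundle of melting-temperature estimates for one oligo (degC)."""

    tm_dna: float
    tm_pna: Optional[float] = None
    tm_lna: Optional[float] = None
    method: str = "nn-unified"
    degenerate_policy: DegeneratePolicy = "min"

    def selected(self, kind: str) -> float:
        value = {"dna": self.tm_dna, "pna": self.tm_pna, "lna": self.tm_lna}[kind]
        if value is None:
            raise ValueError(f"no {kind} estimate available")
        return value


def _aggregate(values: Iterable[float], policy: DegeneratePolicy) -> float:
    vals = list(values)
    if policy == "min":
        return min(vals)
    if policy == "max":
        return max(vals)
    if policy == "mean":
        return sum(vals) / len(vals)
    raise ValueError(f"unknown degenerate policy {policy!r}")


def _tm_concrete(seq: str, params: ThermoParams) -> float:
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        dimer = seq[i:i + 2]
        if dimer in params.nn_table:
            h, s = params.nn_table[dimer]
        else:
            rc = IUPAC_COMPLEMENT[dimer[1]] + IUPAC_COMPLEMENT[dimer[0]]
            h, s = params.nn_table[rc]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = params.init_gc if terminal in "GC" else params.init_at
        dh += h
        ds += s
    if seq == str(reverse_complement(seq)):
        dh += params.symmetry[0]
        ds += params.symmetry[1]
        x = 1.0
    else:
        x = 4.0
    ds += SALT_ENTROPY_COEFF * (len(seq) - 1) * math.log(params.monovalent_salt)
    return 1000.0 * dh / (ds + R_GAS * math.log(params.oligo_conc / x)) - 273.15


def tm_nearest_neighbor(
    s: DegenerateSequence | str,
    params: ThermoParams | None = None,
    degenerate_policy: DegeneratePolicy = "min",
) -> float:
    """NN DNA/DNA duplex Tm in degC.

    Degenerate codes are expanded and the per-variant values aggregated per
    ``degenerate_policy``.  Sequences shorter than 8 nt are rejected: the NN
    model is unreliable there.
    """
    params = params or ThermoParams()
    text = str(s).upper()
    if len(text) < 8:
        raise ValueError("NN Tm requires length >= 8")
    return _aggregate(
        (_tm_concrete(v, params) for v in expand_degenerate(text)),
        degenerate_policy,
    )


def tm_pna_estimate(
    tm_dna: float,
    length: int,
    pyrimidine_fraction: float,
    params: ThermoParams | None = None,
) -> float:
    """PNA/DNA duplex Tm from the linear regression in :class:`ThermoParams`."""
    params = params or ThermoParams()
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= pyrimidine_fraction <= 1.0:
        raise ValueError("pyrimidine_fraction must lie in [0, 1]")
    c0, c1, c2, c3 = params.pna_coeffs
    return c0 + c1 * tm_dna + c2 * pyrimidine_fraction + c3 * length


def tm_lna_estimate(
    s: DegenerateSequence | str,
    lna_positions: Iterable[int],
    params: ThermoParams | None = None,
    degenerate_policy: DegeneratePolicy = "min",
) -> float:
    """NN DNA Tm plus additive per-substitution LNA increments."""
    params = params or ThermoParams()
    text = str(s).upper()
    positions = sorted(set(lna_positions))
    if positions and not (0 <= positions[0] and positions[-1] < len(text)):
        raise ValueError("LNA position out of range")
    base = tm_nearest_neighbor(text, params, degenerate_policy)
    bonus = 0.0
    for i in positions:
        increments = [params.lna_increment_table[b] for b in sorted(IUPAC_EXPANSION[text[i]])]
        bonus += _aggregate(increments, degenerate_policy)
    return base + bonus


def estimate_tm(
    s: DegenerateSequence | str,
    params: ThermoParams | None = None,
    lna_positions: Iterable[int] | None = None,
    degenerate_policy: DegeneratePolicy = "min",
) -> TmEstimate:
    """Convenience bundle: NN DNA Tm, PNA regression estimate, optional LNA."""
    params = params or ThermoParams()
    text = str(s).upper()
    variants = expand_degenerate(text)
    tm_dna = _aggregate((_tm_concrete(v, params) for v in variants), degenerate_policy)
    pnas = []
    for v in variants:
        f_pyr = sum(1 for b in v if b in "CT") / len(v)
        pnas.append(tm_pna_estimate(_tm_concrete(v, params), len(v), f_pyr, params))
    tm_pna = _aggregate(pnas, degenerate_policy)
    tm_lna = None
    if lna_positions is not None:
        tm_lna = tm_lna_estimate(text, lna_positions, params, degenerate_policy)
    return TmEstimate(tm_dna=tm_dna, tm_pna=tm_pna, tm_lna=tm_lna,
                      degenerate_policy=degenerate_policy)


def _complementary(a: str, b: str) -> bool:
    # a can pair with b iff some expansion of a is the Watson-Crick
    # complement of some expansion of b
    return bool(IUPAC_EXPANSION[a] & {IUPAC_COMPLEMENT[x] for x in IUPAC_EXPANSION[b]})


def self_complementarity(s: DegenerateSequence | str) -> int:
    """Maximum number of complementary pairings over all antiparallel
    ungapped self-alignments (self-dimer screen).

    Every paired position counts, so a perfect even-length palindrome scores
    its full length.
    """
    text = str(s).upper()
    n = len(text)
    if n < 2:
        raise ValueError("self_complementarity requires length >= 2")
    best = 0
    for d in range(2 * n - 1):
        score = 0
        for i in range(n):
            j = d - i
            if 0 <= j < n and j != i and _complementary(text[i], text[j]):
                score += 1
        best = max(best, score)
    return best


def hairpin_score(s: DegenerateSequence | str, min_loop: int = 3) -> int:
    """Longest contiguous stem of an internal fold with loop >= ``min_loop``."""
    text = str(s).upper()
    n = len(text)
    best = 0
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            stem = 0
            a, b = i, j
            while a >= 0 and b < n and _complementary(text[a], text[b]):
                stem += 1
                a -= 1
                b += 1
            best = max(best, stem)
    return best
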