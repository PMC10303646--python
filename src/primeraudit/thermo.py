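"""Melting-temperature ranges for degenerate primers.

A degenerate primer is a mixture of all its concrete expansions, so its Tm
is reported as a (min, max) range over those expansions.  Three standard
formulas are offered: the Wallace 2+4 rule (short oligos), the GC-fraction
formula 64.9 + 41*(nGC - 16.4)/L, and unified nearest-neighbor
thermodynamics (via Biopython) with configurable oligo and monovalent-salt
concentrations.

Tm ranges are informational output of the audit report: published ranges
for degenerate marker primers rarely state their formula, and none of the
implemented methods should be assumed to reproduce any particular printed
range exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from Bio.SeqUtils import MeltingTemp as _mt

from .iupac import degeneracy, expansions, normalize, round_half_up

TmMethod = Literal["wallace", "gc_fraction", "nearest_neighbor"]

DEFAULT_ENUMERATION_CAP = 1024


@dataclass(frozen=True)
class TmRange:
    """Min/max melting temperature (°C) over all expansions of an oligo."""

    low: int
    high: int
    method: TmMethod

    def __str__(self) -> str:
        return f"{self.low}" if self.low == self.high else f"{self.low}–{self.high}"


def tm_wallace(seq: str) -> float:
    """Wallace rule: 2·(A+T) + 4·(G+C), for concrete sequences."""
    gc = sum(seq.count(b) for b in "GC")
    return 2.0 * (len(seq) - gc) + 4.0 * gc


def tm_gc_fraction(seq: str) -> float:
    """64.9 + 41·(nGC − 16.4)/L (the simple GC-content formula)."""
    gc = sum(seq.count(b) for b in "GC")
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


def tm_nearest_neighbor(seq: str, dna_conc_nM: float = 250.0, salt_mM: float = 50.0) -> float:
    """Unified nearest-neighbor Tm at the given primer and Na+ concentrations."""
    return float(_mt.Tm_NN(seq, dnac1=dna_conc_nM, dnac2=0, Na=salt_mM))


_METHODS = {
    "wallace": tm_wallace,
    "gc_fraction": tm_gc_fraction,
    "nearest_neighbor": tm_nearest_neighbor,
}


def default_method(oligo: str) -> TmMethod:
    """Wallace for oligos up to 24 nt, nearest-neighbor for longer ones."""
    return "wallace" if len(normalize(oligo)) <= 24 else "nearest_neighbor"


def tm_range(
    oligo: str,
    method: TmMethod | None = None,
    *,
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
    **conditions: float,
) -> TmRange:
    """Enumerate every concrete expansion and return (min, max) Tm in °C.

    Values are rounded half-up to whole degrees.  Oligos whose degeneracy
    exceeds *enumeration_cap* are rejected (the cap is stated in the error).
    Extra keyword arguments (``dna_conc_nM``, ``salt_mM``) are passed to the
    nearest-neighbor method.
    """
    seq = normalize(oligo)
    if method is None:
        method = default_method(seq)
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ValueError(f"unknown Tm method {method!r}; choose from {sorted(_METHODS)}") from None
    d = degeneracy(seq)
    if d > enumeration_cap:
        raise ValueError(
            f"degeneracy {d} exceeds the enumeration cap of {enumeration_cap}; "
            "raise enumeration_cap to force evaluation"
        )
    kwargs = conditions if method == "nearest_neighbor" else {}
    tms = [fn(s, **kwargs) for s in expansions(seq)]
    return TmRange(
        low=int(round_half_up(min(tms), 0)),
        high=int(round_half_up(max(tms), 0)),
        method=method,
    )
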