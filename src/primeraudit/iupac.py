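"""IUPAC nucleotide algebra.

Every other module in the package builds on four small operations over the
15-letter IUPAC nucleotide alphabet: expansion of an ambiguity code into the
set of concrete bases it denotes, *subset compatibility* between a primer
base and a template base, the degeneracy of an oligo (how many concrete
oligos a degenerate sequence represents), and ambiguity-aware reverse
complementation.

Compatibility uses subset semantics: a primer symbol covers a template
symbol iff the primer's expansion contains every base the template could
be.  An ``N`` in a reference record is therefore only covered by an ``N``
in the primer — the conservative reading of "this primer could amplify the
site whatever the true base is".
"""

from __future__ import annotations

import itertools
from decimal import ROUND_HALF_UP, Decimal
from math import prod
from typing import Iterator

#: Standard IUPAC nucleotide ambiguity table (DNA).
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

#: Reverse lookup: concrete base set -> IUPAC symbol.
CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_EXPANSION.items()}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "S": "S", "W": "W",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

ALPHABET = frozenset(IUPAC_EXPANSION)


class InvalidSymbolError(ValueError):
    """A character outside the IUPAC nucleotide alphabet."""


def normalize(seq: str) -> str:
    """Uppercase a sequence, map RNA ``U`` to ``T``, and validate it.

    Raises :class:`InvalidSymbolError` naming the first offending character.
    """
    out = seq.upper().replace("U", "T")
    for i, ch in enumerate(out):
        if ch not in ALPHABET:
            raise InvalidSymbolError(
                f"invalid nucleotide symbol {seq[i]!r} at position {i} in {seq!r}"
            )
    return out


def expand(symbol: str) -> frozenset[str]:
    """Concrete bases denoted by one IUPAC symbol, e.g. ``R`` -> ``{A, G}``."""
    try:
        return IUPAC_EXPANSION[symbol.upper().replace("U", "T")]
    except KeyError:
        raise InvalidSymbolError(f"invalid nucleotide symbol {symbol!r}") from None


def code_for(bases: frozenset[str] | set[str]) -> str:
    """IUPAC symbol for a non-empty set of concrete bases."""
    try:
        return CODE_FOR_SET[frozenset(bases)]
    except KeyError:
        raise InvalidSymbolError(f"no IUPAC code for base set {sorted(bases)}") from None


def compatible(primer_base: str, site_base: str) -> bool:
    """True iff the primer symbol covers the template symbol.

    Subset semantics: ``expand(site_base) <= expand(primer_base)``.
    """
    return expand(site_base) <= expand(primer_base)


def degeneracy(oligo: str) -> int:
    """Number of concrete oligos a (possibly degenerate) oligo represents."""
    seq = normalize(oligo)
    if not seq:
        raise ValueError("empty oligo")
    return prod(len(IUPAC_EXPANSION[b]) for b in seq)


def revcomp(oligo: str) -> str:
    """Ambiguity-aware reverse complement (an involution)."""
    seq = normalize(oligo)
    return "".join(IUPAC_COMPLEMENT[b] for b in reversed(seq))


def expansions(oligo: str, cap: int | None = None) -> Iterator[str]:
    """Yield every concrete expansion of *oligo* in lexicographic order.

    The number of expansions equals ``degeneracy(oligo)``; *cap*, if given,
    rejects oligos whose degeneracy exceeds it before enumerating.
    """
    seq = normalize(oligo)
    if cap is not None:
        d = degeneracy(seq)
        if d > cap:
            raise ValueError(f"degeneracy {d} exceeds enumeration cap {cap}")
    pools = [sorted(IUPAC_EXPANSION[b]) for b in seq]
    for combo in itertools.product(*pools):
        yield "".join(combo)


def mismatches(primer: str, window: str) -> int:
    """Number of positions where the primer does not cover the window."""
    if len(primer) != len(window):
        raise ValueError(
            f"length mismatch: primer {len(primer)} vs window {len(window)}"
        )
    return sum(
        1 for p, w in zip(primer, window)
        if not (IUPAC_EXPANSION[w] <= IUPAC_EXPANSION[p])
    )


def round_half_up(x: float | Decimal, ndigits: int = 4) -> float:
    """Round half away from zero at *ndigits* decimals (53.65005 -> 53.6501)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 4) -> float:
    """``100*count/total`` rounded half-up, computed in exact decimal arithmetic."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))
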