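"""Published ITS2 audit fixtures.

The top-five binding-site variant tables observed for the universal fungal
ITS2 primers ITS86F (forward) and ITS4 (reverse) in an audit of NCBI's ITS
RefSeq Targeted Loci collection, as published: 9695 records carried an
ITS86F site and 2197 an ITS4 site, and the tables below list the five most
frequent site sequences of each with their counts.  These tables alone
support the whole coverage/refinement workflow without any FASTA download.

Note the tables are truncations: their counts sum to less than the located-
site totals, so rates computed from them are lower bounds on full-table
rates for any primer covering variants outside the top five.
"""

from __future__ import annotations

from .audit import PrimerDef, VariantTable

#: Universal primer seeds as published.
ITS86F = PrimerDef("ITS86F", "GTGAATCATCGAATCTTTGAA", "forward")
ITS4 = PrimerDef("ITS4", "TCCTCCGCTTATTGATATGC", "reverse")

#: Degenerate primers produced by the published refinement.
CEP_ITS86F = PrimerDef("CEP-ITS86F", "GTGARTCATYGARTCTTTGAA", "forward")
CEP_ITS4 = PrimerDef("CEP-ITS4", "TCCTCYGCTKAYTGATATGC", "reverse")

_TABLES: dict[str, tuple[int, dict[str, int]]] = {
    "ITS86F": (
        9695,
        {
            "GTGAATCATCGAATCTTTGAA": 7700,
            "GTGAATCATCGAGTCTTTGAA": 888,
            "GTGAGTCATCGAATCTTTGAA": 253,
            "GTGAATCATTGAATCTTTGAA": 108,
            "GTGAACCATCGAATCTTTGAA": 96,
        },
    ),
    "ITS4": (
        2197,
        {
            "TCCTCCGCTTATTGATATGC": 2058,
            "CCTCCGGCTTATTGATATGC": 16,
            "CCTCCCGCTTATTGATATGC": 12,
            "TCCTCTGCTTATTGATATGC": 10,
            "TCCTCCGCTGACTGATATGC": 8,
        },
    ),
}


def published_variant_table(name: str) -> VariantTable:
    """The published top-five variant table for ``"ITS86F"`` or ``"ITS4"``.

    Sequences and counts are byte-exact as printed; proportions are
    recomputed over the published located-site totals (9695 and 2197) and
    reproduce the printed percentages.
    """
    key = name.upper().replace("-", "")
    if key not in _TABLES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_TABLES)}")
    total, counts = _TABLES[key]
    return VariantTable.from_counts(counts, primer_name=key, total_sites=total)
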