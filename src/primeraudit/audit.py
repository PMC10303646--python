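"""Binding-site audit: locate a primer's site in each reference record and
tabulate the distinct site sequences with counts and proportions.

The audit answers the question a universal-primer validation asks of a
reference collection: *where does this primer anneal in each record, what
does the template look like there, and which fraction of the observed site
variants does the primer actually cover?*  The tabulation is the object
published as a "top variants" table: one row per distinct site sequence,
with its count and its percentage of all located sites.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, NamedTuple

import pandas as pd

from .iupac import mismatches, normalize, percent, revcomp

log = logging.getLogger(__name__)

Orientation = Literal["forward", "reverse"]


@dataclass(frozen=True)
class PrimerDef:
    """A named, oriented, possibly degenerate primer.

    ``orientation="reverse"`` means the primer anneals to the reverse strand
    of the reference records, so its binding site appears reverse-
    complemented on the record's forward strand (the usual situation for a
    reverse PCR primer against single-stranded database records).
    """

    name: str
    sequence: str
    orientation: Orientation = "forward"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("primer name must be non-empty")
        object.__setattr__(self, "sequence", normalize(self.sequence))
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward|reverse, got {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def scan_sequence(self) -> str:
        """The sequence to slide along a record's forward strand."""
        return self.sequence if self.orientation == "forward" else revcomp(self.sequence)


@dataclass(frozen=True)
class SiteHit:
    """The best-matching binding-site window in one reference record.

    ``start`` is the 0-based offset of the window on the forward strand of
    the record as scanned; ``strand`` is ``+`` when the window was found on
    the record as given and ``-`` when it was found after reverse-
    complementing the whole record (both-strand search).  ``site`` is always
    reported in primer orientation so variant tables read like the primer.
    """

    record_id: str
    start: int
    strand: str
    mismatch_count: int
    site: str


class Variant(NamedTuple):
    sequence: str
    count: int
    proportion_pct: float


@dataclass
class VariantTable:
    """Distinct binding-site sequences with counts and proportions.

    Rows are sorted by count descending, ties broken lexicographically.
    Proportions are percentages of ``total_sites`` (the number of records in
    which a site was located), rounded half-up to 4 decimals.  ``total_sites``
    may exceed the sum of counts when the table is a published truncation
    (e.g. only the top five variants are listed).
    """

    primer_name: str
    variants: list[Variant]
    total_sites: int

    @classmethod
    def from_counts(
        cls,
        counts: dict[str, int] | Counter,
        primer_name: str = "",
        total_sites: int | None = None,
    ) -> "VariantTable":
        for seq, c in counts.items():
            if not isinstance(c, int) or isinstance(c, bool) or c < 0:
                raise ValueError(f"count for {seq} must be a non-negative integer, got {c!r}")
        lengths = {len(s) for s in counts}
        if len(lengths) > 1:
            raise ValueError(f"variant sequences have unequal lengths: {sorted(lengths)}")
        total = sum(counts.values()) if total_sites is None else total_sites
        if total_sites is not None and sum(counts.values()) > total_sites:
            raise ValueError("counts sum exceeds total_sites")
        rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        variants = [
            Variant(normalize(seq), c, percent(c, total) if total else 0.0)
            for seq, c in rows
        ]
        return cls(primer_name=primer_name, variants=variants, total_sites=total)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def counts(self) -> dict[str, int]:
        return {v.sequence: v.count for v in self.variants}

    @property
    def site_length(self) -> int | None:
        return len(self.variants[0].sequence) if self.variants else None

    def top(self, k: int) -> "VariantTable":
        """Presentation truncation; ``total_sites`` (the denominator) is kept."""
        return VariantTable(self.primer_name, self.variants[:k], self.total_sites)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "primer": self.primer_name,
                "sequence": [v.sequence for v in self.variants],
                "count": [v.count for v in self.variants],
                "proportion_pct": [v.proportion_pct for v in self.variants],
            }
        )


def locate_site(
    record_seq: str,
    primer: PrimerDef,
    max_mismatch: int = 5,
    *,
    search_both_strands: bool = False,
    record_id: str = "",
) -> SiteHit | None:
    """Find the best binding-site window for *primer* in one record.

    Scans every window of primer length along the record's forward strand
    (reverse primers are scanned as their reverse complement), scoring each
    window by the number of positions the primer fails to cover.  Returns
    the leftmost window achieving the minimum mismatch count, provided that
    minimum is ``<= max_mismatch``; otherwise ``None``.  The reported site
    is given in primer orientation.
    """
    seq = normalize(record_seq)
    scan = primer.scan_sequence
    if len(seq) < len(scan):
        log.info("record %s shorter than primer %s; no site", record_id or "<anon>", primer.name)
        return None

    def best_on(strand_seq: str) -> tuple[int, int] | None:
        best: tuple[int, int] | None = None  # (mismatches, start)
        for start in range(len(strand_seq) - len(scan) + 1):
            m = mismatches(scan, strand_seq[start : start + len(scan)])
            if best is None or m < best[0]:
                best = (m, start)
                if m == 0:
                    break
        return best

    candidates: list[tuple[int, str, int, str]] = []  # (mm, strand, start, window)
    fwd = best_on(seq)
    if fwd is not None:
        m, s = fwd
        candidates.append((m, "+", s, seq[s : s + len(scan)]))
    if search_both_strands:
        rc = revcomp(seq)
        rev = best_on(rc)
        if rev is not None:
            m, s = rev
            candidates.append((m, "-", s, rc[s : s + len(scan)]))
    if not candidates:
        return None
    m, strand, start, window = min(candidates, key=lambda c: (c[0], c[1] != "+"))
    if m > max_mismatch:
        return None
    site = window if primer.orientation == "forward" else revcomp(window)
    return SiteHit(record_id=record_id, start=start, strand=strand, mismatch_count=m, site=site)


def scan_collection(
    records: Iterable[tuple[str, str]],
    primer: PrimerDef,
    max_mismatch: int = 5,
    *,
    search_both_strands: bool = False,
) -> tuple[list[SiteHit], int]:
    """Locate the primer site in every record.

    Returns the hits and the number of records in which no acceptable site
    was found.  Duplicate record ids are kept (counted independently) with a
    warning, matching how redundant database records are usually audited.
    """
    hits: list[SiteHit] = []
    n_absent = 0
    seen: set[str] = set()
    for rid, seq in records:
        if rid in seen:
            log.warning("duplicate record id %s kept", rid)
        seen.add(rid)
        hit = locate_site(
            seq, primer, max_mismatch,
            search_both_strands=search_both_strands, record_id=rid,
        )
        if hit is None:
            n_absent += 1
        else:
            hits.append(hit)
    return hits, n_absent


def tabulate(
    records: Iterable[tuple[str, str]],
    primer: PrimerDef,
    max_mismatch: int = 5,
    *,
    search_both_strands: bool = False,
) -> VariantTable:
    """Audit a collection and aggregate located sites into a variant table.

    ``total_sites`` is the number of records with a located site — the
    denominator for all proportions — not the raw record count.
    """
    hits, n_absent = scan_collection(
        records, primer, max_mismatch, search_both_strands=search_both_strands
    )
    if not hits:
        log.warning("no binding site located for %s in any record", primer.name)
        return VariantTable(primer_name=primer.name, variants=[], total_sites=0)
    if n_absent:
        log.info("%d records had no acceptable %s site", n_absent, primer.name)
    return VariantTable.from_counts(Counter(h.site for h in hits), primer_name=primer.name)


# --- TSV persistence -------------------------------------------------------
#
# Format: optional comment header lines ("# key=value"), then tab-separated
# columns primer, sequence, count, proportion_pct.  total_sites may be given
# as a header override (needed for published truncated tables); otherwise it
# defaults to the sum of counts.  Proportions are recomputed at load time.

def save_variant_table(table: VariantTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# total_sites={table.total_sites}\n")
        table.to_frame().to_csv(fh, sep="\t", index=False)


def load_variant_table(path: str | Path) -> VariantTable:
    path = Path(path)
    total_override: int | None = None
    with path.open() as fh:
        header_lines = 0
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line[1:].strip().partition("=")
            if key.strip() == "total_sites":
                total_override = int(value)
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sequence" not in df.columns or "count" not in df.columns:
        raise ValueError(f"{path}: variant table needs 'sequence' and 'count' columns")
    counts: dict[str, int] = {}
    for seq, c in zip(df["sequence"], df["count"]):
        if float(c) != int(c) or int(c) < 0:
            raise ValueError(f"{path}: count {c!r} for {seq} is not a non-negative integer")
        counts[str(seq)] = counts.get(str(seq), 0) + int(c)
    primer_name = str(df["primer"].iloc[0]) if "primer" in df.columns and len(df) else ""
    return VariantTable.from_counts(counts, primer_name=primer_name, total_sites=total_override)
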