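"""FASTA ingestion and report emission.

Machine output is a pair of diff-stable TSVs — the full variant table per
primer and a refinement/coverage table (primer name, sequence, Tm range,
matching rate) — plus a sidecar metadata text block carrying the run
configuration and timestamp, kept out of the data files so reruns diff
clean.  The human summary truncates variant tables to a top-k for display;
all computation always uses the full tables.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

from . import __version__
from .audit import PrimerDef, VariantTable, save_variant_table
from .iupac import normalize
from .refine import CoverageResult, RefinementResult, RescuePrimer
from .thermo import tm_range


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream ``(id, sequence)`` pairs from a FASTA file.

    Record ids are the first whitespace-delimited header token; sequences
    are uppercased with U mapped to T.  Empty files and files whose first
    non-blank line is not a header are rejected.
    """
    path = Path(path)
    with path.open() as fh:
        first = ""
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                first = line
                break
        if not first:
            raise ValueError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise ValueError(f"{path}: line {lineno} is not a FASTA header: {first.strip()!r}")
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, normalize(str(rec.seq))


@dataclass
class ReportRow:
    """One line of the developed-primers table."""

    name: str
    sequence: str
    tm: str
    rate_pct: float | None


def refinement_report_rows(
    primer: PrimerDef,
    result: RefinementResult,
    rescues: list[RescuePrimer] = (),
    tm_method: str | None = None,
) -> list[ReportRow]:
    """Rows for the refined primer and its rescue primers, with Tm ranges."""
    rows = [
        ReportRow(
            name=f"CEP-{primer.name}",
            sequence=result.refined,
            tm=str(tm_range(result.refined, tm_method)),
            rate_pct=result.final.rate_pct,
        )
    ]
    for r in rescues:
        cov = sum(v.count for v in r.cluster)
        rate = (
            None if r.cluster.total_sites == 0
            else round(100 * cov / r.cluster.total_sites, 4)
        )
        rows.append(
            ReportRow(
                name=f"CEP-{primer.name}-{r.name_suffix}",
                sequence=r.sequence,
                tm=str(tm_range(r.sequence, tm_method)),
                rate_pct=rate,
            )
        )
    return rows


def write_report(
    out_dir: str | Path,
    tables: dict[str, VariantTable],
    rows: list[ReportRow],
    metadata: dict[str, object],
) -> None:
    """Emit variant tables, the developed-primers TSV and a metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        save_variant_table(table, out / f"variants_{name}.tsv")
    pd.DataFrame(
        {
            "primer": [r.name for r in rows],
            "sequence": [r.sequence for r in rows],
            "tm_range_c": [r.tm for r in rows],
            "matching_rate_pct": [r.rate_pct for r in rows],
        }
    ).to_csv(out / "developed_primers.tsv", sep="\t", index=False)
    with (out / "run_metadata.txt").open("w") as fh:
        fh.write(f"tool_version\t{__version__}\n")
        fh.write(f"timestamp\t{datetime.datetime.now().isoformat()}\n")
        for k, v in metadata.items():
            fh.write(f"{k}\t{v}\n")


def summarize_table(table: VariantTable, top_k: int = 5) -> str:
    """Human-readable top-k summary of a variant table."""
    lines = [f"{table.primer_name}: {table.total_sites} located sites"]
    for v in table.top(top_k):
        lines.append(f"  {v.sequence}\t{v.count}\t{v.proportion_pct:.4f}%")
    hidden = len(table) - min(len(table), top_k)
    if hidden > 0:
        lines.append(f"  ... {hidden} more variants (full table in machine output)")
    return "\n".join(lines)
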