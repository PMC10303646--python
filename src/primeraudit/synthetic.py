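"""Synthetic reference collections with planted primer-binding sites.

Emulates the shape of a marker-locus reference database at testing scale:
each record is a random flanking context with one binding-site variant
planted at a known position (or no site at all, for records truncated
before the locus), optionally emitted reverse-complemented.  Variant
assignment uses exact largest-remainder quotas rather than sampling, so
the ground-truth counts are deterministic functions of the requested
frequencies — audit results can be compared to truth exactly, with no
tolerance.  A ``sample=True`` mode switches to multinomial draws for
stress tests.

What this generator does *not* emulate: real ITS sequence evolution
(flanks are i.i.d. uniform bases), indels in the binding site, chimeras,
or taxonomic structure.  Passing audits on this output demonstrates the
scanning and tabulation machinery, not robustness to biological mess.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .iupac import normalize, revcomp

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SiteSpec:
    """Planting plan for one collection.

    ``variants`` maps concrete site sequences to target frequencies; with
    ``fraction_no_site`` they must sum to at most 1 (any remaining mass is
    treated as additional no-site records).  ``min_flank_distance`` keeps
    every non-planted window at least that many substitutions away from
    every variant, so site location is unambiguous at the matching
    tolerances the audit uses.
    """

    variants: dict[str, float]
    fraction_no_site: float = 0.0
    fraction_revcomp: float = 0.0
    flank_length: tuple[int, int] = (30, 60)
    substitution_noise_rate: float = 0.0
    min_flank_distance: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("at least one variant is required")
        lengths = {len(v) for v in self.variants}
        if len(lengths) != 1:
            raise ValueError("all variants must have equal length")
        for v, f in self.variants.items():
            normalize(v)
            if f < 0:
                raise ValueError(f"negative frequency for {v}")
        if self.fraction_no_site < 0 or self.fraction_revcomp < 0 or self.fraction_revcomp > 1:
            raise ValueError("fractions must lie in [0, 1]")
        if sum(self.variants.values()) + self.fraction_no_site > 1 + 1e-9:
            raise ValueError("variant frequencies plus fraction_no_site exceed 1")


def largest_remainder_quotas(freqs: Sequence[float], n: int) -> list[int]:
    """Apportion *n* items to frequencies by the largest-remainder rule.

    Deterministic: remainder ties are broken by list position.  The result
    sums exactly to ``round(n * sum(freqs))`` scaled into the available n.
    """
    exact = [f * n for f in freqs]
    floors = [int(x) for x in exact]
    short = round(sum(exact)) - sum(floors)
    order = sorted(range(len(freqs)), key=lambda i: (-(exact[i] - floors[i]), i))
    for i in order[:short]:
        floors[i] += 1
    return floors


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _min_window_distance(seq: str, targets: Sequence[str], skip: int | None = None) -> int:
    """Smallest Hamming distance from any length-L window of seq to any target."""
    L = len(targets[0])
    best = L + 1
    for start in range(len(seq) - L + 1):
        if start == skip:
            continue
        w = seq[start : start + L]
        for t in targets:
            best = min(best, _hamming(w, t))
    return best


def generate(
    spec: SiteSpec,
    n_records: int,
    fasta_path: str | Path | None = None,
    truth_path: str | Path | None = None,
    *,
    sample: bool = False,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Build *n_records* synthetic records plus a ground-truth table.

    Returns ``(records, truth)`` where records are ``(id, sequence)`` pairs
    and truth has columns ``record_id, variant, start, strand`` (empty
    variant for no-site records; start/strand refer to the planted window
    on the emitted record).  If paths are given, the records are written as
    wrapped FASTA and the truth as TSV.  Byte-identical output for a given
    spec (the seed lives in the spec).
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.variants)
    site_len = len(names[0])

    freqs = [spec.variants[v] for v in names]
    if sample:
        counts = rng.multinomial(n_records, freqs + [1 - sum(freqs)])[: len(names)]
        quotas = list(int(c) for c in counts)
    else:
        quotas = largest_remainder_quotas(freqs, n_records)
    n_no_site = n_records - sum(quotas)
    if n_no_site < 0 or any(q < 0 for q in quotas):
        raise ValueError(f"quotas infeasible for n_records={n_records}")

    # category per record, then a fixed shuffle so variants interleave
    cats: list[str | None] = []
    for name, q in zip(names, quotas):
        cats.extend([name] * q)
    cats.extend([None] * n_no_site)
    rng.shuffle(cats)

    n_rc = largest_remainder_quotas([spec.fraction_revcomp], n_records)[0]
    rc_flags = np.zeros(n_records, dtype=bool)
    rc_flags[rng.choice(n_records, size=n_rc, replace=False)] = True

    def random_flank(length: int) -> str:
        return "".join(rng.choice(_BASES, size=length))

    def add_noise(flank: str) -> str:
        if spec.substitution_noise_rate <= 0:
            return flank
        chars = list(flank)
        for i in range(len(chars)):
            if rng.random() < spec.substitution_noise_rate:
                chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
        return "".join(chars)

    records: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    for idx, cat in enumerate(cats):
        rid = f"rec{idx:05d}"
        for _attempt in range(200):
            left = add_noise(random_flank(int(rng.integers(*spec.flank_length, endpoint=True))))
            right = add_noise(random_flank(int(rng.integers(*spec.flank_length, endpoint=True))))
            if cat is None:
                seq, start = left + right, None
                if len(seq) < site_len:
                    continue
                ok = _min_window_distance(seq, names) >= spec.min_flank_distance
            else:
                seq, start = left + cat + right, len(left)
                ok = _min_window_distance(seq, names, skip=start) >= spec.min_flank_distance
            if ok:
                break
        else:  # pragma: no cover - vanishingly unlikely for 20-mers
            raise RuntimeError(f"could not build unambiguous flanks for {rid}")

        strand = "+"
        if rc_flags[idx]:
            strand = "-"
            if start is not None:
                start = len(seq) - start - site_len
            seq = revcomp(seq)
        records.append((rid, seq))
        truth_rows.append(
            {"record_id": rid, "variant": cat or "", "start": -1 if start is None else start,
             "strand": strand if cat else ""}
        )

    truth = pd.DataFrame(truth_rows, columns=["record_id", "variant", "start", "strand"])
    if fasta_path is not None:
        write_fasta(records, fasta_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return records, truth


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write records as line-wrapped FASTA."""
    with Path(path).open("w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def truth_counts(truth: pd.DataFrame) -> dict[str, int]:
    """Planted-variant counts from a truth table (no-site records excluded)."""
    sub = truth[truth["variant"] != ""]
    return sub["variant"].value_counts().to_dict()
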