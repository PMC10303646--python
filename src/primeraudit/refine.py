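"""Coverage computation and greedy IUPAC-degenerate primer refinement.

A primer *covers* a concrete site variant when every position of the
variant lies inside the primer's per-position IUPAC expansion — zero
mismatches; amplifiability is treated as all-or-nothing at the audit level.
The *matching rate* of a primer against a variant table is the percentage
of located sites whose variant it covers.

Refinement introduces degenerate codes one position at a time: each step
finds the single-position widening (current symbol ∪ one observed variant
base) that rescues the largest count of still-uncovered sites, subject to a
degeneracy budget and an untouchable 3'-terminal zone (mismatches near the
3' end abort polymerase extension, so universal primers keep that end
concrete).  The greedy loop stops when the matching rate reaches the target,
the budget is exhausted, or no single-position widening gains anything.
Variants needing simultaneous changes at two or more positions are left to
rescue-primer design (:func:`design_rescue`), which clusters them and emits
one minimal degenerate consensus per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

from .audit import VariantTable
from .iupac import code_for, compatible, expand, normalize, percent

__all__ = [
    "covers",
    "coverage",
    "CoverageResult",
    "RefineConfig",
    "RefinementStep",
    "RefinementResult",
    "refine_greedy",
    "design_rescue",
    "RescuePrimer",
]


def covers(primer: str, variant: str) -> bool:
    """True iff *primer* covers *variant* at every position (zero mismatches)."""
    primer = normalize(primer)
    variant = normalize(variant)
    if len(primer) != len(variant):
        raise ValueError(f"length mismatch: primer {len(primer)} vs variant {len(variant)}")
    return all(compatible(p, v) for p, v in zip(primer, variant))


@dataclass(frozen=True)
class CoverageResult:
    """Matching rate of one primer against one variant table."""

    primer: str
    covered_count: int
    total_sites: int
    rate_pct: float | None          #: percent, half-up to 4 decimals; None for an empty table
    uncovered: VariantTable         #: unmatched variants; denominator (total_sites) preserved


def coverage(primer: str, table: VariantTable) -> CoverageResult:
    """Sum the counts of covered variants and report the rate over total_sites."""
    primer = normalize(primer)
    if table.site_length is not None and table.site_length != len(primer):
        raise ValueError(
            f"variant length {table.site_length} != primer length {len(primer)}"
        )
    covered = 0
    missed: dict[str, int] = {}
    for v in table:
        if covers(primer, v.sequence):
            covered += v.count
        else:
            missed[v.sequence] = v.count
    uncovered = VariantTable.from_counts(
        missed, primer_name=table.primer_name, total_sites=table.total_sites
    ) if missed else VariantTable(table.primer_name, [], table.total_sites)
    rate = percent(covered, table.total_sites) if table.total_sites > 0 else None
    return CoverageResult(
        primer=primer, covered_count=covered, total_sites=table.total_sites,
        rate_pct=rate, uncovered=uncovered,
    )


@dataclass(frozen=True)
class RefineConfig:
    """Knobs of the greedy refinement.

    Defaults encode conservative degenerate-primer practice: a 92% coverage
    bar, two-fold ambiguity codes only (R/Y/S/W/K/M), no degeneracy within
    the last five 3' bases, and at most four degenerate positions overall.
    """

    target_coverage_pct: float = 92.0
    d_max: int = 4                       #: max number of degenerate positions
    protect_3prime: int = 5              #: 3'-terminal positions never widened
    max_expansion_per_position: int = 2  #: cap on |expansion| at any position

    def __post_init__(self) -> None:
        if not (0 < self.target_coverage_pct <= 100):
            raise ValueError("target_coverage_pct must be in (0, 100]")
        if self.protect_3prime < 0:
            raise ValueError("protect_3prime must be >= 0")


@dataclass(frozen=True)
class RefinementStep:
    position: int        #: 0-based position widened
    before: str          #: IUPAC symbol before
    after: str           #: IUPAC symbol after
    gain: int            #: marginal covered-site count gained


@dataclass(frozen=True)
class RefinementResult:
    seed: str
    refined: str
    steps: tuple[RefinementStep, ...]
    final: CoverageResult
    target_reached: bool


def _n_degenerate(primer: str) -> int:
    return sum(1 for b in primer if len(expand(b)) > 1)


def refine_greedy(
    seed: str, table: VariantTable, config: RefineConfig = RefineConfig()
) -> RefinementResult:
    """Greedily widen single positions of *seed* until the target rate is met.

    Each iteration enumerates, over uncovered variants that disagree with
    the current primer at exactly one non-protected position, the proposal
    "widen that position's symbol to (current expansion ∪ variant base)",
    discards proposals violating the per-position expansion cap or the
    degenerate-position budget, scores each by its total covered-count gain,
    and applies the best one.  Ties go to the smaller resulting expansion,
    then to the 5'-most position.  Deterministic; if the target is
    unreachable the best-effort primer is returned with
    ``target_reached=False``.
    """
    primer = normalize(seed)
    if table.site_length is not None and table.site_length != len(primer):
        raise ValueError("seed length differs from variant length")
    steps: list[RefinementStep] = []
    cov = coverage(primer, table)
    allowed = range(max(0, len(primer) - config.protect_3prime))

    while cov.rate_pct is not None and cov.rate_pct < config.target_coverage_pct:
        budget_left = config.d_max - _n_degenerate(primer)
        # candidate widenings: position -> set of widened symbols proposed
        proposals: dict[tuple[int, str], None] = {}
        for v in cov.uncovered:
            bad = [i for i, (p, b) in enumerate(zip(primer, v.sequence)) if not compatible(p, b)]
            if len(bad) != 1:
                continue  # multi-position variants are rescue-primer territory
            i = bad[0]
            if i not in allowed:
                continue
            union = expand(primer[i]) | expand(v.sequence[i])
            if len(union) > config.max_expansion_per_position:
                continue
            if len(expand(primer[i])) == 1 and budget_left <= 0:
                continue  # would open a new degenerate position past the budget
            proposals[(i, code_for(union))] = None

        best: tuple[int, int, int, str] | None = None  # (-gain, |expansion|, pos, symbol)
        for (i, sym) in proposals:
            candidate = primer[:i] + sym + primer[i + 1 :]
            gain = coverage(candidate, table).covered_count - cov.covered_count
            if gain <= 0:
                continue
            key = (-gain, len(expand(sym)), i, sym)
            if best is None or key < best:
                best = key
        if best is None:
            break
        _, _, i, sym = best
        gain = -best[0]
        steps.append(RefinementStep(position=i, before=primer[i], after=sym, gain=gain))
        primer = primer[:i] + sym + primer[i + 1 :]
        cov = coverage(primer, table)

    reached = cov.rate_pct is not None and cov.rate_pct >= config.target_coverage_pct
    return RefinementResult(
        seed=normalize(seed), refined=primer, steps=tuple(steps),
        final=cov, target_reached=reached,
    )


# --- rescue primers --------------------------------------------------------

@dataclass(frozen=True)
class RescuePrimer:
    """A degenerate consensus primer for one cluster of leftover variants."""

    sequence: str
    name_suffix: str     #: first three bases, the conventional -XXX label
    cluster: VariantTable


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def design_rescue(
    uncovered: VariantTable, max_primers: int = 2, radius: int = 2
) -> list[RescuePrimer]:
    """Cluster leftover variants and emit one degenerate consensus per cluster.

    Single-linkage clustering under Hamming distance ``<= radius``; clusters
    are processed largest total count first (ties: lexicographically smallest
    consensus), up to *max_primers*.  Each consensus is the per-position
    union of the cluster's observed bases, so it covers every variant in its
    cluster by construction.
    """
    seqs = [v.sequence for v in uncovered]
    if not seqs:
        return []
    parent = list(range(len(seqs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if _hamming(seqs[i], seqs[j]) <= radius:
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(seqs)):
        clusters.setdefault(find(i), []).append(i)

    counts = uncovered.counts
    built: list[tuple[int, str, list[int]]] = []
    for members in clusters.values():
        consensus = "".join(
            code_for(frozenset().union(*(expand(seqs[i][p]) for i in members)))
            for p in range(len(seqs[members[0]]))
        )
        built.append((sum(counts[seqs[i]] for i in members), consensus, members))
    built.sort(key=lambda t: (-t[0], t[1]))

    out: list[RescuePrimer] = []
    for total, consensus, members in built[:max_primers]:
        cluster_table = VariantTable.from_counts(
            {seqs[i]: counts[seqs[i]] for i in members},
            primer_name=uncovered.primer_name,
            total_sites=uncovered.total_sites,
        )
        out.append(RescuePrimer(sequence=consensus, name_suffix=consensus[:3], cluster=cluster_table))
    return out
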