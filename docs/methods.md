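# Methods

## Model of amplifiability

A primer is treated as a set of concrete oligos (its IUPAC expansions) and
a binding site as amplifiable iff the primer covers it at *every* position
with zero mismatches — subset semantics: primer symbol `p` covers template
symbol `s` iff `expand(s) ⊆ expand(p)`. This is all-or-nothing by design:
the audit asks "could this primer amplify this site whatever the true base
is", not "how efficiently would it amplify". Consequences worth knowing:

- An ambiguous base in a *reference record* (e.g. `N`) is only covered by
  an equal-or-wider primer symbol. Databases rarely state how their
  ambiguous bases should be scored; this is the conservative choice, and
  it is ours — records with `N` in the binding site depress matching rates.
- No position weighting: a 5′ mismatch counts the same as a 3′ mismatch at
  the audit level. The 3′ end is instead protected at the *refinement*
  level (below), where it matters for what we output.

## Site location

For each record, every window of primer length on the given strand is
scored by the number of uncovered positions; reverse primers are scanned
as their reverse complement and their sites reported in primer
orientation, so variant tables read like the primer. The leftmost window
with the minimum score wins (ties are essentially nonexistent in real ITS
data; leftmost makes reruns byte-identical), and the record contributes a
site only if that minimum is ≤ `max_mismatch`.

`max_mismatch` defaults to 5 over a 20–21-mer: loose enough to find the
locus through natural variation, tight enough to exclude records that
simply do not contain it. Published audits rarely state this tolerance;
the absent-site count is reported so either interpretation of a
"matching" denominator can be emulated. Both-strand search is off by
default (reference collections are oriented) and available as a flag.

Proportions use the located-site total as denominator, not the raw record
count — this is forced by the arithmetic of the published tables the
package reproduces (7700/9695 = 79.4224%, not 7700/11892). All
percentages are rounded half-up to 4 decimals in exact decimal
arithmetic; every printed value the packaged tables carry is reproduced
bit-for-bit by this rule.

## Greedy refinement

Each step considers only uncovered variants that disagree with the
current primer at exactly one non-protected position, proposes widening
that position to the union of its current expansion and the variant's
base, and applies the proposal with the largest covered-count gain (ties:
smaller resulting expansion, then 5′-most position). Stopping: target
rate reached, degenerate-position budget spent, or no positive gain.

Defaults, and why:

| parameter | default | rationale |
|---|---|---|
| `target_coverage_pct` | 92 % | the coverage bar the refined ITS2 primers were built to |
| `max_expansion_per_position` | 2 | two-fold codes (R/Y/S/W/K/M) keep the primer mixture simple and the per-expansion concentration high |
| `protect_3prime` | 5 positions | 3′-terminal mismatches abort extension; published degenerate universal primers keep this tail concrete |
| `d_max` | 4 positions | degeneracy 2⁴ = 16 is a practical synthesis/mixture ceiling for a single primer |

Single-position lookahead is deliberate: variants needing simultaneous
widening at ≥ 2 positions cannot be attributed to any per-step printed
gain, and multi-position search grows exponentially; such variants go to
rescue design instead. On the packaged ITS86F table the greedy trace is
exactly three steps (gains 888, 253, 108 sites) ending at
GTGARTCATYGARTCTTTGAA, 92.3053%; the ITS4 seed starts above target and
takes zero steps — both traces are asserted in the test suite.

## Rescue primers

Leftover variants are single-linkage clustered under Hamming distance ≤
`radius` (default 2); clusters are taken largest-count-first up to
`max_primers`, and each emits the per-position union of its observed
bases as a minimal degenerate consensus, which covers its whole cluster
by construction. Primers are suffixed with their first three bases (the
-GCG / -CTG naming convention). This clustering is a principled stand-in:
how published rescue primers chose their 5′ trinucleotides is not
documented anywhere we could verify, so only the construction's
properties (full cluster coverage, disjointness from the refined primer's
coverage) are asserted, never specific rescue sequences.

## Melting temperatures

`tm_range` enumerates all expansions (cap 1024, stated in the error when
exceeded) and reports (min, max) °C rounded to whole degrees. Methods:
Wallace 2·(A+T)+4·(G+C) (default ≤ 24-mers), GC-fraction
64.9+41·(GC−16.4)/L, and unified nearest-neighbor thermodynamics via
Biopython at configurable primer/Na⁺ concentrations (default 250 nM /
50 mM). For Wallace, the range minimum provably equals the Tm of the
all-weak-base expansion — a closed-form check in the tests. Tm ranges are
informational: published ranges for these primers do not state their
formula and none of the implemented ones reproduces them exactly, so Tm
is never an acceptance surface of the audit.

## Synthetic collections

The generator plants site variants into i.i.d.-uniform random flanks at
*exact* largest-remainder quotas (deterministic truth counts; a
multinomial mode exists for stress tests), with optional no-site records,
reverse-complemented records, and flank substitution noise. Flanks are
regenerated until every non-planted window is ≥ `min_flank_distance`
(default 6 = default `max_mismatch`+1) substitutions from every variant,
so site location is unambiguous. Defaults: flank lengths uniform in
30–60 nt, noise 0, seed fixed in the spec; same spec ⇒ byte-identical
FASTA.

What it does *not* emulate: ITS sequence evolution (real flanks are
conserved 5.8S/28S rDNA, not uniform noise), indels inside binding sites,
chimeras, taxonomic structure, or length heterogeneity of real ITS
records. Green tests on synthetic data therefore validate the scanning,
tabulation and refinement machinery — not robustness to biological mess
or database curation artifacts.

## Degenerate inputs and numerical choices

- Record shorter than the primer: no site, logged, never an exception.
- Zero located sites: empty table with `total_sites = 0`, flagged;
  coverage over an empty table is reported as absent, not 0 or 100.
- Published variant tables are truncations (top five rows): their counts
  sum below the located-site totals, so any rate computed from them is a
  lower bound on the full-table rate. This is why the refined *reverse*
  primer's full-collection rate (94.8111%) is not reachable from packaged
  data — the packaged table caps it at 2076/2197 = 94.4925% — and why
  machine output always keeps full tables, truncating only the on-screen
  summary.
- Duplicate record ids are kept and counted independently, with a warning.
- Unreachable refinement targets return the best-effort primer with a
  flag rather than raising.

## Problem sizes

Tests and the acceptance script run on the packaged five-row tables
(exact, sub-second) plus synthetic collections of 10–1000 records; the
oracle-equivalence suite checks 200 random primer/table pairs at
degeneracy ≤ 4⁸ by full enumeration. A full database-scale audit
(~12k records) runs in well under a minute through the same code path
but is not needed to reproduce any packaged number.
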