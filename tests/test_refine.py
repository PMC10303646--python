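"""Coverage arithmetic, greedy degenerate refinement and rescue design."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from primeraudit.audit import VariantTable
from primeraudit.iupac import expansions
from primeraudit.refine import (
    RefineConfig,
    coverage,
    covers,
    design_rescue,
    refine_greedy,
)

SEED_86F = "GTGAATCATCGAATCTTTGAA"
CEP_86F = "GTGARTCATYGARTCTTTGAA"
SEED_4 = "TCCTCCGCTTATTGATATGC"


@pytest.mark.parametrize(
    "primer,variant,ok",
    [
        (CEP_86F, "GTGAGTCATCGAATCTTTGAA", True),   # R absorbs the G substitution
        (CEP_86F, "GTGAACCATCGAATCTTTGAA", False),  # C at a concrete T position
        ("N" * 21, "GTGAATCATCGAATCTTTGAA", True),
        (SEED_86F, SEED_86F, True),
    ],
)
def test_covers(primer, variant, ok):
    assert covers(primer, variant) is ok


def test_covers_rejects_length_mismatch():
    with pytest.raises(ValueError):
        covers("ACGT", "ACG")


def test_seed_coverage_equals_top_variant_proportion(its86f_table):
    cov = coverage(SEED_86F, its86f_table)
    assert (cov.covered_count, cov.rate_pct) == (7700, 79.4224)


def test_degenerate_coverage_sums_absorbed_variants(its86f_table):
    cov = coverage(CEP_86F, its86f_table)
    assert cov.covered_count == 7700 + 888 + 253 + 108 == 8949
    assert cov.rate_pct == 92.3053
    assert cov.uncovered.counts == {"GTGAACCATCGAATCTTTGAA": 96}


def test_self_table_gives_full_coverage():
    t = VariantTable.from_counts({"ACGTACGT": 3})
    assert coverage("ACGTACGT", t).rate_pct == 100.0


def test_empty_table_has_undefined_rate():
    t = VariantTable("x", [], 0)
    assert coverage("ACGT", t).rate_pct is None


def _oracle_coverage(primer, table):
    """Independent oracle: enumerate all concrete expansions, match by equality."""
    exp = set(expansions(primer))
    return sum(v.count for v in table if v.sequence in exp)


@given(st.integers(0, 2**31 - 1))
@settings(derandomize=True, max_examples=200, deadline=None)
def test_coverage_equals_full_expansion_enumeration(seed):
    rng = np.random.default_rng(seed)
    length = int(rng.integers(4, 9))
    symbols = list("ACGTRYSWKMN")
    primer = "".join(rng.choice(symbols, size=length, p=[0.19] * 4 + [0.24 / 7] * 7))
    variants = {
        "".join(rng.choice(list("ACGT"), size=length)): int(rng.integers(1, 50))
        for _ in range(int(rng.integers(1, 8)))
    }
    table = VariantTable.from_counts(variants)
    cov = coverage(primer, table)
    assert cov.covered_count == _oracle_coverage(primer, table)


def test_greedy_refinement_reproduces_published_degenerate_primer(its86f_table):
    result = refine_greedy(SEED_86F, its86f_table, RefineConfig())
    assert result.refined == CEP_86F
    assert [(s.position, s.before, s.after, s.gain) for s in result.steps] == [
        (12, "A", "R", 888),
        (4, "A", "R", 253),
        (9, "C", "Y", 108),
    ]
    assert result.final.rate_pct == 92.3053
    assert result.target_reached


def test_seed_already_above_target_takes_zero_steps(its4_table):
    result = refine_greedy(SEED_4, its4_table, RefineConfig())
    assert result.refined == SEED_4
    assert result.steps == ()
    assert result.final.rate_pct == 93.6732


def test_toy_refinement_matches_brute_force_trace():
    table = VariantTable.from_counts({"AACCGGTT": 70, "AACTGGTT": 20, "TACCGGTT": 10})
    result = refine_greedy(
        "AACCGGTT", table, RefineConfig(target_coverage_pct=95, protect_3prime=2)
    )
    assert result.refined == "WACYGGTT"
    assert [(s.position, s.before, s.after, s.gain) for s in result.steps] == [
        (3, "C", "Y", 20),
        (0, "A", "W", 10),
    ]
    assert result.final.rate_pct == 100.0


def test_three_prime_protection_blocks_terminal_widening():
    table = VariantTable.from_counts({"AACCGGTT": 70, "AACCGGTA": 30})
    result = refine_greedy(
        "AACCGGTT", table, RefineConfig(target_coverage_pct=99, protect_3prime=2)
    )
    assert result.refined == "AACCGGTT"  # the only useful position is protected
    assert not result.target_reached


def test_degenerate_position_budget_is_respected():
    table = VariantTable.from_counts(
        {"AAAAAAAA": 40, "TAAAAAAA": 30, "ATAAAAAA": 20, "AATAAAAA": 10}
    )
    cfg = RefineConfig(target_coverage_pct=100, d_max=2, protect_3prime=0)
    result = refine_greedy("AAAAAAAA", table, cfg)
    assert result.refined == "WWAAAAAA"
    assert not result.target_reached


def test_widening_is_monotone_and_gains_are_positive(its86f_table):
    result = refine_greedy(SEED_86F, its86f_table, RefineConfig(target_coverage_pct=100))
    seen = coverage(result.seed, its86f_table).covered_count
    primer = result.seed
    for step in result.steps:
        assert step.gain > 0
        primer = primer[: step.position] + step.after + primer[step.position + 1 :]
        c = coverage(primer, its86f_table).covered_count
        assert c == seen + step.gain
        seen = c
    # widening never loses a variant covered by the seed
    for v in its86f_table:
        if covers(result.seed, v.sequence):
            assert covers(result.refined, v.sequence)


def test_refinement_is_deterministic(its86f_table):
    a = refine_greedy(SEED_86F, its86f_table)
    b = refine_greedy(SEED_86F, its86f_table)
    assert a == b


def test_rescue_merges_close_variants_into_degenerate_consensus():
    uncovered = VariantTable.from_counts(
        {"GCGAATCATCGAATCTTTGAA": 50, "GCGAGTCATCGAATCTTTGAA": 43}
    )
    primers = design_rescue(uncovered, max_primers=2, radius=2)
    assert len(primers) == 1
    assert primers[0].sequence == "GCGARTCATCGAATCTTTGAA"
    assert primers[0].name_suffix == "GCG"
    for v in uncovered:
        assert covers(primers[0].sequence, v.sequence)


def test_rescue_keeps_distant_clusters_apart():
    a = "AAAAAAAACCCCCCCC"
    b = "TTTTTTTTGGGGGGGG"  # Hamming 16 from a
    uncovered = VariantTable.from_counts({a: 30, b: 20})
    primers = design_rescue(uncovered, max_primers=2, radius=2)
    assert [p.sequence for p in primers] == [a, b]  # largest cluster first


def test_rescue_on_empty_table_is_empty():
    assert design_rescue(VariantTable("x", [], 0)) == []


def test_rescue_plus_refined_cover_disjoint_counts(its86f_table):
    result = refine_greedy(SEED_86F, its86f_table)
    rescues = design_rescue(result.final.uncovered, max_primers=2)
    rescued = sum(v.count for p in rescues for v in p.cluster)
    assert result.final.covered_count + rescued == sum(v.count for v in its86f_table)
    for p in rescues:
        for v in p.cluster:
            assert not covers(result.refined, v.sequence)
            assert covers(p.sequence, v.sequence)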