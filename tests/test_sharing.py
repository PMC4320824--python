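from itertools import combinations

import numpy as np
import pytest

from varcohort.sharing import classify_sharing, line_specific_variants
from varcohort.variant_model import VariantCall, build_multiline_table


def _call(line, pos):
    return VariantCall.make(line, "chr1", pos, "A", "G")


def _random_cohort(rng, n_lines=5, max_sites=50):
    """Random toy cohort: each line carries each site independently."""
    lines = [f"L{i}" for i in range(n_lines)]
    n_sites = int(rng.integers(1, max_sites + 1))
    p = rng.uniform(0.1, 0.9)
    per_line = {line: [] for line in lines}
    for s in range(n_sites):
        carriers = [line for line in lines if rng.random() < p]
        for line in carriers:
            per_line[line].append(_call(line, 10 * (s + 1)))
    return [(line, per_line[line]) for line in lines]


def _brute_force_pattern_counts(callsets):
    """Independent oracle: enumerate all 2^n - 1 patterns and count the
    sites whose carrier set equals each pattern, from the raw call sets."""
    lines = [line for line, _ in callsets]
    membership = {line: {c.key for c in calls} for line, calls in callsets}
    union = set().union(*membership.values()) if callsets else set()
    counts = {}
    for r in range(1, len(lines) + 1):
        for chosen in combinations(range(len(lines)), r):
            pattern = tuple(i in chosen for i in range(len(lines)))
            n = sum(
                1
                for key in union
                if all(
                    (key in membership[line]) == pattern[i]
                    for i, line in enumerate(lines)
                )
            )
            if n:
                counts[pattern] = n
    return counts


def test_full_and_singleton_patterns():
    lines = ["A", "B", "C"]
    common = {line: [_call(line, 10)] for line in lines}
    common["A"].append(_call("A", 20))
    table = build_multiline_table([(l, common[l]) for l in lines])
    profile = classify_sharing(table)
    assert profile.pattern_counts[(True, True, True)] == 1
    assert profile.pattern_counts[(True, False, False)] == 1
    assert profile.common_count == 1
    assert profile.line_specific_counts() == {"A": 1, "B": 0, "C": 0}


def test_pattern_counts_match_bruteforce_on_random_toys():
    rng = np.random.default_rng(11)
    for _ in range(25):
        callsets = _random_cohort(rng)
        table = build_multiline_table(callsets)
        profile = classify_sharing(table)
        assert profile.pattern_counts == _brute_force_pattern_counts(callsets)
        assert profile.n_sites == table.n_sites


def test_partition_of_total_sites():
    rng = np.random.default_rng(3)
    callsets = _random_cohort(rng)
    table = build_multiline_table(callsets)
    profile = classify_sharing(table)
    private_total = sum(profile.line_specific_counts().values())
    multi = sum(
        c for p, c in profile.pattern_counts.items() if sum(p) > 1
    )
    assert private_total + multi == table.n_sites


def test_renaming_lines_preserves_count_multiset():
    rng = np.random.default_rng(5)
    callsets = _random_cohort(rng)
    table = build_multiline_table(callsets)
    renamed = build_multiline_table(
        [
            (
                line + "x",
                [
                    VariantCall.make(line + "x", c.chrom, c.pos, c.ref, c.alt)
                    for c in calls
                ],
            )
            for line, calls in reversed(callsets)
        ]
    )
    a = sorted(classify_sharing(table).pattern_counts.values())
    b = sorted(classify_sharing(renamed).pattern_counts.values())
    assert a == b


def test_line_specific_extraction_and_type_tally():
    calls_a = [
        VariantCall.make("A", "chr1", 10, "A", "G"),
        VariantCall.make("A", "chr1", 20, "A", "AT"),
        VariantCall.make("A", "chr1", 30, "AT", "A"),
        VariantCall.make("A", "chr1", 40, "C", "T"),
    ]
    calls_b = [VariantCall.make("B", "chr1", 40, "C", "T")]
    table = build_multiline_table([("A", calls_a), ("B", calls_b)])
    ls = line_specific_variants(table, "A")
    assert ls.n_total == 3
    assert (ls.n_ins, ls.n_del, ls.n_snp) == (1, 1, 1)
    assert ls.n_ins + ls.n_del + ls.n_snp == ls.n_total
    with pytest.raises(KeyError):
        line_specific_variants(table, "Z")


def test_single_line_cohort_everything_is_private():
    calls = [_call("A", p) for p in (10, 20, 30)]
    table = build_multiline_table([("A", calls)])
    assert line_specific_variants(table, "A").n_total == 3
    profile = classify_sharing(table)
    assert profile.pattern_counts == {(True,): 3}
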