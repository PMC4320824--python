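import pytest

from varcohort.filtration import (
    FilterConfig,
    apply_all_filters,
    filter_excessive_depth,
    filter_min_coverage_all_lines,
    filter_quality,
    filter_type_consistency,
)
from varcohort.genome_io import GenomeIndex, build_coverage_track
from varcohort.variant_model import VariantCall, build_multiline_table

GENOME = GenomeIndex(chromosomes=(("chr1", 10_000),))


def _call(line, pos, ref="A", alt="G", qual=60.0, depth=30):
    return VariantCall.make(line, "chr1", pos, ref, alt, qual, depth)


def _track(line, depth=50, overrides=()):
    rows, cur = [], 0
    for start, end, d in sorted(overrides):
        if start > cur:
            rows.append(("chr1", cur, start, depth))
        rows.append(("chr1", start, end, d))
        cur = end
    rows.append(("chr1", cur, 10_000, depth))
    return build_coverage_track(line, rows, GENOME)


def test_excessive_depth_boundary_is_strict():
    keep = _call("A", 10, depth=10_000)
    drop = _call("A", 20, depth=10_001)
    kept, removed = filter_excessive_depth([keep, drop], FilterConfig())
    assert kept == [keep] and removed == 1
    assert filter_excessive_depth([], FilterConfig()) == ([], 0)


def test_quality_threshold_is_inclusive():
    table = build_multiline_table(
        [("A", [_call("A", 10, qual=30.0), _call("A", 20, qual=29.99)])]
    )
    out = filter_quality(table, FilterConfig())
    assert [k.pos for k in out.sites] == [10]


def test_coverage_applies_to_non_carrier_lines():
    # B does not carry the variant but has depth 3 there: site dropped
    table = build_multiline_table([("A", [_call("A", 100)]), ("B", [])])
    tracks = {"A": _track("A"), "B": _track("B", overrides=[(99, 100, 3)])}
    out = filter_min_coverage_all_lines(table, tracks, FilterConfig())
    assert out.n_sites == 0
    # with depth 4 at the position the site survives (inclusive threshold)
    tracks["B"] = _track("B", overrides=[(99, 100, 4)])
    out = filter_min_coverage_all_lines(table, tracks, FilterConfig())
    assert out.n_sites == 1


def test_deletion_span_tests_every_deleted_base():
    table = build_multiline_table(
        [("A", [_call("A", 100, ref="ATTT", alt="A")]), ("B", [])]
    )
    # low coverage at the last deleted base (pos 103) in the carrier itself
    tracks = {"A": _track("A", overrides=[(102, 103, 2)]), "B": _track("B")}
    full = filter_min_coverage_all_lines(table, tracks, FilterConfig())
    assert full.n_sites == 0
    anchor_only = filter_min_coverage_all_lines(
        table, tracks, FilterConfig(deletion_span="anchor")
    )
    assert anchor_only.n_sites == 1


def test_missing_track_is_a_configuration_error():
    table = build_multiline_table([("A", [_call("A", 100)]), ("B", [])])
    with pytest.raises(ValueError, match="B"):
        filter_min_coverage_all_lines(table, {"A": _track("A")}, FilterConfig())


class TestTypeConsistency:
    def test_snp_vs_insertion_at_one_position_excluded(self):
        table = build_multiline_table(
            [
                ("A", [_call("A", 500, "A", "G")]),
                ("B", [_call("B", 500, "A", "AT")]),
            ]
        )
        out, excluded = filter_type_consistency(table)
        assert out.n_sites == 0
        assert excluded == [("chr1", 500)]

    def test_two_snps_with_different_alts_both_retained(self):
        table = build_multiline_table(
            [
                ("A", [_call("A", 500, "A", "G")]),
                ("B", [_call("B", 500, "A", "T")]),
            ]
        )
        out, excluded = filter_type_consistency(table)
        assert out.n_sites == 2 and excluded == []

    def test_single_line_position_always_retained(self):
        table = build_multiline_table([("A", [_call("A", 500, "A", "AT")])])
        out, excluded = filter_type_consistency(table)
        assert out.n_sites == 1 and excluded == []


def test_all_pass_cohort_is_unchanged_and_filters_idempotent():
    table = build_multiline_table(
        [
            ("A", [_call("A", 100), _call("A", 200, "A", "AT")]),
            ("B", [_call("B", 100)]),
        ]
    )
    tracks = {"A": _track("A"), "B": _track("B")}
    once, report = apply_all_filters(table, tracks)
    assert once.sites.keys() == table.sites.keys()
    twice, report2 = apply_all_filters(once, tracks)
    assert twice.sites.keys() == once.sites.keys()
    assert report2.n_calls_removed_low_quality == 0
    assert report2.n_sites_removed_low_coverage == 0


def test_surviving_set_shrinks_as_thresholds_tighten(cohort, pipeline_result):
    from varcohort.genome_io import read_coverage

    table = pipeline_result.table
    tracks = {
        line: read_coverage(path, cohort.genome, line)
        for line, path in cohort.coverage_paths.items()
    }
    # monotonicity holds for the per-call and coverage criteria; the
    # cross-line consistency filter can rescue a position when a stricter
    # threshold removes its conflict partner, so it is held fixed here
    base, _ = apply_all_filters(
        table, tracks, FilterConfig(require_type_consistency=False)
    )
    stricter, _ = apply_all_filters(
        table,
        tracks,
        FilterConfig(
            min_quality=60.0,
            min_reads_all_lines=10,
            require_type_consistency=False,
        ),
    )
    assert set(stricter.sites) < set(base.sites)
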