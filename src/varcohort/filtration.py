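"""Variant exclusion and the three-criterion multi-line filtration.

Order of application is fixed: excessive-depth exclusion, then the
per-call quality criterion, then the all-lines minimum-coverage
criterion, then the cross-line type-consistency criterion. Only the last
is sensitive to its position after the per-call filters (a call removed
for low quality cannot create a type conflict).

Boundary readings: depth strictly greater than the maximum is excluded;
quality and coverage thresholds are inclusive ("at least").
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .genome_io import CoverageTrack
from .variant_model import MultiLineTable, SiteKey, VariantCall, VarType

__all__ = [
    "FilterConfig",
    "FilterReport",
    "filter_excessive_depth",
    "filter_quality",
    "filter_min_coverage_all_lines",
    "filter_type_consistency",
    "apply_all_filters",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the variant filters.

    ``min_quality`` is a phred-scaled score: the default 30 bounds the
    per-call false-positive probability at 0.001. ``min_reads_all_lines``
    must be met at the variant position in every line of the cohort,
    carriers and non-carriers alike. ``deletion_span`` selects whether the
    coverage criterion tests every deleted base ("full", default) or only
    the anchored position ("anchor").
    """

    min_quality: float = 30.0
    min_reads_all_lines: int = 4
    max_site_depth: int = 10_000
    require_type_consistency: bool = True
    deletion_span: str = "full"

    def __post_init__(self) -> None:
        if self.min_quality < 0:
            raise ValueError("min_quality must be >= 0")
        if self.min_reads_all_lines < 1:
            raise ValueError("min_reads_all_lines must be >= 1")
        if self.max_site_depth <= self.min_reads_all_lines:
            raise ValueError("max_site_depth must exceed min_reads_all_lines")
        if self.deletion_span not in ("full", "anchor"):
            raise ValueError("deletion_span must be 'full' or 'anchor'")


@dataclass
class FilterReport:
    """Per-filter removal counts; a scientific output in its own right."""

    n_input_sites: int = 0
    n_calls_removed_over_depth: int = 0
    n_calls_removed_low_quality: int = 0
    n_sites_removed_low_coverage: int = 0
    n_positions_removed_type_conflict: int = 0
    n_sites_removed_type_conflict: int = 0
    n_output_sites: int = 0
    excluded_positions: list[tuple[str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input_sites": self.n_input_sites,
            "n_calls_removed_over_depth": self.n_calls_removed_over_depth,
            "n_calls_removed_low_quality": self.n_calls_removed_low_quality,
            "n_sites_removed_low_coverage": self.n_sites_removed_low_coverage,
            "n_positions_removed_type_conflict":
                self.n_positions_removed_type_conflict,
            "n_sites_removed_type_conflict": self.n_sites_removed_type_conflict,
            "n_output_sites": self.n_output_sites,
        }


def filter_excessive_depth(
    calls: Iterable[VariantCall], cfg: FilterConfig
) -> tuple[list[VariantCall], int]:
    """Remove calls covered by an excessive number of reads (strict >)."""
    kept, removed = [], 0
    for call in calls:
        if call.site_depth > cfg.max_site_depth:
            removed += 1
        else:
            kept.append(call)
    return kept, removed


def _drop_calls(
    table: MultiLineTable, predicate
) -> tuple[MultiLineTable, int]:
    """Remove calls matching ``predicate``; drop sites left carrier-less."""
    sites: dict[SiteKey, dict[str, VariantCall]] = {}
    removed = 0
    for key, carriers in table.sites.items():
        keep = {}
        for line, call in carriers.items():
            if predicate(call):
                removed += 1
            else:
                keep[line] = call
        if keep:
            sites[key] = keep
    return MultiLineTable(line_ids=table.line_ids, sites=sites), removed


def _table_excessive_depth(
    table: MultiLineTable, cfg: FilterConfig
) -> tuple[MultiLineTable, int]:
    return _drop_calls(table, lambda c: c.site_depth > cfg.max_site_depth)


def filter_quality(
    table: MultiLineTable, cfg: FilterConfig
) -> MultiLineTable:
    """Criterion 1: per-line calls below ``min_quality`` are removed."""
    out, _ = _drop_calls(table, lambda c: c.quality < cfg.min_quality)
    return out


def _coverage_span(key: SiteKey, cfg: FilterConfig) -> tuple[int, int]:
    if len(key.ref) > len(key.alt) and cfg.deletion_span == "full":
        # anchored deletion: anchor base plus every deleted base
        return key.pos, key.pos + len(key.ref) - 1
    return key.pos, key.pos


def filter_min_coverage_all_lines(
    table: MultiLineTable,
    tracks: Mapping[str, CoverageTrack],
    cfg: FilterConfig,
) -> MultiLineTable:
    """Criterion 2: the position must be covered by at least
    ``min_reads_all_lines`` reads in EVERY line, regardless of whether
    the variant is present there."""
    missing = [line for line in table.line_ids if line not in tracks]
    if missing:
        raise ValueError(f"no coverage track for line(s) {missing}")
    sites = {}
    for key, carriers in table.sites.items():
        start, end = _coverage_span(key, cfg)
        if all(
            tracks[line].min_depth(key.chrom, start, end)
            >= cfg.min_reads_all_lines
            for line in table.line_ids
        ):
            sites[key] = dict(carriers)
    return MultiLineTable(line_ids=table.line_ids, sites=sites)


def filter_type_consistency(
    table: MultiLineTable,
) -> tuple[MultiLineTable, list[tuple[str, int]]]:
    """Criterion 3: positions carrying different alteration types in
    different lines are removed entirely.

    Two SNPs with different ALT alleles at one position are the same
    alteration type and are retained (as two distinct, unshared sites).
    """
    types_at: dict[tuple[str, int], set[VarType]] = {}
    for key, carriers in table.sites.items():
        at = types_at.setdefault((key.chrom, key.pos), set())
        for call in carriers.values():
            at.add(call.var_type)
    conflicted = {pos for pos, types in types_at.items() if len(types) > 1}
    sites = {
        key: dict(carriers)
        for key, carriers in table.sites.items()
        if (key.chrom, key.pos) not in conflicted
    }
    return (
        MultiLineTable(line_ids=table.line_ids, sites=sites),
        sorted(conflicted),
    )


def apply_all_filters(
    table: MultiLineTable,
    tracks: Mapping[str, CoverageTrack],
    cfg: FilterConfig | None = None,
) -> tuple[MultiLineTable, FilterReport]:
    """Apply the exclusion and all three criteria in the fixed order."""
    cfg = cfg or FilterConfig()
    report = FilterReport(n_input_sites=table.n_sites)

    table, n_depth = _table_excessive_depth(table, cfg)
    report.n_calls_removed_over_depth = n_depth

    before = sum(table.per_line_counts().values())
    table = filter_quality(table, cfg)
    report.n_calls_removed_low_quality = before - sum(
        table.per_line_counts().values()
    )

    before_sites = table.n_sites
    table = filter_min_coverage_all_lines(table, tracks, cfg)
    report.n_sites_removed_low_coverage = before_sites - table.n_sites

    if cfg.require_type_consistency:
        before_sites = table.n_sites
        table, excluded = filter_type_consistency(table)
        report.excluded_positions = excluded
        report.n_positions_removed_type_conflict = len(excluded)
        report.n_sites_removed_type_conflict = before_sites - table.n_sites

    report.n_output_sites = table.n_sites
    return table, report
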