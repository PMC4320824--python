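"""Variant-sharing profiles and line-specific variant extraction.

A variant is "shared" between lines only when the full allele tuple
(chrom, pos, ref, alt) is identical — same position, same alteration.
Cross-type conflicts at one position were already removed by the
type-consistency filter; two different ALT alleles at one position remain
two distinct, unshared sites. A line-specific variant is one present in
exactly one line of the cohort.
"""
from __future__ import annotations

from dataclasses import dataclass

from .variant_model import MultiLineTable, VariantCall, VarType

__all__ = [
    "SharingProfile",
    "LineSpecificSet",
    "classify_sharing",
    "line_specific_variants",
]


@dataclass
class SharingProfile:
    """Counts of variant sites per presence pattern.

    A pattern is a boolean tuple over ``line_ids`` (in cohort order,
    e.g. transgenic lines first); every site belongs to exactly one of
    the 2^n - 1 non-empty patterns.
    """

    line_ids: tuple[str, ...]
    pattern_counts: dict[tuple[bool, ...], int]

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_sites(self) -> int:
        return sum(self.pattern_counts.values())

    @property
    def common_count(self) -> int:
        """Sites present in all lines."""
        return self.pattern_counts.get((True,) * self.n_lines, 0)

    def count_by_n_lines(self) -> dict[int, int]:
        """Sites grouped by how many lines carry them (1..n)."""
        out = {k: 0 for k in range(1, self.n_lines + 1)}
        for pattern, count in self.pattern_counts.items():
            out[sum(pattern)] += count
        return out

    def line_specific_counts(self) -> dict[str, int]:
        """Per line, the number of sites carried by that line alone."""
        out = {line: 0 for line in self.line_ids}
        for pattern, count in self.pattern_counts.items():
            if sum(pattern) == 1:
                out[self.line_ids[pattern.index(True)]] += count
        return out


def classify_sharing(table: MultiLineTable) -> SharingProfile:
    """Assign every site of a filtered table to its presence pattern."""
    counts: dict[tuple[bool, ...], int] = {}
    for _, carriers in table.iter_sites():
        pattern = tuple(line in carriers for line in table.line_ids)
        counts[pattern] = counts.get(pattern, 0) + 1
    return SharingProfile(line_ids=table.line_ids, pattern_counts=counts)


@dataclass
class LineSpecificSet:
    """Variants private to one line, tallied by alteration type."""

    line_id: str
    variants: list[VariantCall]
    n_ins: int
    n_del: int
    n_snp: int

    @property
    def n_total(self) -> int:
        return len(self.variants)


def line_specific_variants(
    table: MultiLineTable, line_id: str
) -> LineSpecificSet:
    """Variants present in ``line_id`` and absent from every other line."""
    if line_id not in table.line_ids:
        raise KeyError(f"unknown line {line_id!r}")
    variants = [
        carriers[line_id]
        for _, carriers in table.iter_sites()
        if len(carriers) == 1 and line_id in carriers
    ]
    tally = {VarType.INS: 0, VarType.DEL: 0, VarType.SNP: 0}
    for v in variants:
        tally[v.var_type] += 1
    return LineSpecificSet(
        line_id=line_id,
        variants=variants,
        n_ins=tally[VarType.INS],
        n_del=tally[VarType.DEL],
        n_snp=tally[VarType.SNP],
    )
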