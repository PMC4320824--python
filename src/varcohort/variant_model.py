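"""Variant domain types and the multi-line union table.

Every downstream statistic (filtering, sharing profiles, spectra, windowed
densities, effect rollups) consumes either a list of :class:`VariantCall`
or a :class:`MultiLineTable`, the union of variant sites across all lines
keyed by the full allele tuple ``(chrom, pos, ref, alt)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, NamedTuple

__all__ = [
    "VarType",
    "ComplexVariantError",
    "classify_variant_type",
    "SiteKey",
    "VariantCall",
    "MultiLineTable",
    "build_multiline_table",
]

_DNA = frozenset("ACGT")


class VarType(str, Enum):
    """Coarse alteration type of a called variant."""

    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"


class ComplexVariantError(ValueError):
    """Raised for alleles that are neither a SNP nor an anchored indel.

    Multi-nucleotide substitutions (``len(ref) == len(alt) > 1``) fall
    outside the SNP / insertion / deletion trichotomy produced by a
    short-read caller; they are counted and excluded rather than forced
    into a type.
    """


def _check_dna(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"{what} allele is empty")
    if not _DNA.issuperset(seq):
        raise ValueError(f"{what} allele {seq!r} contains non-ACGT characters")


def classify_variant_type(ref: str, alt: str) -> VarType:
    """Classify an allele pair by the length rule.

    SNP iff both alleles are single bases; insertion iff ``alt`` is longer
    than ``ref``; deletion iff ``ref`` is longer. Equal-length alleles of
    length > 1 are complex substitutions and raise
    :class:`ComplexVariantError`. ``ref == alt`` is a non-variant and
    raises ``ValueError``.
    """
    _check_dna(ref, "ref")
    _check_dna(alt, "alt")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r}): not a variant")
    if len(ref) == len(alt):
        if len(ref) == 1:
            return VarType.SNP
        raise ComplexVariantError(
            f"complex substitution {ref!r}->{alt!r} (equal length > 1)"
        )
    return VarType.INS if len(alt) > len(ref) else VarType.DEL


class SiteKey(NamedTuple):
    """Identity of a variant site: same position AND same alteration."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


@dataclass(frozen=True)
class VariantCall:
    """One normalized called variant in one line.

    Positions are 1-based; indels are VCF-anchored (ref and alt share the
    first base). ``var_type`` is derived from the alleles, never trusted
    from annotation fields.
    """

    line_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    var_type: VarType
    quality: float
    site_depth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        if self.quality < 0:
            raise ValueError(f"quality must be >= 0, got {self.quality}")
        if self.site_depth < 0:
            raise ValueError(f"site_depth must be >= 0, got {self.site_depth}")
        expected = classify_variant_type(self.ref, self.alt)
        if expected is not self.var_type:
            raise ValueError(
                f"var_type {self.var_type} inconsistent with alleles "
                f"{self.ref!r}->{self.alt!r} (expected {expected})"
            )

    @property
    def key(self) -> SiteKey:
        return SiteKey(self.chrom, self.pos, self.ref, self.alt)

    @classmethod
    def make(
        cls,
        line_id: str,
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        quality: float = 60.0,
        site_depth: int = 30,
    ) -> "VariantCall":
        """Convenience constructor deriving ``var_type`` from the alleles."""
        return cls(
            line_id=line_id,
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            var_type=classify_variant_type(ref, alt),
            quality=quality,
            site_depth=site_depth,
        )


@dataclass
class MultiLineTable:
    """Union of variant sites across lines with per-line presence.

    ``sites`` maps each :class:`SiteKey` to a ``{line_id: VariantCall}``
    presence map. Iteration order is canonical (sorted by key), so two
    tables built from the same call sets in any line order compare equal.
    """

    line_ids: tuple[str, ...]
    sites: dict[SiteKey, dict[str, VariantCall]] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def iter_sites(self) -> Iterator[tuple[SiteKey, dict[str, VariantCall]]]:
        for key in sorted(self.sites):
            yield key, self.sites[key]

    def calls_for_line(self, line_id: str) -> list[VariantCall]:
        if line_id not in self.line_ids:
            raise KeyError(f"unknown line {line_id!r}")
        return [
            carriers[line_id]
            for _, carriers in self.iter_sites()
            if line_id in carriers
        ]

    def per_line_counts(self) -> dict[str, int]:
        counts = {line: 0 for line in self.line_ids}
        for carriers in self.sites.values():
            for line in carriers:
                counts[line] += 1
        return counts

    def subset(self, keys: Iterable[SiteKey]) -> "MultiLineTable":
        keep = set(keys)
        return MultiLineTable(
            line_ids=self.line_ids,
            sites={k: dict(v) for k, v in self.sites.items() if k in keep},
        )

    def validate(self) -> None:
        for key, carriers in self.sites.items():
            if not carriers:
                raise ValueError(f"site {key} has no carriers")
            for line, call in carriers.items():
                if call.key != key:
                    raise ValueError(f"call {call} stored under wrong key {key}")
                if line != call.line_id or line not in self.line_ids:
                    raise ValueError(f"call {call} stored under wrong line {line}")


def build_multiline_table(
    callsets: Iterable[tuple[str, Iterable[VariantCall]]],
) -> MultiLineTable:
    """List all variants from all lines according to genomic position.

    Parameters
    ----------
    callsets:
        ``(line_id, calls)`` pairs, one per line. Line ids must be unique
        and each call's ``line_id`` must match its call set.

    Raises
    ------
    ValueError
        on duplicate line ids or a duplicated ``(line, chrom, pos, ref,
        alt)`` record (malformed input).
    """
    line_ids: list[str] = []
    sites: dict[SiteKey, dict[str, VariantCall]] = {}
    for line_id, calls in callsets:
        if line_id in line_ids:
            raise ValueError(f"duplicate line id {line_id!r}")
        line_ids.append(line_id)
        for call in calls:
            if call.line_id != line_id:
                raise ValueError(
                    f"call for line {call.line_id!r} listed under {line_id!r}"
                )
            carriers = sites.setdefault(call.key, {})
            if line_id in carriers:
                raise ValueError(
                    f"duplicate call for line {line_id!r} at {call.key}"
                )
            carriers[line_id] = call
    # canonical site order regardless of input order
    ordered = {k: sites[k] for k in sorted(sites)}
    return MultiLineTable(line_ids=tuple(line_ids), sites=ordered)
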