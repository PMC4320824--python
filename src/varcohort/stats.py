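"""Mutation rates, substitution spectra, Ts/Tv ratios and alignment stats.

The per-line mutation rate here is a per-site divergence measure: the
number of line-specific variants divided by the line's covered genome
length (bases with at least one mapped read). It is not a per-generation
rate. Transitions are the within-purine and within-pyrimidine
substitutions (A<->G, C<->T); the other eight directed changes are
transversions.

Display conventions (full precision is always retained in returned
values): rates at 3 significant digits in scientific notation,
percentages at 1 decimal, ratios at 2 decimals.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_io import AlignmentSummary, GenomeIndex
from .variant_model import VariantCall, VarType

__all__ = [
    "SUBSTITUTIONS",
    "TRANSITIONS",
    "SubstitutionSpectrum",
    "RateResult",
    "AlignmentStats",
    "classify_substitution",
    "spectrum",
    "pool_spectra",
    "ts_tv_ratio",
    "mutation_rate",
    "alignment_summary_stats",
    "round_sig",
]

_BASES = ("A", "C", "G", "T")
#: the 12 directed single-base substitutions, in a fixed display order
SUBSTITUTIONS: tuple[tuple[str, str], ...] = tuple(
    (r, a) for r in _BASES for a in _BASES if r != a
)
#: purine<->purine and pyrimidine<->pyrimidine changes
TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


def classify_substitution(ref: str, alt: str) -> tuple[str, tuple[str, str]]:
    """Classify a single-base substitution.

    Returns ``("transition" | "transversion", (ref, alt))``.
    """
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"non-ACGT base in substitution {ref!r}->{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical: not a substitution")
    kind = "transition" if (ref, alt) in TRANSITIONS else "transversion"
    return kind, (ref, alt)


@dataclass
class SubstitutionSpectrum:
    """Counts of the 12 directed substitutions plus Ts/Tv totals."""

    counts: dict[tuple[str, str], int]
    n_skipped_non_snp: int = 0

    def __post_init__(self) -> None:
        full = {sub: 0 for sub in SUBSTITUTIONS}
        for sub, n in self.counts.items():
            if sub not in full:
                raise ValueError(f"unknown substitution {sub}")
            if n < 0:
                raise ValueError(f"negative count for {sub}")
            full[sub] = int(n)
        self.counts = full

    @property
    def ts_count(self) -> int:
        return sum(self.counts[sub] for sub in SUBSTITUTIONS if sub in TRANSITIONS)

    @property
    def tv_count(self) -> int:
        return sum(
            self.counts[sub] for sub in SUBSTITUTIONS if sub not in TRANSITIONS
        )

    @property
    def total(self) -> int:
        return self.ts_count + self.tv_count


def spectrum(variants: Iterable[VariantCall]) -> SubstitutionSpectrum:
    """12-bin substitution spectrum of the SNPs in ``variants``.

    Non-SNP calls are ignored and counted in ``n_skipped_non_snp``.
    """
    counts = {sub: 0 for sub in SUBSTITUTIONS}
    skipped = 0
    for v in variants:
        if v.var_type is not VarType.SNP:
            skipped += 1
            continue
        counts[(v.ref, v.alt)] += 1
    return SubstitutionSpectrum(counts=counts, n_skipped_non_snp=skipped)


def pool_spectra(spectra: Iterable[SubstitutionSpectrum]) -> SubstitutionSpectrum:
    """Element-wise sum of spectra (group pooling)."""
    counts = {sub: 0 for sub in SUBSTITUTIONS}
    skipped = 0
    for s in spectra:
        for sub in SUBSTITUTIONS:
            counts[sub] += s.counts[sub]
        skipped += s.n_skipped_non_snp
    return SubstitutionSpectrum(counts=counts, n_skipped_non_snp=skipped)


def ts_tv_ratio(spec: SubstitutionSpectrum) -> float | None:
    """Transition/transversion ratio; ``None`` (undefined) when Tv = 0."""
    if spec.tv_count == 0:
        return None
    return spec.ts_count / spec.tv_count


@dataclass(frozen=True)
class RateResult:
    """A line's mutation-rate computation, at full precision."""

    line_id: str
    n_line_specific: int
    covered_length: int
    rate: float


def mutation_rate(n_line_specific: int, covered_length: int) -> float:
    """Line-specific variant count divided by covered genome length."""
    if covered_length <= 0:
        raise ValueError("covered_length must be positive")
    if n_line_specific < 0:
        raise ValueError("n_line_specific must be >= 0")
    return n_line_specific / covered_length


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant digits (display convention)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{digits - 1}e}")


@dataclass(frozen=True)
class AlignmentStats:
    """Mapping rate, coverage rate and depth for one line (full precision).

    mapping_rate = mapped / total reads x 100; coverage_rate =
    covered_length / genome length x 100; depth = mapped_reads x
    read_length / covered_length.
    """

    line_id: str
    mapping_rate: float
    coverage_rate: float
    depth: float


def alignment_summary_stats(
    s: AlignmentSummary, genome: GenomeIndex
) -> AlignmentStats:
    if s.total_reads == 0 or s.covered_length == 0 or genome.total_length == 0:
        raise ValueError("zero denominator in alignment summary statistics")
    return AlignmentStats(
        line_id=s.line_id,
        mapping_rate=s.mapped_reads / s.total_reads * 100.0,
        coverage_rate=s.covered_length / genome.total_length * 100.0,
        depth=s.mapped_reads * s.read_length / s.covered_length,
    )
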