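"""Readers and writers for the external formats the pipeline touches.

VCF (via pysam), bedgraph coverage tracks, FAI-dialect genome indexes and
TSV reports are normalized here into the domain types; no other module
parses a file format. VCF positions are 1-based, bedgraph intervals are
0-based half-open; every internal position is stored 1-based and the
conversion happens only at this boundary.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

from .variant_model import (
    ComplexVariantError,
    VariantCall,
    classify_variant_type,
)

__all__ = [
    "FormatError",
    "GenomeIndex",
    "CoverageTrack",
    "AlignmentSummary",
    "read_genome_index",
    "write_genome_index",
    "read_coverage",
    "write_coverage",
    "read_vcf",
    "read_vcf_result",
    "write_vcf",
    "VcfReadResult",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """An input file violates its format contract."""


@dataclass(frozen=True)
class GenomeIndex:
    """Chromosome catalog: the coordinate authority for every module.

    ``chromosomes`` preserves file order; ``centromere_mid`` optionally
    maps chromosome name to the centromere midpoint (1-based bp).
    """

    chromosomes: tuple[tuple[str, int], ...]
    centromere_mid: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise FormatError("duplicate chromosome names in genome index")
        for name, length in self.chromosomes:
            if length <= 0:
                raise FormatError(f"non-positive length for {name!r}: {length}")
        if self.centromere_mid:
            lengths = dict(self.chromosomes)
            for name, mid in self.centromere_mid.items():
                if name not in lengths:
                    raise FormatError(f"centromere for unknown chromosome {name!r}")
                if not 1 <= mid <= lengths[name]:
                    raise FormatError(
                        f"centromere position {mid} outside [1, {lengths[name]}] "
                        f"on {name!r}"
                    )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None


def read_genome_index(
    path: str | Path,
    centromere_path: str | Path | None = None,
    aliases: Mapping[str, str] | None = None,
) -> GenomeIndex:
    """Read a tab-separated name/length table (FAI dialect accepted).

    Only the first two columns are used; extra FAI columns are ignored.
    ``centromere_path`` optionally names a two-column (chromosome,
    midpoint) TSV. ``aliases`` maps file names to canonical names
    (exact-string; no fuzzy matching).
    """
    table = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if table.shape[1] < 2:
        raise FormatError(f"{path}: need at least 2 tab-separated columns")
    chromosomes = []
    for _, row in table.iterrows():
        name = str(row[0])
        if aliases:
            name = aliases.get(name, name)
        try:
            length = int(row[1])
        except ValueError:
            raise FormatError(f"{path}: non-integer length {row[1]!r} for {name!r}")
        chromosomes.append((name, length))
    centromeres = None
    if centromere_path is not None:
        cen = pd.read_csv(centromere_path, sep="\t", header=None, comment="#")
        centromeres = {
            str(row[0]) if not aliases else aliases.get(str(row[0]), str(row[0])):
            int(row[1])
            for _, row in cen.iterrows()
        }
    return GenomeIndex(chromosomes=tuple(chromosomes), centromere_mid=centromeres)


def write_genome_index(genome: GenomeIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


@dataclass
class CoverageTrack:
    """Per-line read-depth intervals (internally 0-based half-open).

    ``covered_length`` is the number of bases with depth >= 1 (the
    genome-coverage figure a per-line mutation rate is divided by).
    """

    line_id: str
    # per chromosome: (starts, ends, depths) int arrays, sorted, non-overlapping
    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    covered_length: int

    def depth_at(self, chrom: str, pos: int) -> int:
        """Depth at a 1-based position; 0 where no interval covers it."""
        if chrom not in self.intervals:
            return 0
        starts, ends, depths = self.intervals[chrom]
        p0 = pos - 1
        idx = int(np.searchsorted(starts, p0, side="right")) - 1
        if idx >= 0 and ends[idx] > p0:
            return int(depths[idx])
        return 0

    def min_depth(self, chrom: str, start: int, end: int) -> int:
        """Minimum depth over the 1-based inclusive span ``start..end``."""
        if end < start:
            raise ValueError("empty span")
        if chrom not in self.intervals:
            return 0
        starts, ends, depths = self.intervals[chrom]
        lo, hi = start - 1, end  # 0-based half-open
        first = max(int(np.searchsorted(starts, lo, side="right")) - 1, 0)
        best = None
        covered_to = lo
        for i in range(first, len(starts)):
            if starts[i] >= hi:
                break
            if ends[i] <= lo:
                continue
            if starts[i] > covered_to:
                return 0  # uncovered gap inside the span
            covered_to = max(covered_to, int(ends[i]))
            d = int(depths[i])
            best = d if best is None else min(best, d)
        if covered_to < hi or best is None:
            return 0
        return best


def _build_track(
    line_id: str,
    rows: Iterable[tuple[str, int, int, int]],
    genome: GenomeIndex,
    source: str = "<coverage>",
) -> CoverageTrack:
    per_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, start, end, depth in rows:
        if chrom not in genome:
            raise FormatError(f"{source}: unknown chromosome {chrom!r}")
        if start < 0 or end <= start:
            raise FormatError(f"{source}: bad interval {chrom}:{start}-{end}")
        if end > genome.length_of(chrom):
            raise FormatError(
                f"{source}: interval {chrom}:{start}-{end} beyond chromosome end "
                f"({genome.length_of(chrom)})"
            )
        if depth < 0:
            raise FormatError(f"{source}: negative depth at {chrom}:{start}-{end}")
        per_chrom.setdefault(chrom, []).append((start, end, depth))
    intervals = {}
    covered = 0
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        prev_end = -1
        for start, end, _ in ivs:
            if start < prev_end:
                raise FormatError(
                    f"{source}: overlapping intervals on {chrom} at {start}"
                )
            prev_end = end
        starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
        depths = np.array([d for _, _, d in ivs], dtype=np.int64)
        intervals[chrom] = (starts, ends, depths)
        covered += int(((ends - starts) * (depths >= 1)).sum())
    return CoverageTrack(line_id=line_id, intervals=intervals, covered_length=covered)


def read_coverage(
    path: str | Path,
    genome: GenomeIndex,
    line_id: str | None = None,
) -> CoverageTrack:
    """Read a bedgraph depth track (chrom, start, end, depth).

    Intervals must lie within chromosome bounds and must not overlap.
    Depth-0 rows (as emitted by ``genomeCoverageBed -bga``) are accepted
    and excluded from ``covered_length``.
    """
    path = Path(path)
    if line_id is None:
        line_id = path.stem
    table = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "depth": np.int64},
    )
    rows = (
        (str(r.chrom), int(r.start), int(r.end), int(r.depth))
        for r in table.itertuples(index=False)
    )
    return _build_track(line_id, rows, genome, source=str(path))


def build_coverage_track(
    line_id: str,
    rows: Sequence[tuple[str, int, int, int]],
    genome: GenomeIndex,
) -> CoverageTrack:
    """Build a validated CoverageTrack from in-memory bedgraph rows."""
    return _build_track(line_id, rows, genome)


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.intervals:
            starts, ends, depths = track.intervals[chrom]
            for s, e, d in zip(starts, ends, depths):
                fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")


@dataclass(frozen=True)
class AlignmentSummary:
    """Per-line read-alignment bookkeeping for summary statistics."""

    line_id: str
    total_reads: int
    mapped_reads: int
    read_length: int
    covered_length: int

    def __post_init__(self) -> None:
        if not 0 <= self.mapped_reads <= self.total_reads:
            raise ValueError("need 0 <= mapped_reads <= total_reads")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")


class VcfReadResult(NamedTuple):
    """Parsed calls plus counts of rejected records."""

    calls: list[VariantCall]
    n_missing_qual: int
    n_missing_depth: int
    n_complex: int


def read_vcf_result(
    path: str | Path,
    line_id: str,
    genome: GenomeIndex,
    aliases: Mapping[str, str] | None = None,
) -> VcfReadResult:
    """Read a single-line VCF into VariantCalls, splitting multi-allelics.

    One :class:`VariantCall` is produced per ALT allele. Records without a
    QUAL or without a resolvable site depth (INFO/DP, else summed
    per-sample DP) are rejected and counted; complex equal-length
    substitutions are counted separately. An unknown chromosome is an
    error naming the record.
    """
    calls: list[VariantCall] = []
    n_missing_qual = n_missing_depth = n_complex = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            chrom = str(rec.chrom)
            if aliases:
                chrom = aliases.get(chrom, chrom)
            if chrom not in genome:
                raise FormatError(
                    f"{path}: unknown chromosome {rec.chrom!r} at record "
                    f"{rec.chrom}:{rec.pos}"
                )
            pos = int(rec.pos)
            if not 1 <= pos <= genome.length_of(chrom):
                raise FormatError(
                    f"{path}: position {pos} outside {chrom} "
                    f"[1, {genome.length_of(chrom)}]"
                )
            if rec.qual is None:
                n_missing_qual += 1
                continue
            depth = rec.info.get("DP")
            if depth is None:
                sample_dp = [
                    s.get("DP") for s in rec.samples.values() if s.get("DP")
                ]
                depth = sum(sample_dp) if sample_dp else None
            if depth is None:
                n_missing_depth += 1
                continue
            for alt in rec.alts or ():
                if alt is None or alt.startswith("<"):
                    continue
                try:
                    var_type = classify_variant_type(rec.ref, alt)
                except ComplexVariantError:
                    n_complex += 1
                    continue
                calls.append(
                    VariantCall(
                        line_id=line_id,
                        chrom=chrom,
                        pos=pos,
                        ref=str(rec.ref),
                        alt=str(alt),
                        var_type=var_type,
                        quality=float(rec.qual),
                        site_depth=int(depth),
                    )
                )
    if n_missing_qual or n_missing_depth:
        logger.warning(
            "%s: rejected %d records without QUAL, %d without depth",
            path, n_missing_qual, n_missing_depth,
        )
    return VcfReadResult(calls, n_missing_qual, n_missing_depth, n_complex)


def read_vcf(
    path: str | Path,
    line_id: str,
    genome: GenomeIndex,
    aliases: Mapping[str, str] | None = None,
) -> list[VariantCall]:
    """Like :func:`read_vcf_result` but returning only the call list."""
    return read_vcf_result(path, line_id, genome, aliases=aliases).calls


def write_vcf(
    calls: Iterable[VariantCall],
    path: str | Path,
    genome: GenomeIndex,
    extra_records: Iterable[tuple[str, int, str, str, float, int]] = (),
) -> None:
    """Write calls as a sites-only VCF v4.2 with QUAL and INFO/DP.

    ``extra_records`` allows emitting raw ``(chrom, pos, ref, alt, qual,
    depth)`` tuples that are not representable as :class:`VariantCall`
    (e.g. complex substitutions planted by the simulator).
    """
    header = pysam.VariantHeader()
    for name, length in genome.chromosomes:
        header.contigs.add(name, length=length)
    header.info.add("DP", number=1, type="Integer", description="Site read depth")
    order = {name: i for i, name in enumerate(genome.names)}
    rows = [
        (order[c.chrom], c.pos, c.ref, c.alt, c.quality, c.site_depth, c.chrom)
        for c in calls
    ]
    rows += [
        (order[chrom], pos, ref, alt, qual, depth, chrom)
        for chrom, pos, ref, alt, qual, depth in extra_records
    ]
    rows.sort()
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for _, pos, ref, alt, qual, depth, chrom in rows:
            rec = out.new_record(
                contig=chrom,
                start=pos - 1,
                alleles=(ref, alt),
                qual=qual,
            )
            rec.info["DP"] = int(depth)
            out.write(rec)
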