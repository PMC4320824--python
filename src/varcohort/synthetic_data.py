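"""Synthetic multi-line variant cohorts and toy gene models with known truth.

The generator emulates the statistical structure of a five-line rice
resequencing cohort: a large block of variants common to all lines,
smaller blocks shared by subsets of lines, per-line private variants,
group-specific substitution spectra (including an excess of G>T / C>A
transversions in the transgenic group), and planted violations of each
filter criterion so per-filter removal counts can be checked exactly.

Default parameters follow the study conditions at one-tenth scale:
private counts 80/62/84/52/83 across the five lines and 1,037 common
variants, with SNP/insertion/deletion fractions matching the pooled
line-specific breakdown (0.58/0.10/0.32) and group Ts/Tv targets of
1.12 (transgenic) and 1.65 (wild type).

Violations are planted by explicit assignment, never by sampling, so
truth counts are exact. One seed drives the whole simulation; derived
sub-streams keep components independently reproducible and the emitted
files byte-identical across runs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    CoverageTrack,
    GenomeIndex,
    build_coverage_track,
    write_coverage,
    write_genome_index,
    write_vcf,
)
from .stats import SUBSTITUTIONS, TRANSITIONS
from .variant_model import VariantCall, VarType

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "spectrum_weights",
    "SimulatedGenes",
    "simulate_gene_models",
]

_BASES = np.array(["A", "C", "G", "T"])


def spectrum_weights(ts_tv: float, gt_ca_weight: float = 0.125) -> dict:
    """12-substitution probability vector with a prescribed Ts/Tv ratio.

    Transition mass is split 0.32/0.32/0.18/0.18 over G>A, C>T, A>G, T>C
    (deamination-dominated profile); ``gt_ca_weight`` is the share of the
    transversion mass given to each of G>T and C>A (0.125 = uniform over
    the 8 transversions; larger values model oxidative G>T/C>A excess).
    """
    if ts_tv <= 0:
        raise ValueError("ts_tv must be positive")
    if not 0 <= gt_ca_weight <= 0.5:
        raise ValueError("gt_ca_weight must lie in [0, 0.5]")
    p_ts = ts_tv / (1.0 + ts_tv)
    ts_split = {("G", "A"): 0.32, ("C", "T"): 0.32, ("A", "G"): 0.18,
                ("T", "C"): 0.18}
    weights = {}
    other = (1.0 - 2 * gt_ca_weight) / 6.0
    for sub in SUBSTITUTIONS:
        if sub in TRANSITIONS:
            weights[sub] = p_ts * ts_split[sub]
        elif sub in (("G", "T"), ("C", "A")):
            weights[sub] = (1 - p_ts) * gt_ca_weight
        else:
            weights[sub] = (1 - p_ts) * other
    return weights


@dataclass
class SimConfig:
    """Configuration of a simulated cohort; defaults are the scaled-down
    five-line study conditions."""

    seed: int = 0
    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 3_000_000),
        ("chr2", 2_500_000),
        ("chr3", 2_000_000),
    )
    line_ids: tuple[str, ...] = ("50A", "51A", "55A", "WT1", "WT2")
    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "transgenic": ("50A", "51A", "55A"),
            "wild_type": ("WT1", "WT2"),
        }
    )
    n_common: int = 1037
    pattern_counts: dict[tuple[str, ...], int] = field(
        default_factory=lambda: {
            ("50A", "51A"): 40,
            ("51A", "55A"): 35,
            ("WT1", "WT2"): 60,
            ("50A", "51A", "55A"): 45,
            ("50A", "51A", "55A", "WT1"): 25,
        }
    )
    private_counts: dict[str, int] = field(
        default_factory=lambda: {
            "50A": 80, "51A": 62, "55A": 84, "WT1": 52, "WT2": 83,
        }
    )
    snp_fraction: float = 0.58
    ins_fraction: float = 0.10
    del_fraction: float = 0.32
    group_ts_tv: dict[str, float] = field(
        default_factory=lambda: {"transgenic": 1.12, "wild_type": 1.65}
    )
    group_gt_ca_weight: dict[str, float] = field(
        default_factory=lambda: {"transgenic": 0.25, "wild_type": 0.125}
    )
    quality_mean: float = 60.0
    quality_sd: float = 15.0
    quality_floor: float = 30.0
    baseline_depth: int = 50
    n_uncovered_gaps_per_line: int = 2
    gap_length: int = 5_000
    centromere_peak_fraction: float = 0.0
    n_low_quality: int = 25
    n_low_coverage_sites: int = 15
    n_type_conflicts: int = 10
    n_over_depth: int = 8
    n_complex: int = 6

    def validate(self) -> None:
        fracs = self.snp_fraction + self.ins_fraction + self.del_fraction
        if abs(fracs - 1.0) > 1e-9:
            raise ValueError("snp/ins/del fractions must sum to 1")
        if any(n < 0 for n in self.private_counts.values()):
            raise ValueError("private counts must be >= 0")
        if set(self.private_counts) != set(self.line_ids):
            raise ValueError("private_counts must cover exactly the line ids")
        grouped = [l for lines in self.groups.values() for l in lines]
        if sorted(grouped) != sorted(self.line_ids):
            raise ValueError("groups must partition the line ids")
        for pattern in self.pattern_counts:
            if not 2 <= len(pattern) < len(self.line_ids):
                raise ValueError(
                    f"pattern {pattern} must name 2..n-1 distinct lines"
                )
            if len(set(pattern)) != len(pattern) or not set(pattern) <= set(
                self.line_ids
            ):
                raise ValueError(f"bad pattern {pattern}")
        if not 0 <= self.centromere_peak_fraction <= 1:
            raise ValueError("centromere_peak_fraction must lie in [0, 1]")

    def group_of(self, line_id: str) -> str:
        for group, lines in self.groups.items():
            if line_id in lines:
                return group
        raise KeyError(line_id)

    def total_sites(self) -> int:
        return (
            self.n_common
            + sum(self.pattern_counts.values())
            + sum(self.private_counts.values())
            + self.n_low_quality
            + self.n_low_coverage_sites
            + self.n_type_conflicts
            + self.n_over_depth
            + self.n_complex
        )


@dataclass
class SimulatedCohort:
    """Simulation output: file paths, genome, and the truth table."""

    config: SimConfig
    genome: GenomeIndex
    truth: pd.DataFrame
    out_dir: Path
    genome_index_path: Path
    vcf_paths: dict[str, Path]
    coverage_paths: dict[str, Path]
    truth_path: Path
    manifest_path: Path
    covered_lengths: dict[str, int]

    def expected_pattern_counts(self) -> dict[tuple[bool, ...], int]:
        """Sharing-pattern counts the filtered pipeline must recover."""
        cfg = self.config
        out: dict[tuple[bool, ...], int] = {}
        full = tuple(True for _ in cfg.line_ids)
        if cfg.n_common:
            out[full] = cfg.n_common
        for pattern, count in cfg.pattern_counts.items():
            if count:
                key = tuple(l in pattern for l in cfg.line_ids)
                out[key] = out.get(key, 0) + count
        for i, line in enumerate(cfg.line_ids):
            n = cfg.private_counts[line]
            if n:
                key = tuple(j == i for j in range(len(cfg.line_ids)))
                out[key] = out.get(key, 0) + n
        return out


_MIN_GAP = 8  # minimum spacing between simulated sites (bp)


class _PositionSampler:
    """Draws distinct, well-spaced positions avoiding forbidden regions."""

    def __init__(
        self,
        length: int,
        rng: np.random.Generator,
        forbidden: Sequence[tuple[int, int]],
    ) -> None:
        self.length = length
        self.rng = rng
        self.forbidden = sorted(forbidden)
        self._bins: dict[int, list[int]] = {}

    def _ok(self, pos: int) -> bool:
        b = pos // _MIN_GAP
        for bb in (b - 1, b, b + 1):
            for other in self._bins.get(bb, ()):
                if abs(other - pos) < _MIN_GAP:
                    return False
        for s, e in self.forbidden:
            if s <= pos <= e:
                return False
        return True

    def draw(self, n: int, window: tuple[int, int] | None = None) -> list[int]:
        lo, hi = window if window else (10, self.length - 10)
        lo, hi = max(lo, 10), min(hi, self.length - 10)
        out: list[int] = []
        attempts = 0
        while len(out) < n:
            attempts += 1
            if attempts > 200:
                raise ValueError(
                    "cannot place requested variants: genome too small for "
                    "the configured counts"
                )
            for pos in self.rng.integers(lo, hi + 1, size=max(2 * n, 64)):
                pos = int(pos)
                if self._ok(pos):
                    self._bins.setdefault(pos // _MIN_GAP, []).append(pos)
                    out.append(pos)
                    if len(out) == n:
                        break
        return out


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, floor: float, n: int
) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    while True:
        bad = out < floor
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def _draw_substitution(
    rng: np.random.Generator, weights: Mapping[tuple[str, str], float]
) -> tuple[str, str]:
    subs = list(weights)
    p = np.array([weights[s] for s in subs], dtype=float)
    idx = rng.choice(len(subs), p=p / p.sum())
    return subs[int(idx)]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def simulate_cohort(
    cfg: SimConfig, out_dir: str | Path
) -> SimulatedCohort:
    """Generate per-line VCFs, coverage tracks, a genome index and the
    truth table for a multi-line cohort. Deterministic given the seed."""
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = GenomeIndex(chromosomes=cfg.chromosomes)

    if cfg.total_sites() * _MIN_GAP > genome.total_length // 2:
        raise ValueError("more variants requested than the genome can hold")

    ss = np.random.SeedSequence(cfg.seed)
    rng_gaps, rng_pos, rng_type, rng_allele, rng_qual, rng_depth, rng_viol = (
        np.random.default_rng(child) for child in ss.spawn(7)
    )

    # --- per-line uncovered gaps (depth 0) --------------------------------
    gaps: dict[str, list[tuple[str, int, int]]] = {l: [] for l in cfg.line_ids}
    forbidden: dict[str, list[tuple[int, int]]] = {
        name: [] for name, _ in cfg.chromosomes
    }
    chrom_names = [name for name, _ in cfg.chromosomes]
    chrom_lengths = np.array([ln for _, ln in cfg.chromosomes], dtype=float)
    for line in cfg.line_ids:
        for _ in range(cfg.n_uncovered_gaps_per_line):
            ci = int(rng_gaps.choice(len(chrom_names),
                                     p=chrom_lengths / chrom_lengths.sum()))
            name, length = cfg.chromosomes[ci]
            start = int(rng_gaps.integers(1000, length - cfg.gap_length - 1000))
            gaps[line].append((name, start, start + cfg.gap_length))
            # keep every simulated site clear of every line's gap
            forbidden[name].append((start - _MIN_GAP,
                                    start + cfg.gap_length + _MIN_GAP))

    # --- site positions ---------------------------------------------------
    samplers = {
        name: _PositionSampler(length, rng_pos, forbidden[name])
        for name, length in cfg.chromosomes
    }
    total = cfg.total_sites()
    n_peak = int(round(cfg.n_common * cfg.centromere_peak_fraction))
    per_chrom = rng_pos.multinomial(
        total - n_peak, chrom_lengths / chrom_lengths.sum()
    )
    positions: list[tuple[str, int]] = []
    for (name, _), n in zip(cfg.chromosomes, per_chrom):
        positions.extend((name, p) for p in samplers[name].draw(int(n)))
    for _ in range(n_peak):  # optional centromere-proximal excess
        ci = int(rng_pos.choice(len(chrom_names)))
        name, length = cfg.chromosomes[ci]
        mid = length // 2
        positions.extend(
            (name, p)
            for p in samplers[name].draw(1, window=(mid - 250_000, mid + 250_000))
        )
    order = rng_pos.permutation(len(positions))
    positions = [positions[i] for i in order]

    # --- assign roles -----------------------------------------------------
    cursor = 0

    def take(n: int) -> list[tuple[str, int]]:
        nonlocal cursor
        block = positions[cursor : cursor + n]
        cursor += n
        return block

    mean_weights = {
        sub: float(
            np.mean(
                [
                    spectrum_weights(
                        cfg.group_ts_tv[g], cfg.group_gt_ca_weight[g]
                    )[sub]
                    for g in cfg.groups
                ]
            )
        )
        for sub in SUBSTITUTIONS
    }
    group_weights = {
        g: spectrum_weights(cfg.group_ts_tv[g], cfg.group_gt_ca_weight[g])
        for g in cfg.groups
    }

    rows: list[dict] = []

    def add_site(
        chrom: str,
        pos: int,
        carriers: Sequence[str],
        fate: str,
        *,
        forced_type: VarType | None = None,
        weights: Mapping | None = None,
        victim: str | None = None,
    ) -> None:
        if forced_type is None:
            r = rng_type.random()
            if r < cfg.snp_fraction:
                var_type = VarType.SNP
            elif r < cfg.snp_fraction + cfg.ins_fraction:
                var_type = VarType.INS
            else:
                var_type = VarType.DEL
        else:
            var_type = forced_type
        substitution = ""
        if var_type is VarType.SNP:
            ref, alt = _draw_substitution(rng_allele, weights or mean_weights)
            substitution = f"{ref}>{alt}"
        elif var_type is VarType.INS:
            ref = _random_seq(rng_allele, 1)
            alt = ref + _random_seq(rng_allele, int(rng_allele.integers(1, 4)))
        else:
            ref = _random_seq(rng_allele, 1 + int(rng_allele.integers(1, 4)))
            alt = ref[0]
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "var_type": var_type.value,
                "lines": ",".join(carriers),
                "n_lines": len(carriers),
                "fate": fate,
                "substitution": substitution,
                "victim_line": victim or "",
            }
        )

    all_lines = list(cfg.line_ids)
    for chrom, pos in take(cfg.n_common):
        add_site(chrom, pos, all_lines, "pass")
    for pattern, count in cfg.pattern_counts.items():
        for chrom, pos in take(count):
            add_site(chrom, pos, list(pattern), "pass")
    for line in cfg.line_ids:
        w = group_weights[cfg.group_of(line)]
        for chrom, pos in take(cfg.private_counts[line]):
            add_site(chrom, pos, [line], "pass", weights=w)

    # planted violations (always private; counts are exact by assignment)
    for chrom, pos in take(cfg.n_low_quality):
        line = all_lines[int(rng_viol.integers(len(all_lines)))]
        add_site(chrom, pos, [line], "low_quality",
                 weights=group_weights[cfg.group_of(line)])
    for chrom, pos in take(cfg.n_low_coverage_sites):
        idx = rng_viol.permutation(len(all_lines))
        carrier, victim = all_lines[idx[0]], all_lines[idx[1]]
        add_site(chrom, pos, [carrier], "low_coverage",
                 forced_type=VarType.SNP, victim=victim)
    conflict_secondaries = []
    for chrom, pos in take(cfg.n_type_conflicts):
        idx = rng_viol.permutation(len(all_lines))
        snp_line, ins_line = all_lines[idx[0]], all_lines[idx[1]]
        add_site(chrom, pos, [snp_line], "type_conflict",
                 forced_type=VarType.SNP)
        ref = rows[-1]["ref"]
        alt = ref + _random_seq(rng_allele, 2)
        conflict_secondaries.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "var_type": VarType.INS.value, "lines": ins_line,
                "n_lines": 1, "fate": "type_conflict", "substitution": "",
                "victim_line": "",
            }
        )
    rows.extend(conflict_secondaries)
    for chrom, pos in take(cfg.n_over_depth):
        line = all_lines[int(rng_viol.integers(len(all_lines)))]
        add_site(chrom, pos, [line], "over_depth")
    for chrom, pos in take(cfg.n_complex):
        line = all_lines[int(rng_viol.integers(len(all_lines)))]
        ref = _random_seq(rng_allele, 2)
        alt = "".join({"A": "C", "C": "G", "G": "T", "T": "A"}[b] for b in ref)
        rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "var_type": "COMPLEX", "lines": line, "n_lines": 1,
                "fate": "complex", "substitution": "", "victim_line": "",
            }
        )

    truth_columns = [
        "chrom", "pos", "ref", "alt", "var_type", "lines", "n_lines",
        "fate", "substitution", "victim_line",
    ]
    truth = pd.DataFrame(rows, columns=truth_columns)
    truth = truth.sort_values(["chrom", "pos", "ref", "alt"]).reset_index(
        drop=True
    )

    # --- per-call quality / depth ----------------------------------------
    n_calls = int(truth["n_lines"].sum())
    quality = _truncated_normal(
        rng_qual, cfg.quality_mean, cfg.quality_sd, cfg.quality_floor, n_calls
    )
    depth = np.clip(rng_depth.poisson(cfg.baseline_depth, size=n_calls),
                    cfg.baseline_depth // 4 + 4, None)

    per_line_calls: dict[str, list[VariantCall]] = {
        l: [] for l in cfg.line_ids
    }
    per_line_extra: dict[str, list[tuple]] = {l: [] for l in cfg.line_ids}
    call_i = 0
    for row in truth.itertuples(index=False):
        for line in str(row.lines).split(","):
            q = float(quality[call_i])
            d = int(depth[call_i])
            call_i += 1
            if row.fate == "low_quality":
                q = float(5.0 + 24.5 * rng_qual.random())
            if row.fate == "over_depth":
                d = 10_001 + int(rng_depth.poisson(500))
            if row.fate == "complex":
                per_line_extra[line].append(
                    (row.chrom, int(row.pos), row.ref, row.alt, q, d)
                )
                continue
            per_line_calls[line].append(
                VariantCall(
                    line_id=line,
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    var_type=VarType(row.var_type),
                    quality=round(q, 1),
                    site_depth=d,
                )
            )

    # --- coverage tracks --------------------------------------------------
    low_cov = truth[truth["fate"] == "low_coverage"]
    coverage_paths = {}
    covered_lengths = {}
    for line in cfg.line_ids:
        overrides: dict[str, list[tuple[int, int, int]]] = {}
        for chrom, s, e in gaps[line]:
            overrides.setdefault(chrom, []).append((s, e, 0))
        for row in low_cov.itertuples(index=False):
            if row.victim_line == line:
                p0 = int(row.pos) - 1
                overrides.setdefault(row.chrom, []).append((p0, p0 + 1, 3))
        bed_rows = []
        for name, length in cfg.chromosomes:
            cur = 0
            for s, e, d in sorted(overrides.get(name, [])):
                if s > cur:
                    bed_rows.append((name, cur, s, cfg.baseline_depth))
                bed_rows.append((name, s, e, d))
                cur = e
            if cur < length:
                bed_rows.append((name, cur, length, cfg.baseline_depth))
        track = build_coverage_track(line, bed_rows, genome)
        path = out_dir / f"{line}.bedgraph"
        write_coverage(track, path)
        coverage_paths[line] = path
        covered_lengths[line] = track.covered_length

    # --- emit files -------------------------------------------------------
    vcf_paths = {}
    for line in cfg.line_ids:
        path = out_dir / f"{line}.vcf"
        write_vcf(
            per_line_calls[line], path, genome,
            extra_records=per_line_extra[line],
        )
        vcf_paths[line] = path
    genome_index_path = out_dir / "genome_index.tsv"
    write_genome_index(genome, genome_index_path)
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    manifest = {
        "line_ids": list(cfg.line_ids),
        "groups": {g: list(lines) for g, lines in cfg.groups.items()},
        "genome_index": genome_index_path.name,
        "vcf": {l: p.name for l, p in vcf_paths.items()},
        "coverage": {l: p.name for l, p in coverage_paths.items()},
        "truth": truth_path.name,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return SimulatedCohort(
        config=cfg,
        genome=genome,
        truth=truth,
        out_dir=out_dir,
        genome_index_path=genome_index_path,
        vcf_paths=vcf_paths,
        coverage_paths=coverage_paths,
        truth_path=truth_path,
        manifest_path=manifest_path,
        covered_lengths=covered_lengths,
    )


# =====================================================================
# toy gene models covering all 23 effect types
# =====================================================================

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _comp(seq: str) -> str:
    return "".join(_COMP[b] for b in seq)


def _revcomp(seq: str) -> str:
    return _comp(seq)[::-1]


@dataclass
class SimulatedGenes:
    """Toy genome + gene models + planted variants with expected effects."""

    fasta_path: Path
    gff3_path: Path
    genome: GenomeIndex
    sequences: dict[str, str]
    planted: pd.DataFrame  # chrom,pos,ref,alt,expected_effect,gene_id,case


_CHROM_LEN = 30_000
# plus-strand toy gene layout on "toyA" (1-based inclusive)
_GENE1 = dict(
    gene=(8001, 17_000),
    exons=[(9001, 9600), (10_101, 10_700), (11_201, 12_100)],
    cds=[(9201, 9600), (10_101, 10_700), (11_201, 11_601)],
)


def _mirror(pos: int) -> int:
    return _CHROM_LEN + 1 - pos


def simulate_gene_models(out_dir: str | Path, seed: int = 0) -> SimulatedGenes:
    """Write a toy two-chromosome genome (FASTA) and two gene models
    (GFF3): a plus-strand gene whose planted variants cover all 23 effect
    types, and its reverse-complement mirror on the minus strand used as
    a strand-symmetry oracle for the SNP-type effects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, _CHROM_LEN))

    def put(pos: int, bases: str) -> None:
        seq[pos - 1 : pos - 1 + len(bases)] = list(bases)

    put(9201, "ATG")          # start codon
    put(9231, "CTACGATTAC"[:3])  # codon 10 = CTA (Leu)
    put(9234, "GAT")          # codon 11 = Asp
    put(9237, "TAC")          # codon 12 = Tyr
    put(11_599, "TGA")        # stop codon
    put(9100, "CCCCC")        # inert 5'UTR context
    put(9120, "ACG")          # one substitution away from ATG

    seq_a = "".join(seq)
    seq_b = _revcomp(seq_a)
    sequences = {"toyA": seq_a, "toyB": seq_b}

    def base(pos: int) -> str:
        return seq_a[pos - 1]

    def other(b: str) -> str:
        return {"A": "C", "C": "G", "G": "T", "T": "A"}[b]

    planted: list[tuple[str, int, str, str, str, str, str]] = []

    def plant(pos: int, ref: str, alt: str, effect: str, case: str) -> None:
        planted.append(("toyA", pos, ref, alt, effect, "gene1", case))

    def plant_snp(pos: int, alt: str, effect: str) -> None:
        plant(pos, base(pos), alt, effect, "snp")

    def plant_any_snp(pos: int, effect: str) -> None:
        plant_snp(pos, other(base(pos)), effect)

    plant_snp(9233, "G", "SYNONYMOUS_CODING")        # CTA -> CTG (Leu)
    plant_snp(9236, "A", "NON_SYNONYMOUS_CODING")    # GAT -> GAA (D->E)
    plant_snp(9239, "G", "STOP_GAINED")              # TAC -> TAG
    plant_snp(9202, "A", "START_LOST")               # ATG -> AAG
    plant_snp(9201, "G", "NON_SYNONYMOUS_START")     # ATG -> GTG
    plant_snp(11_601, "G", "STOP_LOST")              # TGA -> TGG
    plant_snp(11_600, "A", "SYNONYMOUS_STOP")        # TGA -> TAA
    plant(10_400, base(10_400), base(10_400) + "A", "FRAME_SHIFT", "indel")
    plant(10_303, base(10_303), base(10_303) + "GGT", "CODON_INSERTION",
          "indel")
    plant(10_304, base(10_304), base(10_304) + "GGT",
          "CODON_CHANGE_PLUS_CODON_INSERTION", "indel")
    plant(10_330, seq_a[10_329:10_333], base(10_330), "CODON_DELETION",
          "indel")
    plant(10_340, seq_a[10_339:10_343], base(10_340),
          "CODON_CHANGE_PLUS_CODON_DELETION", "indel")
    plant_any_snp(9601, "SPLICE_SITE_DONOR")     # intron 1, first base
    plant_any_snp(10_100, "SPLICE_SITE_ACCEPTOR")  # intron 1, last base
    plant_any_snp(10_704, "SPLICE_SITE_REGION")  # intron 2, 4th base
    plant_any_snp(10_950, "INTRON")
    plant_snp(9102, "G", "UTR_5_PRIME")          # CCCCC context, no new ATG
    plant_snp(9121, "T", "START_GAINED")         # ACG -> ATG
    plant_any_snp(11_800, "UTR_3_PRIME")
    plant_any_snp(7500, "UPSTREAM")
    plant_any_snp(17_500, "DOWNSTREAM")
    plant_any_snp(1500, "INTERGENIC")
    plant_any_snp(13_000, "INTRAGENIC")

    # minus-strand mirror: same labels expected for every mirrored SNP
    mirrored = []
    for chrom, pos, ref, alt, effect, gene, case in list(planted):
        if case != "snp" and effect not in (
            "SPLICE_SITE_DONOR", "SPLICE_SITE_ACCEPTOR", "SPLICE_SITE_REGION",
            "INTRON", "UTR_3_PRIME", "UPSTREAM", "DOWNSTREAM", "INTERGENIC",
            "INTRAGENIC",
        ):
            continue
        if len(ref) != 1 or len(alt) != 1:
            continue
        mirrored.append(
            ("toyB", _mirror(pos), _comp(ref), _comp(alt), effect, "gene2",
             "mirror")
        )
    # frameshift and whole-codon deletion have well-defined minus-strand
    # anchored mirrors; plant them directly
    b = seq_b
    mirrored.append(
        ("toyB", 19_600, b[19_599], b[19_599] + "A", "FRAME_SHIFT", "gene2",
         "mirror_indel")
    )
    mirrored.append(
        ("toyB", 20_767, b[20_766:20_770], b[20_766], "CODON_DELETION",
         "gene2", "mirror_indel")
    )
    planted.extend(mirrored)

    planted_df = pd.DataFrame(
        planted,
        columns=["chrom", "pos", "ref", "alt", "expected_effect", "gene_id",
                 "case"],
    )

    # --- write FASTA ------------------------------------------------------
    fasta_path = out_dir / "toy_genome.fa"
    with open(fasta_path, "w") as fh:
        for name, s in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")

    # --- write GFF3 -------------------------------------------------------
    def gff_lines(chrom, strand, gene_id, gene, exons, cds):
        lines = [
            f"{chrom}\tsim\tgene\t{gene[0]}\t{gene[1]}\t.\t{strand}\t.\t"
            f"ID={gene_id}",
            f"{chrom}\tsim\tmRNA\t{exons[0][0]}\t{exons[-1][1]}\t.\t{strand}"
            f"\t.\tID={gene_id}.1;Parent={gene_id}",
        ]
        for i, (s, e) in enumerate(exons, 1):
            lines.append(
                f"{chrom}\tsim\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                f"ID={gene_id}.1.exon{i};Parent={gene_id}.1"
            )
        ordered = cds if strand == "+" else list(reversed(cds))
        acc = 0
        for i, (s, e) in enumerate(ordered, 1):
            phase = (3 - acc % 3) % 3
            acc += e - s + 1
            lines.append(
                f"{chrom}\tsim\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}\t"
                f"ID={gene_id}.1.cds{i};Parent={gene_id}.1"
            )
        return lines

    g1 = _GENE1
    gene2 = tuple(sorted((_mirror(g1["gene"][0]), _mirror(g1["gene"][1]))))
    exons2 = sorted(
        tuple(sorted((_mirror(s), _mirror(e)))) for s, e in g1["exons"]
    )
    cds2 = sorted(
        tuple(sorted((_mirror(s), _mirror(e)))) for s, e in g1["cds"]
    )
    gff3_path = out_dir / "toy_genes.gff3"
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in gff_lines("toyA", "+", "gene1", g1["gene"], g1["exons"],
                              g1["cds"]):
            fh.write(line + "\n")
        for line in gff_lines("toyB", "-", "gene2", gene2, exons2, cds2):
            fh.write(line + "\n")

    genome = GenomeIndex(
        chromosomes=(("toyA", _CHROM_LEN), ("toyB", _CHROM_LEN))
    )
    return SimulatedGenes(
        fasta_path=fasta_path,
        gff3_path=gff3_path,
        genome=genome,
        sequences=sequences,
        planted=planted_df,
    )
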