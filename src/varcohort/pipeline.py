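"""End-to-end orchestration: from per-line VCFs to report tables.

The pipeline mirrors the analysis workflow for a cohort of resequenced
lines: parse per-line call sets, apply the exclusion and three-criterion
filtration, classify sharing, compute per-line mutation rates and
substitution spectra, windowed density profiles with group contrasts,
and (when gene models are supplied) the coding-effect rollup. Every
summary number in the emitted reports is recomputable from the emitted
per-variant tables, and re-running on the same inputs produces
byte-identical files.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import effects as fx
from .filtration import FilterConfig, FilterReport, apply_all_filters, \
    filter_excessive_depth
from .genome_io import (
    AlignmentSummary,
    CoverageTrack,
    GenomeIndex,
    read_coverage,
    read_genome_index,
    read_vcf_result,
)
from .sharing import LineSpecificSet, SharingProfile, classify_sharing, \
    line_specific_variants
from .stats import (
    RateResult,
    SubstitutionSpectrum,
    alignment_summary_stats,
    mutation_rate,
    pool_spectra,
    round_sig,
    spectrum,
    ts_tv_ratio,
)
from .variant_model import MultiLineTable, build_multiline_table
from .windows import (
    DEFAULT_WINDOW_SIZE,
    group_mean_profile,
    max_window_difference,
    window_counts,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("filter", "share", "spectrum", "windows", "effects", "summary")


@dataclass
class PipelineConfig:
    """Inputs and options of one pipeline run.

    ``manifest`` is a JSON file naming the per-line VCFs and coverage
    tracks, the genome index, and the line groups (the layout written by
    the cohort simulator). Relative paths are resolved against the
    manifest's directory.
    """

    manifest: Path
    out_dir: Path
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    window_size: int = DEFAULT_WINDOW_SIZE
    gene_fasta: Path | None = None
    gene_gff3: Path | None = None
    alignment_summary: Path | None = None
    #: feed windows with all post-depth-exclusion variants (True) or with
    #: the fully filtered set (False)
    windows_use_all_variants: bool = True
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        self.manifest = Path(self.manifest)
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")


@dataclass
class PipelineResult:
    genome: GenomeIndex
    table: MultiLineTable
    filtered: MultiLineTable
    report: FilterReport
    profile: SharingProfile
    line_sets: dict[str, LineSpecificSet]
    rates: dict[str, RateResult]
    spectra: dict[str, SubstitutionSpectrum]
    group_spectra: dict[str, SubstitutionSpectrum]
    group_ts_tv: dict[str, float | None]
    window_means: dict[str, dict[str, np.ndarray]]
    window_max_diff: dict[str, float]
    rollup: fx.EffectRollup | None
    outputs: dict[str, Path]


def _load_manifest(path: Path) -> tuple[dict, Path]:
    manifest = json.loads(Path(path).read_text())
    base = Path(path).parent
    required = {"line_ids", "groups", "genome_index", "vcf", "coverage"}
    missing = required - set(manifest)
    if missing:
        raise ValueError(f"{path}: manifest missing keys {sorted(missing)}")
    groups = manifest["groups"]
    grouped = sorted(l for lines in groups.values() for l in lines)
    if grouped != sorted(manifest["line_ids"]):
        raise ValueError(f"{path}: groups do not partition the line list")
    return manifest, base


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the requested stages and write their report files."""
    manifest, base = _load_manifest(cfg.manifest)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    line_ids: list[str] = list(manifest["line_ids"])
    groups: dict[str, list[str]] = {
        g: list(lines) for g, lines in manifest["groups"].items()
    }

    genome = read_genome_index(
        base / manifest["genome_index"],
        centromere_path=(base / manifest["centromeres"])
        if manifest.get("centromeres")
        else None,
    )
    tracks: dict[str, CoverageTrack] = {
        line: read_coverage(base / manifest["coverage"][line], genome, line)
        for line in line_ids
    }
    parse_stats = {}
    callsets = []
    for line in line_ids:
        res = read_vcf_result(base / manifest["vcf"][line], line, genome)
        parse_stats[line] = {
            "n_calls": len(res.calls),
            "n_missing_qual": res.n_missing_qual,
            "n_missing_depth": res.n_missing_depth,
            "n_complex": res.n_complex,
        }
        callsets.append((line, res.calls))
        logger.info("%s: %d calls parsed", line, len(res.calls))

    table = build_multiline_table(callsets)
    fcfg = cfg.filter_config
    filtered, report = apply_all_filters(table, tracks, fcfg)
    logger.info(
        "filtration: %d sites in, %d out", report.n_input_sites,
        report.n_output_sites,
    )

    profile = classify_sharing(filtered)
    line_sets = {
        line: line_specific_variants(filtered, line) for line in line_ids
    }
    rates = {
        line: RateResult(
            line_id=line,
            n_line_specific=line_sets[line].n_total,
            covered_length=tracks[line].covered_length,
            rate=mutation_rate(
                line_sets[line].n_total, tracks[line].covered_length
            ),
        )
        for line in line_ids
    }
    spectra = {
        line: spectrum(
            [v for v in line_sets[line].variants]
        )
        for line in line_ids
    }
    group_spectra = {
        g: pool_spectra(spectra[line] for line in lines)
        for g, lines in groups.items()
    }
    group_ratio = {g: ts_tv_ratio(s) for g, s in group_spectra.items()}

    # windowed densities
    if cfg.windows_use_all_variants:
        window_input = {
            line: filter_excessive_depth(calls, fcfg)[0]
            for line, calls in callsets
        }
    else:
        window_input = {
            line: filtered.calls_for_line(line) for line in line_ids
        }
    profiles = {
        line: window_counts(calls, genome, cfg.window_size)
        for line, calls in window_input.items()
    }
    means = group_mean_profile(profiles, groups)
    group_names = list(groups)
    if len(group_names) == 2:
        max_diff = max_window_difference(
            means[group_names[0]], means[group_names[1]]
        )
    else:
        max_diff = {name: 0.0 for name in genome.names}

    # effects
    roll = None
    if "effects" in cfg.stages and cfg.gene_gff3 and cfg.gene_fasta:
        import pyfaidx

        models = fx.load_gene_models(cfg.gene_gff3)
        sequences = pyfaidx.Fasta(str(cfg.gene_fasta))
        annotator = fx.EffectAnnotator(models, sequences)
        assignments = {
            line: annotator.annotate_all(line_sets[line].variants)
            for line in line_ids
        }
        roll = fx.rollup(assignments, groups)

    # ------------------------------------------------------------------
    # report files
    # ------------------------------------------------------------------
    stages = set(cfg.stages)

    if "filter" in stages:
        rows = []
        for key, carriers in filtered.iter_sites():
            row = {
                "chrom": key.chrom, "pos": key.pos, "ref": key.ref,
                "alt": key.alt,
                "var_type": next(iter(carriers.values())).var_type.value,
            }
            for line in line_ids:
                row[line] = int(line in carriers)
            rows.append(row)
        cols = ["chrom", "pos", "ref", "alt", "var_type", *line_ids]
        df = pd.DataFrame(rows, columns=cols)
        outputs["variants_filtered"] = cfg.out_dir / "variants_filtered.tsv"
        _write_tsv(df, outputs["variants_filtered"])
        outputs["filter_report"] = cfg.out_dir / "filter_report.json"
        outputs["filter_report"].write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
        )

    if "share" in stages:
        rows = [
            {
                "pattern": ",".join(
                    line for line, hit in zip(line_ids, pattern) if hit
                ),
                "bits": "".join("1" if hit else "0" for hit in pattern),
                "n_lines": sum(pattern),
                "count": count,
            }
            for pattern, count in sorted(profile.pattern_counts.items())
        ]
        df = pd.DataFrame(
            rows, columns=["pattern", "bits", "n_lines", "count"]
        )
        outputs["sharing_profile"] = cfg.out_dir / "sharing_profile.tsv"
        _write_tsv(df, outputs["sharing_profile"])

        group_of = {
            line: g for g, lines in groups.items() for line in lines
        }
        rows = []
        for line in line_ids:
            ls, rr = line_sets[line], rates[line]
            rows.append(
                {
                    "line_id": line,
                    "group": group_of[line],
                    "n_line_specific": ls.n_total,
                    "n_ins": ls.n_ins,
                    "n_del": ls.n_del,
                    "n_snp": ls.n_snp,
                    "covered_length": rr.covered_length,
                    "mutation_rate": repr(rr.rate),
                    "mutation_rate_display": f"{round_sig(rr.rate):.2e}"
                    if rr.rate
                    else "0",
                }
            )
        outputs["line_specific_counts"] = (
            cfg.out_dir / "line_specific_counts.tsv"
        )
        _write_tsv(pd.DataFrame(rows), outputs["line_specific_counts"])

        rows = []
        for line in line_ids:
            for v in line_sets[line].variants:
                rows.append(
                    {
                        "line_id": line, "chrom": v.chrom, "pos": v.pos,
                        "ref": v.ref, "alt": v.alt,
                        "var_type": v.var_type.value,
                    }
                )
        outputs["line_specific_variants"] = (
            cfg.out_dir / "line_specific_variants.tsv"
        )
        _write_tsv(
            pd.DataFrame(
                rows,
                columns=["line_id", "chrom", "pos", "ref", "alt", "var_type"],
            ),
            outputs["line_specific_variants"],
        )

    if "spectrum" in stages:
        rows = []
        for ref, alt in sorted({s for s in spectra[line_ids[0]].counts}):
            row = {"substitution": f"{ref}>{alt}"}
            for line in line_ids:
                row[line] = spectra[line].counts[(ref, alt)]
            for g in groups:
                row[g] = group_spectra[g].counts[(ref, alt)]
            rows.append(row)
        outputs["spectra"] = cfg.out_dir / "spectra.tsv"
        _write_tsv(pd.DataFrame(rows), outputs["spectra"])

        rows = []
        for line in line_ids:
            s = spectra[line]
            r = ts_tv_ratio(s)
            rows.append(
                {
                    "entity": line, "kind": "line", "ts": s.ts_count,
                    "tv": s.tv_count,
                    "ts_tv": "NA" if r is None else f"{r:.2f}",
                }
            )
        for g in groups:
            s = group_spectra[g]
            r = group_ratio[g]
            rows.append(
                {
                    "entity": g, "kind": "group", "ts": s.ts_count,
                    "tv": s.tv_count,
                    "ts_tv": "NA" if r is None else f"{r:.2f}",
                }
            )
        outputs["ts_tv"] = cfg.out_dir / "ts_tv.tsv"
        _write_tsv(pd.DataFrame(rows), outputs["ts_tv"])

    if "windows" in stages:
        rows = []
        for chrom, length in genome.chromosomes:
            vecs = {g: means[g][chrom] for g in groups}
            for w in range(len(next(iter(vecs.values())))):
                row = {
                    "chrom": chrom,
                    "window_start": w * cfg.window_size + 1,
                    "window_end": min((w + 1) * cfg.window_size, length),
                }
                for g in groups:
                    row[g] = repr(float(vecs[g][w]))
                rows.append(row)
        outputs["window_means"] = cfg.out_dir / "window_means.tsv"
        _write_tsv(pd.DataFrame(rows), outputs["window_means"])
        rows = [
            {"chrom": chrom, "max_abs_difference": repr(val)}
            for chrom, val in sorted(max_diff.items())
        ]
        outputs["window_max_diff"] = cfg.out_dir / "window_max_diff.tsv"
        _write_tsv(pd.DataFrame(rows), outputs["window_max_diff"])

    if "effects" in stages and roll is not None:
        df = roll.counts.copy()
        df.insert(
            0, "impact",
            [fx.IMPACT_OF[fx.EffectType(e)].value for e in df.index],
        )
        df = df.reset_index().rename(columns={"index": "effect_type"})
        outputs["effects_rollup"] = cfg.out_dir / "effects_rollup.tsv"
        _write_tsv(df, outputs["effects_rollup"])

    if "summary" in stages:
        summary: dict = {
            "lines": line_ids,
            "groups": groups,
            "parse": parse_stats,
            "filter_report": report.to_dict(),
            "n_filtered_sites": filtered.n_sites,
            "sharing_by_n_lines": profile.count_by_n_lines(),
            "common_count": profile.common_count,
            "line_specific": {
                line: {
                    "total": line_sets[line].n_total,
                    "ins": line_sets[line].n_ins,
                    "del": line_sets[line].n_del,
                    "snp": line_sets[line].n_snp,
                    "covered_length": rates[line].covered_length,
                    "mutation_rate": rates[line].rate,
                }
                for line in line_ids
            },
            "ts_tv": {
                g: group_ratio[g] for g in groups
            },
            "window_max_diff": max_diff,
            "window_size": cfg.window_size,
        }
        if roll is not None:
            summary["impact_percent"] = {
                g: {
                    imp.value: roll.impact_percentages(g)[imp]
                    for imp in fx.Impact
                }
                for g in groups
            }
        if cfg.alignment_summary:
            aln = pd.read_csv(cfg.alignment_summary, sep="\t")
            stats_rows = {}
            for r in aln.itertuples(index=False):
                s = AlignmentSummary(
                    line_id=str(r.line_id),
                    total_reads=int(r.total_reads),
                    mapped_reads=int(r.mapped_reads),
                    read_length=int(r.read_length),
                    covered_length=int(r.covered_length),
                )
                st = alignment_summary_stats(s, genome)
                stats_rows[s.line_id] = {
                    "mapping_rate": st.mapping_rate,
                    "coverage_rate": st.coverage_rate,
                    "depth": st.depth,
                }
            summary["alignment_stats"] = stats_rows
        outputs["summary"] = cfg.out_dir / "summary.json"
        outputs["summary"].write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=float)
            + "\n"
        )

    return PipelineResult(
        genome=genome,
        table=table,
        filtered=filtered,
        report=report,
        profile=profile,
        line_sets=line_sets,
        rates=rates,
        spectra=spectra,
        group_spectra=group_spectra,
        group_ts_tv=group_ratio,
        window_means=means,
        window_max_diff=max_diff,
        rollup=roll,
        outputs=outputs,
    )
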