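"""Bundled example data: published summary tables from a five-line rice
resequencing comparison (three marker-free transgenic lines, 50A/51A/55A,
and two wild-type Nipponbare lines, WT1/WT2).

These are per-line summary statistics only (read-alignment bookkeeping,
variant counts after filtration, and effect-type counts for the
line-specific variants); the underlying reads and calls are not part of
the package. They drive the worked examples and the consistency checks
that recompute mutation rates, alignment statistics and impact-category
percentages from first principles.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .genome_io import AlignmentSummary, GenomeIndex, read_genome_index

__all__ = [
    "rice_genome_index",
    "rice_alignment_summaries",
    "rice_variant_counts",
    "rice_effect_counts",
    "rice_groups",
]


def _data_path(name: str):
    return resources.files("varcohort").joinpath("data", name)


def rice_genome_index() -> GenomeIndex:
    """The 12-chromosome rice (IRGSP-1.0, build 5) index; 373,245,519 bp."""
    with resources.as_file(_data_path("rice_genome_index.tsv")) as path:
        return read_genome_index(path)


def rice_alignment_summaries() -> dict[str, AlignmentSummary]:
    """Per-line read totals, mapped reads and covered genome length."""
    with resources.as_file(_data_path("rice_alignment_summary.tsv")) as path:
        table = pd.read_csv(path, sep="\t")
    return {
        str(r.line_id): AlignmentSummary(
            line_id=str(r.line_id),
            total_reads=int(r.total_reads),
            mapped_reads=int(r.mapped_reads),
            read_length=int(r.read_length),
            covered_length=int(r.covered_length),
        )
        for r in table.itertuples(index=False)
    }


def rice_variant_counts() -> pd.DataFrame:
    """Per-line variant counts: total detected, after filtration, and the
    line-specific breakdown into insertions, deletions and SNPs."""
    with resources.as_file(_data_path("rice_variant_counts.tsv")) as path:
        return pd.read_csv(path, sep="\t", index_col="line_id")


def rice_effect_counts() -> pd.DataFrame:
    """Line-specific variant counts per effect type (23 types x 5 lines)."""
    with resources.as_file(_data_path("rice_effect_counts.tsv")) as path:
        return pd.read_csv(path, sep="\t", index_col="effect_type")


def rice_groups() -> dict[str, tuple[str, ...]]:
    """Cohort grouping: transgenic lines first, then wild types."""
    return {
        "transgenic": ("50A", "51A", "55A"),
        "wild_type": ("WT1", "WT2"),
    }
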