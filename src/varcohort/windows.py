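"""Windowed variant-density profiles and group contrasts.

Counts fall in consecutive, non-overlapping windows (default 500 kbp)
anchored at position 1 of each chromosome; the final window may be
partial and is reported as-is, without length normalization. A variant at
1-based position p belongs to window floor((p - 1) / window_size).
"""
from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import GenomeIndex
from .variant_model import VariantCall

__all__ = [
    "DEFAULT_WINDOW_SIZE",
    "n_windows",
    "window_counts",
    "group_mean_profile",
    "max_window_difference",
]

DEFAULT_WINDOW_SIZE = 500_000

Profile = dict[str, np.ndarray]  # chromosome -> per-window vector


def n_windows(length: int, window_size: int) -> int:
    return math.ceil(length / window_size)


def window_counts(
    variants: Iterable[VariantCall],
    genome: GenomeIndex,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> Profile:
    """Per-chromosome window count vectors for one line's variants."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    profile: Profile = {
        name: np.zeros(n_windows(length, window_size), dtype=np.int64)
        for name, length in genome.chromosomes
    }
    for v in variants:
        if v.chrom not in profile:
            raise KeyError(f"variant on unknown chromosome {v.chrom!r}")
        profile[v.chrom][(v.pos - 1) // window_size] += 1
    return profile


def group_mean_profile(
    profiles: Mapping[str, Profile],
    groups: Mapping[str, Sequence[str]],
) -> dict[str, dict[str, np.ndarray]]:
    """Element-wise arithmetic mean of line profiles within each group."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for group, lines in groups.items():
        if not lines:
            raise ValueError(f"group {group!r} is empty")
        missing = [line for line in lines if line not in profiles]
        if missing:
            raise KeyError(f"no profile for line(s) {missing} in group {group!r}")
        chroms = profiles[lines[0]].keys()
        out[group] = {
            chrom: np.mean(
                [profiles[line][chrom] for line in lines], axis=0
            )
            for chrom in chroms
        }
    return out


def max_window_difference(
    group_a: Mapping[str, np.ndarray],
    group_b: Mapping[str, np.ndarray],
) -> dict[str, float]:
    """Per chromosome, the maximum |meanA - meanB| over windows."""
    if set(group_a) != set(group_b):
        raise ValueError("window grids differ: chromosome sets do not match")
    out = {}
    for chrom in group_a:
        a, b = np.asarray(group_a[chrom]), np.asarray(group_b[chrom])
        if a.shape != b.shape:
            raise ValueError(f"window grids differ on {chrom!r}")
        out[chrom] = float(np.max(np.abs(a - b))) if a.size else 0.0
    return out
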