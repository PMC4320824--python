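"""Single-effect variant consequence classifier and impact rollup.

Each line-specific variant receives exactly one of 23 effect types,
chosen as the most severe applicable effect under a fixed severity
ordering, and each effect type belongs to one of four impact categories
(HIGH, MODERATE, LOW, MODIFIER). Assigning one effect per variant keeps
per-line effect-type counts summing exactly to the line-specific totals.

Distance conventions follow common annotator defaults: up/downstream
extends 5,000 bp from the gene boundaries; the splice donor/acceptor
sites are the 2 intronic bases flanking each exon junction; the splice
region covers intronic bases 3-8 and the outermost 3 exonic bases of a
junction. When a variant overlaps several transcripts or genes the most
severe effect across all of them is kept.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio.Seq import Seq

from .variant_model import MultiLineTable, SiteKey, VariantCall, VarType

__all__ = [
    "EffectType",
    "Impact",
    "IMPACT_OF",
    "SEVERITY_ORDER",
    "EffectConfig",
    "GeneModel",
    "EffectAssignment",
    "EffectRollup",
    "EffectAnnotator",
    "load_gene_models",
    "annotate_effect",
    "impact_category",
    "rollup",
    "rollup_from_counts",
    "parse_precomputed_annotations",
]


class EffectType(str, Enum):
    FRAME_SHIFT = "FRAME_SHIFT"
    SPLICE_SITE_ACCEPTOR = "SPLICE_SITE_ACCEPTOR"
    SPLICE_SITE_DONOR = "SPLICE_SITE_DONOR"
    START_LOST = "START_LOST"
    STOP_GAINED = "STOP_GAINED"
    STOP_LOST = "STOP_LOST"
    CODON_CHANGE_PLUS_CODON_DELETION = "CODON_CHANGE_PLUS_CODON_DELETION"
    CODON_CHANGE_PLUS_CODON_INSERTION = "CODON_CHANGE_PLUS_CODON_INSERTION"
    CODON_DELETION = "CODON_DELETION"
    CODON_INSERTION = "CODON_INSERTION"
    NON_SYNONYMOUS_CODING = "NON_SYNONYMOUS_CODING"
    NON_SYNONYMOUS_START = "NON_SYNONYMOUS_START"
    SPLICE_SITE_REGION = "SPLICE_SITE_REGION"
    START_GAINED = "START_GAINED"
    SYNONYMOUS_CODING = "SYNONYMOUS_CODING"
    SYNONYMOUS_STOP = "SYNONYMOUS_STOP"
    DOWNSTREAM = "DOWNSTREAM"
    INTERGENIC = "INTERGENIC"
    INTRAGENIC = "INTRAGENIC"
    INTRON = "INTRON"
    UPSTREAM = "UPSTREAM"
    UTR_3_PRIME = "UTR_3_PRIME"
    UTR_5_PRIME = "UTR_5_PRIME"


class Impact(str, Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


IMPACT_OF: dict[EffectType, Impact] = {
    EffectType.FRAME_SHIFT: Impact.HIGH,
    EffectType.SPLICE_SITE_ACCEPTOR: Impact.HIGH,
    EffectType.SPLICE_SITE_DONOR: Impact.HIGH,
    EffectType.START_LOST: Impact.HIGH,
    EffectType.STOP_GAINED: Impact.HIGH,
    EffectType.STOP_LOST: Impact.HIGH,
    EffectType.CODON_CHANGE_PLUS_CODON_DELETION: Impact.MODERATE,
    EffectType.CODON_CHANGE_PLUS_CODON_INSERTION: Impact.MODERATE,
    EffectType.CODON_DELETION: Impact.MODERATE,
    EffectType.CODON_INSERTION: Impact.MODERATE,
    EffectType.NON_SYNONYMOUS_CODING: Impact.MODERATE,
    EffectType.NON_SYNONYMOUS_START: Impact.LOW,
    EffectType.SPLICE_SITE_REGION: Impact.LOW,
    EffectType.START_GAINED: Impact.LOW,
    EffectType.SYNONYMOUS_CODING: Impact.LOW,
    EffectType.SYNONYMOUS_STOP: Impact.LOW,
    EffectType.DOWNSTREAM: Impact.MODIFIER,
    EffectType.INTERGENIC: Impact.MODIFIER,
    EffectType.INTRAGENIC: Impact.MODIFIER,
    EffectType.INTRON: Impact.MODIFIER,
    EffectType.UPSTREAM: Impact.MODIFIER,
    EffectType.UTR_3_PRIME: Impact.MODIFIER,
    EffectType.UTR_5_PRIME: Impact.MODIFIER,
}

#: most-severe-first ordering used to pick the single reported effect;
#: ties between candidates are broken by list position.
SEVERITY_ORDER: tuple[EffectType, ...] = (
    EffectType.SPLICE_SITE_ACCEPTOR,
    EffectType.SPLICE_SITE_DONOR,
    EffectType.START_LOST,
    EffectType.STOP_GAINED,
    EffectType.STOP_LOST,
    EffectType.FRAME_SHIFT,
    EffectType.NON_SYNONYMOUS_CODING,
    EffectType.CODON_INSERTION,
    EffectType.CODON_CHANGE_PLUS_CODON_INSERTION,
    EffectType.CODON_DELETION,
    EffectType.CODON_CHANGE_PLUS_CODON_DELETION,
    EffectType.NON_SYNONYMOUS_START,
    EffectType.START_GAINED,
    EffectType.SYNONYMOUS_CODING,
    EffectType.SYNONYMOUS_STOP,
    EffectType.SPLICE_SITE_REGION,
    EffectType.UTR_5_PRIME,
    EffectType.UTR_3_PRIME,
    EffectType.UPSTREAM,
    EffectType.DOWNSTREAM,
    EffectType.INTRON,
    EffectType.INTRAGENIC,
    EffectType.INTERGENIC,
)
_SEVERITY_RANK = {e: i for i, e in enumerate(SEVERITY_ORDER)}

#: canonical display order of the 23 types: impact group, then name
TABLE_ORDER: tuple[EffectType, ...] = tuple(
    sorted(EffectType, key=lambda e: (list(Impact).index(IMPACT_OF[e]), e.value))
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def impact_category(effect_type: EffectType | str) -> Impact:
    """Fixed mapping of the 23 effect types onto the 4 impact categories."""
    effect_type = EffectType(effect_type)
    return IMPACT_OF[effect_type]


@dataclass(frozen=True)
class EffectConfig:
    """Distance parameters of the classifier (bp)."""

    upstream_distance: int = 5000
    downstream_distance: int = 5000
    splice_site_size: int = 2
    splice_region_intron: tuple[int, int] = (3, 8)  # 1-based ordinal range
    splice_region_exon: int = 3
    alternative_start_codons: frozenset[str] = frozenset({"CTG", "GTG", "TTG"})


@dataclass
class GeneModel:
    """One transcript of one gene, 1-based inclusive coordinates.

    UTRs are derived from exons minus CDS relative to the strand, so the
    model stays valid for GFF3 inputs without explicit UTR features.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        exonic = set()
        for s, e in self.exons:
            exonic.update(range(s, e + 1))
        for s, e in self.cds:
            if not set(range(s, e + 1)) <= exonic:
                raise ValueError(
                    f"{self.transcript_id}: CDS {s}-{e} not contained in exons"
                )

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def cds_positions(self) -> list[int]:
        """Genomic positions of the CDS in coding (5'->3') order."""
        pos = [p for s, e in self.cds for p in range(s, e + 1)]
        return pos if self.strand == "+" else pos[::-1]

    def utr_positions(self) -> tuple[list[int], list[int]]:
        """(five_prime, three_prime) UTR genomic positions, coding order."""
        exonic = [p for s, e in self.exons for p in range(s, e + 1)]
        cds_set = set(p for s, e in self.cds for p in range(s, e + 1))
        if not cds_set:
            return [], []
        lo, hi = min(cds_set), max(cds_set)
        before = [p for p in exonic if p < lo]
        after = [p for p in exonic if p > hi]
        if self.strand == "+":
            return before, after
        return after[::-1], before[::-1]


@dataclass(frozen=True)
class EffectAssignment:
    """Exactly one effect type + impact category for one variant."""

    key: SiteKey
    line_id: str
    effect_type: EffectType
    impact: Impact
    gene_id: str | None = None


def load_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Load transcripts from a GFF3 file (one GeneModel per mRNA)."""
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [
                (f.start, f.end) for f in db.children(mrna, featuretype="exon")
            ]
            cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
            models.append(
                GeneModel(
                    gene_id=gene.id,
                    transcript_id=mrna.id,
                    chrom=gene.seqid,
                    strand=gene.strand,
                    gene_start=gene.start,
                    gene_end=gene.end,
                    exons=exons or [(mrna.start, mrna.end)],
                    cds=cds,
                )
            )
    return models


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _fetch(sequences, chrom: str, start: int, end: int) -> str:
    """1-based inclusive fetch from a dict of strings or a pyfaidx Fasta."""
    return str(sequences[chrom][start - 1 : end]).upper()


class _TranscriptIndex:
    """Cached per-transcript lookup structures for classification."""

    def __init__(
        self, model: GeneModel, sequences, cfg: "EffectConfig | None" = None
    ) -> None:
        cfg = cfg or EffectConfig()
        self.model = model
        self.exonic: set[int] = set()
        for s, e in model.exons:
            self.exonic.update(range(s, e + 1))
        cds_pos = model.cds_positions()
        self.cds_index = {p: i for i, p in enumerate(cds_pos)}
        self.cds_seq = ""
        if cds_pos:
            raw = _fetch_blocks(sequences, model)  # genomic order
            self.cds_seq = raw if model.strand == "+" else _revcomp(raw)
        utr5, utr3 = model.utr_positions()
        self.utr5_pos = utr5
        self.utr3_pos = utr3
        self.utr5_index = {p: i for i, p in enumerate(utr5)}
        self.utr5_seq = "".join(
            _fetch(sequences, model.chrom, p, p) for p in utr5
        )
        if model.strand == "-":
            self.utr5_seq = str(Seq(self.utr5_seq).complement())
        self.utr3_set = set(utr3)
        # splice machinery
        self.donor: set[int] = set()
        self.acceptor: set[int] = set()
        self.splice_region: set[int] = set()
        site = cfg.splice_site_size
        reg_lo, reg_hi = cfg.splice_region_intron
        reg_ex = cfg.splice_region_exon
        for istart, iend in model.introns():
            if model.strand == "+":
                self.donor.update(range(istart, istart + site))
                self.acceptor.update(range(iend - site + 1, iend + 1))
            else:
                self.donor.update(range(iend - site + 1, iend + 1))
                self.acceptor.update(range(istart, istart + site))
            # intronic splice region: ordinal bases reg_lo..reg_hi from
            # either junction
            self.splice_region.update(
                p
                for p in range(istart + reg_lo - 1, istart + reg_hi)
                if p <= iend
            )
            self.splice_region.update(
                p
                for p in range(iend - reg_hi + 1, iend - reg_lo + 2)
                if p >= istart
            )
            # exonic splice region: outermost exonic bases at the junction
            self.splice_region.update(range(istart - reg_ex, istart))
            self.splice_region.update(range(iend + 1, iend + reg_ex + 1))


def _fetch_blocks(sequences, model: GeneModel) -> str:
    return "".join(
        _fetch(sequences, model.chrom, s, e) for s, e in model.cds
    )


class EffectAnnotator:
    """Classifies variants against gene models and a reference sequence.

    ``sequences`` is any mapping from chromosome name to a sliceable
    sequence (a plain string dict or a ``pyfaidx.Fasta``).
    """

    def __init__(
        self,
        models: Sequence[GeneModel],
        sequences,
        cfg: EffectConfig | None = None,
    ) -> None:
        self.cfg = cfg or EffectConfig()
        self.sequences = sequences
        self._by_chrom: dict[str, list[_TranscriptIndex]] = {}
        for model in models:
            idx = _TranscriptIndex(model, sequences, self.cfg)
            self._by_chrom.setdefault(model.chrom, []).append(idx)

    # -- candidate collection ------------------------------------------

    def _codon_snp_effect(
        self, tx: _TranscriptIndex, pos: int, alt: str
    ) -> EffectType:
        cfg = self.cfg
        model = tx.model
        c = tx.cds_index[pos]
        k, off = divmod(c, 3)
        ref_codon = tx.cds_seq[3 * k : 3 * k + 3]
        alt_base = alt if model.strand == "+" else str(Seq(alt).complement())
        alt_codon = ref_codon[:off] + alt_base + ref_codon[off + 1 :]
        n_codons = len(tx.cds_seq) // 3
        if k == 0 and ref_codon == "ATG":
            if alt_codon in cfg.alternative_start_codons:
                return EffectType.NON_SYNONYMOUS_START
            return EffectType.START_LOST
        if k == n_codons - 1 and ref_codon in STOP_CODONS:
            if alt_codon in STOP_CODONS:
                return EffectType.SYNONYMOUS_STOP
            return EffectType.STOP_LOST
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if alt_aa == "*":
            return EffectType.STOP_GAINED
        if alt_aa == ref_aa:
            return EffectType.SYNONYMOUS_CODING
        return EffectType.NON_SYNONYMOUS_CODING

    def _cds_indel_effect(
        self, tx: _TranscriptIndex, v_pos: int, ref: str, alt: str
    ) -> EffectType:
        if len(alt) > len(ref):  # insertion between v_pos and v_pos + 1
            ins_len = len(alt) - len(ref)
            if ins_len % 3 != 0:
                return EffectType.FRAME_SHIFT
            ca = tx.cds_index.get(v_pos)
            cb = tx.cds_index.get(v_pos + 1)
            if ca is None or cb is None:
                return EffectType.CODON_CHANGE_PLUS_CODON_INSERTION
            c_after = min(ca, cb)
            if (c_after + 1) % 3 == 0:
                return EffectType.CODON_INSERTION
            return EffectType.CODON_CHANGE_PLUS_CODON_INSERTION
        # deletion of ref[1:]
        deleted = range(v_pos + 1, v_pos + len(ref))
        in_cds = sorted(
            tx.cds_index[p] for p in deleted if p in tx.cds_index
        )
        n_codons = len(tx.cds_seq) // 3
        if in_cds and min(in_cds) <= 2:
            return EffectType.START_LOST
        if in_cds and max(in_cds) >= 3 * (n_codons - 1):
            return EffectType.STOP_LOST
        if len(in_cds) % 3 != 0:
            return EffectType.FRAME_SHIFT
        if in_cds and min(in_cds) % 3 == 0 and (max(in_cds) + 1) % 3 == 0:
            return EffectType.CODON_DELETION
        return EffectType.CODON_CHANGE_PLUS_CODON_DELETION

    def _start_gained(self, tx: _TranscriptIndex, pos: int, alt: str) -> bool:
        u = tx.utr5_index.get(pos)
        if u is None:
            return False
        alt_base = (
            alt if tx.model.strand == "+" else str(Seq(alt).complement())
        )
        seq = tx.utr5_seq[:u] + alt_base + tx.utr5_seq[u + 1 :]
        for w in range(max(0, u - 2), min(u, len(seq) - 3) + 1):
            if seq[w : w + 3] == "ATG":
                return True
        return False

    def _transcript_candidates(
        self, tx: _TranscriptIndex, v: VariantCall
    ) -> list[EffectType]:
        cfg = self.cfg
        model = tx.model
        if v.var_type is VarType.SNP:
            affected = [v.pos]
        elif v.var_type is VarType.INS:
            affected = [v.pos, v.pos + 1]
        else:
            affected = list(range(v.pos + 1, v.pos + len(v.ref)))
        a_lo, a_hi = min(affected), max(affected)

        # entirely outside the transcript span
        if a_hi < model.tx_start or a_lo > model.tx_end:
            if model.gene_start <= a_lo and a_hi <= model.gene_end:
                return [EffectType.INTRAGENIC]
            if model.strand == "+":
                up = (model.gene_start - cfg.upstream_distance, model.gene_start - 1)
                down = (model.gene_end + 1, model.gene_end + cfg.downstream_distance)
            else:
                up = (model.gene_end + 1, model.gene_end + cfg.upstream_distance)
                down = (model.gene_start - cfg.downstream_distance,
                        model.gene_start - 1)
            if up[0] <= a_lo and a_hi <= up[1]:
                return [EffectType.UPSTREAM]
            if down[0] <= a_lo and a_hi <= down[1]:
                return [EffectType.DOWNSTREAM]
            return []

        cands: list[EffectType] = []
        aff = set(affected)
        if aff & tx.donor:
            cands.append(EffectType.SPLICE_SITE_DONOR)
        if aff & tx.acceptor:
            cands.append(EffectType.SPLICE_SITE_ACCEPTOR)
        if aff & tx.splice_region:
            cands.append(EffectType.SPLICE_SITE_REGION)

        if v.var_type is VarType.SNP:
            if v.pos in tx.cds_index:
                cands.append(self._codon_snp_effect(tx, v.pos, v.alt))
            elif v.pos in tx.utr5_index:
                if self._start_gained(tx, v.pos, v.alt):
                    cands.append(EffectType.START_GAINED)
                else:
                    cands.append(EffectType.UTR_5_PRIME)
            elif v.pos in tx.utr3_set:
                cands.append(EffectType.UTR_3_PRIME)
            elif v.pos in tx.exonic:
                cands.append(EffectType.INTRAGENIC)  # non-coding exon
            else:
                cands.append(EffectType.INTRON)
        else:
            touches_cds = any(p in tx.cds_index for p in affected)
            if v.var_type is VarType.INS:
                touches_cds = (
                    v.pos in tx.cds_index and (v.pos + 1) in tx.cds_index
                )
            if touches_cds:
                cands.append(self._cds_indel_effect(tx, v.pos, v.ref, v.alt))
            elif aff & set(tx.utr5_index):
                cands.append(EffectType.UTR_5_PRIME)
            elif aff & tx.utr3_set:
                cands.append(EffectType.UTR_3_PRIME)
            elif aff & tx.exonic:
                cands.append(EffectType.INTRAGENIC)
            else:
                cands.append(EffectType.INTRON)
        return cands

    # -- public API ----------------------------------------------------

    def annotate(self, v: VariantCall) -> EffectAssignment:
        """Most severe applicable effect over all overlapping models.

        A chromosome with no gene model yields INTERGENIC.
        """
        best: tuple[int, EffectType, str | None] | None = None
        for tx in self._by_chrom.get(v.chrom, ()):
            for cand in self._transcript_candidates(tx, v):
                rank = _SEVERITY_RANK[cand]
                if best is None or rank < best[0]:
                    best = (rank, cand, tx.model.gene_id)
        if best is None:
            effect, gene_id = EffectType.INTERGENIC, None
        else:
            _, effect, gene_id = best
        return EffectAssignment(
            key=v.key,
            line_id=v.line_id,
            effect_type=effect,
            impact=IMPACT_OF[effect],
            gene_id=gene_id,
        )

    def annotate_all(self, calls: Iterable[VariantCall]) -> list[EffectAssignment]:
        return [self.annotate(v) for v in calls]


def annotate_effect(
    v: VariantCall,
    models: Sequence[GeneModel],
    sequences,
    cfg: EffectConfig | None = None,
) -> EffectAssignment:
    """One-shot classification of a single variant (builds an annotator)."""
    return EffectAnnotator(models, sequences, cfg).annotate(v)


# ---------------------------------------------------------------------
# rollup
# ---------------------------------------------------------------------

@dataclass
class EffectRollup:
    """Per-line effect-type counts plus per-group impact percentages."""

    counts: pd.DataFrame  # index: 23 effect types; columns: lines
    groups: dict[str, tuple[str, ...]]

    @property
    def line_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def impact_counts(self, group: str) -> dict[Impact, int]:
        lines = list(self.groups[group])
        out = {imp: 0 for imp in Impact}
        for effect in self.counts.index:
            out[IMPACT_OF[EffectType(effect)]] += int(
                self.counts.loc[effect, lines].sum()
            )
        return out

    def impact_percentages(self, group: str) -> dict[Impact, float]:
        counts = self.impact_counts(group)
        total = sum(counts.values())
        if total == 0:
            return {imp: 0.0 for imp in Impact}
        return {imp: n / total * 100.0 for imp, n in counts.items()}

    def effect_total(self, effect: EffectType | str) -> int:
        return int(self.counts.loc[EffectType(effect).value].sum())

    def impact_total(self, impact: Impact | str) -> int:
        impact = Impact(impact)
        return sum(
            self.effect_total(e) for e, imp in IMPACT_OF.items() if imp is impact
        )


def rollup_from_counts(
    counts: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> EffectRollup:
    """Build a rollup from an effect-type x line count table.

    The index must use the 23 canonical effect-type names; missing types
    are filled with zero.
    """
    idx = [e.value for e in TABLE_ORDER]
    unknown = set(counts.index) - set(idx)
    if unknown:
        raise ValueError(f"unknown effect types in counts: {sorted(unknown)}")
    full = counts.reindex(idx).fillna(0).astype(int)
    return EffectRollup(
        counts=full,
        groups={g: tuple(lines) for g, lines in groups.items()},
    )


def rollup(
    assignments_by_line: Mapping[str, Sequence[EffectAssignment]],
    groups: Mapping[str, Sequence[str]],
) -> EffectRollup:
    """Tally assignments per line and derive group impact percentages."""
    lines = list(assignments_by_line)
    data = {line: {e.value: 0 for e in TABLE_ORDER} for line in lines}
    for line, assignments in assignments_by_line.items():
        for a in assignments:
            data[line][a.effect_type.value] += 1
    counts = pd.DataFrame(data, columns=lines)
    counts.index.name = "effect_type"
    return rollup_from_counts(counts, groups)


# ---------------------------------------------------------------------
# precomputed annotations (external annotator output)
# ---------------------------------------------------------------------

#: sequence-ontology and classic-annotator spellings of the 23 types
EFFECT_ALIASES: dict[str, EffectType] = {
    **{e.value: e for e in EffectType},
    "synonymous_variant": EffectType.SYNONYMOUS_CODING,
    "missense_variant": EffectType.NON_SYNONYMOUS_CODING,
    "frameshift_variant": EffectType.FRAME_SHIFT,
    "stop_gained": EffectType.STOP_GAINED,
    "stop_lost": EffectType.STOP_LOST,
    "start_lost": EffectType.START_LOST,
    "initiator_codon_variant": EffectType.NON_SYNONYMOUS_START,
    "splice_acceptor_variant": EffectType.SPLICE_SITE_ACCEPTOR,
    "splice_donor_variant": EffectType.SPLICE_SITE_DONOR,
    "splice_region_variant": EffectType.SPLICE_SITE_REGION,
    "stop_retained_variant": EffectType.SYNONYMOUS_STOP,
    "5_prime_UTR_premature_start_codon_gain_variant": EffectType.START_GAINED,
    "5_prime_UTR_variant": EffectType.UTR_5_PRIME,
    "3_prime_UTR_variant": EffectType.UTR_3_PRIME,
    "upstream_gene_variant": EffectType.UPSTREAM,
    "downstream_gene_variant": EffectType.DOWNSTREAM,
    "intron_variant": EffectType.INTRON,
    "intergenic_region": EffectType.INTERGENIC,
    "intergenic_variant": EffectType.INTERGENIC,
    "intragenic_variant": EffectType.INTRAGENIC,
    "conservative_inframe_insertion": EffectType.CODON_INSERTION,
    "disruptive_inframe_insertion":
        EffectType.CODON_CHANGE_PLUS_CODON_INSERTION,
    "conservative_inframe_deletion": EffectType.CODON_DELETION,
    "disruptive_inframe_deletion":
        EffectType.CODON_CHANGE_PLUS_CODON_DELETION,
}


def _resolve_effects(raw: str) -> EffectType:
    """Resolve a possibly multi-valued ('&'-joined) effect string to the
    single most severe known type."""
    parts = [p.strip() for p in raw.split("&") if p.strip()]
    unknown = [p for p in parts if p not in EFFECT_ALIASES]
    if unknown or not parts:
        raise ValueError(f"unknown effect string(s): {unknown or [raw]}")
    return min(
        (EFFECT_ALIASES[p] for p in parts), key=lambda e: _SEVERITY_RANK[e]
    )


def parse_precomputed_annotations(
    path: str | Path, line_id: str | None = None
) -> list[EffectAssignment]:
    """Parse external annotator output into effect assignments.

    Accepts a TSV (columns: line_id, chrom, pos, ref, alt, effect
    [, gene_id]) or a VCF whose records carry an ``ANN`` or ``EFF`` INFO
    field (standard pipe-separated dialect; the second field is the
    annotation). Multi-effect entries keep the single most severe effect.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        import pysam

        if line_id is None:
            line_id = path.stem
        out = []
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                raw = rec.info.get("ANN") or rec.info.get("EFF")
                if raw is None:
                    raise ValueError(f"{path}: record without ANN/EFF field")
                entries = raw if isinstance(raw, (tuple, list)) else [raw]
                effects = []
                for entry in entries:
                    fields = str(entry).split("|")
                    token = fields[1] if len(fields) > 1 else fields[0]
                    effects.append(_resolve_effects(token))
                effect = min(effects, key=lambda e: _SEVERITY_RANK[e])
                for alt in rec.alts or ():
                    out.append(
                        EffectAssignment(
                            key=SiteKey(str(rec.chrom), int(rec.pos),
                                        str(rec.ref), str(alt)),
                            line_id=line_id,
                            effect_type=effect,
                            impact=IMPACT_OF[effect],
                        )
                    )
        return out
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"line_id", "chrom", "pos", "ref", "alt", "effect"}
    if not required <= set(table.columns):
        raise ValueError(
            f"{path}: missing columns {sorted(required - set(table.columns))}"
        )
    errors = []
    out = []
    for row in table.itertuples(index=False):
        try:
            effect = _resolve_effects(str(row.effect))
        except ValueError:
            errors.append(str(row.effect))
            continue
        out.append(
            EffectAssignment(
                key=SiteKey(str(row.chrom), int(row.pos), str(row.ref),
                            str(row.alt)),
                line_id=str(row.line_id),
                effect_type=effect,
                impact=IMPACT_OF[effect],
                gene_id=getattr(row, "gene_id", None),
            )
        )
    if errors:
        raise ValueError(f"{path}: unknown effect strings: {sorted(set(errors))}")
    return out
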