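import pandas as pd
import pytest

from varcohort import datasets
from varcohort.effects import (
    EffectAnnotator,
    EffectType,
    IMPACT_OF,
    Impact,
    impact_category,
    load_gene_models,
    parse_precomputed_annotations,
    rollup,
    rollup_from_counts,
)
from varcohort.variant_model import VariantCall


class TestImpactMapping:
    def test_partition_sizes(self):
        by_impact = {imp: 0 for imp in Impact}
        for effect in EffectType:
            by_impact[IMPACT_OF[effect]] += 1
        assert by_impact == {
            Impact.HIGH: 6, Impact.MODERATE: 5, Impact.LOW: 5,
            Impact.MODIFIER: 7,
        }
        assert len(EffectType) == 23

    @pytest.mark.parametrize(
        "effect,impact",
        [
            ("FRAME_SHIFT", Impact.HIGH),
            ("NON_SYNONYMOUS_CODING", Impact.MODERATE),
            ("SYNONYMOUS_CODING", Impact.LOW),
            ("INTRON", Impact.MODIFIER),
        ],
    )
    def test_examples(self, effect, impact):
        assert impact_category(effect) is impact

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            impact_category("NOT_AN_EFFECT")


@pytest.fixture(scope="module")
def annotator(toy_genes):
    models = load_gene_models(toy_genes.gff3_path)
    return EffectAnnotator(models, toy_genes.sequences)


# module-scoped alias of the session fixture
@pytest.fixture(scope="module")
def toy_genes(tmp_path_factory):
    from varcohort.synthetic_data import simulate_gene_models

    return simulate_gene_models(tmp_path_factory.mktemp("genes_fx"), seed=3)


class TestAnnotator:
    def test_all_planted_variants_get_their_designed_effect(
        self, toy_genes, annotator
    ):
        for r in toy_genes.planted.itertuples(index=False):
            v = VariantCall.make("L", r.chrom, int(r.pos), r.ref, r.alt)
            got = annotator.annotate(v)
            assert got.effect_type.value == r.expected_effect, (
                f"{r.chrom}:{r.pos} {r.ref}>{r.alt} ({r.case})"
            )

    def test_planted_set_covers_every_effect_type(self, toy_genes):
        assert set(toy_genes.planted.expected_effect) == {
            e.value for e in EffectType
        }

    def test_strand_symmetry_of_mirrored_variants(self, toy_genes, annotator):
        mirrored = toy_genes.planted[
            toy_genes.planted.case.str.startswith("mirror")
        ]
        assert len(mirrored) >= 15
        for r in mirrored.itertuples(index=False):
            v = VariantCall.make("L", r.chrom, int(r.pos), r.ref, r.alt)
            assert annotator.annotate(v).effect_type.value == r.expected_effect

    def test_variant_far_from_any_gene_is_intergenic(self, annotator):
        v = VariantCall.make("L", "toyA", 29_000, "A", "C")
        a = annotator.annotate(v)
        assert a.effect_type is EffectType.INTERGENIC and a.gene_id is None


class TestPrecomputedAnnotations:
    def test_tsv_with_ontology_aliases_and_severity_selection(self, tmp_path):
        path = tmp_path / "ann.tsv"
        pd.DataFrame(
            {
                "line_id": ["A", "A"],
                "chrom": ["chr1", "chr1"],
                "pos": [10, 20],
                "ref": ["A", "C"],
                "alt": ["G", "T"],
                "effect": [
                    "synonymous_variant",
                    "missense_variant&splice_region_variant",
                ],
            }
        ).to_csv(path, sep="\t", index=False)
        out = parse_precomputed_annotations(path)
        assert out[0].effect_type is EffectType.SYNONYMOUS_CODING
        assert out[1].effect_type is EffectType.NON_SYNONYMOUS_CODING

    def test_unknown_effect_strings_listed(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame(
            {
                "line_id": ["A"], "chrom": ["chr1"], "pos": [10],
                "ref": ["A"], "alt": ["G"], "effect": ["mystery_effect"],
            }
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="mystery_effect"):
            parse_precomputed_annotations(path)

    def test_rollup_of_parsed_classifier_output_matches_direct(
        self, toy_genes, annotator, tmp_path
    ):
        calls = [
            VariantCall.make("A", r.chrom, int(r.pos), r.ref, r.alt)
            for r in toy_genes.planted.itertuples(index=False)
        ]
        direct = annotator.annotate_all(calls)
        path = tmp_path / "roundtrip.tsv"
        pd.DataFrame(
            {
                "line_id": [a.line_id for a in direct],
                "chrom": [a.key.chrom for a in direct],
                "pos": [a.key.pos for a in direct],
                "ref": [a.key.ref for a in direct],
                "alt": [a.key.alt for a in direct],
                "effect": [a.effect_type.value for a in direct],
            }
        ).to_csv(path, sep="\t", index=False)
        parsed = parse_precomputed_annotations(path)
        groups = {"g": ["A"]}
        assert rollup({"A": parsed}, groups).counts.equals(
            rollup({"A": direct}, groups).counts
        )


class TestRollup:
    def test_single_variant_single_line_is_100_percent(self, annotator):
        v = VariantCall.make("A", "toyA", 1500, "A", "C")
        roll = rollup({"A": [annotator.annotate(v)]}, {"g": ["A"]})
        assert roll.line_totals["A"] == 1
        assert roll.impact_percentages("g")[Impact.MODIFIER] == 100.0

    def test_group_percentages_sum_to_100(self):
        counts = datasets.rice_effect_counts()
        roll = rollup_from_counts(counts, datasets.rice_groups())
        for group in ("transgenic", "wild_type"):
            pct = roll.impact_percentages(group)
            assert sum(pct.values()) == pytest.approx(100.0, abs=0.1)

    def test_unknown_effect_rows_rejected(self):
        bad = pd.DataFrame({"A": [1]}, index=["NOT_A_TYPE"])
        with pytest.raises(ValueError):
            rollup_from_counts(bad, {"g": ["A"]})
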