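import numpy as np
import pytest

from varcohort import datasets
from varcohort.stats import (
    SUBSTITUTIONS,
    TRANSITIONS,
    alignment_summary_stats,
    classify_substitution,
    mutation_rate,
    pool_spectra,
    round_sig,
    spectrum,
    ts_tv_ratio,
)
from varcohort.synthetic_data import spectrum_weights
from varcohort.variant_model import VariantCall


class TestMutationRate:
    @pytest.mark.parametrize(
        "n,length,display",
        [
            (798, 371_762_264, 2.15e-6),
            (619, 371_570_800, 1.67e-6),
            (842, 369_691_614, 2.28e-6),
            (524, 371_589_770, 1.41e-6),
            (826, 371_575_970, 2.22e-6),
        ],
    )
    def test_line_rates_match_published_display(self, n, length, display):
        assert round_sig(mutation_rate(n, length)) == pytest.approx(display)

    def test_zero_variants_and_zero_length(self):
        assert mutation_rate(0, 12345) == 0.0
        with pytest.raises(ValueError):
            mutation_rate(10, 0)

    def test_rate_is_scale_invariant(self):
        assert mutation_rate(100, 1_000_000) == mutation_rate(200, 2_000_000)


class TestSubstitutions:
    def test_transition_transversion_examples(self):
        assert classify_substitution("G", "A")[0] == "transition"
        assert classify_substitution("G", "T")[0] == "transversion"

    def test_exactly_four_of_twelve_are_transitions(self):
        kinds = [classify_substitution(r, a)[0] for r, a in SUBSTITUTIONS]
        assert kinds.count("transition") == 4
        assert kinds.count("transversion") == 8

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("N", "A")


def _snp(sub, pos):
    return VariantCall.make("L", "chr1", pos, sub[0], sub[1])


class TestSpectrum:
    def test_empty_input_gives_zero_spectrum(self):
        s = spectrum([])
        assert s.total == 0 and all(v == 0 for v in s.counts.values())

    def test_planted_counts(self):
        calls = (
            [_snp(("G", "T"), 10 * i) for i in range(1, 5)]
            + [_snp(("C", "A"), 100 + 10 * i) for i in range(1, 5)]
            + [_snp(("G", "A"), 200 + 10 * i) for i in range(1, 3)]
        )
        s = spectrum(calls)
        assert s.tv_count == 8 and s.ts_count == 2
        assert sum(s.counts.values()) == 10

    def test_indels_skipped_with_count(self):
        calls = [
            _snp(("A", "G"), 10),
            VariantCall.make("L", "chr1", 20, "A", "AT"),
        ]
        s = spectrum(calls)
        assert s.total == 1 and s.n_skipped_non_snp == 1

    def test_ratio_conventions(self):
        s = spectrum([_snp(("A", "G"), 10), _snp(("A", "C"), 20)])
        assert ts_tv_ratio(s) == 1.0
        s = spectrum([_snp(("A", "C"), 10)])
        assert ts_tv_ratio(s) == 0.0
        s = spectrum([_snp(("A", "G"), 10)])
        assert ts_tv_ratio(s) is None  # no transversions: undefined

    @pytest.mark.parametrize("target", [1.12, 1.65])
    def test_configured_ratio_recovered_at_scale(self, target):
        """Sampling 10,000 substitutions from a weighted spectrum recovers
        the configured Ts/Tv within 3 binomial standard errors."""
        rng = np.random.default_rng(42)
        weights = spectrum_weights(target)
        subs = list(weights)
        p = np.array([weights[s] for s in subs])
        n = 10_000
        draws = rng.choice(len(subs), size=n, p=p)
        calls = [_snp(subs[i], 10 * (j + 1)) for j, i in enumerate(draws)]
        s = spectrum(calls)
        p_ts_target = target / (1 + target)
        se = np.sqrt(p_ts_target * (1 - p_ts_target) / n)
        assert s.ts_count / n == pytest.approx(p_ts_target, abs=3 * se)

    def test_pooling_commutes_with_averaging_for_equal_counts(self):
        a = spectrum([_snp(("A", "G"), 10), _snp(("A", "C"), 20)])
        b = spectrum([_snp(("G", "A"), 10), _snp(("G", "T"), 20)])
        pooled = pool_spectra([a, b])
        assert pooled.total == a.total + b.total
        # ratio of pooled counts equals ratio of mean counts
        assert ts_tv_ratio(pooled) == (
            (a.ts_count + b.ts_count) / 2
        ) / ((a.tv_count + b.tv_count) / 2)


class TestAlignmentStats:
    def test_published_line_statistics(self):
        genome = datasets.rice_genome_index()
        summary = datasets.rice_alignment_summaries()["50A"]
        st = alignment_summary_stats(summary, genome)
        assert round(st.mapping_rate, 1) == 97.8
        assert round(st.coverage_rate, 1) == 99.6
        # by the printed formula: mapped reads x 100 bp / covered length
        assert round(st.depth, 1) == 101.1

    def test_zero_denominator_rejected(self, toy_genome):
        from varcohort.genome_io import AlignmentSummary

        bad = AlignmentSummary("L", 10, 0, 100, 0)
        with pytest.raises(ValueError):
            alignment_summary_stats(bad, toy_genome)
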