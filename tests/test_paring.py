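import numpy as np
import pytest

from cldmerge import (CLD, DematelScores, MergedMatrix, ParingConfig,
                      apply_edge_cut, apply_variable_cut, frequencies,
                      frequency, merge, pare, restore_polarity, sensitivity,
                      suggest_cut)
from cldmerge.paring import ParingError


def _scores(values, labels=None):
    labels = labels or tuple(f"v{i}" for i in range(len(values)))
    values = np.asarray(values, dtype=float)
    return DematelScores(index=tuple(labels), R=values / 2, C=values / 2)


class TestVariableCut:
    def test_inclusive_threshold(self):
        scores = _scores([2.0, 1.0, 0.5])
        assert apply_variable_cut(scores, 1.0) == ("v0", "v1")

    def test_cut_zero_retains_everything(self, ref_scores):
        assert len(apply_variable_cut(ref_scores, 1e-9)) == 23

    def test_unretainable_cut_raises_advice(self):
        with pytest.raises(ParingError, match="lower the cut"):
            apply_variable_cut(_scores([0.5, 0.4]), 10.0)

    def test_monotone_nesting_over_sweep(self, ref_scores):
        previous = None
        for cut in np.linspace(0.5, 4.5, 17):
            try:
                retained = set(apply_variable_cut(ref_scores, cut))
            except ParingError:
                retained = set()
            if previous is not None:
                assert retained <= previous
            previous = retained


class TestSuggestCut:
    def test_single_dominant_gap(self):
        suggestion = suggest_cut(_scores([4.4, 4.0, 0.2, 0.1]))
        assert suggestion == pytest.approx(2.1)
        assert 0.2 < suggestion < 4.0

    def test_uniform_prominence_degenerate(self, caplog):
        with caplog.at_level("WARNING"):
            suggestion = suggest_cut(_scores([1.5, 1.5, 1.5]))
        assert suggestion == 1.5

    def test_needs_three_variables(self):
        with pytest.raises(ParingError):
            suggest_cut(_scores([1.0, 2.0]))

    def test_separates_planted_core_from_noise(self):
        from cldmerge import (CLDCollation, canonical_key, generate_ensemble)
        clds, truth, vocab = generate_ensemble(seed=5)
        res = CLDCollation(clds, vocabulary=vocab).fit()
        retained = {canonical_key(v) for v in res.summary_cld.variables}
        assert retained <= truth.core_variable_keys
        assert len(retained) >= 0.8 * len(truth.core_variable_keys)


class TestSensitivity:
    def test_zero_delta_changes_nothing(self, ref_scores):
        result = sensitivity(ref_scores, 1.0, deltas=(0.0,))
        rec = result.for_delta(0.0)
        assert rec["excluded"] == [] and rec["included"] == []

    def test_plus_five_percent_excludes_only_sleep(self, ref_scores):
        rec = sensitivity(ref_scores, 1.0, deltas=(0.05,)).for_delta(0.05)
        assert rec["excluded"] == ["Sleep"] and rec["included"] == []

    def test_plus_ten_percent_excludes_sleep_and_substance_use(self, ref_scores):
        rec = sensitivity(ref_scores, 1.0, deltas=(0.10,)).for_delta(0.10)
        assert set(rec["excluded"]) == {"Sleep", "Alcohol and other substance use"}
        assert rec["included"] == []

    def test_minus_deltas_include_nothing_new(self, ref_scores):
        result = sensitivity(ref_scores, 1.0, deltas=(-0.05, -0.10))
        for delta in (-0.05, -0.10):
            assert result.for_delta(delta)["included"] == []
            assert result.for_delta(delta)["excluded"] == []

    def test_thresholds_multiplicative(self, ref_scores):
        result = sensitivity(ref_scores, 1.0, deltas=(-0.15, 0.15))
        assert result.for_delta(0.15)["threshold"] == pytest.approx(1.15)
        assert result.for_delta(-0.15)["threshold"] == pytest.approx(0.85)


class TestEdgeCutAndPolarity:
    @pytest.fixture
    def merged(self):
        cells = np.array([
            [0, 1, 2, 0],
            [0, 0, -3, 0],
            [0, 0, 0, 1],
            [2, 0, 0, 0],
        ])
        return MergedMatrix(index=("a", "b", "c", "d"), cells=cells, n_clds=3)

    def test_min_count_two_drops_single_diagram_links(self, merged):
        summary = apply_edge_cut(merged, ("a", "b", "c", "d"), 2)
        kept = {(l.source, l.target): l.count for l in summary.links}
        assert kept == {("a", "c"): 2, ("b", "c"): 3, ("d", "a"): 2}

    def test_min_count_one_is_induced_subgraph(self, merged):
        summary = apply_edge_cut(merged, ("a", "b", "c", "d"), 1)
        assert len(summary.links) == merged.n_links

    def test_variable_cut_applied_before_edge_cut(self, merged):
        summary = apply_edge_cut(merged, ("a", "c"), 2)
        assert {(l.source, l.target) for l in summary.links} == {("a", "c")}

    def test_retained_variable_missing_from_index(self, merged):
        with pytest.raises(ParingError, match="not in merged index"):
            apply_edge_cut(merged, ("a", "nope"), 2)

    def test_restore_polarity_signs(self, merged):
        summary = apply_edge_cut(merged, ("a", "b", "c", "d"), 2)
        restored = restore_polarity(summary, merged)
        polarity = {(l.source, l.target): l.polarity for l in restored.links}
        assert polarity == {("a", "c"): 1, ("b", "c"): -1, ("d", "a"): 1}

    def test_restore_polarity_integrity_error_on_zero_cell(self, merged):
        from cldmerge.paring import SummaryCLD, SummaryLink
        bogus = SummaryCLD(variables=("a", "b"),
                           links=(SummaryLink("a", "b", count=2),))
        zeroed = MergedMatrix(index=("a", "b"),
                              cells=np.zeros((2, 2), dtype=int), n_clds=3)
        with pytest.raises(ParingError, match="zero merged cell"):
            restore_polarity(bogus, zeroed)

    def test_isolated_retained_variables_flagged(self, merged):
        summary = apply_edge_cut(merged, ("a", "b", "c", "d"), 3)
        assert set(summary.isolated_variables) == {"a", "d"}
        assert set(summary.variables) == {"a", "b", "c", "d"}

    def test_empty_summary_allowed_with_warning(self, merged, caplog):
        with caplog.at_level("WARNING"):
            summary = apply_edge_cut(merged, ("a", "b"), 5)
        assert summary.links == ()


class TestFrequency:
    def test_counts_presence_in_node_sets(self):
        clds = [CLD(f"c{i}", variables=["shared"]) for i in range(12)]
        clds.append(CLD("c13", variables=["other"]))
        assert frequency(clds, "shared") == 12
        assert frequency(clds, "absent everywhere") == 0

    def test_link_counts_bounded_by_endpoint_frequency(self):
        clds = [CLD(f"c{i}", links=[("a", "b", 1)]) for i in range(4)]
        clds.append(CLD("c5", variables=["a"]))
        merged = merge(clds)
        freq = frequencies(clds)
        for i, src in enumerate(merged.index):
            for j, tgt in enumerate(merged.index):
                if merged.cells[i, j]:
                    bound = min(freq[src.casefold()], freq[tgt.casefold()])
                    assert abs(int(merged.cells[i, j])) <= bound


class TestPipelineIdempotence:
    def test_paring_already_pared_summary_changes_nothing(self):
        clds = [CLD(f"c{i}", links=[("a", "b", 1), ("b", "c", -1), ("c", "a", 1)])
                for i in range(3)]
        clds.append(CLD("extra", links=[("a", "d", 1)]))
        merged = merge(clds)
        from cldmerge import dematel_scores, strip_polarity
        scores = dematel_scores(strip_polarity(merged))
        config = ParingConfig(variable_cut=suggest_cut(scores), edge_min_count=2)
        summary = pare(merged, scores, config, clds=clds)

        matrix2 = summary.to_merged_matrix(merged.n_clds)
        scores2 = dematel_scores(strip_polarity(matrix2))
        summary2 = pare(matrix2, scores2, ParingConfig(
            variable_cut=min(scores2.prominence), edge_min_count=2))
        assert set(summary2.link_keys) == set(summary.link_keys)
        assert {v.casefold() for v in summary2.variables} == \
            {v.casefold() for v in summary.variables}

    def test_config_validation(self):
        with pytest.raises(ParingError):
            ParingConfig(variable_cut=0.0)
        with pytest.raises(ParingError):
            ParingConfig(edge_min_count=0)
        with pytest.raises(ParingError):
            ParingConfig(sensitivity_deltas=(1.5,))
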