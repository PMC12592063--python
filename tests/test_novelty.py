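"""Novelty indicators, prediction strategies, and backtest formulas."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from themetrace import clustering as tc, novelty as nov
from themetrace.errors import ConfigurationError


def cn(cluster_id, score, topic, phase="p"):
    return nov.ClusterNovelty(phase, cluster_id, score, 1, topic)


def profile(cluster_id, topic, phase="p"):
    return tc.ClusterProfile(phase, cluster_id, 1, (topic, 1.0), "d", (), np.array([1.0]))


class TestClusterNovelty:
    def test_simple_mean(self):
        assert nov.cluster_novelty([2020, 2024]) == pytest.approx(2022.0)

    def test_constant_years(self):
        assert nov.cluster_novelty([1999] * 3) == pytest.approx(1999.0)

    def test_multiset_mean(self):
        years = [2020] * 10 + [2021] * 6 + [2022] * 7 + [2023] * 10 + [2024] * 10
        brute = sum(years) / len(years)
        assert nov.cluster_novelty(years) == pytest.approx(brute)
        assert round(nov.cluster_novelty(years), 3) == 2022.093

    def test_empty_cluster(self):
        with pytest.raises(ValueError):
            nov.cluster_novelty([])

    @given(st.lists(st.integers(min_value=1990, max_value=2030), min_size=1, max_size=40),
           st.integers(min_value=-50, max_value=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_and_shift_equivariant(self, years, c):
        score = nov.cluster_novelty(years)
        assert min(years) <= score <= max(years)
        assert nov.cluster_novelty([y + c for y in years]) == pytest.approx(score + c)


class TestTopicNovelty:
    def _members(self, rows):
        return [(f"d{i}", y, np.asarray(theta, dtype=float)) for i, (y, theta) in enumerate(rows)]

    def test_all_members_include_topic(self):
        members = self._members([(2021, [0.9, 0.1]), (2023, [0.8, 0.2])])
        cell = nov.topic_novelty(members, 0)
        assert cell.score == pytest.approx(2022.0)
        assert cell.n_members == 2

    def test_no_member_includes_topic_is_undefined(self):
        # top5 of a 2-topic theta always contains both topics; use the
        # threshold rule to create a non-qualifying topic
        members = self._members([(2021, [0.95, 0.05])])
        cell = nov.topic_novelty(members, 1, inclusion_rule="threshold", theta_threshold=0.1)
        assert cell.score is None and cell.n_members == 0

    def test_filter_then_mean(self):
        """5 members, 3 qualify with years 2020/2022/2024 -> mean 2022, n=3."""
        K = 7
        def theta(top):
            t = np.full(K, 0.01)
            t[top] = 1 - 0.01 * (K - 1)
            return t
        members = self._members([
            (2020, theta(3)), (2022, theta(3)), (2024, theta(3)),
            (2021, theta(6)), (2023, theta(6)),
        ])
        cell = nov.topic_novelty(members, 3, inclusion_rule="threshold", theta_threshold=0.1)
        assert cell.score == pytest.approx(2022.0)
        assert cell.n_members == 3

    def test_weight_share_is_cluster_mean_theta(self):
        members = self._members([(2020, [0.6, 0.4]), (2022, [0.2, 0.8])])
        cell = nov.topic_novelty(members, 1)
        assert cell.weight_share == pytest.approx(0.6)


class TestPredictNovelTopics:
    def test_single_cluster_empty_under_strict_mean(self):
        assert nov.predict_novel_topics([cn(0, 2022.5, 4)]) == frozenset()

    def test_above_mean_rule(self):
        got = nov.predict_novel_topics([cn(0, 2022.5, 4), cn(1, 2021.0, 2)])
        assert got == {4}

    def test_top_m_strategy(self):
        ns = [cn(0, 2022.0, 1), cn(1, 2023.0, 2), cn(2, 2021.0, 3)]
        assert nov.predict_novel_topics(ns, strategy="top_m", top_m=2) == {1, 2}

    def test_year_threshold_strategy(self):
        ns = [cn(0, 2022.0, 1), cn(1, 2023.0, 2)]
        got = nov.predict_novel_topics(ns, strategy="year_threshold", year_threshold=2022.5)
        assert got == {2}

    def test_unknown_strategy_lists_options(self):
        with pytest.raises(ConfigurationError, match="above_mean"):
            nov.predict_novel_topics([cn(0, 2022.0, 1)], strategy="nope")


class TestBacktest:
    ORDER = ["p1", "p2"]

    def _run(self, train_scores_topics, actual_topics, **kw):
        ns = [cn(i, s, t, phase="p1") for i, (s, t) in enumerate(train_scores_topics)]
        profs = [profile(i, t, phase="p2") for i, t in enumerate(actual_topics)]
        return nov.backtest(ns, profs, self.ORDER, **kw)

    def test_perfect_prediction(self):
        # three high-novelty clusters predicting exactly the next phase's topics
        r = self._run([(2003, 0), (2002, 2), (2002.5, 4), (1996, 7), (1995, 8)], [0, 2, 4])
        assert r.predicted_topics == {0, 2, 4}
        assert r.precision == pytest.approx(1.0) and r.recall == pytest.approx(1.0)

    def test_hand_enumerated_sets(self):
        """predicted {1..7} vs actual {1,2,3,4,9}: precision 4/7, recall 4/5."""
        train = [(2003 + i * 0.1, t) for i, t in enumerate(range(1, 8))] + [(1990, 0)]
        r = self._run(train, [1, 2, 3, 4, 9])
        assert r.predicted_topics == set(range(1, 8))
        assert r.precision == pytest.approx(4 / 7)
        assert r.recall == pytest.approx(4 / 5)

    def test_empty_prediction_degenerate_rules(self):
        r = self._run([(2000, 1)], [1])  # single cluster -> empty prediction
        assert r.predicted_topics == frozenset()
        assert r.precision is None
        assert r.recall == 0.0

    def test_non_adjacent_phases_rejected(self):
        ns = [cn(0, 2000, 1, phase="p1")]
        profs = [profile(0, 1, phase="p3")]
        with pytest.raises(ConfigurationError, match="consecutive"):
            nov.backtest(ns, profs, ["p1", "p2", "p3"])

    def test_oracle_equivalence_random_sets(self):
        """precision/recall match exhaustive set computation on random
        predicted/actual pairs over a 9-topic universe."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            predicted = set(rng.choice(9, size=rng.integers(0, 6), replace=False).tolist())
            actual = set(rng.choice(9, size=rng.integers(1, 6), replace=False).tolist())
            train = [(2005.0 + i, int(t)) for i, t in enumerate(sorted(predicted))]
            train.append((1900.0, 0))  # anchor keeps the mean below every real score
            r = self._run(train, sorted(actual))
            inter = len(predicted & actual)
            if predicted:
                assert r.predicted_topics == predicted
                assert r.precision == pytest.approx(inter / len(predicted))
            else:
                assert r.precision is None
            assert r.recall == pytest.approx(inter / len(actual))


class TestSunburstTable:
    def test_single_cell(self):
        cells = [nov.TopicNoveltyCell("p", 0, 0, 2022.0, 3, 1.0)]
        rows = nov.sunburst_table([profile(0, 0)], cells)
        assert len(rows) == 1
        assert rows[0]["weight_share"] == pytest.approx(1.0)

    def test_undefined_cells_omitted(self):
        cells = [nov.TopicNoveltyCell("p", 0, 0, 2022.0, 3, 0.7),
                 nov.TopicNoveltyCell("p", 0, 1, None, 0, 0.3)]
        rows = nov.sunburst_table([profile(0, 0)], cells)
        assert [r["topic_id"] for r in rows] == [0]

    def test_row_count_equals_defined_cells(self):
        rng = np.random.default_rng(0)
        cells = [
            nov.TopicNoveltyCell("p", c, t, 2020.0 if rng.random() < 0.6 else None,
                                 1, 0.1)
            for c in range(4) for t in range(5)
        ]
        rows = nov.sunburst_table([], cells)
        assert len(rows) == sum(1 for c in cells if c.score is not None)
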