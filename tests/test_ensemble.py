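"""Ensemble pooling, conditional-precision estimation and scoring."""

import itertools

import numpy as np
import pytest

from chemner.corpus import EntityMention
from chemner.ensemble import (
    ConditionalTable,
    EnsembleCombiner,
    ExtractorOutput,
    apply_threshold,
    estimate_table,
    pool_candidates,
    pr_curve,
    score,
    score_outputs,
)
from chemner.synthetic import SimulationSpec, simulate_extractors


def _span(i):
    return (f"d{i}", "A", 10 * i, 10 * i + 3)


def _out(name, ids):
    return ExtractorOutput(name, frozenset(_span(i) for i in ids))


def brute_force_precision(outputs, gold, sig):
    """Independent oracle: materialize Y by explicit set algebra.

    Y intersects the firing extractors' span sets and subtracts the
    silent ones'; the estimate is |Y ∩ gold| / |Y|, or None if Y is empty.
    """
    firing = [o.spans for o, b in zip(outputs, sig) if b]
    silent = [o.spans for o, b in zip(outputs, sig) if not b]
    y = set.intersection(*(set(s) for s in firing)) if firing else set()
    for s in silent:
        y -= s
    if not y:
        return None
    return len(y & gold) / len(y)


class TestPoolCandidates:
    def test_signatures_from_two_extractors(self):
        a, b, c = _span(1), _span(2), _span(3)
        cands = dict(pool_candidates([_out("e1", [1, 2]), _out("e2", [1, 3])]))
        assert cands == {a: (1, 1), b: (1, 0), c: (0, 1)}

    def test_identical_outputs_all_ones(self):
        cands = pool_candidates([_out("e1", [1, 2]), _out("e2", [1, 2])])
        assert all(sig == (1, 1) for _, sig in cands)

    def test_single_empty_extractor(self):
        assert pool_candidates([_out("e1", [])]) == []

    def test_zero_extractors_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            pool_candidates([])

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            pool_candidates([_out("e", [1]), _out("e", [2])])


class TestEstimateTable:
    def test_hand_worked_two_extractor_example(self):
        # gold={a,b,c}; E1={a,b,d}; E2={a,d,e}
        gold = {_span(i) for i in (1, 2, 3)}
        table = estimate_table(
            [_out("e1", [1, 2, 4]), _out("e2", [1, 4, 5])], gold
        )
        assert table.probability((1, 1)) == 0.5   # {a,d}, a gold
        assert table.probability((1, 0)) == 1.0   # {b}
        assert table.probability((0, 1)) == 0.0   # {e}

    def test_single_extractor_equal_to_gold(self):
        gold = {_span(1), _span(2)}
        table = estimate_table([_out("e1", [1, 2])], gold)
        assert table.probability((1,)) == 1.0

    def test_three_extractors_at_most_seven_cells(self):
        rng = np.random.default_rng(4)
        outs = [
            _out(f"e{i}", rng.choice(30, size=15, replace=False)) for i in range(3)
        ]
        gold = {_span(i) for i in rng.choice(30, size=10, replace=False)}
        table = estimate_table(outs, gold)
        assert table.n_estimable == 7
        assert len(table.cells) <= 7
        assert (0, 0, 0) not in table.cells

    def test_candidate_counts_partition_pool(self):
        outs = [_out("e1", [1, 2, 4]), _out("e2", [1, 4, 5])]
        table = estimate_table(outs, {_span(1)})
        assert sum(c for c, _ in table.cells.values()) == len(
            pool_candidates(outs)
        )

    def test_empty_gold_gives_zero_probabilities(self):
        table = estimate_table([_out("e1", [1, 2])], set())
        assert table.probability((1,)) == 0.0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty candidate pool"):
            estimate_table([_out("e1", [])], set())

    def test_matches_brute_force_oracle_on_random_instances(self):
        """Estimation equals explicit intersection/difference set algebra."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(1, 5))
            universe = int(rng.integers(4, 51))
            outs = [
                _out(f"e{i}",
                     rng.choice(universe,
                                size=int(rng.integers(1, universe + 1)),
                                replace=False))
                for i in range(n)
            ]
            if not any(o.spans for o in outs):
                continue
            gold = {
                _span(i)
                for i in rng.choice(universe,
                                    size=int(rng.integers(0, universe + 1)),
                                    replace=False)
            }
            table = estimate_table(outs, gold)
            for sig in itertools.product((0, 1), repeat=n):
                if not any(sig):
                    continue
                expected = brute_force_precision(outs, gold, sig)
                assert table.probability(sig) == expected


class TestScore:
    def _paper_style_table(self):
        """A 3-extractor table whose probabilities reproduce the published
        dev-set estimates at the printed precision (hits per 100000)."""
        order = ("chemxseer", "oscar", "chemspot")
        probs = {
            (1, 0, 0): 0.25200, (0, 1, 0): 0.08900, (0, 0, 1): 0.24900,
            (1, 1, 0): 0.82083, (1, 0, 1): 0.72799, (0, 1, 1): 0.55869,
            (1, 1, 1): 0.93316,
        }
        cells = {s: (100000, int(round(p * 100000))) for s, p in probs.items()}
        return ConditionalTable(order, cells)

    def test_published_confidences_reproduced(self):
        table = self._paper_style_table()
        scored = score(
            [(_span(1), (0, 1, 1)), (_span(2), (1, 1, 1))], table
        )
        assert scored[0].confidence == pytest.approx(0.55869)
        assert scored[1].confidence == pytest.approx(0.93316)

    def test_missing_cell_fallback_zero(self):
        table = ConditionalTable(("a", "b"), {(1, 0): (10, 5)})
        [c] = score([(_span(1), (1, 1))], table, fallback="zero")
        assert c.confidence == 0.0

    def test_missing_cell_fallback_mean_singles(self):
        table = ConditionalTable(
            ("a", "b"), {(1, 0): (10, 8), (0, 1): (10, 4)}
        )
        [c] = score([(_span(1), (1, 1))], table)  # mean of 0.8 and 0.4
        assert c.confidence == pytest.approx(0.6)

    def test_missing_cell_fallback_error(self):
        table = ConditionalTable(("a", "b"), {(1, 0): (10, 5)})
        with pytest.raises(KeyError):
            score([(_span(1), (1, 1))], table, fallback="error")

    def test_signature_length_mismatch(self):
        table = ConditionalTable(("a", "b"), {(1, 0): (10, 5)})
        with pytest.raises(ValueError, match="signature length"):
            score([(_span(1), (1, 1, 0))], table)

    def test_extractor_order_mismatch(self):
        table = ConditionalTable(("a", "b"), {(1, 0): (10, 5)})
        with pytest.raises(ValueError, match="order mismatch"):
            score_outputs([_out("b", [1]), _out("a", [2])], table)


class TestThresholdAndCurve:
    def _scored_toy(self):
        gold = {_span(i) for i in (1, 2, 3)}
        outs = [_out("e1", [1, 2, 4]), _out("e2", [1, 4, 5])]
        results = EnsembleCombiner(outs, gold).fit()
        return results, gold

    def test_tau_bounds(self):
        results, _ = self._scored_toy()
        scored = results.score()
        assert len(apply_threshold(scored, 0.0)) == len(scored)
        assert all(c.confidence == 1.0 for c in apply_threshold(scored, 1.0))
        with pytest.raises(ValueError):
            apply_threshold(scored, 1.5)

    def test_midpoint_threshold(self):
        scored = [s for s in self._scored_toy()[0].score()]
        confs = sorted(c.confidence for c in scored)
        retained = apply_threshold(scored, 0.6)
        # cells: (1,1)->0.5 on {a,d}; (1,0)->1.0 on {b}; (0,1)->0.0 on {e}
        assert {c.span for c in retained} == {_span(2)}

    def test_toy_curve_row(self):
        results, gold = self._scored_toy()
        rows = {tau: (p, r) for tau, p, r, _ in results.pr_curve()}
        # above the 0.5 cell only {b} (confidence 1.0) survives
        assert rows[1.0] == (1.0, pytest.approx(1 / 3))
        assert set(rows) == {0.0, 0.5, 1.0}

    def test_recall_non_increasing_in_tau(self):
        results, gold = self._scored_toy()
        rows = results.pr_curve()
        recalls = [r for _, _, r, _ in rows]
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))

    def test_perfect_predictions_all_rows_perfect(self):
        gold = {_span(i) for i in (1, 2)}
        results = EnsembleCombiner([_out("e1", [1, 2])], gold).fit()
        for tau, p, r, f1 in results.pr_curve():
            if tau <= 1.0 and r > 0:
                assert p == r == f1 == 1.0


class TestSelfConsistency:
    def test_retained_precision_at_least_tau_on_estimation_corpus(self):
        """Every retained set scored on its own estimation corpus keeps
        precision >= tau — the combiner's calibration guarantee."""
        for seed in range(25):
            spec = SimulationSpec.full_table(
                ["a", "b", "c"], count_per_cell=40, mode="stochastic", seed=seed
            )
            outputs, gold, _ = simulate_extractors(spec, seed=seed)
            results = EnsembleCombiner(outputs, gold).fit()
            scored = results.score()
            for tau in sorted({c.confidence for c in scored}):
                retained = {c.span for c in apply_threshold(scored, tau)}
                if retained:
                    precision = len(retained & gold) / len(retained)
                    assert precision >= tau - 1e-12

    def test_recall_at_zero_equals_union_recall(self):
        spec = SimulationSpec.full_table(
            ["a", "b"], count_per_cell=50, mode="stochastic", seed=7
        )
        outputs, gold, _ = simulate_extractors(spec, seed=7)
        results = EnsembleCombiner(outputs, gold).fit()
        rows = results.pr_curve()
        union = set().union(*(o.spans for o in outputs))
        union_recall = len(union & gold) / len(gold)
        assert rows[0][2] == pytest.approx(union_recall)


class TestTableSerialization:
    def test_tsv_round_trip(self, tmp_path):
        table = estimate_table(
            [_out("e1", [1, 2, 4]), _out("e2", [1, 4, 5])],
            {_span(i) for i in (1, 2, 3)},
        )
        path = tmp_path / "table.tsv"
        table.to_tsv(path)
        back = ConditionalTable.from_tsv(path)
        assert back.extractor_order == table.extractor_order
        assert back.cells == table.cells

    def test_from_tsv_rejects_other_files(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("a\tb\tc\n1\t2\t3\n")
        with pytest.raises(ValueError, match="not a conditional table"):
            ConditionalTable.from_tsv(path)

    def test_smoothing_changes_probability_but_not_counts(self):
        table = ConditionalTable(("a",), {(1,): (10, 10)}, smoothing=1.0)
        assert table.probability((1,)) == pytest.approx(11 / 12)
        assert table.cells[(1,)] == (10, 10)
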