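"""Preprocessing rules, summaries, vincentiles and repetition effects."""

import numpy as np
import pandas as pd
import pytest

from lexddm.summaries import (
    condition_summaries,
    group_data,
    per_subject_quantiles,
    preprocess,
    quantiles,
    repetition_effects,
    transform_rt,
    vincentize,
)


def make_trials(rows):
    """rows: (subject, lexicality, repetition, correct, rt_ms[, block])"""
    recs = []
    for i, r in enumerate(rows):
        block = r[5] if len(r) > 5 else 2
        lex = r[1]
        recs.append(
            {
                "subject_id": r[0],
                "item_id": f"i{i:03d}",
                "block": block,
                "lexicality": lex,
                "repetition": r[2],
                "response": lex if r[3] else ("nonword" if lex == "word" else "word"),
                "correct": r[3],
                "rt_ms": r[4],
            }
        )
    return pd.DataFrame(recs)


class TestPreprocess:
    def test_fast_correct_trial_leaves_rt_set_but_not_accuracy_set(self):
        trials = make_trials([("s1", "word", "repeated", True, 200.0)])
        rt_set, acc_set, rep = preprocess(trials)
        assert len(rt_set) == 0 and len(acc_set) == 1
        assert rep.n_fast == 1 and rep.n_slow == 0

    def test_error_trial_excluded_from_rt_set_only(self):
        trials = make_trials([("s1", "word", "repeated", False, 800.0)])
        rt_set, acc_set, rep = preprocess(trials)
        assert len(rt_set) == 0 and len(acc_set) == 1
        assert rep.n_errors == 1

    def test_block1_trials_dropped_entirely(self):
        trials = make_trials(
            [("s1", "word", "nonrepeated", True, 500.0, 1), ("s1", "word", "repeated", True, 500.0, 2)]
        )
        rt_set, acc_set, _ = preprocess(trials)
        assert len(acc_set) == 1 and len(rt_set) == 1

    def test_all_valid_input_keeps_every_correct_trial(self):
        trials = make_trials([("s1", "word", "repeated", True, 400.0 + 10 * i) for i in range(20)])
        rt_set, _, rep = preprocess(trials)
        assert len(rt_set) == 20 == rep.n_rt_set

    def test_empty_input(self):
        rt_set, acc_set, rep = preprocess(make_trials([]).reindex(columns=["subject_id", "block", "correct", "rt_ms"]))
        assert len(rt_set) == 0 and rep.n_block2 == 0 and rep.prop_errors == 0.0


class TestTransformRT:
    @pytest.mark.parametrize("rt,expected", [(500.0, -2.0), (1000.0, -1.0), (250.0, -4.0)])
    def test_reciprocal_values(self, rt, expected):
        assert transform_rt(rt) == pytest.approx(expected)

    def test_monotone_in_rt(self):
        rts = np.array([260.0, 300.0, 512.0, 777.0, 1499.0])
        assert np.all(np.diff(transform_rt(rts)) > 0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            transform_rt(0.0)


class TestConditionSummaries:
    def test_mean_of_simple_cell(self):
        trials = make_trials([("s1", "word", "repeated", True, rt) for rt in (400.0, 500.0, 600.0)])
        rt_set, acc_set, _ = preprocess(trials)
        s = [x for x in condition_summaries(rt_set, acc_set) if x.condition == ("word", "repeated")][0]
        assert s.mean_rt_ms == pytest.approx(500.0)
        assert s.accuracy == 1.0

    def test_single_trial_cell_has_flat_quantiles(self):
        trials = make_trials([("s1", "nonword", "nonrepeated", True, 512.0)])
        rt_set, acc_set, _ = preprocess(trials)
        s = [x for x in condition_summaries(rt_set, acc_set) if x.condition == ("nonword", "nonrepeated")][0]
        np.testing.assert_allclose(s.correct_quantiles_ms, 512.0)

    def test_empty_cell_flagged_missing(self):
        trials = make_trials([("s1", "word", "repeated", True, 500.0)])
        rt_set, acc_set, _ = preprocess(trials)
        missing = [x for x in condition_summaries(rt_set, acc_set) if x.condition == ("nonword", "repeated")][0]
        assert missing.missing and np.isnan(missing.accuracy)

    def test_error_quantiles_require_eleven_errors(self):
        ok = [("s1", "word", "repeated", False, 400.0 + i) for i in range(11)]
        trials = make_trials(ok + [("s1", "word", "repeated", True, 500.0)])
        rt_set, acc_set, _ = preprocess(trials)
        s = [x for x in condition_summaries(rt_set, acc_set) if x.condition == ("word", "repeated")][0]
        assert s.error_quantiles_ms is not None
        trials2 = make_trials(ok[:10] + [("s1", "word", "repeated", True, 500.0)])
        rt_set2, acc_set2, _ = preprocess(trials2)
        s2 = [x for x in condition_summaries(rt_set2, acc_set2) if x.condition == ("word", "repeated")][0]
        assert s2.error_quantiles_ms is None

    def test_quantile_monotonicity_on_synthetic_data(self, sim_experiment):
        trials, _ = sim_experiment
        rt_set, acc_set, _ = preprocess(trials)
        for s in condition_summaries(rt_set, acc_set):
            assert np.all(np.diff(s.correct_quantiles_ms) >= 0)
            assert 0.0 <= s.accuracy <= 1.0


class TestVincentize:
    def test_single_subject_identity(self):
        trials = make_trials([("s1", "word", "repeated", True, 400.0 + 7 * i) for i in range(25)])
        rt_set, _, _ = preprocess(trials)
        ps = per_subject_quantiles(rt_set)
        group = vincentize(ps)
        own = quantiles(rt_set["rt_ms"])
        np.testing.assert_allclose(np.sort(group["rt_ms"].to_numpy()), np.sort(own))

    def test_mean_of_two_subjects(self):
        trials = make_trials(
            [("s1", "word", "repeated", True, 500.0)] * 3 + [("s2", "word", "repeated", True, 600.0)] * 3
        )
        rt_set, _, _ = preprocess(trials)
        group = vincentize(per_subject_quantiles(rt_set))
        med = group[(group["prob"] == 0.5)]["rt_ms"].iloc[0]
        assert med == pytest.approx(550.0)

    def test_identical_subjects_reproduce_their_quantiles(self):
        base = [("word", "repeated", True, 380.0 + 11 * i) for i in range(30)]
        trials = make_trials(
            [("s1", *r) for r in base] + [("s2", *r) for r in base] + [("s3", *r) for r in base]
        )
        rt_set, _, _ = preprocess(trials)
        group = vincentize(per_subject_quantiles(rt_set))
        own = quantiles([r[3] for r in base])
        np.testing.assert_allclose(np.sort(group["rt_ms"].to_numpy()), np.sort(own))
        assert (group["n_missing_subjects"] == 0).all()

    def test_missing_subject_counted(self):
        trials = make_trials(
            [("s1", "word", "repeated", True, 500.0)] * 3
            + [("s2", "word", "repeated", True, 600.0)] * 3
            + [("s2", "word", "nonrepeated", True, 650.0)] * 3
        )
        rt_set, _, _ = preprocess(trials)
        group = vincentize(per_subject_quantiles(rt_set))
        nr = group[group["repetition"] == "nonrepeated"]
        assert (nr["n_missing_subjects"] == 1).all()


class TestRepetitionEffects:
    def _table(self, word_nonrep, word_rep, nonword_nonrep, nonword_rep, n_subj=4):
        rows = []
        for s in range(n_subj):
            subj = f"s{s}"
            jitter = 0.0  # identical subjects: effect equals the mean difference
            for lex, rep_label, center in (
                ("word", "nonrepeated", word_nonrep),
                ("word", "repeated", word_rep),
                ("nonword", "nonrepeated", nonword_nonrep),
                ("nonword", "repeated", nonword_rep),
            ):
                for k in range(5):
                    rows.append((subj, lex, rep_label, True, center + jitter + (k - 2) * 10.0))
        return make_trials(rows)

    def test_reference_effect_arithmetic(self):
        """Nonrepeated-minus-repeated means: 531-513 = 18 ms for words,
        583-597 = -14 ms for nonwords."""
        trials = self._table(531.0, 513.0, 583.0, 597.0)
        rt_set, _, _ = preprocess(trials)
        effects = {e.lexicality: e for e in repetition_effects(rt_set, n_boot=200, rng=0)}
        assert effects["word"].effect_ms == pytest.approx(18.0)
        assert effects["nonword"].effect_ms == pytest.approx(-14.0)

    def test_equal_means_give_zero_effect(self):
        trials = self._table(550.0, 550.0, 600.0, 600.0)
        rt_set, _, _ = preprocess(trials)
        effects = repetition_effects(rt_set, n_boot=200, rng=0)
        for e in effects:
            assert e.effect_ms == pytest.approx(0.0)
            assert e.ci_low_ms <= e.effect_ms <= e.ci_high_ms

    def test_ci_brackets_effect(self, sim_experiment):
        trials, _ = sim_experiment
        rt_set, _, _ = preprocess(trials)
        for e in repetition_effects(rt_set, n_boot=500, rng=1):
            assert e.ci_low_ms <= e.effect_ms <= e.ci_high_ms
            assert set(e.per_quantile_effect_ms) == {0.1, 0.3, 0.5, 0.7, 0.9}

    def test_requires_both_repetition_cells(self):
        trials = make_trials([("s1", "word", "repeated", True, 500.0)] * 3)
        rt_set, _, _ = preprocess(trials)
        with pytest.raises(ValueError):
            repetition_effects(rt_set, n_boot=10, rng=0)


def test_group_data_error_counts_only_mode(sim_experiment):
    trials, _ = sim_experiment
    gd = group_data(trials, use_error_quantiles=False)
    assert all(v is None for v in gd.error_quantiles_ms.values())


def test_group_data_assembly(sim_experiment):
    trials, _ = sim_experiment
    gd = group_data(trials)
    assert len(gd.conditions) == 4
    for c in gd.conditions:
        assert 0.0 <= gd.accuracy[c] <= 1.0
        assert gd.n_trials[c] == 1200
        assert np.all(np.diff(gd.correct_quantiles_ms[c]) >= 0)
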