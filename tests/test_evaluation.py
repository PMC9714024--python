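"""Top-1 accuracies, AUC1, precision-recall, bootstrap and length bins."""

import numpy as np
import pytest

from knnhom.evaluation import (
    auc1,
    auc1_per_query,
    bootstrap_ci,
    count_homologs,
    hypothetical_best,
    length_binned,
    precision_recall,
    read_annotations,
    score_correlations,
    se_interval,
    top1_normalized,
    top1_raw,
    write_annotations,
)
from knnhom.hits import Hit, HitList


def ann_of(**kwargs):
    return {k: frozenset(v) for k, v in kwargs.items()}


class TestTop1:
    def test_all_correct(self):
        ann = ann_of(q1={"A"}, q2={"A"}, t={"A"})
        assert top1_raw({"q1": "t", "q2": "t"}, ann) == 1.0

    def test_half_correct(self):
        ann = ann_of(q1={"A"}, q2={"A"}, q3={"B"}, q4={"B"}, t={"A"})
        decisions = {"q1": "t", "q2": "t", "q3": "t", "q4": "t"}
        assert top1_raw(decisions, ann) == 0.5

    def test_no_hit_counts_as_incorrect(self):
        ann = ann_of(q1={"A"}, t={"A"})
        assert top1_raw({"q1": None}, ann) == 0.0

    def test_missing_annotation_is_an_error(self):
        with pytest.raises(KeyError, match="mystery"):
            top1_raw({"mystery": "t"}, ann_of(t={"A"}))

    def test_matches_counting_oracle(self, rng):
        families = [f"F{i}" for i in range(8)]
        ann, decisions = {}, {}
        correct_count = 0
        for i in range(100):
            q, t = f"q{i}", f"t{i}"
            fq = families[rng.integers(0, 8)]
            ft = families[rng.integers(0, 8)]
            ann[q], ann[t] = frozenset({fq}), frozenset({ft})
            decisions[q] = t
            correct_count += fq == ft  # independent counting oracle
        assert top1_raw(decisions, ann) == pytest.approx(correct_count / 100)

    def test_two_family_hand_case(self):
        """Family A: 1 query, correct; family B: 3 queries, all wrong."""
        ann = ann_of(a1={"A"}, b1={"B"}, b2={"B"}, b3={"B"}, hitA={"A"}, hitX={"X"})
        decisions = {"a1": "hitA", "b1": "hitX", "b2": "hitX", "b3": "hitX"}
        assert top1_raw(decisions, ann) == pytest.approx(0.25)
        assert top1_normalized(decisions, ann) == pytest.approx(0.5)

    def test_singleton_families_make_normalized_equal_raw(self, rng):
        ann, decisions = {}, {}
        for i in range(30):
            q, t = f"q{i}", f"t{i}"
            ann[q] = frozenset({f"F{i}"})
            ann[t] = frozenset({f"F{i}" if rng.random() < 0.5 else "other"})
            decisions[q] = t
        assert top1_normalized(decisions, ann) == pytest.approx(top1_raw(decisions, ann))

    def test_matches_group_by_oracle(self, rng):
        """Mixed family sizes against an independent group-by-then-average."""
        ann, decisions, fam_of = {}, {}, {}
        per_family = {}
        qid = 0
        for f in range(50):
            size = int(rng.integers(1, 9))
            flags = []
            for _ in range(size):
                q, t = f"q{qid}", f"t{qid}"
                ok = rng.random() < 0.6
                ann[q] = frozenset({f"F{f}"})
                ann[t] = frozenset({f"F{f}" if ok else "none"})
                decisions[q] = t
                fam_of[q] = f"F{f}"
                flags.append(ok)
                qid += 1
            per_family[f"F{f}"] = flags
        oracle = np.mean([np.mean(v) for v in per_family.values()])
        assert top1_normalized(decisions, ann, fam_of) == pytest.approx(oracle)


class TestAUC1:
    def _ranked(self, query, labels, ann):
        hits = []
        for i, ok in enumerate(labels):
            t = f"t{i}"
            ann[t] = frozenset({"A" if ok else "B"})
            hits.append(Hit(t, 1.0 - i * 0.01))
        ann[query] = frozenset({"A"})
        return HitList(query, hits)

    def test_hand_case_two_thirds(self):
        ann = {}
        hl = self._ranked("q", [True, True, False, True], ann)
        assert auc1("q", hl, ann, total_tp=3) == pytest.approx(2 / 3)

    def test_first_hit_false_scores_zero(self):
        ann = {}
        hl = self._ranked("q", [False, True, True], ann)
        assert auc1("q", hl, ann, total_tp=2) == 0.0

    def test_no_false_positive_scores_found_over_total(self):
        ann = {}
        hl = self._ranked("q", [True, True], ann)
        assert auc1("q", hl, ann, total_tp=4) == pytest.approx(0.5)

    def test_matches_scan_until_first_false_oracle(self, rng):
        for _ in range(200):
            labels = [bool(b) for b in rng.integers(0, 2, size=rng.integers(1, 20))]
            total_tp = max(1, sum(labels))
            ann = {}
            hl = self._ranked("q", labels, ann)
            found = 0  # independent scan oracle
            for ok in labels:
                if not ok:
                    break
                found += 1
            assert auc1("q", hl, ann, total_tp) == pytest.approx(min(found / total_tp, 1.0))

    def test_perfect_iff_all_homologs_before_any_false(self):
        ann = {}
        hl = self._ranked("q", [True, True, True, False], ann)
        assert auc1("q", hl, ann, total_tp=3) == 1.0
        hl2 = self._ranked("q", [True, False, True, True], ann)
        assert auc1("q", hl2, ann, total_tp=3) < 1.0

    def test_removing_a_correct_hit_never_increases_auc1(self, rng):
        for _ in range(50):
            labels = [bool(b) for b in rng.integers(0, 2, size=10)]
            total_tp = max(1, sum(labels))
            ann = {}
            hl = self._ranked("q", labels, ann)
            base = auc1("q", hl, ann, total_tp)
            correct_positions = [i for i, ok in enumerate(labels) if ok]
            if not correct_positions:
                continue
            drop = correct_positions[int(rng.integers(0, len(correct_positions)))]
            edited = HitList("q", [h for i, h in enumerate(hl.hits) if i != drop])
            assert auc1("q", edited, ann, total_tp) <= base + 1e-12

    def test_zero_homolog_queries_excluded(self):
        ann = ann_of(q={"A"}, other={"B"})
        values, excluded = auc1_per_query(
            {"q": HitList("q", [Hit("other", 0.5)])}, ann, ["q", "other"]
        )
        assert values == {} and excluded == ["q"]

    def test_capped_denominator(self):
        ann = {f"t{i}": frozenset({"A"}) for i in range(30)}
        ann["q"] = frozenset({"A"})
        hits = HitList("q", [Hit(f"t{i}", 1.0 - i * 0.01) for i in range(10)])
        values, _ = auc1_per_query({"q": hits}, ann, list(ann), cap=20)
        assert values["q"] == pytest.approx(10 / 20)
        uncapped, _ = auc1_per_query({"q": hits}, ann, list(ann))
        assert uncapped["q"] == pytest.approx(10 / 30)


class TestHypotheticalBest:
    def test_union_hand_case(self):
        """A correct on {q1,q2}, B on {q2,q3}, 4 queries -> 3/4."""
        ann = ann_of(
            q1={"F"}, q2={"F"}, q3={"F"}, q4={"F"}, good={"F"}, bad={"X"}
        )
        a = {"q1": "good", "q2": "good", "q3": "bad", "q4": "bad"}
        b = {"q1": "bad", "q2": "good", "q3": "good", "q4": "bad"}
        assert hypothetical_best(a, b, ann) == pytest.approx(0.75)

    def test_subset_equals_better_method(self, rng):
        ann = ann_of(**{f"q{i}": {"F"} for i in range(20)}, good={"F"}, bad={"X"})
        a = {f"q{i}": ("good" if i < 12 else "bad") for i in range(20)}
        b = {f"q{i}": ("good" if i < 5 else "bad") for i in range(20)}  # B subset of A
        assert hypothetical_best(a, b, ann) == pytest.approx(top1_raw(a, ann))

    def test_matches_union_count_oracle(self, rng):
        ann = ann_of(**{f"q{i}": {"F"} for i in range(100)}, good={"F"}, bad={"X"})
        a_flags = rng.random(100) < 0.6
        b_flags = rng.random(100) < 0.4
        a = {f"q{i}": ("good" if a_flags[i] else "bad") for i in range(100)}
        b = {f"q{i}": ("good" if b_flags[i] else "bad") for i in range(100)}
        assert hypothetical_best(a, b, ann) == pytest.approx(np.mean(a_flags | b_flags))

    def test_query_set_mismatch_rejected(self):
        ann = ann_of(q1={"F"}, t={"F"})
        with pytest.raises(ValueError, match="same query set"):
            hypothetical_best({"q1": "t"}, {"q2": "t"}, ann)


class TestPrecisionRecall:
    def test_all_correct_gives_unit_precision(self):
        ann = ann_of(q={"A"}, t1={"A"}, t2={"A"})
        hl = {"q": HitList("q", [Hit("t1", 0.9), Hit("t2", 0.8)])}
        precision, recall = precision_recall(hl, ann, total_tp=2)
        assert np.all(precision == 1.0)
        assert recall[-1] == pytest.approx(1.0)

    def test_hand_computed_curve(self):
        ann = ann_of(q={"A"}, a={"A"}, b={"B"}, c={"A"}, d={"B"}, e={"A"}, f={"B"})
        hl = {
            "q": HitList(
                "q",
                [Hit("a", 0.9), Hit("b", 0.8), Hit("c", 0.7), Hit("d", 0.6), Hit("e", 0.5), Hit("f", 0.4)],
            )
        }
        precision, recall = precision_recall(hl, ann, total_tp=3)
        np.testing.assert_allclose(precision, [1, 1 / 2, 2 / 3, 2 / 4, 3 / 5, 3 / 6])
        np.testing.assert_allclose(recall, [1 / 3, 1 / 3, 2 / 3, 2 / 3, 1.0, 1.0])

    def test_precision_near_prevalence_for_random_scores(self, rng):
        """At full depth, precision approaches the fraction of correct targets."""
        finals = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            ann = {"q": frozenset({"A"})}
            hits = []
            for i in range(40):
                ok = bool(r.random() < 0.5)
                ann[f"t{i}"] = frozenset({"A" if ok else "B"})
                hits.append(Hit(f"t{i}", float(r.random())))
            precision, _ = precision_recall(
                {"q": HitList("q", hits)}, ann, total_tp=40
            )
            finals.append(precision[-1])
        assert np.mean(finals) == pytest.approx(0.5, abs=0.03)

    def test_mixed_score_kinds_rejected(self):
        ann = ann_of(q={"A"}, t1={"A"}, t2={"A"})
        hl = {"q": HitList("q", [Hit("t1", 5.0, "neg_log_evalue"), Hit("t2", 0.8, "cosine")])}
        with pytest.raises(ValueError, match="mixed score kinds"):
            precision_recall(hl, ann, total_tp=2)
        precision_recall(hl, ann, total_tp=2, allow_mixed_kinds=True)


class TestBootstrap:
    def test_constant_values_zero_width(self):
        iv = bootstrap_ci([0.4] * 50, seed=1)
        assert iv.lo == iv.hi == iv.mean == pytest.approx(0.4)

    def test_same_seed_identical_interval(self, rng):
        values = rng.random(100)
        assert bootstrap_ci(values, seed=7) == bootstrap_ci(values, seed=7)

    def test_interval_brackets_mean(self, rng):
        values = rng.random(200)
        iv = bootstrap_ci(values, seed=3)
        assert iv.lo <= iv.mean <= iv.hi

    def test_width_shrinks_like_inverse_sqrt_n(self):
        widths = []
        for n in (100, 400, 1600):
            r = np.random.default_rng(0)
            values = r.random(n)
            iv = bootstrap_ci(values, seed=5)
            widths.append(iv.hi - iv.lo)
        # each 4x n should roughly halve the width
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.35)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.35)

    def test_se_interval_hand_case(self):
        iv = se_interval([0.0, 1.0, 0.0, 1.0])
        se = np.std([0, 1, 0, 1], ddof=1) / 2
        assert iv.mean == pytest.approx(0.5)
        assert iv.hi == pytest.approx(0.5 + 1.96 * se)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([])


class TestLengthBinned:
    def test_single_bin_equals_global_mean(self, rng):
        values = {f"q{i}": float(rng.random()) for i in range(50)}
        lengths = {q: int(rng.integers(50, 500)) for q in values}
        (b,) = length_binned(values, lengths, [0, 1000], rounds=50)
        assert b.n == 50
        assert b.interval.mean == pytest.approx(np.mean(list(values.values())))

    def test_edge_value_goes_to_right_open_bin(self):
        values = {"q": 1.0}
        bins = length_binned(values, {"q": 200}, [100, 200, 300], rounds=10)
        (b,) = bins
        assert (b.lo, b.hi) == (200, 300)

    def test_matches_group_by_oracle(self, rng):
        values = {f"q{i}": float(rng.random()) for i in range(300)}
        lengths = {q: int(rng.integers(0, 800)) for q in values}
        edges = [0, 200, 400, 600, 800]
        got = {(b.lo, b.hi): (b.n, b.interval.mean) for b in length_binned(values, lengths, edges, rounds=10)}
        for lo, hi in zip(edges, edges[1:]):
            members = [values[q] for q in values if lo <= lengths[q] < hi]
            if members:
                n, mean = got[(lo, hi)]
                assert n == len(members)
                assert mean == pytest.approx(np.mean(members))

    def test_missing_length_is_an_error(self):
        with pytest.raises(KeyError, match="length missing"):
            length_binned({"q": 1.0}, {}, [0, 100])

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            length_binned({"q": 1.0}, {"q": 10}, [100, 100])


def test_annotation_round_trip(tmp_path):
    ann = {"p1": frozenset({"A"}), "p2": frozenset({"A", "B"})}
    path = tmp_path / "ann.tsv"
    write_annotations(ann, path)
    assert read_annotations(path) == ann


def test_count_homologs_excludes_self():
    ann = ann_of(q={"A"}, a={"A"}, b={"A"}, c={"B"})
    assert count_homologs("q", ann, ["q", "a", "b", "c"]) == 2


def test_score_correlations_sign():
    cosines = [0.1, 0.3, 0.5, 0.7, 0.9]
    log_evalues = [-1.0, -3.0, -5.0, -7.0, -9.0]  # perfectly anti... correlated sign
    pearson, spearman = score_correlations(cosines, log_evalues)
    assert pearson == pytest.approx(-1.0)
    assert spearman == pytest.approx(-1.0)
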