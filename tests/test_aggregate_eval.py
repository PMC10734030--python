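"""Voting composition, screening metrics, AUC and its confidence interval."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from voicescreen.aggregate_eval import (
    ConfusionMatrix, aggregate_windows, auc_ci, clip_score, confusion, decide,
    evaluate_level, metrics, participant_decision, roc_auc,
)


def test_clip_score_is_arithmetic_mean():
    assert clip_score([0.2, 0.4, 0.9]) == pytest.approx(0.5)
    assert clip_score([0.37]) == 0.37
    with pytest.raises(ValueError):
        clip_score([])


def test_clip_score_matches_accumulation_oracle(rng):
    probs = rng.random(1000)
    acc = 0.0
    for p in probs:  # independent cumulative-sum oracle
        acc += p
    assert clip_score(probs) == pytest.approx(acc / 1000, abs=1e-12)


def test_participant_decision_rule_and_boundary():
    score, dec = participant_decision([0.2, 0.8, 0.8])
    assert score == pytest.approx(0.6) and dec == "pass"
    assert participant_decision([0.5])[1] == "pass"       # >= 0.5 is a pass
    assert participant_decision([0.4999999])[1] == "fail"  # strict below boundary
    with pytest.raises(ValueError):
        participant_decision([])


def test_confusion_hand_enumeration():
    labels = ["fail", "fail", "fail", "pass", "pass"]
    decisions = ["fail", "fail", "pass", "pass", "pass"]
    cm = confusion(labels, decisions)
    assert (cm.tp, cm.fn, cm.tn, cm.fp) == (2, 1, 2, 0)
    perfect = confusion(labels, labels)
    assert perfect.fp == perfect.fn == 0
    inverted = confusion(labels, ["pass" if l == "fail" else "fail" for l in labels])
    assert inverted.tp == inverted.tn == 0


def test_metrics_formula_case():
    m = metrics(ConfusionMatrix(tp=2, fp=0, tn=2, fn=1))
    assert m.sensitivity == pytest.approx(2 / 3)
    assert m.specificity == 1.0
    assert m.precision == 1.0
    assert m.f1 == pytest.approx(0.8)
    assert m.undefined == ()


def test_metrics_perfect_and_undefined():
    perfect = metrics(ConfusionMatrix(tp=5, fp=0, tn=5, fn=0))
    assert (perfect.sensitivity, perfect.specificity, perfect.precision,
            perfect.f1) == (1.0, 1.0, 1.0, 1.0)
    m = metrics(ConfusionMatrix(tp=0, fp=0, tn=3, fn=2))
    assert m.precision is None and "precision" in m.undefined
    assert m.f1 is None and "f1" in m.undefined
    assert m.specificity == 1.0


def test_metrics_match_formula_recomputation_on_random_pairs(rng):
    for _ in range(300):
        n = int(rng.integers(2, 30))
        labels = list(rng.choice(["pass", "fail"], n))
        decisions = list(rng.choice(["pass", "fail"], n))
        cm = confusion(labels, decisions)
        assert cm.total == n
        m = metrics(cm)
        tp = sum(1 for l, d in zip(labels, decisions) if l == "fail" and d == "fail")
        fn = sum(1 for l, d in zip(labels, decisions) if l == "fail" and d == "pass")
        tn = sum(1 for l, d in zip(labels, decisions) if l == "pass" and d == "pass")
        fp = sum(1 for l, d in zip(labels, decisions) if l == "pass" and d == "fail")
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (tp, fn, tn, fp)
        if tp + fn:
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert m.specificity == pytest.approx(tn / (tn + fp))


def test_sensitivity_specificity_swap_under_inversion(rng):
    labels = list(rng.choice(["pass", "fail"], 50))
    decisions = list(rng.choice(["pass", "fail"], 50))
    m = metrics(confusion(labels, decisions))
    inv = lambda seq: ["pass" if t == "fail" else "fail" for t in seq]
    mi = metrics(confusion(inv(labels), inv(decisions)))
    assert m.sensitivity == pytest.approx(mi.specificity)
    assert m.specificity == pytest.approx(mi.sensitivity)


def _pairwise_auc(scores, labels):
    """Brute-force Mann-Whitney: P(fail ranked above pass), ties count 0.5.

    Operates on the detection score 1 - P(pass), mirroring the contract.
    """
    s = 1.0 - np.asarray(scores)
    pos = s[[l == "fail" for l in labels]]
    neg = s[[l == "pass" for l in labels]]
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(pos) * len(neg))


def test_auc_boundary_cases():
    labels = ["fail"] * 3 + ["pass"] * 3
    assert roc_auc([0.1, 0.2, 0.3, 0.7, 0.8, 0.9], labels) == 1.0
    assert roc_auc([0.5] * 6, labels) == 0.5
    with pytest.raises(ValueError, match="both classes"):
        roc_auc([0.1, 0.9], ["pass", "pass"])


def test_auc_matches_pairwise_oracle(rng):
    scores = np.round(rng.random(200), 2)  # duplicates force tie handling
    labels = list(rng.choice(["pass", "fail"], 200))
    if len(set(labels)) < 2:
        labels[0] = "fail" if labels[0] == "pass" else "pass"
    assert roc_auc(scores, labels) == pytest.approx(
        _pairwise_auc(scores, labels), abs=1e-12)


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.random(100)
    labels = list(rng.choice(["pass", "fail"], 100))
    labels[0], labels[1] = "pass", "fail"
    transformed = scores ** 3  # strictly increasing on (0, 1)
    assert roc_auc(scores, labels) == pytest.approx(
        roc_auc(transformed, labels), abs=1e-12)


def test_auc_ci_hanley_mcneil():
    # symmetry at AUC = 0.5 with balanced classes
    lo, hi = auc_ci(0.5, 12, 12)
    assert lo + hi == pytest.approx(1.0, abs=1e-12)
    # direct evaluation of the formula
    a, n_pos, n_neg = 0.91, 10, 18
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    se = np.sqrt((a * (1 - a) + (n_pos - 1) * (q1 - a * a)
                  + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg))
    z = norm.ppf(0.975)
    lo, hi = auc_ci(a, n_pos, n_neg)
    assert lo == pytest.approx(a - z * se, abs=1e-12)
    assert hi == pytest.approx(a + z * se, abs=1e-12)
    assert hi > 1.0  # uncapped, like small-sample screening reports
    # at AUC = 1 every variance term vanishes: degenerate zero-width interval
    lo1, hi1 = auc_ci(1.0, 5, 5)
    assert lo1 == pytest.approx(1.0, abs=1e-12)
    assert hi1 == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        auc_ci(0.8, 0, 5)


def _window_table(rows):
    return pd.DataFrame(rows, columns=["participant_id", "clip_id", "label", "prob"])


def test_two_stage_vs_pooled_differ_with_unequal_window_counts():
    rows = [("p1", "c1", "fail", 0.9), ("p1", "c1", "fail", 0.9),
            ("p1", "c1", "fail", 0.9), ("p1", "c2", "fail", 0.1)]
    clips, parts = aggregate_windows(_window_table(rows))
    assert parts.loc[0, "score"] == pytest.approx((0.9 + 0.1) / 2)  # mean of clip means
    _, pooled = aggregate_windows(_window_table(rows), pooled=True)
    assert pooled.loc[0, "score"] == pytest.approx((3 * 0.9 + 0.1) / 4)
    assert parts.loc[0, "score"] != pooled.loc[0, "score"]


def test_aggregation_composition_matches_manual(rng):
    rows = []
    for p in range(4):
        for c in range(3):
            for _ in range(int(rng.integers(1, 5))):
                rows.append((f"p{p}", f"p{p}c{c}",
                             "fail" if p % 2 else "pass", float(rng.random())))
    table = _window_table(rows)
    clips, parts = aggregate_windows(table)
    for _, row in clips.iterrows():
        probs = table[table.clip_id == row.clip_id].prob
        assert row.score == pytest.approx(probs.mean(), abs=1e-12)
    for _, row in parts.iterrows():
        cs = clips[clips.participant_id == row.participant_id].score
        assert row.score == pytest.approx(cs.mean(), abs=1e-12)
        assert row.decision == decide(row.score)


def test_evaluate_level_full_report():
    labels = ["fail"] * 4 + ["pass"] * 6
    scores = [0.1, 0.2, 0.3, 0.6, 0.7, 0.8, 0.9, 0.55, 0.65, 0.75]
    report = evaluate_level(labels, scores, "participant")
    assert report.cm.total == 10
    assert report.n_pos == 4 and report.n_neg == 6
    assert 0.0 <= report.auc <= 1.0
    d = report.to_dict()
    assert d["level"] == "participant"
    assert set(d["confusion"]) == {"tp", "fp", "tn", "fn"}
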