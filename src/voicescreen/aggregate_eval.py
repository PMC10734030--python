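"""Window -> clip -> participant voting and screening metrics.

Window probabilities (P(pass) per spectrogram image) are averaged to a clip
score, clip scores are averaged to a participant score, and a fixed decision
boundary of 0.5 maps scores to decisions: *fail* if score < 0.5, *pass* if
score >= 0.5 (ties go to pass).

All reported metrics take the screen-positive class to be **fail** — the
clinically critical detection — so ROC curves are built on inverted scores
(1 - P(pass)). AUC confidence intervals use the Hanley-McNeil normal
approximation and are deliberately reported uncapped, so upper bounds may
exceed 1 at small n.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from .audio_io import LABELS, POSITIVE_LABEL

DECISION_BOUNDARY = 0.5


def clip_score(window_probs: Sequence[float]) -> float:
    """Arithmetic mean of a clip's window probabilities."""
    if len(window_probs) == 0:
        raise ValueError("clip has no window probabilities")
    return float(np.mean(np.asarray(window_probs, dtype=np.float64)))


def decide(score: float, boundary: float = DECISION_BOUNDARY) -> str:
    """fail if score < boundary, pass if score >= boundary."""
    return "fail" if score < boundary else "pass"


def participant_decision(
    clip_scores: Sequence[float], boundary: float = DECISION_BOUNDARY
) -> tuple[float, str]:
    """Mean of clip scores and the pass/fail decision at the boundary."""
    if len(clip_scores) == 0:
        raise ValueError("participant has no clip scores")
    score = float(np.mean(np.asarray(clip_scores, dtype=np.float64)))
    return score, decide(score, boundary)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with positive = fail (screen-positive)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(labels: Sequence[str], decisions: Sequence[str]) -> ConfusionMatrix:
    if len(labels) != len(decisions):
        raise ValueError("labels and decisions differ in length")
    if len(labels) == 0:
        raise ValueError("cannot build a confusion matrix from no units")
    for token in list(labels) + list(decisions):
        if token not in LABELS:
            raise ValueError(f"unknown label token {token!r}")
    tp = fp = tn = fn = 0
    for lab, dec in zip(labels, decisions):
        if lab == POSITIVE_LABEL:
            if dec == POSITIVE_LABEL:
                tp += 1
            else:
                fn += 1
        else:
            if dec == POSITIVE_LABEL:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class Metrics:
    """Screening metrics; a 0/0 ratio is undefined (flagged), never 0."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    undefined: tuple[str, ...] = ()


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> Metrics:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    if sens is None or prec is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    undefined = tuple(
        name for name, v in
        (("sensitivity", sens), ("specificity", spec), ("precision", prec), ("f1", f1))
        if v is None
    )
    return Metrics(sensitivity=sens, specificity=spec, precision=prec, f1=f1,
                   undefined=undefined)


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """AUC for detecting fail; scores are P(pass), so ranking uses 1 - score.

    Equals the Mann-Whitney probability of correct ranking with ties
    counted 0.5.
    """
    labels = list(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if len(labels) != len(scores):
        raise ValueError("scores and labels differ in length")
    y = np.array([1 if l == POSITIVE_LABEL else 0 for l in labels])
    if y.min() == y.max():
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, 1.0 - scores))


def auc_ci(
    auc: float, n_pos: int, n_neg: int, level: float = 0.95
) -> tuple[float, float]:
    """Hanley-McNeil normal-approximation interval for an AUC; NOT clipped.

    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos*n_neg)
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A). Bounds may exceed [0, 1] at
    small n; they are reported as computed.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one unit in each class")
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must lie in [0, 1]")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    se2 = (a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    se = float(np.sqrt(max(se2, 0.0)))
    z = float(norm.ppf(0.5 + level / 2.0))
    return a - z * se, a + z * se


@dataclass
class EvalReport:
    """Screening performance at one evaluation level."""

    level: str  # window | clip | participant
    cm: ConfusionMatrix
    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "confusion": {"tp": self.cm.tp, "fp": self.cm.fp,
                          "tn": self.cm.tn, "fn": self.cm.fn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "undefined": list(self.undefined),
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    def summary(self) -> str:
        def fmt(v):
            return "undefined" if v is None else f"{v:.3f}"
        lo, hi = self.auc_ci
        return (
            f"{self.level:>12}-level  sens {fmt(self.sensitivity)}  "
            f"spec {fmt(self.specificity)}  prec {fmt(self.precision)}  "
            f"F1 {fmt(self.f1)}  AUC {self.auc:.3f} [{lo:.2f}, {hi:.2f}]  "
            f"(fail n={self.n_pos}, pass n={self.n_neg})"
        )


def evaluate_level(
    labels: Sequence[str], scores: Sequence[float], level: str,
    boundary: float = DECISION_BOUNDARY,
) -> EvalReport:
    """Build a full report (confusion, ratios, AUC with CI) at one level."""
    scores = np.asarray(scores, dtype=np.float64)
    decisions = [decide(s, boundary) for s in scores]
    cm = confusion(labels, decisions)
    m = metrics(cm)
    auc = roc_auc(scores, labels)
    n_pos = sum(1 for l in labels if l == POSITIVE_LABEL)
    n_neg = len(list(labels)) - n_pos
    ci = auc_ci(auc, n_pos, n_neg)
    return EvalReport(level=level, cm=cm, sensitivity=m.sensitivity,
                      specificity=m.specificity, precision=m.precision, f1=m.f1,
                      auc=auc, auc_ci=ci, n_pos=n_pos, n_neg=n_neg,
                      undefined=m.undefined)


def aggregate_windows(
    window_table: pd.DataFrame, pooled: bool = False,
    boundary: float = DECISION_BOUNDARY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vote window probabilities up to clip and participant tables.

    ``window_table`` needs columns participant_id, clip_id, label, prob.
    Two-stage voting (windows -> clip mean -> participant mean of clip
    means) is the default; ``pooled=True`` instead averages all of a
    participant's windows in one stage, which differs whenever clips have
    unequal window counts.
    """
    required = {"participant_id", "clip_id", "label", "prob"}
    missing = required - set(window_table.columns)
    if missing:
        raise ValueError(f"window table missing columns: {sorted(missing)}")

    clip_rows = []
    for (pid, cid), grp in window_table.groupby(["participant_id", "clip_id"], sort=False):
        clip_rows.append({
            "participant_id": pid, "clip_id": cid,
            "label": grp["label"].iloc[0],
            "score": clip_score(grp["prob"].to_list()),
            "n_windows": len(grp),
        })
    clips = pd.DataFrame(clip_rows)
    clips["decision"] = [decide(s, boundary) for s in clips["score"]]

    part_rows = []
    for pid, grp in window_table.groupby("participant_id", sort=False):
        if pooled:
            score = float(grp["prob"].mean())
            dec = decide(score, boundary)
        else:
            sub = clips[clips["participant_id"] == pid]
            score, dec = participant_decision(sub["score"].to_list(), boundary)
        part_rows.append({
            "participant_id": pid, "label": grp["label"].iloc[0],
            "score": score, "decision": dec,
            "n_clips": int((clips["participant_id"] == pid).sum()),
        })
    participants = pd.DataFrame(part_rows)
    return clips, participants


def write_score_sheet(participants: pd.DataFrame, path: str | Path) -> Path:
    """Per-participant CSV ``participant_id,score,decision,label``."""
    path = Path(path)
    participants[["participant_id", "score", "decision", "label"]].to_csv(path, index=False)
    return path
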