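"""Scoring predictions against gold labels, and inter-rater agreement.

Classification is scored as one binary task per category — event (mild or
severe) versus none — matching chart-level review practice; a
severity-stratified mode scores only a chosen severity as positive.
Metrics keep their integer numerators and denominators alongside the
proportions so reports can print the field's conventional "293/300 (97.7%)"
form, and undefined metrics are reported as NA (None), never as exceptions
or silent zeros.

For the gold standard itself, two chance-corrected agreement coefficients
are provided.  Cohen's kappa corrects by the raters' marginal chance
agreement p_e = sum_k p_k1 p_k2 and famously degrades at low prevalence even
when raw agreement is high (the "kappa paradox" — rare severe events make
the correction term explode).  Gwet's AC1 instead uses
e(gamma) = 1/(q-1) * sum_k pi_k (1 - pi_k) with pi_k the mean marginal
proportion, which stays stable as prevalence shrinks; that is why AC1 is the
primary agreement measure for rare adverse events, with kappa reported as
the comparison baseline.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any, Iterable, Mapping, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "Metrics",
    "metrics",
    "RatingTable",
    "gwet_ac1",
    "cohen_kappa",
    "evaluation_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts for one binary task (event vs none)."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


def _is_positive(severity: Optional[str], positive: Sequence[str]) -> bool:
    return severity in positive


def confusion(
    preds: Mapping[str, Optional[str]],
    gold: Mapping[str, str],
    *,
    positive: Sequence[str] = ("mild", "severe"),
) -> ConfusionMatrix:
    """2x2 counts over the gold chart ids.

    ``preds`` maps chart id to a severity (or None when the pipeline could
    not classify).  A missing or unclassifiable prediction counts as a
    negative-class prediction with a logged warning — charts are never
    silently dropped from the denominator.  Predictions for unknown chart
    ids are an alignment error.
    """
    unknown = set(preds) - set(gold)
    if unknown:
        raise ValueError(f"predictions for chart ids not in gold: {sorted(unknown)[:5]}")
    tp = fp = fn = tn = 0
    for cid in gold:
        if cid not in preds:
            log.warning("no prediction for chart %s; counted as negative", cid)
        elif preds[cid] is None:
            log.warning("unclassifiable prediction for chart %s; counted as negative", cid)
        p = _is_positive(preds.get(cid), positive)
        g = _is_positive(gold[cid], positive)
        tp += p and g
        fp += p and not g
        fn += g and not p
        tn += not p and not g
    return ConfusionMatrix(tp, fp, fn, tn)


@dataclass(frozen=True)
class Metrics:
    """Proportions with their defining integer fractions; None marks NA."""

    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    f_score: Optional[float]
    fractions: dict[str, tuple[int, int]]

    def percent(self, name: str) -> Optional[float]:
        v = getattr(self, name)
        return None if v is None else round(100 * v, 1)

    def fraction_str(self, name: str) -> str:
        v = getattr(self, name)
        if v is None:
            return "NA"
        if name in self.fractions:
            num, den = self.fractions[name]
            return f"{num}/{den} ({self.percent(name):g}%)"
        return f"{self.percent(name):g}%"


def metrics(cm: ConfusionMatrix) -> Metrics:
    """accuracy, precision, recall and F1 from a 2x2 table, NA-aware.

    F1 is the harmonic mean of precision and recall; it is NA when either is
    undefined or when both are zero (the harmonic mean's denominator
    vanishes).
    """
    fractions: dict[str, tuple[int, int]] = {}
    accuracy = precision = recall = f_score = None
    if cm.n > 0:
        accuracy = (cm.tp + cm.tn) / cm.n
        fractions["accuracy"] = (cm.tp + cm.tn, cm.n)
    if cm.tp + cm.fp > 0:
        precision = cm.tp / (cm.tp + cm.fp)
        fractions["precision"] = (cm.tp, cm.tp + cm.fp)
    if cm.tp + cm.fn > 0:
        recall = cm.tp / (cm.tp + cm.fn)
        fractions["recall"] = (cm.tp, cm.tp + cm.fn)
    if precision is not None and recall is not None and (precision + recall) > 0:
        f_score = 2 * precision * recall / (precision + recall)
    return Metrics(accuracy, precision, recall, f_score, fractions)


class RatingTable:
    """Paired categorical ratings of the same items by two raters."""

    def __init__(self, items: Iterable[tuple[Any, Any]],
                 categories: Optional[Sequence[Any]] = None):
        self.items = list(items)
        if not self.items:
            raise ValueError("rating table needs at least one item")
        observed = sorted({r for pair in self.items for r in pair}, key=str)
        self.categories = list(categories) if categories is not None else observed
        missing = set(observed) - set(self.categories)
        if missing:
            raise ValueError(f"ratings outside declared categories: {missing}")

    @classmethod
    def from_counts_2x2(cls, both_yes: int, yes_no: int, no_yes: int, both_no: int
                        ) -> "RatingTable":
        items = ([("yes", "yes")] * both_yes + [("yes", "no")] * yes_no
                 + [("no", "yes")] * no_yes + [("no", "no")] * both_no)
        return cls(items, categories=["no", "yes"])

    @property
    def n_items(self) -> int:
        return len(self.items)

    def observed_agreement(self) -> float:
        return sum(a == b for a, b in self.items) / self.n_items

    def marginals(self) -> tuple[dict[Any, float], dict[Any, float]]:
        n = self.n_items
        p1 = {c: sum(a == c for a, _ in self.items) / n for c in self.categories}
        p2 = {c: sum(b == c for _, b in self.items) / n for c in self.categories}
        return p1, p2


def gwet_ac1(table: RatingTable) -> Optional[float]:
    """Gwet's first-order agreement coefficient AC1.

    AC1 = (p_a - p_e) / (1 - p_e) with p_e = 1/(q-1) * sum_k pi_k(1 - pi_k),
    pi_k the mean of the two raters' marginal proportions for category k.
    Returns None (NA) in the degenerate p_e = 1 case; equals 1 exactly when
    the raters agree on every item.
    """
    q = len(table.categories)
    pa = table.observed_agreement()
    if q < 2:
        return 1.0 if pa == 1.0 else None
    p1, p2 = table.marginals()
    pe = sum((p1[c] + p2[c]) / 2 * (1 - (p1[c] + p2[c]) / 2) for c in table.categories)
    pe /= q - 1
    if pe >= 1.0:
        return None
    return (pa - pe) / (1 - pe)


def cohen_kappa(table: RatingTable) -> Optional[float]:
    """Cohen's kappa: chance correction by the product of rater marginals."""
    pa = table.observed_agreement()
    p1, p2 = table.marginals()
    pe = sum(p1[c] * p2[c] for c in table.categories)
    if pe >= 1.0:
        return None
    return (pa - pe) / (1 - pe)


def evaluation_report(
    preds: Mapping[str, Mapping[str, Optional[str]]],
    gold: Mapping[str, Mapping[str, str]],
    *,
    severity_stratified: bool = False,
) -> dict[str, Any]:
    """Per-category confusion matrices and metrics.

    ``preds``/``gold`` map chart id -> {category -> severity}.  The default
    binary event definition is any event (mild or severe); with
    ``severity_stratified`` each severity level is scored as its own
    positive class.
    """
    categories = sorted({c for labels in gold.values() for c in labels})
    report: dict[str, Any] = {"n_charts": len(gold), "categories": {}}
    for cat in categories:
        gold_cat = {cid: labels.get(cat, "none") for cid, labels in gold.items()}
        pred_cat = {cid: labels.get(cat) for cid, labels in preds.items()}
        tasks = ({"event": ("mild", "severe")} if not severity_stratified
                 else {"mild": ("mild",), "severe": ("severe",)})
        entry: dict[str, Any] = {}
        for task, positive in tasks.items():
            cm = confusion(pred_cat, gold_cat, positive=positive)
            m = metrics(cm)
            entry[task] = {
                "confusion": cm.as_dict(),
                "metrics": {k: m.percent(k) for k in
                            ("accuracy", "precision", "recall", "f_score")},
                "fractions": {k: m.fraction_str(k) for k in
                              ("accuracy", "precision", "recall", "f_score")},
            }
        report["categories"][cat] = entry
    return report


def report_table(report: Mapping[str, Any]) -> pd.DataFrame:
    """Human-readable metric table from :func:`evaluation_report` output."""
    rows = []
    for cat, entry in report["categories"].items():
        for task, data in entry.items():
            rows.append({"category": cat, "task": task, **data["fractions"]})
    return pd.DataFrame(rows)
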