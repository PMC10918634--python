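"""Comparison of automated identifications against manual labels.

ZooMS taxa are often compound ("Cervus/Saiga/Gazella sp."), so a
prediction and a manual label count as a match when their sets of taxon
atoms intersect. Accuracies are reported per site and as sample-size
weighted averages; correlation scores of true vs false identifications
are compared with an independent two-sample t-test.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

FAIL_TOKENS = {"", "fail", "failed", "na", "n/a", "none", "unknown"}

LEVELS = ("taxon", "family", "order")


@dataclass(frozen=True)
class LabelSet:
    """A free-text taxon label and its normalized atom set.

    Atoms are obtained by splitting on "/", stripping the " sp." suffix,
    question marks and periods, and case-folding, so "Bos/Bison sp.?"
    becomes {"bos", "bison"}.
    """

    raw: str
    atoms: frozenset[str]

    @classmethod
    def parse(cls, raw: object) -> "LabelSet":
        text = "" if raw is None or (isinstance(raw, float) and pd.isna(raw)) else str(raw)
        atoms = []
        for part in text.split("/"):
            token = part.strip().strip("*").replace("?", "").strip()
            token = re.sub(r"\bsp\.?$", "", token, flags=re.IGNORECASE).strip()
            token = token.strip(" .").casefold()
            if token and token not in FAIL_TOKENS:
                atoms.append(token)
        return cls(raw=text, atoms=frozenset(atoms))

    @property
    def is_fail(self) -> bool:
        return not self.atoms


def is_match(predicted: LabelSet, truth: LabelSet) -> bool:
    """True when the two labels share at least one taxon atom.

    A broader compound prediction containing the manual taxon (or vice
    versa) therefore counts as correct.
    """
    return bool(predicted.atoms & truth.atoms)


@dataclass
class ConfusionMatrix:
    level: str
    labels: list[str]
    counts: np.ndarray

    def normalized(self) -> np.ndarray:
        row_sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row_sums > 0, self.counts / row_sums, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def _as_labelset(value: object) -> LabelSet:
    return value if isinstance(value, LabelSet) else LabelSet.parse(value)


def confusion(pairs: Sequence[tuple[object, object]], level: str = "taxon") -> ConfusionMatrix:
    """Counted confusion matrix over (predicted, truth) label pairs.

    Fails must be excluded beforehand; rows are true labels, columns
    predicted labels, both ordered alphabetically over the union.
    """
    if not pairs:
        raise ValueError("cannot build a confusion matrix from zero pairs")
    parsed = [(_as_labelset(p), _as_labelset(t)) for p, t in pairs]
    labels = sorted({ls.raw.strip() or "?" for pair in parsed for ls in pair})
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for pred, truth in parsed:
        counts[index[truth.raw.strip() or "?"], index[pred.raw.strip() or "?"]] += 1
    return ConfusionMatrix(level=level, labels=labels, counts=counts)


def site_accuracy(pairs: Sequence[tuple[object, object]], level: str = "taxon") -> float:
    """Percentage of pairs where prediction and manual label match."""
    if not pairs:
        raise ValueError("cannot compute accuracy of zero pairs")
    hits = sum(is_match(_as_labelset(p), _as_labelset(t)) for p, t in pairs)
    return 100.0 * hits / len(pairs)


def weighted_accuracy(per_site: Sequence[tuple[int, float]]) -> float:
    """Sample-size weighted mean accuracy over sites, to 2 decimals."""
    if not per_site:
        raise ValueError("no per-site accuracies")
    ns = np.array([n for n, _ in per_site], dtype=float)
    accs = np.array([a for _, a in per_site], dtype=float)
    if np.any(ns <= 0):
        raise ValueError("site sample sizes must be positive")
    return round(float((ns * accs).sum() / ns.sum()), 2)


def ttest_true_false(
    true_scores: Sequence[float],
    false_scores: Sequence[float],
    equal_var: bool = False,
) -> dict:
    """Independent t-test on correlation scores of true vs false IDs.

    Welch's unequal-variance form by default; set ``equal_var=True`` for
    the pooled-variance Student form.
    """
    a = np.asarray(true_scores, dtype=float)
    b = np.asarray(false_scores, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 scores")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {
        "t": float(t),
        "p": float(p),
        "n_true": int(a.size),
        "n_false": int(b.size),
        "mean_true": float(a.mean()),
        "mean_false": float(b.mean()),
        "sd_true": float(a.std(ddof=1)),
        "sd_false": float(b.std(ddof=1)),
    }


def evaluate_results(
    results: pd.DataFrame,
    manual: pd.DataFrame,
    site_column: str | None = None,
) -> dict:
    """Join rank-1 identifications to manual labels and compute the report.

    ``results`` is the identification results table (rank-1 rows are
    used); ``manual`` has columns ``sample_id`` and ``manual_label``
    (optionally ``family``/``order`` and a site column). Pairs where
    either source is a fail are excluded before any statistic.
    """
    top = results[results["rank"].astype(str) == "1"].copy()
    merged = top.merge(manual, on="sample_id", how="inner", suffixes=("", "_manual"))
    merged["pred_set"] = merged["zooms_taxon"].map(LabelSet.parse)
    merged["true_set"] = merged["manual_label"].map(LabelSet.parse)
    usable = merged[
        (merged["status"] != "fail") & ~merged["pred_set"].map(lambda s: s.is_fail) & ~merged["true_set"].map(lambda s: s.is_fail)
    ]
    if usable.empty:
        raise ValueError("no usable (non-fail) pairs to evaluate")

    def frame_accuracy(frame: pd.DataFrame) -> float:
        return site_accuracy(list(zip(frame["pred_set"], frame["true_set"])))

    report: dict = {"n": int(len(usable))}
    if site_column and site_column in usable.columns:
        sites = []
        for site, sub in usable.groupby(site_column, sort=True):
            sites.append({"site": site, "n": int(len(sub)), "accuracy": round(frame_accuracy(sub), 2)})
        report["per_site"] = sites
        report["weighted_accuracy"] = weighted_accuracy([(s["n"], s["accuracy"]) for s in sites])
    else:
        report["weighted_accuracy"] = round(frame_accuracy(usable), 2)
    report["accuracy"] = round(frame_accuracy(usable), 2)

    matches = [is_match(p, t) for p, t in zip(usable["pred_set"], usable["true_set"])]
    scores = usable["correlation"].astype(float).to_numpy()
    true_scores = scores[np.array(matches)]
    false_scores = scores[~np.array(matches)]
    if true_scores.size >= 2 and false_scores.size >= 2:
        report["ttest"] = ttest_true_false(true_scores, false_scores)
    cm = confusion(list(zip(usable["pred_set"], usable["true_set"])))
    report["confusion_labels"] = cm.labels
    report["confusion_counts"] = cm.counts.tolist()
    return report
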