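"""Ranking metrics and set-level evaluation statistics.

Prediction quality is summarised per (pathway, graphlet, mode) by the
area under the ROC curve and the area under the precision-recall curve.
Conventions matter at this scale, so they are fixed here:

* AUC-ROC is the Mann-Whitney rank statistic — the probability that a
  random positive outscores a random negative, with half credit for
  ties.
* AUC-PR is stepwise average precision: thresholds sweep the distinct
  score values (ties grouped at one threshold) and each threshold
  contributes precision x delta-recall.  No trapezoidal interpolation in
  PR space.
* The *normalized AUC-PR* locates a pathway's AUC-PR within the
  distribution over all pathways of the same (graphlet, mode) stratum:
  subtract the median and divide by the mean absolute deviation about
  the median.  A pathway is *described* by a graphlet adjacency when its
  normalized AUC-PR exceeds 3 (in analogy with the 99.7% interval of a
  standard normal).
* The *correctly predicted* positives of a ranking are the true
  positives at or above the threshold that maximises F1.

Set-overlap across graphlet adjacencies is measured by the Jaccard
index, and functional coherence of a selected pathway set by
hypergeometric over-representation of annotation terms with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence, Set
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EvaluationRecord",
    "auc_roc",
    "auc_pr",
    "normalize_auc_pr",
    "described_set",
    "jaccard",
    "max_f1_positives",
    "enrich",
]

NA = float("nan")


@dataclass(frozen=True)
class EvaluationRecord:
    """Per-(pathway, graphlet, mode) evaluation summary.

    ``auc_roc``/``auc_pr``/``norm_auc_pr`` are NaN exactly when the
    test set was single-class or the scorer was flagged degenerate.
    """

    pathway: str
    graphlet: int
    mode: str
    auc_roc: float
    auc_pr: float
    n_pos: int
    n_total: int
    norm_auc_pr: float = NA
    degenerate: bool = False

    @property
    def is_na(self) -> bool:
        return math.isnan(self.auc_pr)


def _to_arrays(
    scores: Sequence[float] | Mapping[str, float],
    labels: Sequence[int] | Mapping[str, int],
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(scores, Mapping):
        keys = sorted(scores)
        if set(keys) != set(labels):
            raise ValueError("scores and labels cover different genes")
        s = np.array([scores[k] for k in keys], dtype=float)
        y = np.array([labels[k] for k in keys], dtype=int)
    else:
        s = np.asarray(scores, dtype=float)
        y = np.asarray(labels, dtype=int)
        if s.shape != y.shape:
            raise ValueError("scores and labels differ in length")
    if s.size == 0:
        raise ValueError("empty score vector")
    return s, y


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve via the rank (U) statistic.

    AUC = U / (n_pos * n_neg) with average ranks, i.e. tied
    positive/negative pairs contribute half credit.  Returns NaN when
    only one class is present.
    """
    s, y = _to_arrays(scores, labels)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return NA
    ranks = rankdata(s, method="average")
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_pr(scores, labels) -> float:
    """Area under the precision-recall curve (average precision).

    Thresholds at the distinct score values, descending; ties grouped.
    AP = sum over thresholds of precision x delta-recall.  Returns NaN
    when there is no positive; a test set with no negative scores 1.
    """
    s, y = _to_arrays(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        return NA
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    # group boundaries between distinct score values
    boundary = np.flatnonzero(np.diff(s) != 0)
    ends = np.concatenate([boundary + 1, [s.size]])
    tp = np.cumsum(y)[ends - 1]
    n_pred = ends
    precision = tp / n_pred
    recall = tp / n_pos
    d_recall = np.diff(np.concatenate([[0.0], recall]))
    return float(np.sum(precision * d_recall))


def normalize_auc_pr(values: Iterable[float]) -> list[float]:
    """Centre by the median, scale by the mean absolute deviation.

    out_i = (v_i - median) / mean(|v - median|), computed over the
    non-NaN entries; NaN inputs propagate unchanged.  A zero deviation
    (all finite values identical) is an error.
    """
    vals = np.array(list(values), dtype=float)
    finite = vals[~np.isnan(vals)]
    if finite.size < 2:
        raise ValueError("need at least two non-NA values to normalize")
    med = float(np.median(finite))
    mad = float(np.mean(np.abs(finite - med)))
    if mad == 0:
        raise ValueError("degenerate score distribution (zero mean "
                         "absolute deviation)")
    return [v if math.isnan(v) else (v - med) / mad for v in vals]


def described_set(
    records: Iterable[EvaluationRecord], threshold: float = 3.0
) -> frozenset[str]:
    """Pathways whose normalized AUC-PR exceeds ``threshold``.

    ``records`` must belong to a single (graphlet, mode) stratum with
    ``norm_auc_pr`` already filled in; NaN records never qualify.
    """
    return frozenset(
        r.pathway
        for r in records
        if not math.isnan(r.norm_auc_pr) and r.norm_auc_pr > threshold
    )


def jaccard(a: Set, b: Set) -> float:
    """|a & b| / |a | b|; NaN when both sets are empty."""
    union = len(a | b)
    if union == 0:
        return NA
    return len(a & b) / union


def max_f1_positives(
    scores: Mapping[str, float], labels: Mapping[str, int]
) -> frozenset[str]:
    """True positives at or above the F1-maximising threshold.

    Thresholds sweep the distinct score values; among ties in F1 the
    highest threshold (fewest predictions) wins.  With no positive
    labels the result is empty.
    """
    if not scores:
        return frozenset()
    keys = sorted(scores)
    s = np.array([scores[k] for k in keys], dtype=float)
    y = np.array([labels[k] for k in keys], dtype=int)
    n_pos = int(y.sum())
    if n_pos == 0:
        return frozenset()
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    boundary = np.flatnonzero(np.diff(s_sorted) != 0)
    ends = np.concatenate([boundary + 1, [s_sorted.size]])
    tp = np.cumsum(y_sorted)[ends - 1]
    precision = tp / ends
    recall = tp / n_pos
    with np.errstate(invalid="ignore"):
        f1 = np.where(tp > 0, 2 * precision * recall
                      / (precision + recall), 0.0)
    best = int(np.argmax(f1))  # argmax takes the first = highest threshold
    thr = s_sorted[ends[best] - 1]
    return frozenset(k for k in keys if scores[k] >= thr and labels[k] == 1)


def enrich(
    selected: Set[str],
    annotation: Mapping[str, Set[str]],
    universe: Set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Term over-representation in ``selected`` versus ``universe``.

    For every term annotating at least one universe pathway, an exact
    hypergeometric upper-tail p-value for the overlap with ``selected``
    is computed and Benjamini-Hochberg adjusted across terms.  Rows are
    sorted by adjusted then raw p-value; ``enriched`` marks adjusted
    p < ``alpha``.
    """
    if not universe:
        raise ValueError("empty universe")
    if not selected <= set(universe):
        raise ValueError("selected pathways must be a subset of the universe")
    term_members: dict[str, set[str]] = {}
    for pathway, terms in annotation.items():
        if pathway not in universe:
            continue
        for t in terms:
            term_members.setdefault(t, set()).add(pathway)
    big_m, big_n = len(universe), len(selected)
    rows = []
    for term in sorted(term_members):
        members = term_members[term]
        k_term = len(members)
        k_hit = len(members & selected)
        p = float(hypergeom.sf(k_hit - 1, big_m, k_term, big_n))
        rows.append((term, k_hit, k_term, p))
    df = pd.DataFrame(
        rows, columns=["term", "n_selected", "n_universe", "p_value"]
    )
    if len(df):
        _, padj, _, _ = multipletests(df["p_value"], method="fdr_bh")
        df["p_adjusted"] = padj
    else:
        df["p_adjusted"] = []
    df["enriched"] = df["p_adjusted"] < alpha
    return df.sort_values(
        ["p_adjusted", "p_value", "term"], ignore_index=True
    )
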