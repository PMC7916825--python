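"""Retrieval metrics for ranked set-level results with known truth.

A method returns per-set p-values; sets with p strictly below the
significance threshold alpha (0.05 by convention) are the positives.
Against a truth set of genuinely changing pathways this yields TP/FP/FN
counts and the usual precision / recall / F1 summaries.

For real-data-style robustness studies where no planted truth exists,
:func:`truth_from_full_data` defines each method's truth as its own
significant sets on the complete (unperturbed) data — 0.05 for the
activity scorer and ORA, 0.25 for GSEA, whose permutation p-values are
coarser.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import math

#: per-method truth thresholds for the full-data robustness protocol
FULL_DATA_THRESHOLDS = {"mplage": 0.05, "ora": 0.05, "gsea": 0.25}


def classify(
    ranking: Mapping[str, float],
    truth: Iterable[str],
    alpha: float = 0.05,
) -> tuple[int, int, int]:
    """TP/FP/FN counts of a p-value ranking against a truth set.

    Positives are sets with p < alpha (strict); NaN p-values (unscoreable
    sets) are never positive.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    truth = set(truth)
    positives = {
        s for s, p in ranking.items()
        if p is not None and not math.isnan(p) and p < alpha
    }
    tp = len(positives & truth)
    fp = len(positives - truth)
    fn = len(truth - positives)
    return tp, fp, fn


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1; zero-denominator cases give 0.

    F1 is the harmonic mean 2*P*R/(P+R), algebraically equal to
    2TP/(2TP+FP+FN).
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f1


def truth_from_full_data(
    full_results: Mapping[str, Mapping[str, float]],
    thresholds: Mapping[str, float] | None = None,
) -> dict[str, set[str]]:
    """Per-method truth sets from results on complete (unperturbed) data.

    ``full_results`` maps method name -> {set_id: p_value}.  Each method's
    truth is its significant sets at its own threshold (defaults:
    0.05, GSEA 0.25).  An empty truth is legitimate (downstream F1 is 0
    by the zero-denominator convention) and left to the caller to flag.
    """
    thresholds = dict(FULL_DATA_THRESHOLDS if thresholds is None else thresholds)
    out: dict[str, set[str]] = {}
    for method, ranking in full_results.items():
        alpha = thresholds.get(method, 0.05)
        out[method] = {
            s for s, p in ranking.items()
            if p is not None and not math.isnan(p) and p < alpha
        }
    return out
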