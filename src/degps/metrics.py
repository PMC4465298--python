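"""Evaluation metrics for DE calls against known truth."""

from __future__ import annotations

import numpy as np

__all__ = ["type_i_error", "fdr_tpr", "partial_auc", "summarize_replicates"]


def type_i_error(p_values, truth, alpha: float = 0.05) -> float:
    """Fraction of transcripts with nominal p below ``alpha`` under the null.

    Only defined on null scenarios; raises if any transcript is truly DE.
    """
    p = np.asarray(p_values, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.any():
        raise ValueError("type I error is defined only for all-null truth")
    if p.size == 0:
        raise ValueError("empty p-value vector")
    return float(np.mean(p < alpha))


def fdr_tpr(adjusted_p, truth, alpha: float = 0.05) -> tuple[float, float]:
    """Observed FDR and TPR of the call set {adjusted p < alpha}.

    FDR is the fraction of calls that are truly non-DE (0 when nothing is
    called); TPR is the fraction of truly DE transcripts called.
    """
    p = np.asarray(adjusted_p, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.size == 0:
        raise ValueError("empty truth vector")
    called = p < alpha
    n_called = int(called.sum())
    fdr = float((called & ~truth).sum() / n_called) if n_called else 0.0
    n_de = int(truth.sum())
    tpr = float((called & truth).sum() / n_de) if n_de else 0.0
    return fdr, tpr


def partial_auc(
    scores, truth, fpr_max: float = 0.05, normalized: bool = False
) -> float:
    """Area under the ROC curve restricted to FPR in [0, fpr_max].

    ``scores`` rank transcripts with *smaller = stronger call* (p-value
    convention).  Ties share one diagonal ROC segment, equivalent to
    averaging over all tie-consistent orderings.  The raw area (maximum
    ``fpr_max``) is returned unless ``normalized``, which divides by
    ``fpr_max`` to land in [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an ROC curve")
    if not (0.0 < fpr_max <= 1.0):
        raise ValueError("fpr_max must be in (0, 1]")
    order = np.argsort(s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # Collapse ties: cumulative TP/FP at the end of each distinct-score block.
    _, block_ends = np.unique(s_sorted[::-1], return_index=True)
    ends = np.sort(s_sorted.size - block_ends)  # 1-based end index of each block
    tp = np.concatenate([[0], np.cumsum(y_sorted)[ends - 1]])
    fp = np.concatenate([[0], np.cumsum(~y_sorted)[ends - 1]])
    tpr = tp / n_pos
    fpr = fp / n_neg
    # Trapezoid over the step curve, clipped at fpr_max.
    area = 0.0
    for i in range(1, fpr.size):
        x0, x1 = fpr[i - 1], min(fpr[i], fpr_max)
        if x1 <= x0:
            if fpr[i - 1] >= fpr_max:
                break
            continue
        # Linear interpolation of tpr inside a tie block's diagonal segment.
        if fpr[i] > fpr[i - 1]:
            t1 = tpr[i - 1] + (tpr[i] - tpr[i - 1]) * (x1 - fpr[i - 1]) / (
                fpr[i] - fpr[i - 1]
            )
        else:
            t1 = tpr[i]
        t0 = tpr[i - 1]
        area += 0.5 * (t0 + t1) * (x1 - x0)
        if fpr[i] >= fpr_max:
            break
    return float(area / fpr_max) if normalized else float(area)


def summarize_replicates(values) -> dict[str, float]:
    """Median and interquartile range across replicates."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}
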