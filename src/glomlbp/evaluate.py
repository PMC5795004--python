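"""Detection evaluation against ground-truth centroids.

Ground truth for glomerulus detection is a list of hand-marked centroid
positions per slide.  A detection counts as a true positive when it can be
matched one-to-one with a truth centroid within a pixel radius; matching is
greedy in ascending centroid-distance order.  Precision, recall and F1 then
follow the standard formulas TP/(TP+FP), TP/(TP+FN) and their harmonic mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GlomLBPError


@dataclass(frozen=True)
class EvalResult:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f1: float
    match_radius: float | None = None
    #: set when a metric denominator was zero and the metric defaulted to 0
    degenerate: bool = False

    def __add__(self, other: "EvalResult") -> "EvalResult":
        return metrics_from_counts(
            self.true_positives + other.true_positives,
            self.false_positives + other.false_positives,
            self.false_negatives + other.false_negatives,
            match_radius=self.match_radius,
        )


def metrics_from_counts(
    tp: int, fp: int, fn: int, match_radius: float | None = None
) -> EvalResult:
    """Precision/recall/F1 from raw counts; zero denominators yield 0, flagged."""
    if min(tp, fp, fn) < 0:
        raise GlomLBPError("counts must be non-negative")
    degenerate = False
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, degenerate = 0.0, True
    return EvalResult(tp, fp, fn, precision, recall, f1, match_radius, degenerate)


def aggregate_results(results: list[EvalResult]) -> EvalResult:
    """Pool per-slide counts into one aggregate result."""
    if not results:
        raise GlomLBPError("nothing to aggregate")
    total = results[0]
    for r in results[1:]:
        total = total + r
    return total


def match_detections(
    detections, truth, match_radius: float = 288.0
) -> EvalResult:
    """Greedy one-to-one matching of detections to truth centroids.

    ``detections`` is a DetectionSet or an (N, 2) array of (x, y) positions;
    ``truth`` is an (M, 2) array of (x, y) positions.  Candidate pairs within
    ``match_radius`` are matched in ascending distance order (ties broken by
    truth index, then detection index); each centroid matches at most once.
    Greedy matching equals optimal assignment for well-separated
    configurations and is a deterministic approximation otherwise.
    """
    if not match_radius > 0:
        raise GlomLBPError("match_radius must be positive")
    det_xy = getattr(detections, "centroids_xy", detections)
    det_xy = np.asarray(det_xy, dtype=np.float64).reshape(-1, 2)
    truth_xy = np.asarray(truth, dtype=np.float64).reshape(-1, 2)
    n_det, n_truth = len(det_xy), len(truth_xy)

    if n_det and n_truth:
        from scipy.spatial.distance import cdist

        dist = cdist(det_xy, truth_xy)
        di, ti = np.nonzero(dist <= match_radius)
        order = np.lexsort((di, ti, dist[di, ti]))
        det_used = np.zeros(n_det, dtype=bool)
        truth_used = np.zeros(n_truth, dtype=bool)
        tp = 0
        for k in order:
            d, t = di[k], ti[k]
            if not det_used[d] and not truth_used[t]:
                det_used[d] = truth_used[t] = True
                tp += 1
    else:
        tp = 0
    return metrics_from_counts(tp, n_det - tp, n_truth - tp, match_radius)


def format_report(result: EvalResult, slide_id: str = "") -> str:
    """Human-readable one-result report."""
    head = f"slide {slide_id}: " if slide_id else ""
    return (
        f"{head}TP={result.true_positives} FP={result.false_positives} "
        f"FN={result.false_negatives} | "
        f"precision {100 * result.precision:.1f}% "
        f"recall {100 * result.recall:.1f}% "
        f"F1 {result.f1:.3f}"
        + (" (degenerate counts)" if result.degenerate else "")
    )
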