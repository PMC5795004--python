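"""Cross-validated score-distribution analysis of disease vs. control glomeruli.

Instead of separating glomeruli from background, the same mrcLBP + linear SVM
machinery is trained to separate glomerulus patches from a disease model
(e.g. STZ-induced diabetic mice) from control glomeruli.  Robustness is
assessed by repeated random cross-validation: each run holds out a fixed
number of patches per class, trains on the remainder, and scores the
holdouts.  Pooled holdout scores form the class score histograms; per-run
mean scores summarize the separation.

Class A is passed as the glom(+) side of the detector convention and so
scores negative; class B scores positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detector import train_detector
from .errors import GlomLBPError

_MAX_SEED = 2**31 - 1


@dataclass
class CrossValResult:
    """Holdout scores from repeated random cross-validation.

    per_run : one dict per run with keys ``seed``, ``mean_a``, ``mean_b``.
    pooled_scores / pooled_labels : all holdout scores with class labels
        ('A' or 'B'), pooled across runs with repetition.
    """

    per_run: list[dict]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    n_runs: int
    holdout_per_class: int

    def class_scores(self, label: str) -> np.ndarray:
        return self.pooled_scores[self.pooled_labels == label]


def crossval_scores(
    features_a: np.ndarray,
    features_b: np.ndarray,
    n_runs: int = 10,
    holdout_per_class: int = 100,
    seed: int = 0,
) -> CrossValResult:
    """Repeated random holdout cross-validation of the two-class detector.

    Each run draws ``holdout_per_class`` rows per class (disjoint from that
    run's training rows), trains the linear SVM on the remainder, and records
    the raw signed holdout scores.  A master seed spawns per-run seeds, so the
    whole result is reproducible from one integer.
    """
    fa = np.atleast_2d(np.asarray(features_a, dtype=np.float64))
    fb = np.atleast_2d(np.asarray(features_b, dtype=np.float64))
    for name, f in (("A", fa), ("B", fb)):
        if len(f) <= holdout_per_class:
            raise GlomLBPError(
                f"class {name} has {len(f)} rows; needs more than "
                f"holdout_per_class={holdout_per_class}"
            )
    master = np.random.default_rng(seed)
    run_seeds = master.integers(0, _MAX_SEED, size=n_runs)

    per_run: list[dict] = []
    scores_parts: list[np.ndarray] = []
    labels_parts: list[np.ndarray] = []
    for run_seed in run_seeds:
        rng = np.random.default_rng(int(run_seed))
        hold_a = rng.choice(len(fa), size=holdout_per_class, replace=False)
        hold_b = rng.choice(len(fb), size=holdout_per_class, replace=False)
        train_a = np.setdiff1d(np.arange(len(fa)), hold_a)
        train_b = np.setdiff1d(np.arange(len(fb)), hold_b)
        model = train_detector(fa[train_a], fb[train_b], seed=int(run_seed))
        sa = model.score(fa[hold_a])
        sb = model.score(fb[hold_b])
        per_run.append(
            {"seed": int(run_seed), "mean_a": float(sa.mean()), "mean_b": float(sb.mean())}
        )
        scores_parts.extend([sa, sb])
        labels_parts.extend([np.full(len(sa), "A"), np.full(len(sb), "B")])

    return CrossValResult(
        per_run=per_run,
        pooled_scores=np.concatenate(scores_parts),
        pooled_labels=np.concatenate(labels_parts),
        n_runs=n_runs,
        holdout_per_class=holdout_per_class,
    )


def score_histogram(
    result: CrossValResult, n_bins: int = 30
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-class histogram counts over common bin edges.

    Edges span the pooled score range; returns (edges, {'A': counts,
    'B': counts}).
    """
    lo = float(result.pooled_scores.min())
    hi = float(result.pooled_scores.max())
    if lo == hi:  # all scores identical: one degenerate bin still counts all
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    counts = {
        label: np.histogram(result.class_scores(label), bins=edges)[0]
        for label in ("A", "B")
    }
    return edges, counts


def class_separation_summary(result: CrossValResult) -> dict:
    """Separation summary mirroring a mean-score boxplot.

    mean gap = mean(class B scores) - mean(class A scores), per run and
    pooled.  The overlap fraction — the fraction of class A scores above the
    pooled class B median — is an assertable proxy for how much of class A
    overlaps the class B score distribution.
    """
    per_run_gap = [run["mean_b"] - run["mean_a"] for run in result.per_run]
    a = result.class_scores("A")
    b = result.class_scores("B")
    pooled_gap = float(b.mean() - a.mean())
    overlap = float(np.mean(a > np.median(b)))
    return {
        "per_run_gap": per_run_gap,
        "pooled_gap": pooled_gap,
        "overlap_fraction": overlap,
    }
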