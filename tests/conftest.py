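"""Shared fixtures: small trained detectors and synthetic data.

Everything is generated programmatically with fixed seeds; no image files
ship with the tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import glomlbp as g


@pytest.fixture(scope="session")
def small_model():
    """Detector trained on a small synthetic patch set (40 pos / 80 neg)."""
    pos, neg = g.make_training_patches(g.SyntheticSlideSpec(seed=0), 40, 80)
    fp = g.featurize_patches(pos)
    fn = g.featurize_patches(neg)
    return g.train_detector(fp, fn, seed=0)


@pytest.fixture(scope="session")
def small_slide():
    """A 1000x1000 synthetic slide with 3 planted glomeruli."""
    return g.make_slide(
        g.SyntheticSlideSpec(width=1000, height=1000, n_glomeruli=3, seed=11)
    )


@pytest.fixture(scope="session")
def headline_run():
    """The scaled-down headline detection experiment.

    Trains on 200 glom(+) / 400 glom(-) synthetic patches (seed 0), scans
    5 synthetic slides (2000x2000, 30 planted glomeruli, seeds 1..5) at
    default parameters, and evaluates pooled over all slides.
    """
    pos, neg = g.make_training_patches(g.SyntheticSlideSpec(seed=0), 200, 400)
    model = g.train_detector(
        g.featurize_patches(pos), g.featurize_patches(neg), seed=0
    )
    per_slide = []
    for s in range(1, 6):
        slide = g.make_slide(g.SyntheticSlideSpec(seed=s))
        score_map = g.scan_slide(slide.image, model, slide_id=f"synthetic{s}")
        detections = g.final_detections(score_map)
        per_slide.append(g.match_detections(detections, slide.centroids_xy))
    return g.aggregate_results(per_slide), per_slide


def random_model(n_features: int = 120, seed: int = 0) -> g.DetectorModel:
    """Untrained model with random weights; enough for scan geometry tests."""
    rng = np.random.default_rng(seed)
    return g.DetectorModel(
        weights=rng.normal(size=n_features),
        bias=float(rng.normal()),
        feature_config=g.FeatureConfig(),
        n_pos=0,
        n_neg=0,
        seed=seed,
    )
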