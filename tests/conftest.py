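import numpy as np
import pytest

from nucleoshuttle import imgio, simulate
from nucleoshuttle.simulate import CHANNEL_ROLES, SimConfig, render_movie

SMALL = SimConfig(
    image_size_px=(260, 260), n_cells=12, n_frames=8, seed=7,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SMALL


@pytest.fixture(scope="session")
def noise_free_movie():
    """Small noise-free movie + truth; exact-arithmetic fixture."""
    cfg = SMALL.without_noise()
    pixels, truth = render_movie(cfg)
    return pixels, truth


@pytest.fixture(scope="session")
def noisy_movie():
    pixels, truth = render_movie(SMALL)
    return pixels, truth


@pytest.fixture(scope="session")
def noise_free_stack(noise_free_movie):
    pixels, truth = noise_free_movie
    return imgio.ImageStack(pixels, dict(CHANNEL_ROLES), SMALL.frame_interval_min)


@pytest.fixture(scope="session")
def trained_classifier(noisy_movie):
    """Pixel classifier trained on brush strokes from the noisy fixture."""
    from nucleoshuttle import segment_nucleoli as so

    pixels, truth = noisy_movie
    brush = simulate.make_brush_labels(truth, n_per_class=100, seed=3)
    stack = so.compute_features(pixels[0, 1])
    return so.train_classifier([stack], [brush], seed=3)


def matched_iou(pred: np.ndarray, truth_labels: np.ndarray) -> np.ndarray:
    """Best IoU of each truth object against any predicted object."""
    out = []
    for lab in range(1, int(truth_labels.max()) + 1):
        tmask = truth_labels == lab
        cand = np.unique(pred[tmask])
        cand = cand[cand > 0]
        best = 0.0
        for c in cand:
            pm = pred == c
            best = max(best, (pm & tmask).sum() / (pm | tmask).sum())
        out.append(best)
    return np.array(out)


def object_recall(pred: np.ndarray, truth_labels: np.ndarray, iou_min: float = 0.5) -> float:
    ious = matched_iou(pred, truth_labels)
    return float((ious >= iou_min).mean())
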