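import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")

from casig.synthetic import make_layout, render_stack


@pytest.fixture(scope="session")
def five_cell_field():
    """The standard synthetic field: 5 agonist cells on 128x128, 120 frames,
    noise-free."""
    layout = make_layout(5, (128, 128), min_gap=3.0, seed=11)
    stack, truth = render_stack(layout, dt=1.0, n_frames=120, noise_sd=0.0, seed=11)
    return stack, truth


def iou_per_label(labels, truth_labels):
    """Best intersection-over-union of each detected label against any
    ground-truth label."""
    out = {}
    gt_ids = [g for g in np.unique(truth_labels) if g > 0]
    for k in np.unique(labels):
        if k == 0:
            continue
        det = labels == k
        best = 0.0
        for g in gt_ids:
            gt = truth_labels == g
            inter = np.logical_and(det, gt).sum()
            union = np.logical_or(det, gt).sum()
            best = max(best, inter / union)
        out[int(k)] = best
    return out


@pytest.fixture
def iou():
    return iou_per_label
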