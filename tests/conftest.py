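import numpy as np
import pytest

import gaitpose as gp


@pytest.fixture(scope="session")
def standard_noiseless():
    """Clean standard-gait recording at a 20 deg walking-direction tilt."""
    arch = gp.make_archetype("standard", jitter_deg=0.0)
    rec, truth = gp.simulate_recording(
        arch, duration_s=10.0, fps=30.0, theta1_deg=20.0, noise_px=0.0, seed=7
    )
    return rec, truth


@pytest.fixture(scope="session")
def dataset240():
    """The default balanced synthetic dataset (6 classes x 40 recordings)."""
    recs, labels, truths = gp.simulate_dataset(seed=0)
    return recs, labels, truths


@pytest.fixture(scope="session")
def feature_tables(dataset240):
    """2D- and 3D-mode feature tables of the default dataset."""
    recs, labels, _ = dataset240
    X3d, y = gp.build_feature_table(recs, labels, mode="3d")
    X2d, _ = gp.build_feature_table(recs, labels, mode="2d")
    return X2d, X3d, np.asarray(y)


def make_frame(points, time=0.0, conf=0.9):
    """LowerLimbFrame from {(side, joint): (x, y)} with defaults elsewhere."""
    kps = {}
    for side in gp.io.SIDES:
        for ji, joint in enumerate(gp.io.JOINTS):
            val = points.get((side, joint), (10.0 * ji, 50.0 * ji))
            if val is None:  # explicit missing detection
                kps[(side, joint)] = gp.Keypoint2D(0.0, 0.0, 0.0)
            else:
                kps[(side, joint)] = gp.Keypoint2D(val[0], val[1], conf)
    return gp.LowerLimbFrame(time=time, keypoints=kps)
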