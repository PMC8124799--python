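import numpy as np
import pytest

from ethotrace.synthetic import SceneSpec, generate_video


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def lane_video(tmp_path_factory):
    """3 non-crossing blobs, constant speed 2 px/frame, 60 frames."""
    d = tmp_path_factory.mktemp("vids")
    path = d / "lanes.avi"
    spec = SceneSpec(n_blobs=3, speed=2.0, duration=60, seed=5)
    truth = generate_video(spec, path)
    return path, truth, spec


@pytest.fixture(scope="session")
def pose_set():
    """20 labeled pose frames (10 merged pairs, 10 singles-only) with the
    per-frame contour lists of an Otsu segmentation."""
    from ethotrace.segment import threshold_otsu
    from ethotrace.synthetic import generate_pair_pose_set
    from ethotrace.track import ContourFilter, extract_contours

    spec = SceneSpec(width=400, height=300, seed=7, size_jitter=0.03)
    frames, labels, _ = generate_pair_pose_set(spec, 10, 10)
    per_frame = []
    for f in range(len(frames)):
        _, mask = threshold_otsu(frames[f])
        per_frame.append(extract_contours(mask, ContourFilter(min_area=30)))
    return frames, labels, per_frame


@pytest.fixture(scope="session")
def single_blob_video(tmp_path_factory):
    d = tmp_path_factory.mktemp("vids1")
    path = d / "one.avi"
    spec = SceneSpec(n_blobs=1, speed=0.0, duration=20, seed=3)
    truth = generate_video(spec, path)
    return path, truth, spec
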