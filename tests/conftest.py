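import numpy as np
import pytest

from cav.core import ActivityRecording, LabeledDataset, canonicalize_quaternions


def random_frames(rng: np.random.Generator, n_frames: int) -> np.ndarray:
    """Random canonical frames of shape (n, 9, 4)."""
    return canonicalize_quaternions(rng.normal(size=(n_frames, 9, 4)))


def make_recording(
    frames: np.ndarray,
    frame_rate: float = 30.0,
    label: str = "act",
    subject: str = "subj01",
    recording_id: str = "rec01",
) -> ActivityRecording:
    return ActivityRecording(
        frames=frames,
        frame_rate=frame_rate,
        label=label,
        subject_id=subject,
        recording_id=recording_id,
    )


def make_dataset(recordings) -> LabeledDataset:
    return LabeledDataset(recordings=list(recordings))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
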