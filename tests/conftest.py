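import numpy as np
import pytest

from aogm import (
    LineageParams,
    Marker,
    Track,
    TrackingResult,
    generate_reference,
    worked_example,
)


@pytest.fixture(scope="session")
def example_pair():
    """The synthetic worked example exhibiting all six error types."""
    return worked_example()


@pytest.fixture
def small_reference():
    """A deterministic small synthetic lineage."""
    return generate_reference(LineageParams(n_frames=8, n_initial=5, seed=7))


def square(cy, cx, r=1):
    return frozenset(
        (y, x) for y in range(cy - r, cy + r + 1) for x in range(cx - r, cx + r + 1)
    )


def build_result(n_frames, tracks, markers):
    """tracks: (label, t0, t1, parent); markers: (label, frame, pixels)."""
    return TrackingResult(
        n_frames=n_frames,
        tracks={t[0]: Track(label=t[0], t_init=t[1], t_end=t[2], parent=t[3]) for t in tracks},
        markers={
            (label, frame): Marker(label=label, frame=frame, pixels=pixels)
            for label, frame, pixels in markers
        },
    )


@pytest.fixture
def two_track_result():
    """Two straight parallel tracks over three frames."""
    tracks = [(1, 0, 2, None), (2, 0, 2, None)]
    markers = [(1, t, square(2, 2 + t)) for t in range(3)] + [
        (2, t, square(8, 2 + t)) for t in range(3)
    ]
    return build_result(3, tracks, markers)
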