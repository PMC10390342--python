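import numpy as np
import pytest

from vncflow.containers import DisplacementFieldSeries


def make_field(
    u=1.0,
    v=0.0,
    n_frames=5,
    nx=12,
    ny=10,
    spacing=5.0,
    frame_interval=5.0,
    interpolated=False,
):
    """A constant displacement-field series on a regular grid."""
    x = np.arange(nx) * spacing
    y = np.arange(ny) * spacing
    uu = np.full((n_frames, ny, nx), float(u))
    vv = np.full((n_frames, ny, nx), float(v))
    valid = np.ones_like(uu, dtype=bool)
    return DisplacementFieldSeries(
        x=x, y=y, u=uu, v=vv, valid=valid,
        frame_interval=frame_interval, interpolated=interpolated,
    )


@pytest.fixture
def uniform_field():
    return make_field(u=1.0, v=0.5)


@pytest.fixture
def random_orientation_field():
    rng = np.random.default_rng(7)
    nx = ny = 40
    spacing = 2.0
    th = rng.uniform(0, 2 * np.pi, (3, ny, nx))
    return DisplacementFieldSeries(
        x=np.arange(nx) * spacing,
        y=np.arange(ny) * spacing,
        u=np.cos(th),
        v=np.sin(th),
        valid=np.ones_like(th, dtype=bool),
        frame_interval=1.0,
    )
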