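import numpy as np
import pytest

from tconfine.simulate import CellSpec, SimParams, gen_fura_stack


@pytest.fixture
def sm_params():
    """Small, fast single-molecule acquisition with mild noise."""
    return SimParams(field_size=(15.0, 15.0), n_frames=30, noise_sd=3.0,
                     bleach_rate=0.05, seed=1)


def make_fura_recording(
    n_frames: int,
    areas: np.ndarray,
    ratios: np.ndarray,
    centers: np.ndarray,
    seed: int,
    pixel_size: float = 0.5,
    field: float = 80.0,
    noise_sd: float = 2.0,
    background: float = 20.0,
    wander_sd: float = 0.3,
):
    """Render one Fura-2 recording of slowly wandering disk cells."""
    n_cells = len(centers)
    params = SimParams(
        field_size=(field, field), pixel_size=pixel_size, frame_rate=1.0,
        n_frames=n_frames, noise_sd=noise_sd, background_level=background, seed=seed,
    )
    rng = np.random.default_rng(seed + 1000)
    cells = []
    for i in range(n_cells):
        drift = rng.normal(0, wander_sd, size=(n_frames, 2)).cumsum(axis=0)
        cells.append(
            CellSpec(
                positions=centers[i] + drift,
                area_um2=np.broadcast_to(np.atleast_1d(areas[i]), (n_frames,)),
                ratio=np.broadcast_to(np.atleast_1d(ratios[i]), (n_frames,)),
            )
        )
    return gen_fura_stack(params, cells)
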