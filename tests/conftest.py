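import numpy as np
import pytest

from eventreact.events_io import BoldRun, Scene, SceneTable


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_table(lengths, gaps=None, labels=None, start=1):
    """Contiguous (or gapped) scene table from TR lengths."""
    gaps = gaps or [0] * len(lengths)
    labels = labels or ["NONE"] * len(lengths)
    scenes = []
    cur = start
    for k, (L, g, lab) in enumerate(zip(lengths, gaps, labels)):
        scenes.append(
            Scene(index=k + 1, onset_tr=cur, offset_tr=cur + L - 1, narrative=lab)
        )
        cur += L + g
    return SceneTable(scenes)


def make_run(n_trs, n_voxels, rng=None, tr_seconds=1.5, data=None):
    if data is None:
        data = rng.standard_normal((n_trs, n_voxels))
    coords = np.array(
        [(i, 0, 0) for i in range(data.shape[1])]
    )
    return BoldRun(data=data, tr_seconds=tr_seconds, voxel_coords=coords)


@pytest.fixture()
def toy_table():
    return make_table([20, 20, 20, 20, 20, 20])


@pytest.fixture()
def toy_run(rng, toy_table):
    return make_run(toy_table.max_offset_tr + 20, 30, rng)
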