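import numpy as np
import pytest

from ktrkit.trajectory import Trajectory


def make_trajectory(frames, residue_index, segment, residue_name=None,
                    heavy=None):
    """Build a small trajectory from explicit per-frame coordinates."""
    coords = np.asarray(frames, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    n = coords.shape[1]
    if residue_name is None:
        residue_name = ["GLY"] * n
    return Trajectory(coords=coords,
                      residue_index=np.asarray(residue_index),
                      residue_name=np.asarray(residue_name, dtype=object),
                      segment=np.asarray(segment, dtype=object),
                      heavy=heavy)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_pairs(xyz_a, xyz_b, cutoff):
    """O(n^2) reference for pairwise contact detection."""
    pairs = []
    for i, a in enumerate(xyz_a):
        for j, b in enumerate(xyz_b):
            d = float(np.sqrt(((a - b) ** 2).sum()))
            if d < cutoff:
                pairs.append((i, j, d))
    return pairs
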