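"""Shared fixtures and brute-force oracles for the test suite."""

import numpy as np
import pytest
from scipy import ndimage

from alongtract.skeleton import TractVolume


def betti_numbers(vol: np.ndarray) -> tuple[int, int, int]:
    """Brute-force (b0, b1, b2) of a voxel object via its cubical complex.

    Components are counted with 26-connectivity, cavities as bounded
    6-connected background components, and tunnels from the Euler
    characteristic of the union of closed unit cubes:
    chi = V - E + F - C and b1 = b0 + b2 - chi.
    """
    occ = np.pad(np.asarray(vol, dtype=bool), 1)
    b0 = ndimage.label(occ, np.ones((3, 3, 3)))[1]
    b2 = ndimage.label(~occ)[1] - 1
    n_cubes = occ.sum()
    n_faces = 0
    n_edges = 0
    for ax in range(3):
        sh = list(occ.shape)
        sh[ax] += 1
        f = np.zeros(sh, bool)
        sl = [slice(None)] * 3
        sl[ax] = slice(0, occ.shape[ax])
        f[tuple(sl)] |= occ
        sl[ax] = slice(1, None)
        f[tuple(sl)] |= occ
        n_faces += f.sum()
        oth = [i for i in range(3) if i != ax]
        sh = list(occ.shape)
        sh[oth[0]] += 1
        sh[oth[1]] += 1
        e = np.zeros(sh, bool)
        for d0 in (0, 1):
            for d1 in (0, 1):
                idx = [slice(None)] * 3
                idx[oth[0]] = slice(d0, occ.shape[oth[0]] + d0)
                idx[oth[1]] = slice(d1, occ.shape[oth[1]] + d1)
                e[tuple(idx)] |= occ
        n_edges += e.sum()
    sh = [s + 1 for s in occ.shape]
    v = np.zeros(sh, bool)
    for d0 in (0, 1):
        for d1 in (0, 1):
            for d2 in (0, 1):
                v[d0:occ.shape[0] + d0, d1:occ.shape[1] + d1, d2:occ.shape[2] + d2] |= occ
    n_verts = v.sum()
    chi = int(n_verts) - int(n_edges) + int(n_faces) - int(n_cubes)
    return int(b0), int(b0 + b2 - chi), int(b2)


def as_tract_volume(mask: np.ndarray, voxel_mm: float = 1.0) -> TractVolume:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_mm
    return TractVolume(np.asarray(mask, dtype=float), aff, threshold=0.5)


@pytest.fixture(scope="session")
def torus_mask():
    torus = np.zeros((22, 22, 10), bool)
    zz, yy, xx = np.mgrid[0:22, 0:22, 0:10]
    r = np.sqrt((zz - 10.5) ** 2 + (yy - 10.5) ** 2)
    torus[np.sqrt((r - 6) ** 2 + (xx - 4.5) ** 2) < 2.2] = True
    return torus


@pytest.fixture(scope="session")
def line_phantom():
    from alongtract.synthetic import PhantomSpec, make_phantom

    spec = PhantomSpec(curve="line")
    vol, curve, arclen = make_phantom(spec)
    return spec, vol, curve, arclen


@pytest.fixture(scope="session")
def line_skeleton(line_phantom):
    from alongtract.skeleton import skeletonize_tract

    _, vol, _, _ = line_phantom
    return skeletonize_tract(vol, clip_fractions=(0.1, 0.9))
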