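"""Shared fixtures: hand-built frames and traces for the analysis tests."""

from __future__ import annotations

import numpy as np
import pytest

from monosurf.monolayer import MonolayerFrame


def frame_from_marker_points(
    points_xy: np.ndarray,
    box_l: float,
    box_z: float = 8.0,
    z_head: float = 5.0,
) -> MonolayerFrame:
    """One single-chain phospholipid per xy point, C10 marker at the point.

    Minimal but valid monolayer frame (upper leaflet + water) whose packing
    entities are exactly the supplied xy positions.
    """
    points_xy = np.asarray(points_xy, dtype=float)
    n = points_xy.shape[0]
    coords, names, species, resnames, mol_ids = [], [], [], [], []
    for i, (x, y) in enumerate(points_xy):
        for name, dz in (("P", 0.0), ("C1A", 0.2), ("C10A", 1.0), ("C16A", 1.6)):
            coords.append([x, y, z_head + dz])
            names.append(name)
            species.append("DPPC")
            resnames.append("DPPC")
            mol_ids.append(i)
    # Small water slab below the heads to define the midplane.
    for j in range(4):
        coords.append([(j + 0.5) * box_l / 4.0, box_l / 2.0, 4.0])
        names.append("OW")
        species.append("WATER")
        resnames.append("SOL")
        mol_ids.append(n + j)
    return MonolayerFrame(
        coords=np.asarray(coords),
        names=np.asarray(names),
        species=np.asarray(species),
        resnames=np.asarray(resnames),
        mol_ids=np.asarray(mol_ids, dtype=int),
        box=np.array([box_l, box_l, box_z]),
    )


@pytest.fixture
def marker_frame_factory():
    return frame_from_marker_points
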