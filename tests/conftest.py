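"""Shared fixtures: one mid-sized related cohort reused across tests.

The cohort is the parameter-recovery configuration: 80 MZ pairs, 45 DZ
pairs, 80 full-sibling pairs and 90 singletons (500 analysis individuals)
with 2,000 SNPs.  Building it once per session keeps the expensive
replicate-based tests within budget.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import sfcoupling as sfc
from sfcoupling.datatypes import SurfaceMesh


@pytest.fixture(scope="session")
def cohort500():
    ped = sfc.generate_pedigree(80, 45, 80, 90, seed=1)
    geno = sfc.simulate_genotypes(ped, 2000, seed=1)
    K = sfc.compute_grm(geno)
    K_eig = np.linalg.eigh(K.values)
    return {"pedigree": ped, "genotypes": geno, "K": K, "K_eig": K_eig}


@pytest.fixture(scope="session")
def cohort200():
    """Smaller related cohort for calibration-style loops."""
    ped = sfc.generate_pedigree(30, 20, 30, 40, seed=7)
    geno = sfc.simulate_genotypes(ped, 1000, seed=7)
    K = sfc.compute_grm(geno)
    K_eig = np.linalg.eigh(K.values)
    return {"pedigree": ped, "genotypes": geno, "K": K, "K_eig": K_eig}


def flat_mesh(n_vertices: int, hemisphere: str = "L", network: int = 1,
              masked: list[int] | None = None) -> SurfaceMesh:
    """A one-network line mesh for hand-constructed coupling tests."""
    masked = set(masked or [])
    return SurfaceMesh(pd.DataFrame({
        "vertex_id": [f"v{i}" for i in range(n_vertices)],
        "x": np.arange(n_vertices, dtype=float),
        "y": 0.0,
        "z": 0.0,
        "hemisphere": hemisphere,
        "network": network,
        "region": 1,
        "mask": [i in masked for i in range(n_vertices)],
    }))
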