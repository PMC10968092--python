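import numpy as np
import pytest

import ecgforge as ef
from ecgforge.phantom import coarse_geometry
from ecgforge.tissues import DEFAULT_SIGMA, MYOCARDIUM, TissueTable


@pytest.fixture(scope="session")
def mg_cfg():
    return ef.SolverConfig(method="multigrid_preconditioned", tolerance=1e-6)


@pytest.fixture(scope="session")
def torso8():
    """Demo-scale torso phantom (8 mm voxels) shared across the suite."""
    return ef.build_phantom(coarse_geometry(8.0))


@pytest.fixture(scope="session")
def torso8_solution(torso8, mg_cfg):
    """Assembled system, dipole fields, electrode grid and lead pairs for torso8."""
    seq = ef.build_path(torso8, ef.default_path_spec(torso8.heart_centroid_mm()))
    sys_ = ef.assemble(torso8, ef.default_tissue_table())
    fields = ef.solve_sequence(sys_, seq, mg_cfg)
    grid = ef.place_grid(torso8)
    pairs = ef.lead_pairs(grid)
    return {"seq": seq, "sys": sys_, "fields": fields, "grid": grid, "pairs": pairs}


@pytest.fixture(scope="session")
def block24():
    """24^3 homogeneous muscle block with its assembled system (4 mm voxels)."""
    vol = ef.homogeneous_block(24, 4.0)
    return vol, ef.assemble(vol, ef.default_tissue_table())


@pytest.fixture(scope="session")
def heart_block():
    """All-myocardium block on a fine 2 mm grid for path-snapping tests."""
    return ef.homogeneous_block(28, 2.0, tissue=MYOCARDIUM)


@pytest.fixture(scope="session")
def homogeneous_tissues():
    """Every body tissue at 0.2 S/m (air stays 0)."""
    return TissueTable(sigma={k: (0.0 if k == 0 else 0.2) for k in DEFAULT_SIGMA})


@pytest.fixture()
def rng():
    return np.random.default_rng(20240321)
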