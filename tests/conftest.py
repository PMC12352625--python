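import numpy as np
import pytest

from hemelink import synthetic_data as sd
from hemelink import structure_io as sio


@pytest.fixture
def ferric_like_site():
    """Idealized site mimicking a double-crosslinked ferric structure."""
    spec = sd.PorphyrinSpec(
        fe_oop=0.11,
        fe_his_n=2.11,
        fe_water=2.15,
        lys_nz_cha=1.40,
        lys_cd_c2a=1.58,
        c3a_cma=1.33,
        seed=11,
    )
    structure, truth = sd.make_porphyrin(spec)
    return spec, structure, truth


@pytest.fixture
def ferrous_like_site():
    """Idealized site mimicking a single-crosslinked ferrous structure."""
    spec = sd.PorphyrinSpec(
        fe_oop=0.35,
        fe_his_n=2.10,
        fe_water=3.33,
        lys_nz_cha=1.44,
        lys_cd_c2a=3.70,
        c3a_cma=1.53,
        seed=12,
    )
    structure, truth = sd.make_porphyrin(spec)
    return spec, structure, truth


@pytest.fixture
def mapped_site(ferric_like_site):
    _, structure, _ = ferric_like_site
    return structure, sio.map_haem_site(structure, "A")


def random_rigid_motion(rng):
    """A uniformly random rotation matrix and a translation vector."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-50.0, 50.0, size=3)
    return rot, trans


def apply_rigid_motion(structure, rot, trans):
    from dataclasses import replace

    models = [
        [replace(a, pos=rot @ a.pos + trans) for a in atoms]
        for atoms in structure.models
    ]
    return sio.Structure(
        models=models, source_format=structure.source_format, id=structure.id
    )
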