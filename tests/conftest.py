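import numpy as np
import pytest
import trimesh

from electrolocate import (
    PhantomSpec,
    Surface,
    auto_detect,
    build_surfaces,
    interior_mask,
    make_head_phantom,
)

# Test-scale study conditions: same tissue/intensity model as the default
# phantom, on a smaller grid at 0.5 mm so the full pipeline runs in seconds.
SMALL_KW = dict(
    grid_shape=(104, 104, 88),
    voxel_mm=0.5,
    brain_radii_mm=(20.0, 22.0, 18.0),
    gray_shell_mm=5.5,
)


def small_spec(seed: int = 0, **overrides) -> PhantomSpec:
    kw = dict(SMALL_KW)
    kw.update(overrides)
    return PhantomSpec(seed=seed, **kw)


class PhantomBundle:
    """One fully processed phantom shared across tests."""

    def __init__(self, spec):
        self.spec = spec
        (
            self.ct,
            self.gm,
            self.wm,
            self.atlas,
            (self.forward, self.inverse),
            self.truth,
        ) = make_head_phantom(spec)
        self.brain, self.projection = build_surfaces(self.gm, self.wm)
        self.inside = interior_mask(self.projection, self.ct)
        self.detection = auto_detect(self.ct, self.projection, inside=self.inside)


@pytest.fixture(scope="session")
def bundle() -> PhantomBundle:
    return PhantomBundle(small_spec(seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def sphere_surface(radius_mm=20.0, center=(0.0, 0.0, 0.0), subdivisions=3, kind="projection"):
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius_mm)
    return Surface(np.asarray(tm.vertices) + np.asarray(center), np.asarray(tm.faces), kind=kind)


@pytest.fixture()
def sphere_mesh() -> Surface:
    return sphere_surface()
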