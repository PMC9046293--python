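import numpy as np
import pytest

from cytoparcel import AreaSpec, RibbonGeometry
from cytoparcel.pipeline import DEFAULT_AREAS


@pytest.fixture(scope="session")
def two_areas() -> tuple[AreaSpec, AreaSpec]:
    return DEFAULT_AREAS


@pytest.fixture(scope="session")
def small_geometry() -> RibbonGeometry:
    """A compact annulus-sector ribbon that still carries ~120 traverses."""
    return RibbonGeometry(outer_radius_um=1200.0, thickness_um=400.0,
                          arc_deg=92.0, traverse_spacing_um=16.0)


@pytest.fixture(scope="session")
def laminar_section(two_areas, small_geometry):
    """One synthetic two-area section (expensive: built once per session)."""
    from cytoparcel import generate_section

    section, truth = generate_section(
        list(two_areas), small_geometry, pixel_size_um=2.0, seed=11,
        section_id="fixture",
    )
    return section, truth


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
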