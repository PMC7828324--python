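import numpy as np
import pytest

from leukomorph.imagegen import CellSpec, SceneSpec, render_scene, single_cell_crop


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def disk_crop():
    """Clean crop with one planted disk (diameter 80)."""
    cell = CellSpec(center=(0, 0), shape_kind="disk", major_axis=80, minor_axis=80)
    return single_cell_crop(cell, seed=101)


@pytest.fixture(scope="session")
def ellipse_crop():
    """Clean crop with one planted 2:1 ellipse (80x40), tilted."""
    cell = CellSpec(
        center=(0, 0), shape_kind="ellipse", major_axis=80, minor_axis=40,
        orientation=0.6,
    )
    return single_cell_crop(cell, seed=102)


@pytest.fixture(scope="session")
def worm_crop():
    """Clean crop with one planted 3:1 worm."""
    cell = CellSpec(
        center=(0, 0), shape_kind="worm", major_axis=110, minor_axis=36,
        orientation=0.4, activation="activated",
    )
    return single_cell_crop(cell, seed=103)


@pytest.fixture(scope="session")
def simple_scene():
    """3 interior disks + 1 edge-crossing disk + 1 adhered pair, 512x512."""
    cells = (
        CellSpec(center=(100, 100), shape_kind="disk", major_axis=56, minor_axis=56),
        CellSpec(center=(250, 300), shape_kind="disk", major_axis=48, minor_axis=48),
        CellSpec(center=(400, 120), shape_kind="disk", major_axis=60, minor_axis=60),
        CellSpec(center=(10, 400), shape_kind="disk", major_axis=56, minor_axis=56),
        CellSpec(center=(380, 380), shape_kind="disk", major_axis=56, minor_axis=56),
        CellSpec(center=(380, 420), shape_kind="disk", major_axis=56, minor_axis=56),
    )
    spec = SceneSpec(cells=cells, seed=42)
    frame, gt = render_scene(spec)
    return spec, frame, gt
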