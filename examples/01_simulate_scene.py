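"""Render a synthetic bright-field frame and inspect its ground truth.

The generator plants textured cell blobs (darker than the illuminated
background) and reports, per cell, its bounding box plus whether it touches
the frame edge or overlaps a neighbour — the two situations the screening
stage must reject.
"""

from leukomorph import CellSpec, SceneSpec, render_scene

cells = (
    CellSpec(center=(100, 100), shape_kind="disk", major_axis=56, minor_axis=56),
    CellSpec(center=(250, 300), shape_kind="worm", major_axis=110, minor_axis=36,
             orientation=0.5, activation="activated"),
    CellSpec(center=(10, 400), shape_kind="disk", major_axis=56, minor_axis=56),
)
frame, truth = render_scene(SceneSpec(cells=cells, seed=42))

print(f"frame {frame.shape[0]}x{frame.shape[1]}, gray levels "
      f"{frame.min()}..{frame.max()} (bright background ~200, cells ~120)")
for i, rec in enumerate(truth.cells):
    print(f"cell {i}: {rec.spec.shape_kind:5s} bbox={rec.bbox} "
          f"edge={rec.touches_edge} adhered_group={rec.adhered_group_id}")
# The disk at (10, 400) straddles the top border, so its edge flag is True:
# segmentation must drop it, keeping only whole, isolated cells.
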