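"""Segment a frame into screened single-cell crops.

Otsu's threshold splits the gray-level histogram where the between-class
variance w1*w2*(mu1-mu2)^2 peaks; after open/close cleanup, each connected
component becomes a contour, and contours touching the edge, outside the
area bounds, or with a pinched (low-solidity) outline are rejected.
"""

from leukomorph import DatasetConfig, ScreeningParams, make_dataset, otsu_threshold, segment_frame

frames, manifest = make_dataset(
    DatasetConfig(class_counts={"granulocyte": 6}, activated_fraction=0.0,
                  edge_cells=1, adhered_pairs=1),
    out_dir=None, seed=7,
)
frame, _ = frames[0]  # the frame holding the edge and adhered challenges

stats = otsu_threshold(frame)
print(f"Otsu threshold g={stats.g}: {stats.omega1:.0%} of pixels below "
      f"(cells, mean {stats.mu1:.0f}) vs {stats.omega2:.0%} above "
      f"(background, mean {stats.mu2:.0f})")

crops, index = segment_frame(frame, params=ScreeningParams(max_area=3450))
print(index[["cell_id", "area_px", "perimeter_px", "rejected_reason"]].to_string(index=False))
print(f"{len(crops)} crops kept — the edge-touching cell and the merged "
      "adhered pair were screened out.")
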