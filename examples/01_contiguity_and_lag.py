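"""Queen contiguity and adjacent locality deprivation (ALD) on a small grid.

Builds a 3x3 block of unit-square areas two ways (from polygons and from
the grid shortcut), then computes each area's ALD — the mean deprivation of
its queen-contiguous neighbours.
"""

import pandas as pd
from shapely.geometry import box

from deprivdiff import queen_from_grid, queen_from_polygons, spatial_lag

# queen contiguity: shared boundary OR shared corner makes a neighbour
polygons = {f"r{i}c{j}": box(j, i, j + 1, i + 1) for i in range(3) for j in range(3)}
graph = queen_from_polygons(polygons)
assert graph.neighbours == queen_from_grid(3, 3).neighbours

print("degrees:", {n: graph.degree(n) for n in graph.nodes})
# corners touch 3 areas, edge cells 5, the centre all 8

imd = pd.Series(
    {n: 10.0 for n in graph.nodes} | {"r1c1": 50.0}  # one deprived centre
)
lag = spatial_lag(imd, graph)
print("\nALD (neighbour-mean deprivation):")
print(lag.ald.round(2).to_string())
# the centre's ALD is 10 (its neighbours are all affluent); each corner's
# ALD is pulled up to 23.3 by the deprived centre: the centre is much more
# deprived than its surroundings, its neighbours slightly less affluent
# than theirs
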