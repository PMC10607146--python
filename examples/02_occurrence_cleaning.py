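"""Clean a noisy occurrence dataset: deduplicate, drop uncertain
coordinates, spatially rarefy, and split into native/introduced populations.

Simulates records with duplicates and mixed coordinate uncertainty, then
runs the standard cleaning chain: one record per coordinate, records with
uncertainty over 5 km removed (missing uncertainty retained), and greedy
5-km rarefaction so no two retained records are closer than 5 km.
"""

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

import vectorshift as vs

rng = np.random.default_rng(0)
n = 400
lon = np.concatenate([rng.uniform(0, 1.0, n), rng.uniform(0, 1.0, 50)])
lat = np.concatenate([rng.uniform(0, 1.0, n), rng.uniform(0, 1.0, 50)])
lon[:50] = lon[n:n + 50]  # duplicated coordinates
lat[:50] = lat[n:n + 50]
uncertainty = rng.choice([1.0, 3.0, 8.0, np.nan], size=n + 50, p=[0.4, 0.3, 0.2, 0.1])

occ = vs.OccurrenceSet(pd.DataFrame({
    "lon": lon, "lat": lat, "uncertainty_km": uncertainty,
    "source": "simulated", "population": "unassigned",
}))
print(f"raw records:            {len(occ)}")

occ = vs.deduplicate(occ)
print(f"after deduplication:    {len(occ)}")

occ = vs.filter_uncertainty(occ, max_km=5.0)
print(f"after 5-km uncertainty: {len(occ)} (records over 5 km removed)")

occ = vs.spatial_thin(occ, radius_km=5.0, seed=42)
print(f"after 5-km rarefaction: {len(occ)} (min pairwise distance >= 5 km)")

native_region = Polygon([(0, 0), (0.5, 0), (0.5, 1), (0, 1)])
native, introduced = vs.split_populations(occ, native_region)
print(f"native: {len(native)}, introduced: {len(introduced)} "
      f"(split by the native-region polygon)")
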