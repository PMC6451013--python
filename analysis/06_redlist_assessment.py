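#!/usr/bin/env python
"""Geospatial red-listing: dedupe occurrence records by locality, compute
EOO (convex hull, equal-area projection) and AOO (2-km occupancy grid),
and classify under IUCN criterion B with declared B2 subconditions.
Writes results/redlist.json."""

import json
from pathlib import Path

from congenstatus.geospatial import (aoo_area, dedupe_records, eoo_area,
                                     iucn_criterion_b, read_occurrences)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    occ = dedupe_records(read_occurrences(OUT / "occurrences.csv"))
    eoo, _hull = eoo_area(occ)
    aoo, cells, scan = aoo_area(occ, origin_scan=True)
    assess = iucn_criterion_b(eoo, aoo, fragmentation_flag=True,
                              decline_flag=True, cell_count=cells)
    report = {
        "records": len(occ),
        "eoo_km2": round(assess.eoo_km2, 1),
        "aoo_km2": assess.aoo_km2,
        "occupied_cells": cells,
        "aoo_grid_origin_sensitivity": scan,
        "eoo_category": assess.eoo_category,
        "aoo_category": assess.aoo_category,
        "final_category": assess.final_category,
    }
    (OUT / "redlist.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"{len(occ)} records: EOO = {report['eoo_km2']:.0f} km^2 "
          f"({assess.eoo_category}), AOO = {aoo:.0f} km^2 over {cells} "
          f"cells ({assess.aoo_category})")
    print(f"criterion-B category with declared fragmentation + decline: "
          f"{assess.final_category}")


if __name__ == "__main__":
    main()
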