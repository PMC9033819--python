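"""Management zoning from significant LISA clusters.

Significant L-L units (low quality surrounded by low) become the
management zone needing active rehabilitation; significant H-H units the
close-attention zone (good quality at risk from future mining);
significant spatial outliers (H-L or L-H) the protective zone.  Units
without a significant cluster get an explicit "none" label so that area
accounting covers every retained unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spatial_stats import LisaResult

MANAGEMENT = "management"
CLOSE_ATTENTION = "close_attention"
PROTECTIVE = "protective"
NONE = "none"

_LABEL_TO_ZONE = {"L-L": MANAGEMENT, "H-H": CLOSE_ATTENTION,
                  "H-L": PROTECTIVE, "L-H": PROTECTIVE}


@dataclass
class ZoningMap:
    zones: np.ndarray            # per-unit zone label
    counts: dict[str, int]
    positions: np.ndarray | None = None


def classify_zones(lisa: LisaResult) -> ZoningMap:
    """Pure function of the LISA labels; deterministic by construction."""
    zones = np.array([_LABEL_TO_ZONE.get(lab, NONE)
                      for lab in lisa.cluster_label], dtype=object)
    counts = {z: int(np.sum(zones == z))
              for z in (MANAGEMENT, CLOSE_ATTENTION, PROTECTIVE, NONE)}
    return ZoningMap(zones=zones, counts=counts, positions=lisa.positions)
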